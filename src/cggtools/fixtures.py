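"""Synthetic proteome generator with machine-readable ground truth.

Every other module is tested against fixtures built here: random protein
sequences drawn uniformly over the 20 standard residues (the simplest null
model — compositional bias exists only where an implant puts it, so ground
truth is exact), with optional implanted low-complexity tracts, planted
protein-family groups sharing an identical core segment, and constructed
gene-fusion trios (component A, component B, composite = A-segment +
linker + B-segment).

Identical seeds yield byte-identical output: generation is a pure function
of the :class:`FixtureSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .io import STANDARD_AA, SequenceRecord

# geometry of constructed features, in residues
_FAMILY_FLANK = 20
_FAMILY_CORE = 80
_COMPONENT_LEN = 120
_LINKER_LEN = 15


@dataclass
class LcrImplant:
    """A homopolymer tract overwriting a span of one background record."""

    record_index: int
    start: int  # 1-based inclusive
    end: int
    residue: str


@dataclass
class FixtureSpec:
    """Recipe for one synthetic proteome.

    ``lcr_implants`` entries may be :class:`LcrImplant` instances or plain
    ``(record_index, start, end, residue)`` tuples (1-based inclusive span).
    """

    n_sequences: int = 30
    length_range: tuple[int, int] = (80, 200)
    seed: int = 0
    lcr_implants: list = field(default_factory=list)
    fusion_trios: int = 0
    family_groups: int = 0


@dataclass
class TruthRow:
    """One implanted feature: ``kind record_id start end detail``."""

    kind: str  # lcr | family | fusion_component | fusion_composite
    record_id: str
    start: int  # 1-based inclusive
    end: int
    detail: str


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(STANDARD_AA), size=length))


def make_fixture(spec: FixtureSpec) -> tuple[list[SequenceRecord], list[TruthRow]]:
    """Generate the fixture proteome and its truth table.

    Background records come first (``SYN00000`` …), then family groups
    (``FAM00A``/``B``/``C``), then fusion trios (``FUS00A``/``B``/``C``
    with ``C`` the composite).
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    if not (0 < lo <= hi):
        raise ValueError(f"bad length_range {spec.length_range}")

    records: list[SequenceRecord] = []
    truth: list[TruthRow] = []

    for i in range(spec.n_sequences):
        length = int(rng.integers(lo, hi + 1))
        records.append(
            SequenceRecord(
                id=f"SYN{i:05d}",
                description="synthetic background protein",
                residues=_random_protein(rng, length),
            )
        )

    for implant in spec.lcr_implants:
        if isinstance(implant, LcrImplant):
            idx, start, end, residue = (
                implant.record_index,
                implant.start,
                implant.end,
                implant.residue,
            )
        else:
            idx, start, end, residue = implant
        rec = records[idx]
        if not (1 <= start <= end <= len(rec.residues)):
            raise ValueError(
                f"implant span {start}-{end} exceeds record {rec.id} "
                f"(length {len(rec.residues)})"
            )
        if residue not in STANDARD_AA:
            raise ValueError(f"implant residue {residue!r} not a standard amino acid")
        s = rec.residues
        rec.residues = s[: start - 1] + residue * (end - start + 1) + s[end:]
        truth.append(TruthRow("lcr", rec.id, start, end, residue))

    for g in range(spec.family_groups):
        core = _random_protein(rng, _FAMILY_CORE)
        for m, tag in enumerate("ABC"):
            left = _random_protein(rng, _FAMILY_FLANK)
            right = _random_protein(rng, _FAMILY_FLANK)
            rid = f"FAM{g:02d}{tag}"
            records.append(
                SequenceRecord(
                    id=rid,
                    description=f"synthetic family member (group {g})",
                    residues=left + core + right,
                )
            )
            truth.append(
                TruthRow(
                    "family",
                    rid,
                    _FAMILY_FLANK + 1,
                    _FAMILY_FLANK + _FAMILY_CORE,
                    f"FAMGROUP{g:02d}",
                )
            )

    for t in range(spec.fusion_trios):
        a = _random_protein(rng, _COMPONENT_LEN)
        b = _random_protein(rng, _COMPONENT_LEN)
        linker = _random_protein(rng, _LINKER_LEN)
        a_id, b_id, c_id = f"FUS{t:02d}A", f"FUS{t:02d}B", f"FUS{t:02d}C"
        # the composite carries both components in full (complete-protein
        # fusion), so each component's alignment span on the composite is
        # sharply bounded by the component itself
        composite = a + linker + b
        records.append(
            SequenceRecord(a_id, f"synthetic fusion component A (trio {t})", a)
        )
        records.append(
            SequenceRecord(b_id, f"synthetic fusion component B (trio {t})", b)
        )
        records.append(
            SequenceRecord(c_id, f"synthetic fusion composite (trio {t})", composite)
        )
        truth.append(TruthRow("fusion_component", c_id, 1, _COMPONENT_LEN, a_id))
        truth.append(
            TruthRow(
                "fusion_component",
                c_id,
                _COMPONENT_LEN + _LINKER_LEN + 1,
                2 * _COMPONENT_LEN + _LINKER_LEN,
                b_id,
            )
        )
        truth.append(
            TruthRow(
                "fusion_composite", c_id, 1, len(composite), f"{a_id},{b_id}"
            )
        )

    return records, truth


def write_truth_table(rows: Iterable[TruthRow], path: str | Path) -> None:
    """Write the truth table as TSV: kind, record_id, start, end, detail."""
    with open(path, "wt") as fh:
        for r in rows:
            fh.write(f"{r.kind}\t{r.record_id}\t{r.start}\t{r.end}\t{r.detail}\n")


def read_truth_table(path: str | Path) -> list[TruthRow]:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            kind, rid, start, end, detail = line.rstrip("\n").split("\t")
            rows.append(TruthRow(kind, rid, int(start), int(end), detail))
    return rows
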