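"""MD5 sequence fingerprinting for identity mapping across collections.

Two protein entries are the same molecule exactly when their canonicalized
residue strings are equal; the MD5 digest of those residues (ASCII bytes,
nothing else — no header, no terminator) is therefore a fixed-length proxy
for sequence identity that lets whole collections be cross-indexed in one
pass. MD5 is a deliberate choice despite its cryptographic weakness: the
job is identity mapping, not security. A genuine digest collision between
unequal sequences, should one ever appear, is raised loudly rather than
silently merged.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .io import SequenceRecord, canonicalize


class FingerprintCollisionError(RuntimeError):
    """Two unequal sequences produced the same digest."""


@dataclass
class MatchRow:
    fingerprint: str
    ids_a: list[str]
    ids_b: list[str]


def fingerprint(record: SequenceRecord) -> str:
    """32-character lowercase hex MD5 of the canonical residues.

    Independent of id and description; equal canonical residues give equal
    fingerprints, and (collisions aside) conversely.
    """
    residues = canonicalize(record.residues)
    return hashlib.md5(residues.encode("ascii")).hexdigest()


def build_index(records: Iterable[SequenceRecord]) -> dict[str, list[str]]:
    """Group record ids by fingerprint, insertion order preserved.

    Raises :class:`FingerprintCollisionError` if two records share a
    fingerprint but differ in canonical residues.
    """
    index: dict[str, list[str]] = {}
    witness: dict[str, str] = {}
    for rec in records:
        residues = canonicalize(rec.residues)
        fp = hashlib.md5(residues.encode("ascii")).hexdigest()
        if fp in witness:
            if witness[fp] != residues:
                raise FingerprintCollisionError(
                    f"MD5 collision: {rec.id!r} vs ids {index[fp]} "
                    f"share fingerprint {fp} with unequal sequences"
                )
            index[fp].append(rec.id)
        else:
            witness[fp] = residues
            index[fp] = [rec.id]
    return index


def cross_match(
    set_a: Sequence[SequenceRecord], set_b: Sequence[SequenceRecord]
) -> list[MatchRow]:
    """Cross-index two collections at the sequence level.

    One row per fingerprint present in either set, in first-seen order
    (A scanned before B); rows populated on both sides are the entries
    shared between the collections. Every input id appears in exactly one
    row, so the table is a partition refinement of both inputs.
    """
    idx_a = build_index(set_a)
    idx_b = build_index(set_b)
    rows: list[MatchRow] = []
    for fp in dict.fromkeys(list(idx_a) + list(idx_b)):
        rows.append(MatchRow(fp, list(idx_a.get(fp, [])), list(idx_b.get(fp, []))))
    return rows


def shared_rows(table: Iterable[MatchRow]) -> list[MatchRow]:
    """Rows with at least one id on each side (the shared sequences)."""
    return [r for r in table if r.ids_a and r.ids_b]


def write_index(index: dict[str, list[str]], path: str | Path) -> None:
    """TSV ``fingerprint<TAB>id``, one line per record."""
    with open(path, "wt") as fh:
        for fp, ids in index.items():
            for rid in ids:
                fh.write(f"{fp}\t{rid}\n")


def write_cross(table: Iterable[MatchRow], path: str | Path) -> None:
    """TSV ``fingerprint<TAB>ids_A(comma)<TAB>ids_B(comma)``."""
    with open(path, "wt") as fh:
        for row in table:
            fh.write(f"{row.fingerprint}\t{','.join(row.ids_a)}\t{','.join(row.ids_b)}\n")
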