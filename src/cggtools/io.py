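"""Readers and writers for the two carrier formats of the toolkit.

Everything downstream flows through two plain-text formats: FASTA protein
collections and the 12-column tabular pairs-list produced by ``blastp
-outfmt 6`` (and compatible search tools, including :mod:`cggtools.align`).
Coordinates are 1-based inclusive at every file interface, matching BLAST
tabular; any 0-based arithmetic is confined to the modules that need it.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid letters, alphabetical.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguity / rare-residue letters tolerated in real data and passed through.
AMBIGUOUS_AA = "BZJUOX"
_ALLOWED = frozenset(STANDARD_AA + AMBIGUOUS_AA)

FASTA_WRAP = 60


class SequenceError(ValueError):
    """A residue string violates the admission rules."""


class FastaError(ValueError):
    """A FASTA file is malformed."""


class PairsListError(ValueError):
    """A tabular pairs-list line is malformed."""


@dataclass
class SequenceRecord:
    """One protein sequence: identifier, free-text description, residues.

    ``id`` is the first whitespace-delimited token of the FASTA header;
    ``description`` is the remainder (possibly empty).
    """

    id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SequenceError(
                f"record id {self.id!r} must be a non-empty whitespace-free token"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SimilarityEdge:
    """One directed hit of a sequence comparison (a pairs-list row).

    Field order mirrors the 12 columns of BLAST tabular output
    (qseqid, sseqid, pident, length, mismatch, gapopen, qstart, qend,
    sstart, send, evalue, bitscore). Coordinates are 1-based inclusive.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    line_number: int | None = None

    def __post_init__(self) -> None:
        # orientation normalization: protein coordinates are always forward
        if self.q_start > self.q_end:
            self.q_start, self.q_end = self.q_end, self.q_start
        if self.s_start > self.s_end:
            self.s_start, self.s_end = self.s_end, self.s_start
        if self.evalue < 0:
            raise PairsListError(
                f"negative E-value {self.evalue} for {self.query_id}->{self.subject_id}"
            )


def canonicalize(residues: str) -> str:
    """Normalize a residue string for analysis.

    Uppercases, removes all whitespace, strips a single trailing stop
    ``*``, and rejects internal stops, unknown letters and empty results.
    Idempotent: applying it twice equals applying it once.
    """
    s = "".join(residues.split()).upper()
    if s.endswith("*"):
        s = s[:-1]
    if "*" in s:
        raise SequenceError(f"internal stop '*' at position {s.index('*') + 1}")
    if not s:
        raise SequenceError("empty sequence after canonicalization")
    bad = sorted(set(s) - _ALLOWED)
    if bad:
        raise SequenceError(f"unknown residue letters: {''.join(bad)}")
    return s


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path, canonical: bool = True) -> list[SequenceRecord]:
    """Read a protein FASTA file into a list of :class:`SequenceRecord`.

    Input order is preserved. Duplicate ids are permitted with a warning;
    modules that index by id fail fast on them instead. With ``canonical``
    (the default) residues are passed through :func:`canonicalize`.
    """
    path = Path(path)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaError(
                        f"{path}: line {lineno}: expected '>' to start the first record"
                    )
                break
        else:
            raise FastaError(f"{path}: empty FASTA file")

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for ordinal, (title, seq) in enumerate(SimpleFastaParser(fh), 1):
            parts = title.split(maxsplit=1)
            if not parts:
                raise FastaError(f"{path}: record {ordinal}: empty header")
            rid = parts[0]
            desc = parts[1] if len(parts) == 2 else ""
            if not seq:
                raise FastaError(f"{path}: record {ordinal} ({rid!r}): empty sequence")
            if canonical:
                try:
                    seq = canonicalize(seq)
                except SequenceError as exc:
                    raise FastaError(
                        f"{path}: record {ordinal} ({rid!r}): {exc}"
                    ) from exc
            if rid in seen:
                logger.warning("%s: duplicate record id %r", path, rid)
            seen.add(rid)
            records.append(SequenceRecord(id=rid, description=desc, residues=seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA, sequences wrapped at 60 columns."""
    with open(path, "wt") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), FASTA_WRAP):
                fh.write(rec.residues[i : i + FASTA_WRAP] + "\n")


def parse_pairslist(
    path: str | Path, dialect: str = "blast12"
) -> list[SimilarityEdge]:
    """Parse a 12-column tabular pairs-list into :class:`SimilarityEdge` rows.

    ``dialect`` is ``blast12`` (pure data lines) or ``blast12_commented``
    (``#``-prefixed lines skipped, as written by ``-outfmt 7`` or by this
    package's own search driver). Line numbers are retained on each edge
    for error reporting. Self-hits are parsed and retained; downstream
    stages decide what to do with them.
    """
    if dialect not in ("blast12", "blast12_commented"):
        raise ValueError(f"unknown pairs-list dialect {dialect!r}")
    path = Path(path)
    edges: list[SimilarityEdge] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if dialect == "blast12_commented":
                    continue
                raise PairsListError(
                    f"{path}: line {lineno}: comment line not allowed in dialect 'blast12'"
                )
            fields = line.split("\t")
            if len(fields) != 12:
                raise PairsListError(
                    f"{path}: line {lineno}: expected 12 tab-separated fields, got {len(fields)}"
                )
            try:
                edge = SimilarityEdge(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    line_number=lineno,
                )
            except ValueError as exc:
                raise PairsListError(
                    f"{path}: line {lineno}: non-numeric field ({exc})"
                ) from exc
            edges.append(edge)
    return edges


def write_pairslist(
    edges: Iterable[SimilarityEdge],
    path: str | Path,
    comments: Iterable[str] = (),
) -> None:
    """Write edges in the 12-column tabular dialect.

    ``comments`` lines, if any, are emitted with a ``#`` prefix; files with
    comments must be read back with dialect ``blast12_commented``.
    """
    with open(path, "wt") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        for e in edges:
            fh.write(
                "\t".join(
                    [
                        e.query_id,
                        e.subject_id,
                        f"{e.percent_identity:.2f}",
                        str(e.aln_length),
                        str(e.mismatches),
                        str(e.gap_opens),
                        str(e.q_start),
                        str(e.q_end),
                        str(e.s_start),
                        str(e.s_end),
                        f"{e.evalue:.3g}",
                        f"{e.bitscore:g}",
                    ]
                )
                + "\n"
            )


def records_by_id(records: Iterable[SequenceRecord]) -> dict[str, SequenceRecord]:
    """Index records by id, failing fast on duplicates."""
    out: dict[str, SequenceRecord] = {}
    for rec in records:
        if rec.id in out:
            raise SequenceError(f"duplicate record id {rec.id!r}")
        out[rec.id] = rec
    return out
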