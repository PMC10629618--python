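"""Selective masking of compositionally biased (low-complexity) tracts.

A tract biased toward residue ``r`` is exactly a high-scoring local
alignment of the sequence against an unbounded homopolymer of ``r`` under
infinite gap penalties: no optimal alignment can afford a gap, so the
problem reduces — exactly — to the maximum-scoring contiguous segment of
per-position substitution scores ``s_i = matrix(residue_i, r)``. Detection
runs that reduction for all 20 homopolymer targets, takes the best segment,
and if it reaches the score threshold masks the offending residue's
occurrences inside the span on a working copy, then repeats; multiple
passes let weaker tracts of other residue types emerge once a dominant
tract is neutralized. Masking is *selective*: only the biased residue is
replaced, other residues inside the span survive, and sequence length
never changes.

Default threshold 40 over BLOSUM62 with mask character ``X`` (which scores
negatively against every homopolymer, so a fully masked sequence is a
fixed point of detection).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Align import substitution_matrices

from .io import STANDARD_AA, SequenceRecord
from .align import load_matrix

DEFAULT_THRESHOLD = 40
DEFAULT_MASK_CHAR = "X"


@dataclass
class MaskedRegion:
    """A detected low-complexity tract (span 1-based inclusive)."""

    residue: str
    start: int
    end: int
    score: int
    pass_index: int


@dataclass
class MaskReport:
    """Aggregate statistics and geometry of detected tracts."""

    regions_by_record: dict[str, list[MaskedRegion]]
    regions_per_residue: Counter = field(default_factory=Counter)
    span_length_histogram: Counter = field(default_factory=Counter)
    total_masked_positions: int = 0
    total_residues: int = 0

    @property
    def fraction_masked(self) -> float:
        if self.total_residues == 0:
            return 0.0
        return self.total_masked_positions / self.total_residues

    @property
    def n_regions(self) -> int:
        return sum(len(v) for v in self.regions_by_record.values())


def homopolymer_targets() -> str:
    """The homopolymer comparison targets: one per standard residue (20)."""
    return STANDARD_AA


def homopolymer_segment(
    residues: str,
    target_residue: str,
    matrix: substitution_matrices.Array | None = None,
) -> tuple[int, int | None, int | None]:
    """Best local alignment of ``residues`` vs an unbounded homopolymer.

    With infinite gap penalties this is the maximum-scoring contiguous
    segment of position scores. Returns ``(score, start, end)`` with a
    1-based inclusive span, or ``(0, None, None)`` when every segment
    scores negatively. Ties go to the leftmost, then shortest, segment.
    """
    if not residues:
        raise ValueError("empty sequence")
    if matrix is None:
        matrix = load_matrix()
    best_score = 0
    best_span: tuple[int | None, int | None] = (None, None)
    run = 0
    run_start = 0
    for i, res in enumerate(residues):
        s = int(matrix[res, target_residue])
        if run < 0:  # zero-sum prefixes are kept: leftmost-start tie rule
            run = s
            run_start = i
        else:
            run += s
        if run > best_score:
            best_score = run
            best_span = (run_start + 1, i + 1)
    return best_score, best_span[0], best_span[1]


def detect(
    record: SequenceRecord,
    matrix: substitution_matrices.Array | None = None,
    threshold: int = DEFAULT_THRESHOLD,
    mask_char: str = DEFAULT_MASK_CHAR,
) -> list[MaskedRegion]:
    """Iteratively detect biased tracts in one record.

    Each pass scores all 20 homopolymer targets on the current working
    sequence; the best segment (ties broken by alphabetical residue) is
    recorded if it reaches ``threshold``, its offending residue is masked
    inside the span on the working copy, and the next pass runs. Spans are
    reported in original coordinates (masking never shifts positions).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if matrix is None:
        matrix = load_matrix()
    work = list(record.residues)
    regions: list[MaskedRegion] = []
    pass_index = 1
    while True:
        seq = "".join(work)
        best: tuple[int, str, int, int] | None = None
        for aa in STANDARD_AA:
            score, start, end = homopolymer_segment(seq, aa, matrix)
            if score >= threshold and (best is None or score > best[0]):
                best = (score, aa, start, end)
        if best is None:
            break
        score, aa, start, end = best
        regions.append(
            MaskedRegion(residue=aa, start=start, end=end, score=score,
                         pass_index=pass_index)
        )
        masked_any = False
        for i in range(start - 1, end):
            if work[i] == aa:
                work[i] = mask_char
                masked_any = True
        if not masked_any:
            # a segment can reach the threshold on near-neighbour scores
            # alone; without an occurrence to mask the pass cannot progress
            break
        pass_index += 1
    return regions


def mask(
    record: SequenceRecord,
    regions: Sequence[MaskedRegion],
    mask_char: str = DEFAULT_MASK_CHAR,
) -> SequenceRecord:
    """Apply selective masking: within each region, replace only that
    region's offending residue by ``mask_char``. Length is preserved."""
    work = list(record.residues)
    for region in regions:
        if not (1 <= region.start <= region.end <= len(work)):
            raise ValueError(
                f"region {region.start}-{region.end} out of bounds for "
                f"{record.id} (length {len(work)})"
            )
        for i in range(region.start - 1, region.end):
            if record.residues[i] == region.residue:
                work[i] = mask_char
    return SequenceRecord(record.id, record.description, "".join(work))


def masked_positions(record: SequenceRecord, regions: Sequence[MaskedRegion]) -> set[int]:
    """0-based positions that selective masking would replace."""
    out: set[int] = set()
    for region in regions:
        for i in range(region.start - 1, region.end):
            if record.residues[i] == region.residue:
                out.add(i)
    return out


def report(
    records: Sequence[SequenceRecord],
    all_regions: Mapping[str, Sequence[MaskedRegion]],
) -> MaskReport:
    """Aggregate the statistics and geometry of detected tracts."""
    rep = MaskReport(regions_by_record={k: list(v) for k, v in all_regions.items()})
    by_id = {r.id: r for r in records}
    rep.total_residues = sum(len(r.residues) for r in records)
    for rid, regions in all_regions.items():
        for region in regions:
            rep.regions_per_residue[region.residue] += 1
            rep.span_length_histogram[region.end - region.start + 1] += 1
        rep.total_masked_positions += len(masked_positions(by_id[rid], regions))
    return rep


def write_regions(
    all_regions: Mapping[str, Sequence[MaskedRegion]], path: str | Path
) -> None:
    """TSV ``record_id residue start end score pass`` (1-based inclusive)."""
    with open(path, "wt") as fh:
        for rid, regions in all_regions.items():
            for r in regions:
                fh.write(
                    f"{rid}\t{r.residue}\t{r.start}\t{r.end}\t{r.score}\t{r.pass_index}\n"
                )
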