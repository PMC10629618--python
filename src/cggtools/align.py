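"""Shared Smith-Waterman machinery: scoring matrix, local alignment, search.

The local aligner is Bio.Align.PairwiseAligner in local mode with affine
gaps. Gap costs follow the BLASTP convention: a gap of length k costs
``gap_open + k * gap_extend`` (defaults 11/1). The packaged BLOSUM62 is
extended over the ambiguity letters (B, Z, J, U, O, X) with a flat
fallback score of -1 for any pair involving a non-standard letter, so
masked residues (``X``) score non-positively against everything — the
property the masking stage's fixed point relies on.

The internal all-vs-all / query-vs-reference drivers exist so the whole
pipeline can run without external BLAST. They emit raw Smith-Waterman
scores in the bitscore column; the evalue column carries a monotone
transform of the score (``10**(-score/10)``), not a Karlin-Altschul
calibrated E-value, and files written by the drivers say so in a comment
header. Thresholds downstream accept either a minimal score or a maximal
E-value, so either column can drive filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .io import STANDARD_AA, SequenceRecord, SimilarityEdge

#: Alphabet of the extended scoring matrix.
MATRIX_ALPHABET = STANDARD_AA + "BZJUOX*"
#: Score for any pair involving a letter outside the 20 standard residues.
FALLBACK_SCORE = -1

DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1

_matrix_cache: dict[str, substitution_matrices.Array] = {}


def load_matrix(name: str = "BLOSUM62") -> substitution_matrices.Array:
    """Load a packaged NCBI substitution matrix, extended to the full alphabet.

    Standard-residue pairs keep their published scores; any pair touching
    an ambiguity letter or ``*`` scores :data:`FALLBACK_SCORE`. The result
    is cached — treat it as read-only.
    """
    if name in _matrix_cache:
        return _matrix_cache[name]
    base = substitution_matrices.load(name)
    ext = substitution_matrices.Array(alphabet=MATRIX_ALPHABET, dims=2)
    ext[:, :] = FALLBACK_SCORE
    for a in STANDARD_AA:
        for b in STANDARD_AA:
            ext[a, b] = base[a, b]
    _matrix_cache[name] = ext
    return ext


@dataclass
class LocalAlignment:
    """Best local alignment of two residue strings.

    Spans are 1-based inclusive; an all-zero alignment (no positive-scoring
    pair) has score 0 and empty spans (all coordinates 0).
    """

    score: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    aligned_columns: int
    identities: int
    mismatches: int
    gap_opens: int

    @property
    def identity(self) -> float:
        return self.identities / self.aligned_columns if self.aligned_columns else 0.0


def _make_aligner(
    matrix: substitution_matrices.Array, gap_open: int, gap_extend: int
) -> PairwiseAligner:
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap costs must be positive")
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    # BLAST convention: length-k gap costs open + k*extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def sw_align(
    a: str,
    b: str,
    matrix: substitution_matrices.Array | None = None,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> LocalAlignment:
    """Optimal local alignment of ``a`` vs ``b`` under affine gaps."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if matrix is None:
        matrix = load_matrix()
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    score = float(aligner.score(a, b))
    if score <= 0:
        return LocalAlignment(0.0, 0, 0, 0, 0, 0, 0, 0, 0)
    aln = aligner.align(a, b)[0]
    q_blocks, s_blocks = aln.aligned
    q_start, q_end = int(q_blocks[0][0]) + 1, int(q_blocks[-1][1])
    s_start, s_end = int(s_blocks[0][0]) + 1, int(s_blocks[-1][1])
    identities = 0
    aligned_pairs = 0
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        for i in range(qe - qs):
            aligned_pairs += 1
            if a[qs + i] == b[ss + i]:
                identities += 1
    gap_opens = len(q_blocks) - 1
    gap_columns = (q_end - q_start + 1) + (s_end - s_start + 1) - 2 * aligned_pairs
    return LocalAlignment(
        score=score,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        aligned_columns=aligned_pairs + gap_columns,
        identities=identities,
        mismatches=aligned_pairs - identities,
        gap_opens=gap_opens,
    )


def _score_only(
    aligner: PairwiseAligner, a: str, b: str
) -> float:
    return float(aligner.score(a, b))


def placeholder_evalue(score: float) -> float:
    """Monotone score transform filling the evalue column of internal searches."""
    return 10.0 ** (-score / 10.0)


SEARCH_COMMENT = (
    "evalue column is the monotone transform 10^(-score/10) of the raw "
    "Smith-Waterman score, not a calibrated E-value"
)


def _edge_from_alignment(
    q: SequenceRecord, s: SequenceRecord, aln: LocalAlignment
) -> SimilarityEdge:
    pident = 100.0 * aln.identities / aln.aligned_columns if aln.aligned_columns else 0.0
    return SimilarityEdge(
        query_id=q.id,
        subject_id=s.id,
        percent_identity=pident,
        aln_length=aln.aligned_columns,
        mismatches=aln.mismatches,
        gap_opens=aln.gap_opens,
        q_start=aln.q_start,
        q_end=aln.q_end,
        s_start=aln.s_start,
        s_end=aln.s_end,
        evalue=placeholder_evalue(aln.score),
        bitscore=aln.score,
    )


def _swap_edge(e: SimilarityEdge) -> SimilarityEdge:
    return SimilarityEdge(
        query_id=e.subject_id,
        subject_id=e.query_id,
        percent_identity=e.percent_identity,
        aln_length=e.aln_length,
        mismatches=e.mismatches,
        gap_opens=e.gap_opens,
        q_start=e.s_start,
        q_end=e.s_end,
        s_start=e.q_start,
        s_end=e.q_end,
        evalue=e.evalue,
        bitscore=e.bitscore,
    )


def all_vs_all(
    records: Sequence[SequenceRecord],
    matrix: substitution_matrices.Array | None = None,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
    min_score: float = 50.0,
    include_self: bool = False,
) -> list[SimilarityEdge]:
    """All ordered pairs with local-alignment score >= ``min_score``.

    Both directions of every unordered pair are emitted (the score is
    symmetric; spans swap). Self comparisons are skipped unless
    ``include_self``.
    """
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("all_vs_all requires unique record ids")
    if matrix is None:
        matrix = load_matrix()
    edges: list[SimilarityEdge] = []
    for i, q in enumerate(records):
        if include_self:
            aln = sw_align(q.residues, q.residues, matrix, gap_open, gap_extend)
            if aln.score >= min_score:
                edges.append(_edge_from_alignment(q, q, aln))
        for s in records[i + 1 :]:
            aln = sw_align(q.residues, s.residues, matrix, gap_open, gap_extend)
            if aln.score >= min_score:
                fwd = _edge_from_alignment(q, s, aln)
                edges.append(fwd)
                edges.append(_swap_edge(fwd))
    return edges


def search(
    query_records: Sequence[SequenceRecord],
    ref_records: Sequence[SequenceRecord],
    matrix: substitution_matrices.Array | None = None,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
    min_score: float = 50.0,
    skip_same_id: bool = True,
) -> list[SimilarityEdge]:
    """Query-vs-reference search: one directed edge per passing (q, r) pair."""
    if matrix is None:
        matrix = load_matrix()
    edges: list[SimilarityEdge] = []
    for q in query_records:
        for r in ref_records:
            if skip_same_id and q.id == r.id:
                continue
            aln = sw_align(q.residues, r.residues, matrix, gap_open, gap_extend)
            if aln.score >= min_score:
                edges.append(_edge_from_alignment(q, r, aln))
    return edges


def shuffle_significance(
    a: str,
    b: str,
    matrix: substitution_matrices.Array | None = None,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
    n_shuffles: int = 100,
    z_min: float = 10.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float, bool]:
    """Monte-Carlo shuffle test of local-alignment significance.

    Scores the real pair, then ``n_shuffles`` random permutations of ``b``
    (composition preserved, order destroyed), and reports
    ``z = (S - mean) / sd`` of the real score against that null. The pair
    is significant when ``z >= z_min``. A degenerate null (sd = 0) gives
    z = +inf when the real score exceeds the null mean, else 0.

    Returns ``(real_score, z, significant)``.
    """
    if matrix is None:
        matrix = load_matrix()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    real = _score_only(aligner, a, b)
    chars = np.array(list(b))
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        null[i] = _score_only(aligner, a, "".join(rng.permutation(chars)))
    mean = float(null.mean())
    sd = float(null.std(ddof=1)) if n_shuffles > 1 else 0.0
    if sd == 0.0:
        z = float("inf") if real > mean else 0.0
    else:
        z = (real - mean) / sd
    return real, z, z >= z_min
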