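"""Gene-fusion (Rosetta Stone) detection.

A fusion *composite* in a reference species is a protein matching two or
more *component* proteins from a query species at distinct regions of its
own sequence. The hit matrix here is rectangular — rows are query-species
components, columns are reference-species composites — and each cell
keeps only the best-scoring hit of that component on that composite, with
its composite-side span.

A composite with two or more component hits becomes a candidate when at
least one component pair survives two filters: (1) the composite-side
spans must be essentially distinct — pairs overlapping by more than
``max_component_overlap`` of the shorter span are dropped; (2) the
components themselves must be mutually non-homologous — a significant
alignment between them (shuffle z-test, shared with the symmetrification
machinery) means an internal repeat, not a fusion.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import (
    DEFAULT_GAP_EXTEND,
    DEFAULT_GAP_OPEN,
    load_matrix,
    search,
    shuffle_significance,
)
from .io import SequenceRecord, SimilarityEdge

DEFAULT_MAX_OVERLAP = 0.1


@dataclass(frozen=True)
class RectHit:
    """Best hit of one component on one composite (composite-side span,
    1-based inclusive)."""

    component_id: str
    composite_id: str
    score: float
    start: int
    end: int


@dataclass
class ComponentMatch:
    component_id: str
    start: int
    end: int
    score: float


@dataclass
class FusionCandidate:
    """One composite with its retained, mutually unrelated components."""

    composite_id: str
    components: list[ComponentMatch]
    overlap_fractions: dict[tuple[str, str], float]


def span_overlap_fraction(
    a: tuple[int, int], b: tuple[int, int]
) -> float:
    """Overlap of two 1-based inclusive spans as a fraction of the shorter."""
    overlap = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if overlap <= 0:
        return 0.0
    shorter = min(a[1] - a[0] + 1, b[1] - b[0] + 1)
    return overlap / shorter


def build_rect_matrix(
    query_records: Sequence[SequenceRecord],
    reference_records: Sequence[SequenceRecord],
    edges: Iterable[SimilarityEdge] | None = None,
    max_evalue: float | None = None,
    min_score: float | None = None,
    substitution_matrix=None,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> dict[tuple[str, str], RectHit]:
    """Rectangular component-vs-composite hit matrix.

    With ``edges`` given, rows q→r are taken from the pairs-list (query id
    in the query set, subject id in the reference set; other rows are
    ignored); otherwise an internal search runs. Only the best-scoring hit
    per (component, composite) cell is kept — repeats are not split into
    units. The two id spaces must be disjoint.
    """
    q_ids = {r.id for r in query_records}
    r_ids = {r.id for r in reference_records}
    clash = q_ids & r_ids
    if clash:
        raise ValueError(
            f"query and reference id spaces overlap: {sorted(clash)[:5]} — "
            "prefix one collection before building the matrix"
        )
    if edges is None:
        edges = search(
            query_records,
            reference_records,
            matrix=substitution_matrix,
            gap_open=gap_open,
            gap_extend=gap_extend,
            min_score=min_score if min_score is not None else 50.0,
        )
    cells: dict[tuple[str, str], RectHit] = {}
    for e in edges:
        if e.query_id not in q_ids or e.subject_id not in r_ids:
            continue
        if max_evalue is not None and e.evalue > max_evalue:
            continue
        if min_score is not None and e.bitscore < min_score:
            continue
        key = (e.query_id, e.subject_id)
        hit = RectHit(e.query_id, e.subject_id, e.bitscore, e.s_start, e.s_end)
        if key not in cells or hit.score > cells[key].score:
            cells[key] = hit
    return cells


def detect_fusions(
    matrix: Mapping[tuple[str, str], RectHit],
    query_records: Sequence[SequenceRecord],
    substitution_matrix=None,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
    max_component_overlap: float = DEFAULT_MAX_OVERLAP,
    validate_components: bool = True,
    z_min: float = 10.0,
    n_shuffles: int = 100,
    seed: int = 0,
) -> list[FusionCandidate]:
    """Call fusion composites from the rectangular matrix.

    For each composite with >= 2 component hits, a component pair is
    *valid* when its composite-side spans overlap by at most
    ``max_component_overlap`` of the shorter span and (if
    ``validate_components``) the components are not significantly similar
    to each other. Composites with at least one valid pair are emitted
    with every component participating in a valid pair; candidates are
    sorted by composite id, components by id.
    """
    if not (0.0 <= max_component_overlap <= 1.0):
        raise ValueError("max_component_overlap must be in [0, 1]")
    if substitution_matrix is None:
        substitution_matrix = load_matrix()
    seqs = {r.id: r for r in query_records}

    by_composite: dict[str, list[RectHit]] = {}
    for hit in matrix.values():
        by_composite.setdefault(hit.composite_id, []).append(hit)

    homology_cache: dict[tuple[str, str], bool] = {}

    def homologous(a: str, b: str) -> bool:
        key = (min(a, b), max(a, b))
        if key not in homology_cache:
            pair_tag = zlib.crc32("\t".join(key).encode())
            rng = np.random.default_rng([seed, pair_tag])
            _, _, significant = shuffle_significance(
                seqs[key[0]].residues,
                seqs[key[1]].residues,
                substitution_matrix,
                gap_open,
                gap_extend,
                n_shuffles=n_shuffles,
                z_min=z_min,
                rng=rng,
            )
            homology_cache[key] = significant
        return homology_cache[key]

    candidates: list[FusionCandidate] = []
    for composite_id in sorted(by_composite):
        hits = sorted(by_composite[composite_id], key=lambda h: h.component_id)
        if len(hits) < 2:
            continue
        overlaps: dict[tuple[str, str], float] = {}
        valid_members: set[str] = set()
        for i, h1 in enumerate(hits):
            for h2 in hits[i + 1 :]:
                frac = span_overlap_fraction((h1.start, h1.end), (h2.start, h2.end))
                overlaps[(h1.component_id, h2.component_id)] = frac
                if frac > max_component_overlap:
                    continue
                if validate_components and homologous(h1.component_id, h2.component_id):
                    continue
                valid_members.update((h1.component_id, h2.component_id))
        if not valid_members:
            continue
        components = [
            ComponentMatch(h.component_id, h.start, h.end, h.score)
            for h in hits
            if h.component_id in valid_members
        ]
        candidates.append(FusionCandidate(composite_id, components, overlaps))
    return candidates


def write_fusions(candidates: Sequence[FusionCandidate], path: str | Path) -> None:
    """TSV ``composite_id n_components component_id:start-end:score(;…)``."""
    with open(path, "wt") as fh:
        for cand in candidates:
            parts = ";".join(
                f"{c.component_id}:{c.start}-{c.end}:{c.score:g}"
                for c in cand.components
            )
            fh.write(f"{cand.composite_id}\t{len(cand.components)}\t{parts}\n")
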