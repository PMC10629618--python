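"""Binary-matrix protein-family clustering with multi-domain detection.

The all-vs-all hit list becomes a binary square matrix over the sequence
set (cell (q, s) true when q hit s below the E-value threshold). Search
asymmetries — hits found one way but not the other — are arbitrated by an
explicit Smith-Waterman test (*symmetrification*): a significant alignment
corrects the false negative (both cells set), an insignificant one removes
the false positive (both cleared). Significance is a Monte-Carlo shuffle
z-score (see :func:`cggtools.align.shuffle_significance`).

Multi-domain proteins are then read off the validated matrix as
transitivity violations: a protein similar to two proteins that are not
similar to each other bridges families it does not wholly belong to.
Single-linkage families are assembled from the matrix *excluding* those
bridging proteins — preventing domain-chaining collapse of unrelated
families — and each multi-domain protein is afterwards attached to every
core family containing at least one of its neighbours, annotated as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import (
    DEFAULT_GAP_EXTEND,
    DEFAULT_GAP_OPEN,
    load_matrix,
    shuffle_significance,
)
from .io import SequenceRecord, SimilarityEdge
from .mcl import FamilySet

# provenance codes, per cell
ABSENT = 0
SEARCH_HIT = 1
SW_VALIDATED = 2
CLEARED = 3

DEFAULT_Z_MIN = 10.0
DEFAULT_SHUFFLES = 100


@dataclass
class BinaryHitMatrix:
    """Boolean hit matrix over a fixed id list, with per-cell provenance."""

    ids: list[str]
    hits: np.ndarray  # bool, square
    provenance: np.ndarray  # int8, same shape

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.hits.shape != (n, n) or self.provenance.shape != (n, n):
            raise ValueError("matrix shape does not match id list")
        self._index = {v: i for i, v in enumerate(self.ids)}

    def index(self, rid: str) -> int:
        return self._index[rid]

    def is_symmetric(self) -> bool:
        return bool(np.array_equal(self.hits, self.hits.T))

    def __getitem__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return bool(self.hits[self._index[a], self._index[b]])


@dataclass
class MultiDomainCall:
    """A protein bridging mutually unrelated neighbours."""

    protein_id: str
    witnesses: list[tuple[str, str]]


@dataclass
class GenerageFamilies:
    """Core single-linkage families plus annotated multi-domain memberships."""

    families: list[tuple[int, list[str], list[str]]]  # (id, core, attached md)
    multidomain: list[str]

    def as_familyset(self) -> FamilySet:
        """Partition view: every protein once, multi-domain ones in the
        lowest-numbered family they attach to (or a singleton)."""
        placed: set[str] = set()
        fams: list[list[str]] = []
        for _, core, attached in self.families:
            fam = list(core)
            for m in attached:
                if m not in placed:
                    fam.append(m)
                    placed.add(m)
            fams.append(sorted(fam))
        for m in self.multidomain:
            if m not in placed and not any(m in f for f in fams):
                fams.append([m])
        fams.sort(key=lambda f: (-len(f), f[0]))
        return FamilySet(families=[(i + 1, f) for i, f in enumerate(fams)])


def build_matrix(
    edges: Iterable[SimilarityEdge],
    ids: Sequence[str],
    max_evalue: float | None = None,
) -> BinaryHitMatrix:
    """Directed hit matrix: cell (q, s) true iff some edge q→s passes the
    threshold. The diagonal is true by convention (self-similarity is
    axiomatic) and never validated."""
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in matrix index")
    ids = list(ids)
    index = {v: i for i, v in enumerate(ids)}
    n = len(ids)
    hits = np.zeros((n, n), dtype=bool)
    prov = np.zeros((n, n), dtype=np.int8)
    np.fill_diagonal(hits, True)
    np.fill_diagonal(prov, SEARCH_HIT)
    for e in edges:
        if e.query_id not in index or e.subject_id not in index:
            raise KeyError(
                f"edge {e.query_id}->{e.subject_id} references an unknown id"
            )
        if max_evalue is not None and e.evalue > max_evalue:
            continue
        q, s = index[e.query_id], index[e.subject_id]
        hits[q, s] = True
        prov[q, s] = SEARCH_HIT
    return BinaryHitMatrix(ids=ids, hits=hits, provenance=prov)


def symmetrify(
    matrix: BinaryHitMatrix,
    records: Mapping[str, SequenceRecord] | Sequence[SequenceRecord],
    substitution_matrix=None,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
    z_min: float = DEFAULT_Z_MIN,
    n_shuffles: int = DEFAULT_SHUFFLES,
    seed: int = 0,
) -> BinaryHitMatrix:
    """Validate every asymmetric pair with the shuffle z-test.

    Significant pairs are set true both ways (false negative corrected,
    provenance ``SW_VALIDATED``); insignificant ones are cleared both ways
    (false positive removed, provenance ``CLEARED``). Symmetric pairs are
    untouched, so the operation is idempotent. Pairs are visited in index
    order with a per-pair RNG stream derived from ``seed``, making the
    result independent of any external iteration state.
    """
    if not isinstance(records, Mapping):
        records = {r.id: r for r in records}
    if substitution_matrix is None:
        substitution_matrix = load_matrix()
    hits = matrix.hits.copy()
    prov = matrix.provenance.copy()
    n = len(matrix.ids)
    asym = np.argwhere(hits != hits.T)
    for q, s in asym:
        if q >= s:  # handle each unordered pair once
            continue
        a_id, b_id = matrix.ids[q], matrix.ids[s]
        for rid in (a_id, b_id):
            if rid not in records:
                raise KeyError(f"no sequence available for {rid!r}")
        pair_rng = np.random.default_rng([seed, q, s])
        _, _, significant = shuffle_significance(
            records[a_id].residues,
            records[b_id].residues,
            substitution_matrix,
            gap_open,
            gap_extend,
            n_shuffles=n_shuffles,
            z_min=z_min,
            rng=pair_rng,
        )
        if significant:
            hits[q, s] = hits[s, q] = True
            prov[q, s] = prov[s, q] = SW_VALIDATED
        else:
            hits[q, s] = hits[s, q] = False
            prov[q, s] = prov[s, q] = CLEARED
    out = BinaryHitMatrix(ids=list(matrix.ids), hits=hits, provenance=prov)
    assert out.is_symmetric()
    return out


def detect_multidomain(matrix: BinaryHitMatrix) -> list[MultiDomainCall]:
    """Transitivity violations of the validated matrix.

    A protein p is called multi-domain iff it has neighbours x, y that are
    not similar to each other; all witness pairs are reported. Calls are
    sorted by protein id, witnesses by (x, y).
    """
    if not matrix.is_symmetric():
        raise ValueError("multi-domain detection requires a symmetric matrix")
    hits = matrix.hits
    calls = []
    for p in range(len(matrix.ids)):
        neighbors = [x for x in np.nonzero(hits[p])[0] if x != p]
        witnesses = [
            (matrix.ids[x], matrix.ids[y])
            for i, x in enumerate(neighbors)
            for y in neighbors[i + 1 :]
            if not hits[x, y]
        ]
        if witnesses:
            calls.append(
                MultiDomainCall(matrix.ids[p], sorted(witnesses))
            )
    calls.sort(key=lambda c: c.protein_id)
    return calls


def cluster(
    matrix: BinaryHitMatrix, multidomain_calls: Sequence[MultiDomainCall]
) -> GenerageFamilies:
    """Single-linkage families with multi-domain proteins re-attached.

    Core families are the connected components of the matrix restricted to
    non-multi-domain proteins; each multi-domain protein is then listed as
    an (annotated) member of every core family containing at least one of
    its neighbours. Families are numbered from 1 by descending core size,
    ties by smallest member id.
    """
    if not matrix.is_symmetric():
        raise ValueError("clustering requires a symmetric matrix")
    md = {c.protein_id for c in multidomain_calls}
    hits = matrix.hits
    ids = matrix.ids
    n = len(ids)
    core_idx = [i for i in range(n) if ids[i] not in md]

    # single-linkage = connected components via union-find
    parent = {i: i for i in core_idx}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a in core_idx:
        for b in core_idx:
            if b > a and hits[a, b]:
                parent[find(a)] = find(b)

    comps: dict[int, list[str]] = {}
    for i in core_idx:
        comps.setdefault(find(i), []).append(ids[i])
    cores = sorted((sorted(c) for c in comps.values()), key=lambda f: (-len(f), f[0]))

    families: list[tuple[int, list[str], list[str]]] = []
    core_index_sets = [set(matrix.index(m) for m in core) for core in cores]
    for fam_id, (core, idx_set) in enumerate(zip(cores, core_index_sets), 1):
        attached = sorted(
            pid
            for pid in md
            if any(hits[matrix.index(pid), j] for j in idx_set)
        )
        families.append((fam_id, core, attached))
    return GenerageFamilies(families=families, multidomain=sorted(md))


def write_families(fams: GenerageFamilies, path: str | Path) -> None:
    """``family_id member_count members(comma)``; multi-domain members are
    annotated with a ``*`` suffix."""
    with open(path, "wt") as fh:
        for fam_id, core, attached in fams.families:
            members = core + [f"{m}*" for m in attached]
            fh.write(f"{fam_id}\t{len(members)}\t{','.join(members)}\n")


def write_multidomain(calls: Sequence[MultiDomainCall], path: str | Path) -> None:
    """``protein_id witness_x witness_y``, one line per witness pair."""
    with open(path, "wt") as fh:
        for call in calls:
            for x, y in call.witnesses:
                fh.write(f"{call.protein_id}\t{x}\t{y}\n")
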