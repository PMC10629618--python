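"""Similarity-graph construction and native Markov clustering (MCL).

A pairs-list of significant hits becomes an undirected weighted graph
(weight = -log10 E-value, capped, or raw bitscore); Markov clustering then
simulates stochastic flow on that graph: the column-stochastic transition
matrix is alternately *expanded* (matrix power, spreading flow along
paths) and *inflated* (entry-wise power followed by column renormalization,
strengthening strong currents and starving weak ones) until the flow
freezes into disjoint attractor basins — the protein families. Larger
inflation values cut the flow sooner and give finer-grained families.

One clustering invocation emits three files: a plain weighted edge list
for network viewers, the raw cluster output (one family per line), and a
human-readable families table with incremental family identifiers and
member counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .io import SimilarityEdge

logger = logging.getLogger(__name__)

DEFAULT_INFLATION = 2.0
DEFAULT_PRUNE = 1e-5
DEFAULT_EPS = 1e-6
DEFAULT_MAX_ITER = 100
#: weight assigned to an E-value of exactly 0 under neglog weighting
DEFAULT_EVALUE_CAP = 200.0

#: column sums must equal 1 within this tolerance after every normalization
STOCHASTIC_TOL = 1e-9


@dataclass
class FamilySet:
    """A partition of the graph vertices into families.

    ``families`` maps the incremental family id (from 1) to its sorted
    member ids; numbering is by descending member count, ties by smallest
    member id. ``unassigned`` lists vertices that were not claimed by any
    attractor and therefore became singletons (informational; they still
    appear in ``families``).
    """

    families: list[tuple[int, list[str]]]
    unassigned: list[str] = field(default_factory=list)

    @property
    def n_families(self) -> int:
        return len(self.families)

    def members(self) -> list[str]:
        return [m for _, fam in self.families for m in fam]

    def as_partition(self) -> set[frozenset[str]]:
        return {frozenset(fam) for _, fam in self.families}


def build_graph(
    edges: Iterable[SimilarityEdge],
    max_evalue: float | None = None,
    min_score: float | None = None,
    weighting: str = "neglog_evalue",
    evalue_cap: float = DEFAULT_EVALUE_CAP,
) -> nx.Graph:
    """Build the undirected weighted similarity graph from a pairs-list.

    Edges failing the thresholds are dropped; the two directions of a pair
    collapse to one undirected edge carrying the maximum weight of the
    directions; self-hits are discarded (self-loops are added later, at
    the matrix stage).
    """
    if weighting not in ("neglog_evalue", "bitscore"):
        raise ValueError(f"unknown weighting {weighting!r}")
    g = nx.Graph()
    for e in edges:
        if max_evalue is not None and e.evalue > max_evalue:
            continue
        if min_score is not None and e.bitscore < min_score:
            continue
        if e.query_id == e.subject_id:
            continue
        if weighting == "neglog_evalue":
            w = evalue_cap if e.evalue <= 0 else min(-math.log10(e.evalue), evalue_cap)
        else:
            w = e.bitscore
        assert w >= 0, "similarity weights are nonnegative by construction"
        if g.has_edge(e.query_id, e.subject_id):
            g[e.query_id][e.subject_id]["weight"] = max(
                g[e.query_id][e.subject_id]["weight"], w
            )
        else:
            g.add_edge(e.query_id, e.subject_id, weight=w)
    return g


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    sums = m.sum(axis=0)
    sums[sums == 0] = 1.0
    m = m / sums
    assert np.all(np.abs(m.sum(axis=0) - 1.0) < STOCHASTIC_TOL)
    return m


def inflate(m: np.ndarray, inflation: float) -> np.ndarray:
    """Entry-wise power followed by column renormalization."""
    return _normalize_columns(np.power(m, inflation))


def mcl(
    graph: nx.Graph,
    inflation: float = DEFAULT_INFLATION,
    expansion: int = 2,
    prune: float = DEFAULT_PRUNE,
    max_iter: int = DEFAULT_MAX_ITER,
    eps: float = DEFAULT_EPS,
) -> FamilySet:
    """Markov clustering of a similarity graph into protein families.

    Self-loops of weight max(incident weight, 1) regularize the flow
    (aperiodicity); iteration alternates expansion (matrix power
    ``expansion``), inflation, and pruning of entries below ``prune``,
    stopping when the largest entry change falls below ``eps`` or after
    ``max_iter`` rounds (with a warning — clusters are then read from the
    current state). Vertices are indexed in sorted order, so the result
    does not depend on input edge order.
    """
    if inflation < 1:
        raise ValueError("inflation must be >= 1")
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        return FamilySet(families=[])
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        m[idx[u], idx[v]] = m[idx[v], idx[u]] = data["weight"]
    for i in range(n):
        m[i, i] = max(m[:, i].max(), 1.0)
    m = _normalize_columns(m)

    converged = False
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = inflate(m, inflation)
        m[m < prune] = 0.0
        m = _normalize_columns(m)
        if np.max(np.abs(m - prev)) < eps:
            converged = True
            break
    if not converged:
        logger.warning(
            "MCL did not converge within %d iterations; clustering current state",
            max_iter,
        )

    return _read_clusters(m, nodes, tol=prune)


def _read_clusters(m: np.ndarray, nodes: Sequence[str], tol: float) -> FamilySet:
    n = len(nodes)
    attractors = [i for i in range(n) if m[i, i] > tol]
    raw: list[set[int]] = []
    for i in attractors:
        support = set(np.nonzero(m[i, :] > tol)[0].tolist())
        # attractor systems: merge clusters sharing an attractor vertex
        merged = False
        for cluster in raw:
            if (support & cluster) & set(attractors):
                cluster |= support
                merged = True
                break
        if not merged:
            raw.append(support)

    assigned: dict[int, int] = {}
    for ci, cluster in enumerate(raw):
        for v in sorted(cluster):
            if v in assigned:
                logger.info(
                    "vertex %s attracted by multiple clusters; kept in the "
                    "lowest-indexed one",
                    nodes[v],
                )
            else:
                assigned[v] = ci

    unassigned = [nodes[i] for i in range(n) if i not in assigned]
    groups: dict[int, list[str]] = {}
    for v, ci in assigned.items():
        groups.setdefault(ci, []).append(nodes[v])
    clusters = [sorted(g) for g in groups.values()]
    clusters.extend([[u] for u in unassigned])  # orphans become singletons
    clusters.sort(key=lambda fam: (-len(fam), fam[0]))
    return FamilySet(
        families=[(i + 1, fam) for i, fam in enumerate(clusters)],
        unassigned=unassigned,
    )


def emit_outputs(
    graph: nx.Graph, families: FamilySet, out_prefix: str | Path
) -> tuple[Path, Path, Path]:
    """Write the three clustering outputs.

    ``<prefix>.pairs.tsv`` — weighted edge list for network viewers;
    ``<prefix>.mcl`` — raw clusters, one family per line, members
    whitespace-separated; ``<prefix>.families.tsv`` — ``family_id
    member_count members(comma)`` with family ids incremental from 1.
    """
    prefix = Path(out_prefix)
    vis_path = prefix.with_name(prefix.name + ".pairs.tsv")
    mcl_path = prefix.with_name(prefix.name + ".mcl")
    fam_path = prefix.with_name(prefix.name + ".families.tsv")
    with open(vis_path, "wt") as fh:
        for u, v, data in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data['weight']:g}\n")
    with open(mcl_path, "wt") as fh:
        for _, members in families.families:
            fh.write(" ".join(members) + "\n")
    with open(fam_path, "wt") as fh:
        for fam_id, members in families.families:
            fh.write(f"{fam_id}\t{len(members)}\t{','.join(members)}\n")
    return vis_path, mcl_path, fam_path
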