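"""Measures of the evolving networks.

Connectedness, average efficiency under topological edge lengths 1/w,
convergent/divergent hub detection, convergent-divergent units (CDUs) with
their source/target/intermediate decomposition, intermediate-subgraph
density, directed weighted modularity, and spatial edge statistics.

Orientation note: with the package convention ``adjacency[i, j]`` = weight
of j -> i, all reachability here is phrased in the information-flow
direction (i "reaches" j when there is a directed path i -> j), which works
on the transposed boolean adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sparse
import scipy.sparse.csgraph as csgraph

from .network_model import SpatialDigraph, to_networkx

__all__ = [
    "ConvergentDivergentUnit",
    "MetricsRecord",
    "topological_length",
    "average_efficiency",
    "connected_pairs",
    "find_hubs",
    "find_cdus",
    "cdu_present",
    "intermediate_subgraph_stats",
    "source_target_overlap",
    "modularity_score",
    "graph_density",
    "mean_edge_length",
    "mean_edge_field_cosine",
    "compute_metrics_record",
    "record_as_dict",
]

#: default hub degree threshold ("above 15" in/out-links)
HUB_THRESHOLD = 15


@dataclass(frozen=True)
class ConvergentDivergentUnit:
    """A convergent hub joined to a divergent hub by a directed path.

    ``source_nodes`` reach the convergent hub, ``target_nodes`` are reached
    from the divergent hub, and ``intermediate_nodes`` lie on directed walks
    from the convergent to the divergent hub (reachable from the former and
    reaching the latter), hubs excluded.  ``intermediate_density`` is the
    binary edge density of the induced intermediate subgraph, or None when
    that subgraph has fewer than two nodes.
    """

    convergent_hub: int
    divergent_hub: int
    source_nodes: frozenset[int]
    target_nodes: frozenset[int]
    intermediate_nodes: frozenset[int]
    intermediate_density: float | None


@dataclass(frozen=True)
class MetricsRecord:
    """Full measurement vector at one checkpoint."""

    step: int
    proportion_connected_pairs: float
    average_efficiency: float
    convergent_hub_proportion: float
    divergent_hub_proportion: float
    cdu_count: int
    cdu_present: bool
    source_proportion: float
    target_proportion: float
    overlap_proportion: float
    intermediate_size_proportion: float
    intermediate_mean_density: float
    modularity: float
    mean_edge_length: float
    mean_edge_cosine: float


# ---------------------------------------------------------------------------
# paths, efficiency, connectedness
# ---------------------------------------------------------------------------

def topological_length(w: float) -> float:
    """Topological edge length 1/w: the difficulty of transmission."""
    if w <= 0:
        raise ValueError("edge weight must be > 0")
    return 1.0 / w


def _forward_bool(g: SpatialDigraph) -> np.ndarray:
    """Boolean matrix B with B[i, j] = True iff edge i -> j exists."""
    return (g.adjacency > 0).T


def _reach_closure(B: np.ndarray) -> np.ndarray:
    """R[i, j] = True iff a directed path i -> j of length >= 0 exists."""
    n = B.shape[0]
    R = B | np.eye(n, dtype=bool)
    # repeated squaring: (I|B)^(2^k) covers paths up to length 2^k;
    # float matmul so BLAS does the work
    length = 1
    while length < n:
        R = (R.astype(np.float64) @ R.astype(np.float64)) > 0
        length *= 2
    return R


def _reach_positive(g: SpatialDigraph) -> np.ndarray:
    """P[i, j] = True iff a directed path i -> j of length >= 1 exists."""
    B = _forward_bool(g)
    return (B.astype(np.float64) @ _reach_closure(B).astype(np.float64)) > 0


def average_efficiency(g: SpatialDigraph) -> float:
    """Mean inverse shortest directed path length over ordered pairs i != j.

    Edge lengths are 1/weight; unreachable pairs contribute 0.
    """
    n = g.n
    with np.errstate(divide="ignore"):
        lengths = np.where(g.adjacency.T > 0, 1.0 / g.adjacency.T, 0.0)
    dist = csgraph.dijkstra(lengths, directed=True)
    np.fill_diagonal(dist, np.inf)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist), 1.0 / dist, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def connected_pairs(g: SpatialDigraph) -> int:
    """Ordered pairs (i, j), including i = j, joined by a path of length >= 1.

    A self-pair counts only when the node lies on a directed cycle, so the
    upper bound n^2 is attained exactly when every node can send information
    to every node including itself.
    """
    return int(_reach_positive(g).sum())


# ---------------------------------------------------------------------------
# hubs and convergent-divergent units
# ---------------------------------------------------------------------------

def find_hubs(g: SpatialDigraph, threshold: int = HUB_THRESHOLD,
              kind: str = "convergent", strict: bool = True) -> frozenset[int]:
    """Convergent hubs (in-degree above threshold, >=1 out-link) or divergent
    hubs (out-degree above threshold, >=1 in-link).

    "Above" is the strict inequality degree > threshold by default;
    ``strict=False`` uses degree >= threshold.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    ind, outd = g.in_degrees(), g.out_degrees()
    if kind == "convergent":
        main, other = ind, outd
    elif kind == "divergent":
        main, other = outd, ind
    else:
        raise ValueError(f"kind must be 'convergent' or 'divergent', got {kind!r}")
    above = main > threshold if strict else main >= threshold
    return frozenset(int(v) for v in np.flatnonzero(above & (other >= 1)))


def cdu_present(g: SpatialDigraph, threshold: int = HUB_THRESHOLD) -> bool:
    """Cheap per-step flag: does any convergent->divergent hub path exist?

    Breadth-first search from the convergent hubs only, so it is much
    cheaper than the full unit decomposition and safe to call every step.
    """
    conv = sorted(find_hubs(g, threshold, "convergent"))
    div = np.fromiter(sorted(find_hubs(g, threshold, "divergent")), int, -1)
    if not conv or div.size == 0:
        return False
    csr = sparse.csr_matrix(_forward_bool(g))
    dist = csgraph.dijkstra(csr, indices=conv, unweighted=True)
    dist = np.atleast_2d(dist)
    for a, c in enumerate(conv):
        if (np.isfinite(dist[a, div]) & (div != c)).any():
            return True
    return False


def find_cdus(g: SpatialDigraph, threshold: int = HUB_THRESHOLD
              ) -> list[ConvergentDivergentUnit]:
    """All convergent-divergent units: ordered hub pairs joined by a path.

    One unit per ordered pair (c, d), c a convergent hub, d a divergent hub,
    c != d, with a directed path c -> d.  Sources of c are the nodes (other
    than c) that reach c; targets of d the nodes (other than d) reached from
    d; intermediates the non-hub-pair nodes reachable from c that reach d.
    """
    conv = sorted(find_hubs(g, threshold, "convergent"))
    div = sorted(find_hubs(g, threshold, "divergent"))
    if not conv or not div:
        return []
    B = _forward_bool(g)
    R = _reach_closure(B)  # off-diagonal entries equal length >= 1 reachability
    units = []
    for c in conv:
        for d in div:
            if c == d or not R[c, d]:
                continue
            sources = frozenset(int(u) for u in np.flatnonzero(R[:, c]) if u != c)
            targets = frozenset(int(u) for u in np.flatnonzero(R[d, :]) if u != d)
            inter_mask = R[c, :] & R[:, d]
            inter_mask[[c, d]] = False
            inter = frozenset(int(u) for u in np.flatnonzero(inter_mask))
            _, density = _subgraph_stats(B, inter_mask)
            units.append(ConvergentDivergentUnit(
                convergent_hub=int(c), divergent_hub=int(d),
                source_nodes=sources, target_nodes=targets,
                intermediate_nodes=inter, intermediate_density=density))
    return units


def _subgraph_stats(B: np.ndarray, mask: np.ndarray) -> tuple[int, float | None]:
    ns = int(mask.sum())
    if ns < 2:
        return ns, None
    edges = int(B[np.ix_(mask, mask)].sum())
    return ns, edges / (ns * (ns - 1))


def intermediate_subgraph_stats(g: SpatialDigraph, unit: ConvergentDivergentUnit
                                ) -> tuple[float, float | None]:
    """(size proportion |I|/n, binary density of the induced subgraph).

    Density is edges / (ns (ns - 1)) and None for subgraphs with < 2 nodes,
    which are excluded from any aggregation.
    """
    mask = np.zeros(g.n, dtype=bool)
    mask[list(unit.intermediate_nodes)] = True
    ns, density = _subgraph_stats(_forward_bool(g), mask)
    return ns / g.n, density


def source_target_overlap(units: list[ConvergentDivergentUnit], n: int
                          ) -> tuple[float, float, float]:
    """Mean per-unit proportions (|S|/n, |T|/n, |S intersect T|/n)."""
    if not units:
        raise ValueError("source_target_overlap is undefined for an empty unit list")
    s = np.mean([len(u.source_nodes) / n for u in units])
    t = np.mean([len(u.target_nodes) / n for u in units])
    o = np.mean([len(u.source_nodes & u.target_nodes) / n for u in units])
    return float(s), float(t), float(o)


# ---------------------------------------------------------------------------
# modularity and plumbing measures
# ---------------------------------------------------------------------------

def modularity_score(g: SpatialDigraph, resolution: float = 1.0,
                     seed: int = 0, partition=None) -> tuple[float, list[set[int]]]:
    """Directed weighted modularity of a Louvain partition (fixed seed).

    The objective is the Newman directed modularity
    Q = sum_e [w_e/w - (s_e^in s_e^out)/w^2] over communities e, evaluated by
    networkx; the partition is found by seeded Louvain unless one is given.
    """
    G = to_networkx(g)
    if partition is None:
        partition = nx.community.louvain_communities(
            G, weight="weight", resolution=resolution, seed=seed)
    q = nx.community.modularity(G, partition, weight="weight",
                                resolution=resolution)
    return float(q), [set(c) for c in partition]


def graph_density(g: SpatialDigraph) -> float:
    """Binary edge density m / (n (n - 1))."""
    return g.m / (g.n * (g.n - 1))


def mean_edge_length(g: SpatialDigraph) -> float:
    """Mean Euclidean length of the edges."""
    heads, tails = np.nonzero(g.adjacency > 0)
    if heads.size == 0:
        return float("nan")
    d = np.linalg.norm(g.coordinates[heads] - g.coordinates[tails], axis=1)
    return float(d.mean())


def mean_edge_field_cosine(g: SpatialDigraph, field) -> float:
    """Mean cosine between each edge j->i and the field at the edge midpoint.

    Zero-length edges and points where the field is undefined are skipped;
    NaN when no edge has a defined angle (or field is None).
    """
    if field is None:
        return float("nan")
    heads, tails = np.nonzero(g.adjacency > 0)
    cosines = []
    for i, j in zip(heads, tails):
        edge = g.coordinates[i] - g.coordinates[j]
        d = np.linalg.norm(edge)
        fv = field((g.coordinates[i] + g.coordinates[j]) / 2.0)
        if d == 0 or fv is None:
            continue
        cosines.append(edge @ fv / (d * np.linalg.norm(fv)))
    return float(np.mean(cosines)) if cosines else float("nan")


# ---------------------------------------------------------------------------
# checkpoint assembly
# ---------------------------------------------------------------------------

def compute_metrics_record(
    g: SpatialDigraph, step: int, hub_threshold: int = HUB_THRESHOLD,
    field=None, compute_modularity: bool = True,
) -> MetricsRecord:
    """Evaluate the full measurement vector on the current network."""
    n = g.n
    units = find_cdus(g, hub_threshold)
    if units:
        s, t, o = source_target_overlap(units, n)
        sizes = [len(u.intermediate_nodes) / n for u in units]
        densities = [u.intermediate_density for u in units
                     if u.intermediate_density is not None]
        size_prop = float(np.mean(sizes))
        mean_density = float(np.mean(densities)) if densities else float("nan")
    else:
        s = t = o = size_prop = mean_density = float("nan")
    if compute_modularity:
        q, _ = modularity_score(g)
    else:
        q = float("nan")
    return MetricsRecord(
        step=step,
        proportion_connected_pairs=connected_pairs(g) / n**2,
        average_efficiency=average_efficiency(g),
        convergent_hub_proportion=len(find_hubs(g, hub_threshold, "convergent")) / n,
        divergent_hub_proportion=len(find_hubs(g, hub_threshold, "divergent")) / n,
        cdu_count=len(units),
        cdu_present=bool(units),
        source_proportion=s, target_proportion=t, overlap_proportion=o,
        intermediate_size_proportion=size_prop,
        intermediate_mean_density=mean_density,
        modularity=q,
        mean_edge_length=mean_edge_length(g),
        mean_edge_cosine=mean_edge_field_cosine(g, field),
    )


def record_as_dict(rec: MetricsRecord) -> dict:
    from dataclasses import asdict

    return asdict(rec)
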