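"""Directed, weighted, spatially embedded networks.

The simulator evolves digraphs G = (V, E, W) with n nodes and m weighted
directed edges, embedded in the plane with every node inside the closed unit
disk.  The adjacency convention throughout the package is

    ``adjacency[i, j]`` = weight of the edge j -> i,

i.e. *rows hold in-link weights* and columns hold out-link weights.  Most
graph libraries use the transpose; the import/export helpers at the bottom of
this module convert at the boundary.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "ConfigurationError",
    "WeightSpec",
    "SpatialDigraph",
    "NeighborhoodView",
    "sample_and_normalize_weights",
    "embed_nodes_unit_disk",
    "generate_random_digraph",
    "neighborhood",
    "strength",
    "fingerprint",
    "weight_multiset",
    "to_networkx",
    "from_networkx",
    "write_edgelist",
    "read_edgelist",
    "write_graphml",
    "read_graphml",
]


class ConfigurationError(ValueError):
    """Raised for invalid simulation configurations (e.g. m > n(n-1))."""


def as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    """Coerce ``rng`` (Generator, seed, or None) to a numpy Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class WeightSpec:
    """Distribution from which raw edge weights are sampled.

    Draws that come out non-positive are replaced by ``clamp_value`` *before*
    normalization.  Defaults follow the normal N(1, 0.25^2) weight model with
    a 0.05 clamp.
    """

    family: str = "normal"  # "normal" | "lognormal"
    loc: float = 1.0
    scale: float = 0.25
    clamp_value: float = 0.05

    def __post_init__(self) -> None:
        if self.family not in ("normal", "lognormal"):
            raise ConfigurationError(f"unknown weight family: {self.family!r}")
        if not self.scale > 0:
            raise ConfigurationError("weight scale must be > 0")
        if not self.clamp_value > 0:
            raise ConfigurationError("clamp_value must be > 0")


@dataclass
class SpatialDigraph:
    """A weighted digraph with planar coordinates.

    ``adjacency[i, j]`` is the weight of edge j -> i (0 when absent); the
    diagonal is zero (no self-loops).  ``coordinates`` is an (n, 2) array with
    every point inside the closed unit disk.
    """

    adjacency: np.ndarray
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)

    # -- basic queries -----------------------------------------------------
    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def m(self) -> int:
        """Number of directed edges (strictly positive adjacency entries)."""
        return int(np.count_nonzero(self.adjacency > 0))

    def in_degrees(self) -> np.ndarray:
        return np.count_nonzero(self.adjacency > 0, axis=1)

    def out_degrees(self) -> np.ndarray:
        return np.count_nonzero(self.adjacency > 0, axis=0)

    def in_strengths(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def out_strengths(self) -> np.ndarray:
        return self.adjacency.sum(axis=0)

    def copy(self) -> "SpatialDigraph":
        return SpatialDigraph(self.adjacency.copy(), self.coordinates.copy())

    def validate(self) -> None:
        """Raise ConfigurationError if any structural invariant is violated."""
        a, c = self.adjacency, self.coordinates
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ConfigurationError("adjacency must be square")
        if c.shape != (a.shape[0], 2):
            raise ConfigurationError("coordinates must be (n, 2)")
        if not np.all(np.isfinite(a)):
            raise ConfigurationError("non-finite weights")
        if np.any(a < 0):
            raise ConfigurationError("negative weights")
        if np.any(np.diag(a) != 0):
            raise ConfigurationError("self-loops present")
        if np.any(np.linalg.norm(c, axis=1) > 1 + 1e-12):
            raise ConfigurationError("coordinates outside the unit disk")


@dataclass(frozen=True)
class NeighborhoodView:
    """In- or out-neighborhood of a node together with its complement.

    ``members`` are the tails of v's in-links (side="in") or the heads of its
    out-links (side="out"); ``complement`` is V minus v minus members — the
    candidate endpoints for a new link on that side.
    """

    node: int
    side: str
    members: frozenset[int]
    complement: frozenset[int]


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def sample_and_normalize_weights(
    m: int,
    spec: WeightSpec = WeightSpec(),
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw m raw weights, clamp non-positive draws, normalize to sum m.

    Non-positive draws are replaced by ``spec.clamp_value`` before the
    rescaling; the rescaling divides by the sample mean so the normalized
    weights sum exactly to the number of edges.
    """
    if m < 1:
        raise ConfigurationError("m must be >= 1")
    rng = as_rng(rng)
    if spec.family == "normal":
        w = rng.normal(spec.loc, spec.scale, size=m)
    else:
        w = rng.lognormal(mean=spec.loc, sigma=spec.scale, size=m)
    w = np.where(w <= 0, spec.clamp_value, w)
    w *= m / w.sum()
    return w


def embed_nodes_unit_disk(
    n: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """n points i.i.d. uniform by area over the unit disk (radius = sqrt(U))."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = as_rng(rng)
    r = np.sqrt(rng.random(n))
    theta = 2 * np.pi * rng.random(n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def generate_random_digraph(
    n: int,
    m: int,
    weights: WeightSpec = WeightSpec(),
    rng: np.random.Generator | int | None = None,
) -> SpatialDigraph:
    """Random digraph: m distinct ordered pairs, sampled weights, disk layout.

    Edges occupy m ordered node pairs drawn uniformly without replacement from
    all n(n-1) candidates; weights come from ``sample_and_normalize_weights``;
    coordinates from ``embed_nodes_unit_disk``.  The generator consumes the
    RNG in that order (pairs, weights, coordinates).
    """
    if n < 2:
        raise ConfigurationError("n must be >= 2")
    if not 0 < m <= n * (n - 1):
        raise ConfigurationError(f"m must satisfy 0 < m <= n(n-1) = {n * (n - 1)}")
    rng = as_rng(rng)
    offdiag = np.flatnonzero(~np.eye(n, dtype=bool).ravel())
    chosen = rng.choice(offdiag, size=m, replace=False)
    w = sample_and_normalize_weights(m, weights, rng)
    a = np.zeros((n, n))
    a.ravel()[chosen] = w
    coords = embed_nodes_unit_disk(n, rng)
    g = SpatialDigraph(a, coords)
    g.validate()
    return g


# ---------------------------------------------------------------------------
# queries
# ---------------------------------------------------------------------------

def _check_node(g: SpatialDigraph, v: int) -> None:
    if not 0 <= v < g.n:
        raise IndexError(f"node {v} out of range [0, {g.n})")


def neighborhood(g: SpatialDigraph, v: int, side: str) -> NeighborhoodView:
    """N_in(v) / N_out(v) and its complement (excluding v itself)."""
    _check_node(g, v)
    if side == "in":
        members = np.flatnonzero(g.adjacency[v] > 0)
    elif side == "out":
        members = np.flatnonzero(g.adjacency[:, v] > 0)
    else:
        raise ConfigurationError(f"side must be 'in' or 'out', got {side!r}")
    mem = frozenset(int(u) for u in members)
    comp = frozenset(range(g.n)) - mem - {v}
    return NeighborhoodView(node=v, side=side, members=mem, complement=comp)


def strength(g: SpatialDigraph, v: int, side: str) -> float:
    """In-strength (row sum) or out-strength (column sum) of node v."""
    _check_node(g, v)
    if side == "in":
        return float(g.adjacency[v].sum())
    if side == "out":
        return float(g.adjacency[:, v].sum())
    raise ConfigurationError(f"side must be 'in' or 'out', got {side!r}")


def fingerprint(g: SpatialDigraph) -> str:
    """SHA-256 over (n, adjacency bytes, coordinate bytes); byte-identity id."""
    h = hashlib.sha256()
    h.update(str(g.n).encode())
    h.update(np.ascontiguousarray(g.adjacency).tobytes())
    h.update(np.ascontiguousarray(g.coordinates).tobytes())
    return h.hexdigest()


def weight_multiset(g: SpatialDigraph) -> np.ndarray:
    """Sorted array of the strictly positive edge weights."""
    a = g.adjacency
    return np.sort(a[a > 0])


# ---------------------------------------------------------------------------
# interchange: networkx / edge list / GraphML
# ---------------------------------------------------------------------------

def to_networkx(g: SpatialDigraph) -> nx.DiGraph:
    """Convert to a networkx DiGraph (edge (u, v) means u -> v).

    Note the transpose: ``adjacency[i, j]`` (edge j -> i) becomes the
    networkx edge (j, i) with attribute ``weight``; coordinates become node
    attributes ``x`` and ``y``.
    """
    G = nx.DiGraph()
    for i in range(g.n):
        G.add_node(i, x=float(g.coordinates[i, 0]), y=float(g.coordinates[i, 1]))
    heads, tails = np.nonzero(g.adjacency > 0)
    for i, j in zip(heads, tails):
        G.add_edge(int(j), int(i), weight=float(g.adjacency[i, j]))
    return G


def from_networkx(G: nx.DiGraph) -> SpatialDigraph:
    """Inverse of :func:`to_networkx`; nodes must be labelled 0..n-1."""
    n = G.number_of_nodes()
    a = np.zeros((n, n))
    for u, v, data in G.edges(data=True):
        a[int(v), int(u)] = float(data.get("weight", 1.0))
    coords = np.zeros((n, 2))
    for v, data in G.nodes(data=True):
        coords[int(v)] = (float(data.get("x", 0.0)), float(data.get("y", 0.0)))
    return SpatialDigraph(a, coords)


def write_edgelist(g: SpatialDigraph, path) -> None:
    """TSV edge list: source, target, weight (0-based, one edge per line)."""
    heads, tails = np.nonzero(g.adjacency > 0)
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for i, j in zip(heads, tails):
            fh.write(f"{j}\t{i}\t{float(g.adjacency[i, j])!r}\n")


def read_edgelist(path, n: int | None = None, coordinates=None) -> SpatialDigraph:
    """Read a TSV edge list; n defaults to max index + 1, coordinates to 0."""
    edges = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("source"):
            raise ConfigurationError("edge list must have a source/target/weight header")
        for line in fh:
            s, t, w = line.split("\t")
            edges.append((int(s), int(t), float(w)))
    if n is None:
        n = 1 + max(max(s, t) for s, t, _ in edges)
    a = np.zeros((n, n))
    for s, t, w in edges:
        a[t, s] = w
    coords = np.zeros((n, 2)) if coordinates is None else np.asarray(coordinates, float)
    return SpatialDigraph(a, coords)


def write_graphml(g: SpatialDigraph, path) -> None:
    """GraphML with node attributes x, y and edge attribute weight."""
    nx.write_graphml(to_networkx(g), path)


def read_graphml(path) -> SpatialDigraph:
    G = nx.read_graphml(path)
    G = nx.relabel_nodes(G, {v: int(v) for v in G.nodes})
    return from_networkx(G)
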