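"""Rewiring principles and the iterative rewiring loop.

At each step a pivot node v is drawn (rewire an in-link with probability
p_in, else an out-link), one of four principles is drawn (distance | wave |
functional | random, partitioning [0,1) in that order), and a single edge
swap is applied: one existing link on the chosen side of v is cut and
replaced by a link to a previously unconnected node, the new link inheriting
the cut link's weight.  Node count, edge count, the weight multiset and the
pivot's side-strength are conserved at every step.

Principles
----------
functional   cut the side-neighborhood member with the lowest kernel value,
             add the complement node with the highest (consensus kernel row
             for in-links, advection kernel column for out-links); either
             deterministic argmin/argmax with uniform tie-breaks, or the
             stochastic variant that cuts with probability proportional to
             1/value and adds with probability proportional to value.
distance     cut the spatially longest link, add the spatially closest.
wave         cut the link most misaligned with an external vector field
             evaluated at the pivot, add the best aligned.
random       cut and add uniformly.

A single numpy Generator seeded from the config drives every draw, consumed
in a documented order per step: r1 (side), pivot choice, r2 (principle),
then the principle's own draws (tie-break draws are always consumed, even
when unique).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import network_metrics
from .flow_kernels import inflow_profile, outflow_profile
from .network_model import (
    ConfigurationError,
    SpatialDigraph,
    as_rng,
    fingerprint,
    neighborhood,
)

__all__ = [
    "RewiringConfig",
    "EdgeSwap",
    "VectorField",
    "PivotEligibilityError",
    "SwapIntegrityError",
    "UndefinedAngleError",
    "select_pivot",
    "choose_principle",
    "functional_rewire",
    "distance_rewire",
    "wave_rewire",
    "random_rewire",
    "edge_field_cosine",
    "cut_probabilities",
    "add_probabilities",
    "apply_swap",
    "run_rewiring",
    "RunResult",
]

logger = logging.getLogger(__name__)


class PivotEligibilityError(RuntimeError):
    """No node has side-degree in {1, ..., n-2} for the drawn side."""


class SwapIntegrityError(RuntimeError):
    """An EdgeSwap is inconsistent with the graph it is applied to."""


class UndefinedAngleError(ValueError):
    """Zero-length edge or zero field vector: the angle is undefined."""


@dataclass(frozen=True)
class RewiringConfig:
    """All parameters of a rewiring run.

    ``p_function + p_distance + p_wave + p_random`` must equal 1; if
    ``p_function`` is None it is derived as the remainder
    1 - p_distance - p_wave - p_random.
    """

    p_in: float = 0.5
    p_distance: float = 0.0
    p_wave: float = 0.0
    p_random: float = 0.0
    p_function: float | None = None
    mode: str = "deterministic"  # functional variant: deterministic|stochastic
    field: str = "none"  # lateral|radial|none (wave principle's field)
    t: float = 1.0  # kernel/rewiring interval
    steps: int = 15000
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {"p_in": self.p_in, "p_distance": self.p_distance,
                 "p_wave": self.p_wave, "p_random": self.p_random}
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        rest = self.p_distance + self.p_wave + self.p_random
        if self.p_function is None:
            if rest > 1.0 + 1e-12:
                raise ConfigurationError("p_distance + p_wave + p_random > 1")
            object.__setattr__(self, "p_function", max(0.0, 1.0 - rest))
        elif abs(self.p_function + rest - 1.0) > 1e-9:
            raise ConfigurationError("principle probabilities must sum to 1")
        if self.mode not in ("deterministic", "stochastic"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.field not in ("lateral", "radial", "none"):
            raise ConfigurationError(f"unknown field {self.field!r}")
        if self.p_wave > 0 and self.field == "none":
            raise ConfigurationError("wave principle requires a field")
        if self.steps < 0:
            raise ConfigurationError("steps must be >= 0")
        if self.t < 0:
            raise ConfigurationError("t must be >= 0")


@dataclass(frozen=True)
class EdgeSwap:
    """One rewiring event: cut (removed, side of pivot), add (added), move weight."""

    pivot: int
    side: str
    removed: int
    added: int
    weight: float
    principle: str


class VectorField:
    """Lateral field (1, 0) or radial field x/||x||.

    Calling the field at a point returns a 2-vector, or None where the field
    is undefined (the radial field at the origin).
    """

    def __init__(self, kind: str):
        if kind not in ("lateral", "radial"):
            raise ConfigurationError(f"unknown field kind {kind!r}")
        self.kind = kind

    def __call__(self, point: np.ndarray) -> np.ndarray | None:
        if self.kind == "lateral":
            return np.array([1.0, 0.0])
        norm = float(np.linalg.norm(point))
        if norm == 0.0:
            return None
        return np.asarray(point, float) / norm

    def __repr__(self) -> str:  # pragma: no cover
        return f"VectorField({self.kind!r})"


# ---------------------------------------------------------------------------
# step ingredients
# ---------------------------------------------------------------------------

def select_pivot(
    g: SpatialDigraph, p_in: float, rng: np.random.Generator | int | None = None
) -> tuple[int, str]:
    """Draw the side (in with prob p_in) then a uniform eligible pivot.

    A node is eligible when its degree on the drawn side is neither 0 nor
    n-1.  If no node qualifies a PivotEligibilityError is raised; the side is
    not silently re-drawn.
    """
    rng = as_rng(rng)
    r1 = rng.random()
    side = "in" if r1 < p_in else "out"
    degrees = g.in_degrees() if side == "in" else g.out_degrees()
    eligible = np.flatnonzero((degrees >= 1) & (degrees <= g.n - 2))
    if eligible.size == 0:
        raise PivotEligibilityError(f"no node with {side}-degree in [1, n-2]")
    return int(rng.choice(eligible)), side


def choose_principle(
    config: RewiringConfig, rng: np.random.Generator | int | None = None
) -> str:
    """One uniform draw over the partition distance | wave | functional | random."""
    return _principle_from_draw(config, as_rng(rng).random())


def _principle_from_draw(config: RewiringConfig, r2: float) -> str:
    if r2 < config.p_distance:
        return "distance"
    if r2 < config.p_distance + config.p_wave:
        return "wave"
    if r2 < config.p_distance + config.p_wave + config.p_function:
        return "functional"
    return "random"


def _argopt(candidates: np.ndarray, values: np.ndarray, best: str,
            rng: np.random.Generator) -> int:
    """Arg-max/min over candidates with uniform tie-breaking.

    The tie-break draw is consumed unconditionally so that the RNG stream
    advances by the same amount whether or not the optimum is unique.
    """
    opt = values.max() if best == "max" else values.min()
    ties = candidates[values == opt]
    return int(rng.choice(ties))


def cut_probabilities(values: np.ndarray) -> np.ndarray:
    """Stochastic-mode cut distribution: p(k) proportional to 1/value.

    If any value is zero, its reciprocal dominates every finite one; the cut
    is then uniform over the zero-valued members (the limit of the formula).
    """
    values = np.asarray(values, dtype=float)
    zero = values <= 0.0
    if zero.any():
        return zero / zero.sum()
    inv = 1.0 / values
    return inv / inv.sum()


def add_probabilities(values: np.ndarray) -> np.ndarray:
    """Stochastic-mode add distribution: p(l) proportional to value.

    All-zero values (no signal reaches any candidate) fall back to uniform.
    """
    values = np.asarray(values, dtype=float)
    total = values.sum()
    if total <= 0.0:
        return np.full(values.shape, 1.0 / values.size)
    return values / total


def _side_candidates(g: SpatialDigraph, v: int, side: str):
    view = neighborhood(g, v, side)
    members = np.fromiter(sorted(view.members), dtype=int)
    complement = np.fromiter(sorted(view.complement), dtype=int)
    if members.size == 0 or complement.size == 0:
        raise PivotEligibilityError(
            f"pivot {v} has empty {side}-neighborhood or complement")
    return members, complement


def _swap_weight(g: SpatialDigraph, v: int, side: str, k: int) -> float:
    return float(g.adjacency[v, k] if side == "in" else g.adjacency[k, v])


def functional_rewire(
    g: SpatialDigraph, v: int, side: str, t: float = 1.0,
    mode: str = "deterministic", rng: np.random.Generator | int | None = None,
) -> EdgeSwap:
    """Adaptive rewiring of one link of v, driven by the flow kernels.

    side="in" scores candidates by the consensus-kernel row of v (in-flow);
    side="out" by the advection-kernel column (out-flow).  Deterministic
    mode cuts the argmin member and adds the argmax complement node (uniform
    tie-breaks); stochastic mode draws from :func:`cut_probabilities` /
    :func:`add_probabilities`.
    """
    rng = as_rng(rng)
    members, complement = _side_candidates(g, v, side)
    profile = inflow_profile(g, v, t) if side == "in" else outflow_profile(g, v, t)
    mvals, cvals = profile[members], profile[complement]
    if mode == "deterministic":
        k = _argopt(members, mvals, "min", rng)
        l = _argopt(complement, cvals, "max", rng)
    elif mode == "stochastic":
        k = int(rng.choice(members, p=cut_probabilities(mvals)))
        l = int(rng.choice(complement, p=add_probabilities(cvals)))
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")
    return EdgeSwap(v, side, k, l, _swap_weight(g, v, side, k), "functional")


def distance_rewire(
    g: SpatialDigraph, v: int, side: str,
    rng: np.random.Generator | int | None = None,
) -> EdgeSwap:
    """Cut the spatially longest link of v, add the spatially closest."""
    rng = as_rng(rng)
    members, complement = _side_candidates(g, v, side)
    dist = np.linalg.norm(g.coordinates - g.coordinates[v], axis=1)
    k = _argopt(members, dist[members], "max", rng)
    l = _argopt(complement, dist[complement], "min", rng)
    return EdgeSwap(v, side, k, l, _swap_weight(g, v, side, k), "distance")


def edge_field_cosine(head: np.ndarray, tail: np.ndarray,
                      field_vector: np.ndarray) -> float:
    """Cosine of the angle between edge vector (head - tail) and the field."""
    head, tail = np.asarray(head, float), np.asarray(tail, float)
    f = np.asarray(field_vector, float)
    edge = head - tail
    d = float(np.linalg.norm(edge))
    fn = float(np.linalg.norm(f))
    if d == 0.0 or fn == 0.0:
        raise UndefinedAngleError("zero-length edge or zero field vector")
    return float(edge @ f / (d * fn))


def wave_rewire(
    g: SpatialDigraph, v: int, side: str, field: VectorField,
    rng: np.random.Generator | int | None = None,
) -> EdgeSwap:
    """Cut the link most misaligned with the field at v, add the best aligned.

    In-links of v are oriented u -> v (head v, tail u); out-links v -> u.
    Where the field is undefined at the pivot (radial field at the origin,
    a measure-zero event) the step falls back to random rewiring, logged.
    """
    rng = as_rng(rng)
    fv = field(g.coordinates[v])
    if fv is None:
        logger.warning("field undefined at pivot %d; falling back to random", v)
        swap = random_rewire(g, v, side, rng)
        return EdgeSwap(swap.pivot, swap.side, swap.removed, swap.added,
                        swap.weight, "wave_fallback_random")
    members, complement = _side_candidates(g, v, side)

    def cosines(nodes: np.ndarray) -> np.ndarray:
        others = g.coordinates[nodes]
        if side == "in":  # u -> v
            edges = g.coordinates[v] - others
        else:  # v -> u
            edges = others - g.coordinates[v]
        d = np.linalg.norm(edges, axis=1)
        return (edges @ fv) / (d * np.linalg.norm(fv))

    k = _argopt(members, cosines(members), "min", rng)
    l = _argopt(complement, cosines(complement), "max", rng)
    return EdgeSwap(v, side, k, l, _swap_weight(g, v, side, k), "wave")


def random_rewire(
    g: SpatialDigraph, v: int, side: str,
    rng: np.random.Generator | int | None = None,
) -> EdgeSwap:
    """Cut a uniform member link, add a uniform complement link."""
    rng = as_rng(rng)
    members, complement = _side_candidates(g, v, side)
    k = int(rng.choice(members))
    l = int(rng.choice(complement))
    return EdgeSwap(v, side, k, l, _swap_weight(g, v, side, k), "random")


def apply_swap(g: SpatialDigraph, swap: EdgeSwap, inplace: bool = False
               ) -> SpatialDigraph:
    """Move the removed edge's weight onto the added edge.

    The removed edge must exist, the added edge must be absent, and the added
    endpoint must differ from the pivot; otherwise SwapIntegrityError.  The
    pivot's side-strength, the edge count and the weight multiset are exactly
    preserved.
    """
    v, k, l = swap.pivot, swap.removed, swap.added
    if k == l or l == v or k == v:
        raise SwapIntegrityError("swap endpoints must be distinct from the pivot")
    out = g if inplace else g.copy()
    a = out.adjacency
    if swap.side == "in":
        old, new = (v, k), (v, l)
    else:
        old, new = (k, v), (l, v)
    if not a[old] > 0:
        raise SwapIntegrityError(f"removed edge {old} absent")
    if a[new] != 0:
        raise SwapIntegrityError(f"added edge {new} already present")
    a[new] = a[old]
    a[old] = 0.0
    return out


# ---------------------------------------------------------------------------
# the rewiring loop
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    """Trajectory of one rewiring run.

    ``metrics`` has one row per checkpoint (step 0, every ``checkpoint_every``
    steps, and the final step); ``cdu_flags`` records (step, unit-present)
    pairs at the cheap-flag cadence; fingerprints identify the initial and
    final networks byte-exactly.
    """

    config: RewiringConfig
    initial: SpatialDigraph
    final: SpatialDigraph
    metrics: pd.DataFrame
    cdu_flags: pd.DataFrame
    principle_counts: dict = dc_field(default_factory=dict)

    @property
    def initial_fingerprint(self) -> str:
        return fingerprint(self.initial)

    @property
    def final_fingerprint(self) -> str:
        return fingerprint(self.final)

    def proportion_steps_no_cdu(self) -> float:
        """Share of flag evaluations at which no convergent-divergent unit existed."""
        if len(self.cdu_flags) == 0:
            return float("nan")
        return float(1.0 - self.cdu_flags["cdu_present"].mean())


def _make_swap(g: SpatialDigraph, v: int, side: str, principle: str,
               config: RewiringConfig, field: VectorField | None,
               rng: np.random.Generator) -> EdgeSwap:
    if principle == "functional":
        return functional_rewire(g, v, side, config.t, config.mode, rng)
    if principle == "distance":
        return distance_rewire(g, v, side, rng)
    if principle == "wave":
        return wave_rewire(g, v, side, field, rng)
    return random_rewire(g, v, side, rng)


def run_rewiring(
    g0: SpatialDigraph,
    config: RewiringConfig,
    checkpoint_every: int = 100,
    cdu_flag_every: int = 1,
    hub_threshold: int = 15,
    compute_modularity: bool = True,
) -> RunResult:
    """Execute ``config.steps`` rewiring steps from g0, recording metrics.

    Each step: draw side and pivot, draw principle, build and apply the swap.
    The full metric suite is evaluated at step 0, every ``checkpoint_every``
    steps, and the final step; a cheap unit-existence flag is evaluated every
    ``cdu_flag_every`` steps (0 disables it).  Fully reproducible from
    (g0, config): a single Generator seeded with ``config.seed`` drives all
    randomness.
    """
    g0.validate()
    rng = np.random.default_rng(config.seed)
    g = g0.copy()
    field = VectorField(config.field) if config.field != "none" else None

    def checkpoint(step: int) -> dict:
        rec = network_metrics.compute_metrics_record(
            g, step, hub_threshold=hub_threshold, field=field,
            compute_modularity=compute_modularity)
        return network_metrics.record_as_dict(rec)

    records = [checkpoint(0)]
    flags: list[tuple[int, bool]] = []
    counts: dict[str, int] = {}
    for step in range(1, config.steps + 1):
        try:
            v, side = select_pivot(g, config.p_in, rng)
        except PivotEligibilityError as err:
            raise PivotEligibilityError(f"step {step}: {err}") from err
        principle = choose_principle(config, rng)
        swap = _make_swap(g, v, side, principle, config, field, rng)
        apply_swap(g, swap, inplace=True)
        counts[swap.principle] = counts.get(swap.principle, 0) + 1
        if cdu_flag_every and step % cdu_flag_every == 0:
            flags.append((step, network_metrics.cdu_present(g, hub_threshold)))
        if step % checkpoint_every == 0 or step == config.steps:
            records.append(checkpoint(step))
    metrics = pd.DataFrame.from_records(records)
    cdu_flags = pd.DataFrame(flags, columns=["step", "cdu_present"])
    return RunResult(config=config, initial=g0.copy(), final=g,
                     metrics=metrics, cdu_flags=cdu_flags,
                     principle_counts=counts)
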