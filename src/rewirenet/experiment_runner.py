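"""Multi-seed experiments: conditions, sweeps, stabilization, fixtures, plots.

A *condition* is one parameter combination (p_in, principle probabilities,
mode, field); it is run for several independent instantiations (seeds
base_seed, base_seed+1, ...) and summarized by the mean and standard
deviation of every measure at the final checkpoint.  A *sweep* is the
Cartesian product of parameter grids, one ConditionSummary per point,
flattened into a long-format table.

Default experiment scale is reduced (3 runs x 3000 steps) so a sweep runs at
a desk in minutes; the full protocol (10 runs x 15000 steps) is a parameter
choice away.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .network_model import ConfigurationError, SpatialDigraph, WeightSpec, generate_random_digraph
from .network_metrics import find_cdus
from .rewiring_engine import RewiringConfig, RunResult, run_rewiring

__all__ = [
    "SweepSpec",
    "ConditionSummary",
    "run_condition",
    "sweep",
    "stabilization_step",
    "make_fixture",
    "plot_panels",
    "plot_layout",
]

#: reduced desk scale; the full protocol is runs=10, steps=15000
DEFAULT_RUNS = 3
DEFAULT_STEPS = 3000
DEFAULT_CHECKPOINT_EVERY = 100
DEFAULT_CDU_FLAG_EVERY = 10


@dataclass(frozen=True)
class SweepSpec:
    """Grids over the rewiring probabilities plus the run protocol."""

    p_in: tuple = (0.5,)
    p_distance: tuple = (0.0,)
    p_wave: tuple = (0.0,)
    p_random: tuple = (0.0,)
    mode: tuple = ("deterministic",)
    field: str = "none"
    n: int = 100
    m: int = 912
    runs: int = DEFAULT_RUNS
    steps: int = DEFAULT_STEPS
    base_seed: int = 0
    checkpoint_every: int = DEFAULT_CHECKPOINT_EVERY
    cdu_flag_every: int = DEFAULT_CDU_FLAG_EVERY
    hub_threshold: int = 15

    def conditions(self) -> list[dict]:
        out = []
        for pi, pd_, pw, pr, mo in itertools.product(
                self.p_in, self.p_distance, self.p_wave, self.p_random, self.mode):
            out.append(dict(p_in=pi, p_distance=pd_, p_wave=pw, p_random=pr,
                            mode=mo, field=self.field))
        return out

    def __post_init__(self) -> None:
        if self.runs < 1:
            raise ConfigurationError("runs must be >= 1")
        for cond in self.conditions():
            RewiringConfig(steps=1, **cond)  # validates each grid point


@dataclass
class ConditionSummary:
    """Aggregate of one condition across its instantiations.

    ``final_metrics`` holds one row per successful run (measures at the final
    checkpoint plus the proportion of no-unit steps); ``means``/``sds`` are
    its per-metric mean and population standard deviation.  Per-run
    time series and pooled final-step intermediate-subgraph densities are
    retained for downstream analyses.
    """

    params: dict
    n_runs: int
    seeds: list[int]
    final_metrics: pd.DataFrame
    means: pd.Series
    sds: pd.Series
    timeseries: list[pd.DataFrame]
    intermediate_densities: np.ndarray
    failures: list[tuple[int, str]] = dc_field(default_factory=list)


def run_condition(
    params: dict,
    runs: int = DEFAULT_RUNS,
    steps: int = DEFAULT_STEPS,
    base_seed: int = 0,
    n: int = 100,
    m: int = 912,
    weights: WeightSpec = WeightSpec(),
    checkpoint_every: int = DEFAULT_CHECKPOINT_EVERY,
    cdu_flag_every: int = DEFAULT_CDU_FLAG_EVERY,
    hub_threshold: int = 15,
    seeds: list[int] | None = None,
    compute_modularity: bool = True,
) -> ConditionSummary:
    """Run one condition for several instantiations and aggregate.

    Each instantiation generates its own initial random digraph and runs the
    rewiring loop, both from seed base_seed + i (``seeds`` overrides the
    sequence).  Aggregation uses the population standard deviation, so a
    single run, or repeated identical seeds, give sd = 0.  Run failures are
    recorded per seed and excluded from the aggregates.
    """
    seeds = list(seeds) if seeds is not None else [base_seed + i for i in range(runs)]
    rows, series, failures = [], [], []
    pooled_densities: list[float] = []
    for seed in seeds:
        config = RewiringConfig(steps=steps, seed=seed, **params)
        try:
            g0 = generate_random_digraph(n, m, weights, rng=seed)
            result = run_rewiring(
                g0, config, checkpoint_every=checkpoint_every,
                cdu_flag_every=cdu_flag_every, hub_threshold=hub_threshold,
                compute_modularity=compute_modularity)
        except Exception as err:  # noqa: BLE001 - recorded, summary marks the run
            failures.append((seed, f"{type(err).__name__}: {err}"))
            continue
        final = result.metrics.iloc[-1].copy()
        final["proportion_steps_no_cdu"] = result.proportion_steps_no_cdu()
        final["seed"] = seed
        rows.append(final)
        series.append(result.metrics.assign(seed=seed))
        pooled_densities.extend(
            u.intermediate_density for u in find_cdus(result.final, hub_threshold)
            if u.intermediate_density is not None)
    final_metrics = pd.DataFrame(rows).reset_index(drop=True)
    numeric = final_metrics.drop(columns=["seed"], errors="ignore").apply(
        pd.to_numeric, errors="coerce")
    means = numeric.mean()
    sds = numeric.std(ddof=0)
    return ConditionSummary(
        params=dict(params), n_runs=len(rows), seeds=seeds,
        final_metrics=final_metrics, means=means, sds=sds,
        timeseries=series,
        intermediate_densities=np.asarray(pooled_densities, dtype=float),
        failures=failures)


def sweep(spec: SweepSpec, weights: WeightSpec = WeightSpec(),
          compute_modularity: bool = True) -> tuple[pd.DataFrame, list[ConditionSummary]]:
    """Run every grid point of ``spec``; long-format table plus summaries.

    The table has one row per (condition, metric) with the mean and standard
    deviation over instantiations; partial failures are reported in the
    summaries' ``failures`` lists.
    """
    summaries, rows = [], []
    for cond in spec.conditions():
        summary = run_condition(
            cond, runs=spec.runs, steps=spec.steps, base_seed=spec.base_seed,
            n=spec.n, m=spec.m, weights=weights,
            checkpoint_every=spec.checkpoint_every,
            cdu_flag_every=spec.cdu_flag_every,
            hub_threshold=spec.hub_threshold,
            compute_modularity=compute_modularity)
        summaries.append(summary)
        for metric in summary.means.index:
            rows.append({**cond, "metric": metric,
                         "mean": summary.means[metric],
                         "sd": summary.sds[metric],
                         "n_runs": summary.n_runs})
    return pd.DataFrame(rows), summaries


def stabilization_step(steps: np.ndarray, values: np.ndarray,
                       tolerance: float = 0.1) -> int:
    """First checkpoint after which the series stays in the terminal band.

    The terminal mean is the mean of the last 10% of checkpoints (at least
    one); the band is +/- ``tolerance`` x |terminal mean|.  Returns the step
    of the first checkpoint from which every subsequent value (itself
    included) lies inside the band, or the final step if the series never
    settles.
    """
    steps = np.asarray(steps)
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 checkpoints")
    tail = max(1, int(round(0.1 * values.size)))
    terminal = values[-tail:].mean()
    band = tolerance * abs(terminal)
    inside = np.abs(values - terminal) <= band
    # first index i with inside[i:] all True
    suffix_ok = np.flip(np.cumprod(np.flip(inside))).astype(bool)
    idx = np.flatnonzero(suffix_ok)
    return int(steps[idx[0]]) if idx.size else int(steps[-1])


# ---------------------------------------------------------------------------
# deterministic fixtures
# ---------------------------------------------------------------------------

def _circle_coords(n: int, radius: float = 0.8) -> np.ndarray:
    theta = 2 * np.pi * np.arange(n) / n
    return radius * np.column_stack([np.cos(theta), np.sin(theta)])


def make_fixture(name: str) -> SpatialDigraph:
    """Small deterministic graphs used across the test-suite and docs.

    Tags: "two-node-single-edge" (edge 1 -> 0), "three-cycle",
    "cdu-minimal" (exactly one convergent-divergent unit at threshold 15),
    "two-cliques" (two disconnected complete loopless digraphs on 5 nodes),
    "complete-4".
    """
    if name == "two-node-single-edge":
        a = np.zeros((2, 2))
        a[0, 1] = 1.0  # edge 1 -> 0
        coords = np.array([[-0.5, 0.0], [0.5, 0.0]])
        return SpatialDigraph(a, coords)
    if name == "three-cycle":
        a = np.zeros((3, 3))
        for j, i in [(0, 1), (1, 2), (2, 0)]:
            a[i, j] = 1.0
        return SpatialDigraph(a, _circle_coords(3))
    if name == "complete-4":
        a = np.ones((4, 4)) - np.eye(4)
        return SpatialDigraph(a, _circle_coords(4, 0.6))
    if name == "two-cliques":
        a = np.zeros((10, 10))
        for block in (range(5), range(5, 10)):
            for i in block:
                for j in block:
                    if i != j:
                        a[i, j] = 1.0
        coords = np.vstack([_circle_coords(5, 0.3) - (0.5, 0),
                            _circle_coords(5, 0.3) + (0.5, 0)])
        return SpatialDigraph(a, coords)
    if name == "cdu-minimal":
        # c=0 collects 16 in-links and feeds u=1; u feeds d=2, which
        # broadcasts to 16 targets: one unit with intermediate set {1}.
        n = 35
        c, u, d = 0, 1, 2
        sources = range(3, 19)
        targets = range(19, 35)
        a = np.zeros((n, n))
        for s in sources:
            a[c, s] = 1.0
        a[u, c] = 1.0
        a[d, u] = 1.0
        for t in targets:
            a[t, d] = 1.0
        return SpatialDigraph(a, _circle_coords(n, 0.9))
    raise KeyError(f"unknown fixture tag {name!r}")


# ---------------------------------------------------------------------------
# figure-style outputs (conveniences; analyses read the tables)
# ---------------------------------------------------------------------------

def _new_figure():
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    fig = Figure(figsize=(5, 4))
    FigureCanvasAgg(fig)
    return fig


def plot_panels(table: pd.DataFrame, x: str, metrics: list[str], out_dir,
                hue: str = "p_in", fmt: str = "png") -> list[str]:
    """Metric-vs-probability line plots with sd error bands, one file each."""
    import pathlib

    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for metric in metrics:
        sub = table[table["metric"] == metric]
        if sub.empty:
            raise KeyError(f"metric {metric!r} not present in the table")
        fig = _new_figure()
        ax = fig.add_subplot(111)
        for hv, grp in sub.groupby(hue):
            grp = grp.sort_values(x)
            ax.plot(grp[x], grp["mean"], marker="o", label=f"{hue}={hv}")
            ax.fill_between(grp[x], grp["mean"] - grp["sd"],
                            grp["mean"] + grp["sd"], alpha=0.2)
        ax.set_xlabel(x)
        ax.set_ylabel(metric)
        ax.legend(fontsize=8)
        path = out_dir / f"{metric}_vs_{x}.{fmt}"
        fig.savefig(path, dpi=120)
        paths.append(str(path))
    return paths


def plot_layout(g: SpatialDigraph, path) -> str:
    """Spatial snapshot: nodes at their coordinates, edges as arrows."""
    fig = _new_figure()
    ax = fig.add_subplot(111)
    heads, tails = np.nonzero(g.adjacency > 0)
    for i, j in zip(heads, tails):
        x0, y0 = g.coordinates[j]
        x1, y1 = g.coordinates[i]
        ax.annotate("", xy=(x1, y1), xytext=(x0, y0),
                    arrowprops=dict(arrowstyle="->", lw=0.5, alpha=0.6))
    ax.scatter(g.coordinates[:, 0], g.coordinates[:, 1], s=12, zorder=3)
    ax.set_aspect("equal")
    ax.set_xlim(-1.1, 1.1)
    ax.set_ylim(-1.1, 1.1)
    fig.savefig(path, dpi=120)
    return str(path)
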