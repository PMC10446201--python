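# Methods

## Model

The simulator evolves a fixed-size directed weighted graph embedded in the
plane. The state is the adjacency matrix `A` (convention: `A[i, j]` is the
weight of edge `j → i`; rows are in-links) plus fixed node coordinates
inside the closed unit disk. Network evolution is pure rewiring: node count,
edge count and the multiset of edge weights never change; one edge moves
per step and carries its weight with it, so the pivot node's in- (or out-)
strength is invariant across the step that rewires that side.

Signal traffic is summarized by the linear flows `x'(t) = −L x(t)`:
consensus dynamics uses the in-degree Laplacian `L_in = D_in − A` and
drives node states toward agreement; advection uses the out-degree
Laplacian `L_out = D_out − A` and transports concentration along edges,
conserving the total. Their kernels `c(t) = e^{−L_in t}` and
`a(t) = e^{−L_out t}` are row- and column-stochastic respectively, entrywise
non-negative, and entry `(i, j)` is positive exactly when `j` can reach `i`
— the property that makes them a usable "traffic intensity" score for
rewiring. Both are assumptions of the model, not fitted quantities: nodes
stand for pools of excitatory neurons whose inhibitory balancing is
implicit in the homeostatic character of the dynamics.

One rewiring step:

1. draw `r1 ~ U[0,1]`; rewire an in-link if `r1 < p_in`, else an out-link;
   draw the pivot `v` uniformly among nodes whose degree on that side is in
   `{1, …, n−2}` (if none exists the run stops with an explicit error — the
   side is not silently re-drawn; at the default density this never occurs);
2. draw `r2 ~ U[0,1]` over the partition
   `distance | wave | functional | random` with probabilities
   `p_distance, p_wave, p_function, p_random` summing to 1
   (`p_function` defaults to the remainder);
3. the chosen principle picks the member link to cut and the complement
   node to connect; the new link takes the cut link's weight.

Functional rewiring recomputes the kernel from the current adjacency at
every step (no caching: each swap changes the Laplacian). In deterministic
mode it cuts the argmin / adds the argmax of the kernel scores, with exact
ties broken uniformly at random; the tie-break draw is consumed even when
the optimum is unique so the RNG stream advances identically in all cases.
In stochastic mode the cut distribution is ∝ 1/value and the add
distribution ∝ value; a zero kernel value has infinite reciprocal, so when
any member scores 0 the cut is uniform over the zero-valued members (the
limit of the formula), and an all-zero add profile falls back to uniform.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n` | 100 | nodes |
| `m` | 912 | directed edges (required explicitly for other `n`) |
| weights | `N(1, 0.25²)` | raw weight distribution; draws ≤ 0 (probability 3.17e−5) are set to 0.05 before normalization; normalization divides by the sample mean so the weights sum to `m`. A lognormal family is available with user-chosen parameters. |
| coordinates | uniform by area | `r = √U`, `θ = 2πU` on the unit disk |
| `p_in` | 0.5 | probability of rewiring an in-link (consensus side) |
| `p_distance, p_wave, p_random` | 0 | spatial/baseline mixing probabilities |
| `t` | 1.0 | kernel interval between rewiring events |
| `M` (steps) | 15000 | rewiring steps per run |
| hub threshold | 15 | strict: a convergent hub has in-degree > 15 and ≥ 1 out-link (an inclusive-≥ option exists) |
| instantiations | 10 (full scale) / 3 (desk scale) | runs per condition, seeds `base, base+1, …` |

Hub degrees are binary link counts, not strengths. Reciprocal edges are
legal: the complement for a new in-link of `v` excludes only existing
in-links, so `l → v` may be added while `v → l` exists.

## Measures

- **Average efficiency**: mean of `1/ℓ_ij` over ordered pairs `i ≠ j`,
  where `ℓ_ij` is the shortest directed path length under topological edge
  lengths `1/w`; unreachable pairs contribute 0. Computed with Dijkstra on
  the dense length matrix. Self-pairs are excluded here but *included* in
  the connected-pairs count — the two measures intentionally differ.
- **Connected node pairs**: ordered pairs joined by a directed path of
  length ≥ 1, self-pairs counting exactly when the node lies on a cycle, so
  the bound `n²` is attainable. Computed by boolean transitive closure via
  repeated squaring.
- **Hubs and convergent-divergent units (CDUs)**: one unit per ordered pair
  (convergent hub `c`, divergent hub `d`), `c ≠ d`, with a directed path
  `c → d`. Sources are nodes that reach `c`; targets nodes reached from
  `d`; intermediates the nodes (excluding the hub pair) reachable from `c`
  that reach `d`, i.e. nodes on directed *walks* from `c` to `d`. The
  walk-based definition is used because simple-path membership is
  exponentially hard in general; on small instances the walk set can
  strictly contain the simple-path set, and the tests assert the inclusion.
  Intermediate-subgraph density is the binary density
  `edges / (n_s (n_s − 1))`, defined only for `n_s ≥ 2`; smaller subgraphs
  are excluded from aggregation.
- **Modularity**: directed weighted Newman modularity of a partition found
  by Louvain with a fixed seed (resolution 1). The choice of community
  algorithm is a package decision — users comparing against other software
  should fix the partition explicitly (the function accepts one).
- **Spatial statistics**: mean Euclidean edge length, and mean cosine
  between each edge and the field evaluated at the edge midpoint (for the
  lateral field the evaluation point is immaterial).

Per-run bookkeeping: the full measure suite is evaluated at step 0, every
`checkpoint_every` steps (default 100) and the final step; a cheap
unit-existence flag (BFS from the convergent hubs only) runs every
`cdu_flag_every` steps (default 1; 10 at sweep scale) and yields the
proportion of steps without a CDU.

## Numerical choices

- Matrix exponentials use dense scaling-and-squaring. Exact kernels are
  provably non-negative; entries within `1e−9` below zero are clamped to 0
  and anything worse raises an error. Row/column stochasticity holds to
  < 1e−9 at `n = 100` (asserted on 100 random graphs in the tests).
- Kernel positivity is numerically identified with reachability at an
  entrywise threshold of `1e−12`.
- Ties in the distance and wave principles are broken uniformly at random,
  matching the functional principle's stated tie rule.
- The radial field is undefined at the origin; a pivot exactly there (a
  measure-zero event) falls back to random rewiring for that step and is
  logged.
- Stabilization of a checkpoint series: terminal mean = mean of the last
  10% of checkpoints; the reported step is the first checkpoint from which
  every subsequent value stays within a ±10% (configurable) relative band,
  with the final step as the "never stabilized" sentinel. On single
  instantiations the checkpoint-to-checkpoint fluctuation of connectedness
  and efficiency is of order 10–15% of the mean, so this per-run detector is
  conservative: a series that is stationary by eye can still report the
  sentinel. This is a known property of the detector, not of the dynamics.
- All randomness in a run comes from one numpy `Generator` seeded by the
  config; draws occur in a fixed documented order (side, pivot, principle,
  principle-internal draws), making trajectories byte-reproducible.

## Synthetic data and what the tests show

All inputs are generated internally; there is no empirical data path. The
generator emulates the study conditions (sparse random digraph at density
0.092, near-unit normal weights, area-uniform disk embedding). It does not
emulate features of real connectomes — degree correlations, geometric
contact constraints, distance-dependent wiring priors, neuron types — so
passing tests demonstrate properties of the *model* (conservation laws,
kernel algebra, measure correctness, directional parameter effects), not
claims about biological networks.

Experiment scale: sweeps default to 3 instantiations × 3000 steps per
condition with checkpoints every 100 steps and the unit flag every 10 — the
package's desk-scale protocol, chosen so a full trend suite runs in minutes
— while the full protocol (10 × 15000, per-step flags) is available through
the same interfaces. The trend comparisons in the tests use endpoint grid
values ({0.1, 0.9}, and {0, 0.5} where a claim names them); the
random-versus-distance efficiency comparison is made on the mean over the
matched mixing-proportion grid, because at a single matched point (0.5) the
difference is smaller than seed noise at desk scale while across the grid
the direction is unambiguous.

## Known limitations

- Principle probabilities are constant within a run; time-varying schedules
  are out of scope.
- Networks neither grow nor prune; 3-D embeddings and multigraphs are
  unsupported.
- The intermediate-node definition is walk-based (see above); brute-force
  simple-path enumeration can disagree on adversarial small graphs.
- At `n ≈ 100` the dense kernel recomputation is ~1 ms/step; the design
  point is desk-scale `n`, not large sparse networks (no Krylov
  approximations).
- The edge-count default 912 is tied to `n = 100`; other sizes require an
  explicit `m`.
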