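import numpy as np
import pytest

import rewirenet as rw
from rewirenet.network_model import ConfigurationError
from rewirenet.rewiring_engine import (
    PivotEligibilityError,
    SwapIntegrityError,
    UndefinedAngleError,
    _principle_from_draw,
    add_probabilities,
    cut_probabilities,
)


def graph_from_edges(n, edges, coords=None):
    """edges: iterable of (tail, head, weight) in information-flow direction."""
    a = np.zeros((n, n))
    for j, i, w in edges:
        a[i, j] = w
    c = np.zeros((n, 2)) if coords is None else np.asarray(coords, float)
    return rw.SpatialDigraph(a, c)


class TestSelectPivot:
    def test_p_in_one_always_rewires_in_links(self, study_graph):
        rng = np.random.default_rng(0)
        sides = {rw.select_pivot(study_graph, 1.0, rng)[1] for _ in range(50)}
        assert sides == {"in"}

    def test_unique_eligible_node_is_chosen(self):
        # only node 2 has in-degree in {1, ..., n-2}: 0 has none, 1 has n-1
        g = graph_from_edges(4, [(0, 1, 1), (2, 1, 1), (3, 1, 1), (0, 2, 1)])
        rng = np.random.default_rng(1)
        for _ in range(10):
            v, side = rw.select_pivot(g, 1.0, rng)
            assert side == "in" and v == 2

    def test_complete_digraph_has_no_eligible_pivot(self, complete4):
        with pytest.raises(PivotEligibilityError):
            rw.select_pivot(complete4, 1.0, rng=0)
        with pytest.raises(PivotEligibilityError):
            rw.select_pivot(complete4, 0.0, rng=0)


class TestChoosePrinciple:
    @pytest.mark.parametrize("r2, expected", [
        (0.0, "distance"), (0.29, "distance"), (0.45, "wave"),
        (0.61, "functional"), (0.95, "functional"),
    ])
    def test_partition_order_distance_wave_functional(self, r2, expected):
        config = rw.RewiringConfig(p_distance=0.3, p_wave=0.3, field="lateral")
        assert _principle_from_draw(config, r2) == expected

    def test_random_takes_the_remainder(self):
        config = rw.RewiringConfig(p_distance=0.2, p_random=0.5)
        assert _principle_from_draw(config, 0.95) == "random"
        assert _principle_from_draw(config, 0.45) == "functional"

    def test_pure_distance_always_distance(self):
        config = rw.RewiringConfig(p_distance=1.0)
        rng = np.random.default_rng(0)
        assert {rw.choose_principle(config, rng) for _ in range(20)} == {"distance"}

    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            rw.RewiringConfig(p_distance=0.6, p_random=0.6)
        with pytest.raises(ConfigurationError):
            rw.RewiringConfig(p_distance=0.5, p_random=0.2, p_function=0.5)


class TestStochasticDistributions:
    def test_cut_probabilities_inverse_to_kernel_values(self):
        assert np.allclose(cut_probabilities([1.0, 3.0]), [0.75, 0.25])

    def test_add_probabilities_proportional_to_kernel_values(self):
        assert np.allclose(add_probabilities([1.0, 3.0]), [0.25, 0.75])

    def test_zero_kernel_values_dominate_cutting(self):
        assert np.allclose(cut_probabilities([0.0, 2.0, 0.0]), [0.5, 0.0, 0.5])

    def test_all_zero_add_values_fall_back_to_uniform(self):
        assert np.allclose(add_probabilities([0.0, 0.0]), [0.5, 0.5])


class TestFunctionalRewire:
    def test_deterministic_cuts_min_adds_max(self):
        # pivot 0 in-links from 1 (strong) and 2 (weak); 3 unreachable, 4
        # reaches 0 via 1 so it has positive kernel value -> added
        g = graph_from_edges(5, [(1, 0, 5.0), (2, 0, 0.01), (4, 1, 5.0)])
        swap = rw.functional_rewire(g, 0, "in", mode="deterministic", rng=0)
        assert swap.removed == 2
        assert swap.added == 4
        assert swap.weight == pytest.approx(0.01)

    def test_modes_coincide_with_single_candidates(self):
        g = graph_from_edges(3, [(1, 0, 2.0)])
        det = rw.functional_rewire(g, 0, "in", mode="deterministic", rng=0)
        sto = rw.functional_rewire(g, 0, "in", mode="stochastic", rng=1)
        assert (det.removed, det.added) == (sto.removed, sto.added) == (1, 2)
        assert det.weight == sto.weight == pytest.approx(2.0)

    def test_out_side_uses_advection_flow(self):
        # pivot 0 sends to 1 (strong) and 2 (weak); 3 receives from 1, so
        # out-flow from 0 reaches 3 -> 3 is the best new out-link
        g = graph_from_edges(4, [(0, 1, 5.0), (0, 2, 0.01), (1, 3, 5.0)])
        swap = rw.functional_rewire(g, 0, "out", mode="deterministic", rng=0)
        assert swap.side == "out"
        assert swap.removed == 2
        assert swap.added == 3


class TestDistanceRewire:
    def test_cuts_farthest_adds_closest(self):
        coords = [(0, 0), (0.9, 0), (0.2, 0), (0.1, 0), (0.5, 0)]
        g = graph_from_edges(5, [(1, 0, 1.0), (2, 0, 1.0)], coords)
        swap = rw.distance_rewire(g, 0, "in", rng=0)
        assert swap.removed == 1  # distance 0.9 > 0.2
        assert swap.added == 3  # distance 0.1 < 0.5

    def test_equidistant_members_cut_uniformly(self):
        coords = [(0, 0), (0.5, 0), (-0.5, 0), (0, 0.9)]
        g = graph_from_edges(4, [(1, 0, 1.0), (2, 0, 1.0)], coords)
        cuts = [rw.distance_rewire(g, 0, "in", rng=s).removed for s in range(400)]
        freq = np.mean(np.array(cuts) == 1)
        assert 0.4 < freq < 0.6


class TestEdgeFieldCosine:
    @pytest.mark.parametrize("head, tail, expected", [
        ((1, 0), (0, 0), 1.0), ((0, 0), (1, 0), -1.0), ((0, 1), (0, 0), 0.0),
    ])
    def test_alignment_examples(self, head, tail, expected):
        assert rw.edge_field_cosine(head, tail, (1.0, 0.0)) == pytest.approx(expected)

    def test_undefined_angles_rejected(self):
        with pytest.raises(UndefinedAngleError):
            rw.edge_field_cosine((0, 0), (0, 0), (1, 0))
        with pytest.raises(UndefinedAngleError):
            rw.edge_field_cosine((1, 0), (0, 0), (0, 0))


class TestWaveRewire:
    def test_lateral_field_prefers_westward_tails(self):
        # in-link tails: 1 east of pivot (cos -1, cut), 2 north (cos 0);
        # complement: 3 west (cos +1, added), 4 north-west
        coords = [(0, 0), (0.5, 0), (0, 0.5), (-0.5, 0), (-0.3, 0.4)]
        g = graph_from_edges(5, [(1, 0, 1.0), (2, 0, 1.0)], coords)
        swap = rw.wave_rewire(g, 0, "in", rw.VectorField("lateral"), rng=0)
        assert swap.removed == 1
        assert swap.added == 3

    def test_radial_field_matches_lateral_on_positive_x_axis(self):
        coords = [(0.5, 0), (0.9, 0), (0.5, 0.4), (0.1, 0), (0.5, -0.4)]
        g = graph_from_edges(5, [(1, 0, 1.0), (2, 0, 1.0)], coords)
        lat = rw.wave_rewire(g, 0, "in", rw.VectorField("lateral"), rng=0)
        rad = rw.wave_rewire(g, 0, "in", rw.VectorField("radial"), rng=0)
        assert (lat.removed, lat.added) == (rad.removed, rad.added)

    def test_radial_field_at_origin_falls_back_to_random(self):
        coords = [(0, 0), (0.5, 0), (0, 0.5), (-0.5, 0)]
        g = graph_from_edges(4, [(1, 0, 1.0), (2, 0, 1.0)], coords)
        swap = rw.wave_rewire(g, 0, "in", rw.VectorField("radial"), rng=0)
        assert swap.principle == "wave_fallback_random"
        assert swap.removed in {1, 2} and swap.added == 3


class TestRandomRewire:
    def test_unique_swap(self):
        g = graph_from_edges(3, [(1, 0, 1.0)])
        swap = rw.random_rewire(g, 0, "in", rng=0)
        assert (swap.removed, swap.added) == (1, 2)

    def test_cut_choice_uniform_over_members(self):
        g = graph_from_edges(6, [(j, 0, 1.0) for j in range(1, 5)])
        rng = np.random.default_rng(0)
        cuts = np.array([rw.random_rewire(g, 0, "in", rng).removed
                         for _ in range(4000)])
        for j in range(1, 5):
            assert 0.2 < np.mean(cuts == j) < 0.3

    def test_never_selects_pivot_as_new_endpoint(self):
        g = graph_from_edges(4, [(1, 0, 1.0), (2, 0, 1.0)])
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert rw.random_rewire(g, 0, "in", rng).added != 0


class TestApplySwap:
    def test_weight_transfers_to_new_edge(self):
        g = graph_from_edges(3, [(1, 0, 0.7)])
        swap = rw.EdgeSwap(0, "in", 1, 2, 0.7, "random")
        out = rw.apply_swap(g, swap)
        assert out.adjacency[0, 1] == 0.0
        assert out.adjacency[0, 2] == pytest.approx(0.7)

    def test_pivot_in_strength_invariant(self, study_graph):
        g = study_graph.copy()
        swap = rw.random_rewire(g, 10, "in", rng=0)
        before = rw.strength(g, 10, "in")
        after = rw.strength(rw.apply_swap(g, swap), 10, "in")
        assert after == pytest.approx(before)

    def test_out_degrees_shift_by_one_on_in_side_swap(self):
        g = graph_from_edges(4, [(1, 0, 1.0), (1, 3, 1.0)])
        swap = rw.EdgeSwap(0, "in", 1, 2, 1.0, "random")
        out = rw.apply_swap(g, swap)
        assert out.out_degrees()[1] == g.out_degrees()[1] - 1
        assert out.out_degrees()[2] == g.out_degrees()[2] + 1

    def test_inconsistent_swaps_rejected(self):
        g = graph_from_edges(3, [(1, 0, 1.0)])
        with pytest.raises(SwapIntegrityError):
            rw.apply_swap(g, rw.EdgeSwap(0, "in", 2, 1, 1.0, "random"))  # absent edge
        with pytest.raises(SwapIntegrityError):
            rw.apply_swap(g, rw.EdgeSwap(0, "in", 1, 0, 1.0, "random"))  # self-loop


class TestRunRewiring:
    def test_zero_steps_records_only_initial_state(self, study_graph):
        config = rw.RewiringConfig(p_random=1.0, steps=0, seed=0)
        result = rw.run_rewiring(study_graph, config)
        assert len(result.metrics) == 1
        assert result.final_fingerprint == rw.fingerprint(study_graph)

    def test_conservation_over_a_mixed_run(self, study_graph):
        config = rw.RewiringConfig(p_distance=0.3, p_wave=0.2, p_random=0.2,
                                   field="lateral", steps=300, seed=5)
        result = rw.run_rewiring(study_graph, config, checkpoint_every=300,
                                 cdu_flag_every=0, compute_modularity=False)
        assert result.final.m == study_graph.m
        assert np.allclose(rw.weight_multiset(result.final),
                           rw.weight_multiset(study_graph))
        assert np.all(np.diag(result.final.adjacency) == 0)

    def test_trajectory_fully_deterministic(self, study_graph):
        config = rw.RewiringConfig(p_random=0.5, steps=200, seed=11)
        r1 = rw.run_rewiring(study_graph, config, checkpoint_every=50)
        r2 = rw.run_rewiring(study_graph, config, checkpoint_every=50)
        assert r1.final_fingerprint == r2.final_fingerprint
        assert r1.metrics.equals(r2.metrics)
        assert r1.cdu_flags.equals(r2.cdu_flags)


class TestPrincipleTrends:
    """Directional signatures of each principle on short pure runs."""

    def _final(self, params, seed, steps=500):
        g0 = rw.generate_random_digraph(100, 912, rng=seed)
        config = rw.RewiringConfig(steps=steps, seed=seed, **params)
        result = rw.run_rewiring(g0, config, checkpoint_every=steps,
                                 cdu_flag_every=0, compute_modularity=False)
        return g0, result

    def test_pure_distance_rewiring_shortens_edges(self):
        wins = 0
        for seed in range(10):
            g0, res = self._final(dict(p_distance=1.0), seed)
            first, last = res.metrics["mean_edge_length"].iloc[[0, -1]]
            wins += last < first
        assert wins >= 8

    def test_pure_lateral_wave_rewiring_aligns_edges(self):
        wins = 0
        for seed in range(10):
            g0, res = self._final(dict(p_wave=1.0, field="lateral"), seed)
            first, last = res.metrics["mean_edge_cosine"].iloc[[0, -1]]
            wins += last > first
        assert wins >= 8

    def test_pure_functional_rewiring_spreads_degrees(self):
        wins = 0
        for seed in range(10):
            g0, res = self._final(dict(), seed)  # p_function defaults to 1
            before = g0.in_degrees().var() + g0.out_degrees().var()
            after = (res.final.in_degrees().var()
                     + res.final.out_degrees().var())
            wins += after > before
        assert wins >= 8

    def test_functional_out_rewiring_grows_winner_take_all_in_hubs(self):
        # pure adaptive rewiring of out-links concentrates in-links on a few
        # winners within the first ~1000 steps
        wins = 0
        for seed in range(10):
            g0 = rw.generate_random_digraph(100, 912, rng=seed)
            config = rw.RewiringConfig(p_in=0.0, steps=1000, seed=seed)
            res = rw.run_rewiring(g0, config, checkpoint_every=1000,
                                  cdu_flag_every=0, compute_modularity=False)
            wins += res.final.in_degrees().max() > g0.in_degrees().max()
        assert wins >= 9
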