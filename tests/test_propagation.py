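"""Transition operator, restart-walk propagation, and cosine comparison."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirank.interactome import (
    FF,
    PF,
    PP,
    Edge,
    build_interactome,
    make_seed_vector,
)
from mirank.propagation import (
    WalkParams,
    build_transition_operator,
    cosine_similarity,
    load_walk_params,
    propagate,
    propagate_many,
    read_profile,
    stationary_oracle,
    write_profile,
)

from conftest import path_interactome, random_interactome


class TestWalkParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"r": 0.0},
            {"r": 1.5},
            {"k": 0},
            {"bias_weights": {"pp": 1.0}},
            {"bias_weights": {t: 0.0 for t in ("pp", "pf", "fp", "ff_up", "ff_down")}},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            WalkParams(**kwargs)

    def test_yaml_config_round_trip(self, tmp_path):
        (tmp_path / "cfg.yaml").write_text(
            "walk:\n  r: 0.3\n  k: 50\n  weights:\n    pf: 2.5\n"
        )
        params = load_walk_params(tmp_path / "cfg.yaml")
        assert params.r == 0.3 and params.k == 50
        assert params.bias_weights["pf"] == 2.5
        assert params.bias_weights["pp"] == 1.0  # default preserved


class TestTransitionOperator:
    def test_bias_weights_set_row_probabilities(self):
        # protein P2 has one protein neighbor and one function neighbor:
        # with weights pp=1, pf=2 its row must split 1/3 vs 2/3
        graph = build_interactome(
            {PP: [Edge("P1", "P2", PP)], PF: [Edge("P2", "F1", PF)]}
        )
        weights = {"pp": 1.0, "pf": 2.0, "fp": 1.0, "ff_up": 1.0, "ff_down": 1.0}
        op = build_transition_operator(graph, WalkParams(bias_weights=weights))
        i = graph.node_index["P2"]
        row = op.matrix[i].toarray().ravel()
        assert row[graph.node_index["P1"]] == pytest.approx(1 / 3)
        assert row[graph.node_index["F1"]] == pytest.approx(2 / 3)

    def test_equal_weights_match_simple_random_walk(self, toy_interactome):
        op = build_transition_operator(toy_interactome, WalkParams())
        deg = np.zeros(toy_interactome.n_nodes)
        for e in toy_interactome.edges:
            deg[toy_interactome.node_index[e.source]] += 1
            deg[toy_interactome.node_index[e.target]] += 1
        dense = op.matrix.toarray()
        for i in range(toy_interactome.n_nodes):
            nz = dense[i][dense[i] > 0]
            assert np.allclose(nz, 1.0 / deg[i])

    def test_rows_stochastic_and_hierarchy_weights_directional(self):
        graph = build_interactome(
            {PP: [Edge("P1", "P2", PP)], PF: [Edge("P1", "F1", PF)],
             FF: [Edge("F1", "F0", FF)]}
        )
        weights = {"pp": 1.0, "pf": 1.0, "fp": 1.0, "ff_up": 3.0, "ff_down": 0.5}
        op = build_transition_operator(graph, WalkParams(bias_weights=weights))
        sums = np.asarray(op.matrix.sum(axis=1)).ravel()
        assert np.allclose(sums[~op.dangling], 1.0, atol=1e-12)
        f1, f0, p1 = (graph.node_index[n] for n in ("F1", "F0", "P1"))
        dense = op.matrix.toarray()
        # child F1 -> parent F0 uses ff_up; parent -> child uses ff_down
        assert dense[f1, f0] == pytest.approx(3.0 / 4.0)
        assert dense[f0, f1] == pytest.approx(1.0)

    def test_connected_graph_has_no_dangling_rows(self, toy_interactome):
        # every stored edge is traversable both ways, so graphs built from
        # edge lists never produce dangling rows
        op = build_transition_operator(toy_interactome, WalkParams())
        assert not op.dangling.any()

    def test_dangling_row_flagged_and_mass_redirected(self):
        # hand-built operator with an out-degree-zero node: a walk seeded
        # there collapses to a delta profile (restart is the only move)
        import scipy.sparse as sp

        from mirank.interactome import SeedVector
        from mirank.propagation import TransitionOperator

        matrix = sp.csr_matrix(np.array([[0.0, 0.0], [1.0, 0.0]]))
        op = TransitionOperator(matrix=matrix, dangling=np.array([True, False]))
        seed = SeedVector(values=np.array([1.0, 0.0]), n_seeds=1, missing_ids=[])
        dp = propagate(op, seed, WalkParams(r=0.3, k=100))
        assert np.allclose(dp.values, [1.0, 0.0])
        assert dp.values.sum() == pytest.approx(1.0, abs=1e-12)


class TestPropagate:
    def test_two_node_fixed_point(self, two_node_interactome):
        """A-B single edge, seed {A}, r=0.5: closed form gives (2/3, 1/3)."""
        params = WalkParams(r=0.5, k=1000)
        op = build_transition_operator(two_node_interactome, params)
        seed = make_seed_vector(two_node_interactome, {"A"})
        dp = propagate(op, seed, params)
        expect = np.zeros(2)
        expect[two_node_interactome.node_index["A"]] = 2 / 3
        expect[two_node_interactome.node_index["B"]] = 1 / 3
        assert np.allclose(dp.values, expect, atol=1e-9)

    def test_pure_restart_returns_seed_distribution(self, toy_interactome):
        params = WalkParams(r=1.0, k=5)
        op = build_transition_operator(toy_interactome, params)
        seed = make_seed_vector(toy_interactome, {"P1", "P3"})
        dp = propagate(op, seed, params)
        assert np.allclose(dp.values, seed.values / 2)

    def test_conservation_and_nonnegativity(self, rng):
        graph = random_interactome(rng)
        params = WalkParams(k=200)
        op = build_transition_operator(graph, params)
        for start in ("P0", "P10", "P25"):
            dp = propagate(op, make_seed_vector(graph, {start}), params)
            assert dp.values.min() >= 0
            assert dp.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_mirror_symmetry(self):
        # path P1..P5, seed at center P3: profile symmetric about the axis
        graph = path_interactome(5)
        params = WalkParams(k=500)
        op = build_transition_operator(graph, params)
        dp = propagate(op, make_seed_vector(graph, {"P3"}), params)
        idx = graph.node_index
        assert dp.values[idx["P1"]] == pytest.approx(dp.values[idx["P5"]], abs=1e-12)
        assert dp.values[idx["P2"]] == pytest.approx(dp.values[idx["P4"]], abs=1e-12)

    def test_seed_beats_distant_nodes_on_path(self):
        graph = path_interactome(8)
        params = WalkParams(k=500)
        op = build_transition_operator(graph, params)
        dp = propagate(op, make_seed_vector(graph, {"P1"}), params)
        idx = graph.node_index
        for far in ("P5", "P6", "P7", "P8"):
            assert dp.values[idx["P1"]] > dp.values[idx[far]]

    def test_permutation_equivariance(self, toy_edges):
        mapping = {"P1": "X3", "P2": "X1", "P3": "X2", "F1": "H2", "F2": "H1"}
        relabeled = {
            t: [Edge(mapping[e.source], mapping[e.target], t) for e in es]
            for t, es in toy_edges.items()
        }
        a = build_interactome(toy_edges)
        b = build_interactome(relabeled)
        params = WalkParams(k=300)
        dp_a = propagate(
            build_transition_operator(a, params),
            make_seed_vector(a, {"P1"}),
            params,
        )
        dp_b = propagate(
            build_transition_operator(b, params),
            make_seed_vector(b, {"X3"}),
            params,
        )
        for old, new in mapping.items():
            assert dp_a.values[a.node_index[old]] == pytest.approx(
                dp_b.values[b.node_index[new]], abs=1e-12
            )

    def test_batch_matches_single(self, rng):
        graph = random_interactome(rng, n_proteins=30)
        params = WalkParams(k=100)
        op = build_transition_operator(graph, params)
        seeds = [make_seed_vector(graph, {f"P{i}", f"P{i+3}"}) for i in (0, 5, 11)]
        batch = propagate_many(op, seeds, params)
        for seed, dp in zip(seeds, batch):
            single = propagate(op, seed, params)
            np.testing.assert_allclose(dp.values, single.values, atol=1e-15)

    def test_dimension_mismatch(self, toy_interactome, two_node_interactome):
        params = WalkParams()
        op = build_transition_operator(two_node_interactome, params)
        seed = make_seed_vector(toy_interactome, {"P1"})
        with pytest.raises(ValueError, match="mismatch|size"):
            propagate(op, seed, params)


class TestStationaryOracle:
    def test_two_node_exact(self, two_node_interactome):
        op = build_transition_operator(two_node_interactome, WalkParams())
        seed = make_seed_vector(two_node_interactome, {"A"})
        dp = stationary_oracle(op, seed, r=0.5)
        expect = {"A": 2 / 3, "B": 1 / 3}
        for nid, v in expect.items():
            assert dp.values[two_node_interactome.node_index[nid]] == pytest.approx(v)

    def test_r_one_returns_seed_distribution(self, toy_interactome):
        op = build_transition_operator(toy_interactome, WalkParams())
        seed = make_seed_vector(toy_interactome, {"P1", "P2"})
        dp = stationary_oracle(op, seed, r=1.0)
        assert np.allclose(dp.values, seed.values / 2)

    @pytest.mark.parametrize("r", [0.05, 0.15, 0.5])
    def test_iteration_converges_to_fixed_point(self, rng, r):
        graph = random_interactome(rng, n_proteins=80, n_functions=15)
        params = WalkParams(r=r, k=1000)
        op = build_transition_operator(graph, params)
        seed = make_seed_vector(graph, {"P3", "P40"})
        iterated = propagate(op, seed, params)
        exact = stationary_oracle(op, seed, r)
        assert np.abs(iterated.values - exact.values).sum() <= 1e-8


class TestCosineSimilarity:
    def test_identical_profiles_score_one(self, rng):
        v = rng.random(10)
        v /= v.sum()
        assert cosine_similarity(v, v) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_supports_score_zero(self):
        assert cosine_similarity([1, 0, 0, 0], [0, 0, 0.5, 0.5]) == 0.0

    def test_closed_form(self):
        assert cosine_similarity([0.5, 0.5, 0.0], [1.0, 0.0, 0.0]) == pytest.approx(
            1 / np.sqrt(2)
        )

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            cosine_similarity([0.0, 0.0], [1.0, 0.0])

    @given(
        st.lists(st.floats(0, 1e3), min_size=2, max_size=8),
        st.lists(st.floats(0, 1e3), min_size=2, max_size=8),
        st.floats(1e-3, 1e3),
    )
    def test_symmetric_and_scale_invariant(self, xs, ys, a):
        n = min(len(xs), len(ys))
        x, y = np.array(xs[:n]) + 1e-9, np.array(ys[:n]) + 1e-9
        assert cosine_similarity(x, y) == pytest.approx(cosine_similarity(y, x))
        assert cosine_similarity(a * x, y) == pytest.approx(
            cosine_similarity(x, y), abs=1e-9
        )
        assert 0.0 <= cosine_similarity(x, y) <= 1.0


def test_profile_tsv_round_trip_is_bit_exact(tmp_path, toy_interactome):
    params = WalkParams(k=50)
    op = build_transition_operator(toy_interactome, params)
    seed = make_seed_vector(toy_interactome, {"P1"})
    dp = propagate(op, seed, params)
    write_profile(tmp_path / "dp.tsv", toy_interactome, dp)
    back = read_profile(tmp_path / "dp.tsv", toy_interactome, seed)
    assert (back.values == dp.values).all()
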