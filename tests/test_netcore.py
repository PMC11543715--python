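"""Network engine: inhibition, settling, trial dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from teach.netcore import (
    LayerSpec,
    Network,
    ProjectionSpec,
    QuarterSpec,
    apply_kwta,
    init_network,
)
from teach.plasticity import LearnParams


class TestApplyKwta:
    def test_single_winner(self):
        act = apply_kwta(np.array([3.0, 1.0, 2.0]), k=1)
        assert np.count_nonzero(act) == 1 and act[0] > 0

    def test_ties_break_to_lowest_index(self):
        act = apply_kwta(np.zeros(5) + 0.7, k=2)
        assert np.flatnonzero(act).tolist() == [0, 1]

    def test_k_equals_n_activates_everything(self):
        act = apply_kwta(np.array([0.2, 0.9, 0.4]), k=3)
        assert np.count_nonzero(act) == 3

    def test_k_zero(self):
        assert np.count_nonzero(apply_kwta(np.ones(4), k=0)) == 0

    @given(
        net=st.lists(st.floats(-2, 2), min_size=1, max_size=30),
        data=st.data(),
    )
    @settings(max_examples=100, deadline=None)
    def test_exactly_k_nonzero_for_any_input(self, net, data):
        net = np.array(net)
        k = data.draw(st.integers(0, net.size))
        act = apply_kwta(net, k)
        assert np.count_nonzero(act) == k
        assert (act >= 0).all() and (act <= 1).all()

    def test_out_of_range_k(self):
        with pytest.raises(ValueError):
            apply_kwta(np.ones(3), k=4)


def _two_layer(rng, n=4, **proj_kw):
    specs = [
        LayerSpec("src", (1, n), kwta_pct=0.5, act_floor=0.0),
        LayerSpec("dst", (1, n), kwta_pct=0.5, act_floor=0.0),
    ]
    return Network(specs, [ProjectionSpec("src", "dst", **proj_kw)], rng)


class TestNetInput:
    def test_zero_senders_zero_input(self, rng):
        net = _two_layer(rng)
        assert np.allclose(net.compute_net_input("dst"), 0)

    def test_wt_scale_is_linear(self, rng):
        n1 = _two_layer(np.random.default_rng(0), wt_scale=1.0)
        n2 = _two_layer(np.random.default_rng(0), wt_scale=2.0)
        for n in (n1, n2):
            n.layers["src"].acts[:] = [1, 0, 1, 0]
        np.testing.assert_allclose(
            2 * n1.compute_net_input("dst"), n2.compute_net_input("dst")
        )

    def test_matches_manual_matrix_product(self, rng):
        net = _two_layer(rng, n=2)
        proj = net.projections["src->dst"]
        proj.w[:] = [[0.2, 0.8], [0.6, 0.4]]
        net.layers["src"].acts[:] = [1.0, 0.5]
        want = np.array([1.0, 0.5]) @ proj.w / proj.norm
        np.testing.assert_allclose(net.compute_net_input("dst"), want)


class TestInitAndStructure:
    def test_same_seed_identical_weights(self):
        s = [LayerSpec("a", (2, 2)), LayerSpec("b", (3, 3))]
        p = [ProjectionSpec("a", "b")]
        n1 = init_network(s, p, np.random.default_rng(5))
        n2 = init_network(s, p, np.random.default_rng(5))
        np.testing.assert_array_equal(
            n1.projections["a->b"].w, n2.projections["a->b"].w
        )

    def test_one_to_one_is_diagonal(self, rng):
        s = [LayerSpec("a", (2, 3)), LayerSpec("b", (2, 3))]
        p = [ProjectionSpec("a", "b", connectivity="one_to_one",
                            init_weight=1.0)]
        net = init_network(s, p, rng)
        np.testing.assert_array_equal(net.projections["a->b"].w, np.eye(6))

    def test_pool_aligned_blocks(self, rng):
        s = [
            LayerSpec("a", (1, 3), n_pools=2),
            LayerSpec("b", (1, 2), n_pools=2),
        ]
        p = [ProjectionSpec("a", "b", connectivity="pool_aligned")]
        net = init_network(s, p, rng)
        w = net.projections["a->b"].w
        assert (w[:3, :2] != 0).all() and (w[3:, 2:] != 0).all()
        assert (w[:3, 2:] == 0).all() and (w[3:, :2] == 0).all()

    def test_dangling_projection_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown layer"):
            init_network(
                [LayerSpec("a", (2, 2))],
                [ProjectionSpec("a", "ghost")],
                rng,
            )

    def test_empty_projection_list_settles_to_clamps_only(self, rng):
        s = [LayerSpec("a", (2, 2)), LayerSpec("b", (2, 2))]
        net = init_network(s, [], rng)
        clamp = np.array([1.0, 0, 0, 1.0])
        net.settle({"a": clamp}, 10)
        np.testing.assert_array_equal(net.acts("a"), clamp)
        assert np.allclose(net.acts("b"), 0)


class TestSettle:
    def test_clamped_layer_stays_clamped(self, rng):
        net = _two_layer(rng)
        pattern = np.array([1.0, 0.0, 1.0, 0.0])
        net.settle({"src": pattern}, 7)
        np.testing.assert_array_equal(net.acts("src"), pattern)

    def test_partial_clamp_frees_other_units(self, rng):
        net = _two_layer(rng, wt_scale=0.0)
        pattern = np.zeros(4)
        pattern[0] = 1.0
        mask = np.zeros(4, dtype=bool)
        mask[0] = True
        net.layers["src"].acts[:] = 0.25
        net.settle({"src": (pattern, mask)}, 3)
        assert net.acts("src")[0] == 1.0
        # unmasked units evolve under the dynamics instead
        assert not np.allclose(net.acts("src")[1:], 0.25)

    def test_determinism(self):
        for _ in range(2):
            net = _two_layer(np.random.default_rng(3))
            net.settle({"src": np.array([1.0, 1, 0, 0])}, 9)
            acts = net.acts("dst").copy()
        np.testing.assert_array_equal(acts, net.acts("dst"))


class TestTrialAndLearning:
    def test_learning_disabled_for_fixed_projections(self, rng):
        net = _two_layer(rng, learn=None)
        w0 = net.projections["src->dst"].w.copy()
        snaps = net.run_trial(
            {"src": np.array([1.0, 1, 0, 0])},
            [QuarterSpec(4, snapshot="minus"), QuarterSpec(4, snapshot="plus")],
        )
        net.learn(snaps)
        np.testing.assert_array_equal(net.projections["src->dst"].w, w0)

    def test_plus_clamp_contract(self, rng):
        net = _two_layer(rng)
        target = np.array([0.0, 1.0, 0.0, 1.0])
        snaps = net.run_trial(
            {"src": np.ones(4)},
            [
                QuarterSpec(4, snapshot="minus"),
                QuarterSpec(4, clamps={"dst": target}, snapshot="plus"),
            ],
        )
        np.testing.assert_array_equal(snaps["plus"]["dst"], target)

    def test_callable_clamp_sees_current_state(self, rng):
        net = _two_layer(rng)
        seen = {}

        def grab(n):
            seen["src"] = n.acts("src").copy()
            return n.acts("src").copy()

        net.run_trial(
            {"src": np.array([1.0, 0, 0, 0])},
            [QuarterSpec(3), QuarterSpec(3, clamps={"dst": grab})],
        )
        np.testing.assert_array_equal(seen["src"], [1, 0, 0, 0])


def test_pattern_completion_from_half_cue(rng):
    """A Hebbian auto-associator recovers stored patterns from 50% cues.

    Small one-layer recurrent network, three random sparse patterns,
    trained by clamped Hebbian exposure; each pattern must be recovered
    from half of its active units with >= 90% unit overlap.
    """
    n, k = 40, 8
    spec = LayerSpec("m", (1, n), kwta_pct=k / n, act_floor=0.05, gain=10)
    proj = ProjectionSpec(
        "m", "m", learn=LearnParams(lr=0.5, hebb_mix=1.0),
        init_range=(0.0, 0.1),
    )
    net = Network([spec], [proj], rng)
    pats = []
    while len(pats) < 3:  # enforce distinct, low-overlap patterns
        p = np.zeros(n)
        p[rng.choice(n, k, replace=False)] = 1.0
        if all((p * q).sum() <= 2 for q in pats):
            pats.append(p)
    for _ in range(10):
        for p in pats:
            snaps = {"minus": {"m": p}, "plus": {"m": p}}
            net.learn(snaps)
    for p in pats:
        cue = p.copy()
        cue[np.flatnonzero(p)[: k // 2]] = 0.0  # drop half the pattern
        net.reset_activity()
        net.layers["m"].acts[:] = cue
        net.settle({}, 30)
        retrieved = net.acts("m") > 0.5
        overlap = (retrieved & (p > 0)).sum() / k
        assert overlap >= 0.9
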