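"""d' scoring and the statistics pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from teach.design import PoolPattern
from teach.evaluation import (
    aggregate,
    dprime,
    planned_comparison,
    three_way_anova,
)


def _pattern(active_idx, size=49):
    u = np.zeros(size, dtype=np.int8)
    u[list(active_idx)] = 1
    return PoolPattern(u)


class TestDprime:
    def test_chance_gives_zero(self):
        # hit rate == false-alarm rate -> d' = 0
        tgt = _pattern(range(10), size=20)
        out = np.zeros(20)
        out[[0, 1, 2, 3, 4, 10, 11, 12, 13, 14]] = 1.0
        assert dprime(tgt, out).dprime == pytest.approx(0.0, abs=1e-12)

    def test_worked_example(self):
        # 8 of 10 target units retrieved, 2 of 39 false alarms:
        # d' = z(0.8) - z(2/39) ~ 2.474
        tgt = _pattern(range(10))
        out = np.zeros(49)
        out[:8] = 1.0
        out[[10, 11]] = 1.0
        score = dprime(tgt, out)
        assert score.hit_rate == pytest.approx(0.8)
        assert score.fa_rate == pytest.approx(2 / 39)
        want = sps.norm.ppf(0.8) - sps.norm.ppf(2 / 39)
        assert score.dprime == pytest.approx(want, abs=1e-9)
        assert score.dprime == pytest.approx(2.474, abs=0.001)

    def test_perfect_retrieval_is_clipped(self):
        tgt = _pattern(range(10))
        out = tgt.units.astype(float)
        score = dprime(tgt, out)
        assert score.hit_rate == pytest.approx(0.95)  # 1 - 1/(2*10)
        assert score.fa_rate == pytest.approx(1 / 78)
        want = sps.norm.ppf(0.95) - sps.norm.ppf(1 / 78)
        assert score.dprime == pytest.approx(want, abs=1e-9)
        assert score.dprime == pytest.approx(3.88, abs=0.01)

    def test_monotone_in_hits_and_false_alarms(self):
        tgt = _pattern(range(10))
        prev = -np.inf
        for n_hits in range(0, 11):
            out = np.zeros(49)
            out[:n_hits] = 1.0
            d = dprime(tgt, out).dprime
            assert d >= prev
            prev = d
        prev = np.inf
        for n_fa in range(0, 40):
            out = np.ones(49)
            out[10 : 10 + (39 - n_fa)] = 0.0
            d = dprime(tgt, out).dprime
            assert d <= prev
            prev = d

    def test_degenerate_targets_rejected(self):
        with pytest.raises(ValueError):
            dprime(_pattern(range(49)), np.zeros(49))
        with pytest.raises(ValueError):
            dprime(_pattern([]), np.zeros(49))


def _trial_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "run", "temporal", "semantic", "sleep_state", "role",
            "matched_control", "dprime",
        ],
    )


class TestAggregate:
    def test_simple_difference(self):
        df = _trial_frame(
            [
                (1, "far", "related", "wake", "nontarget", False, 2.0),
                (1, "far", "related", "wake", "control", True, 1.5),
                (1, "far", "related", "wake", "control", False, 9.0),
                (1, "far", "related", "wake", "target", False, 3.0),
            ]
        )
        out = aggregate(df)
        assert len(out) == 1
        # only the list-matched control enters the baseline
        assert out.loc[0, "diff"] == pytest.approx(0.5)

    def test_trial_order_invariance(self):
        rows = [
            (1, "far", "related", "wake", "nontarget", False, 1.0),
            (1, "far", "related", "wake", "nontarget", False, 3.0),
            (1, "far", "related", "wake", "control", True, 1.0),
        ]
        a = aggregate(_trial_frame(rows))
        b = aggregate(_trial_frame(rows[::-1]))
        pd.testing.assert_frame_equal(a, b)

    def test_missing_role_is_an_error(self):
        df = _trial_frame(
            [(1, "far", "related", "wake", "target", False, 1.0)]
        )
        with pytest.raises(ValueError, match="lacks"):
            aggregate(df)


class TestPlannedComparison:
    def test_all_zero(self):
        out = planned_comparison(np.zeros(10))
        assert out["t"] == 0.0 and out["cohens_d"] == 0.0

    def test_two_point_analytic(self):
        out = planned_comparison(np.array([2.0, 0.0]))
        assert out["t"] == pytest.approx(1.0)
        assert out["df"] == 1
        assert out["cohens_d"] == pytest.approx(1 / np.sqrt(2))

    def test_antisymmetry(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=12)
        fwd = planned_comparison(x, y)
        rev = planned_comparison(y, x)
        assert fwd["t"] == pytest.approx(-rev["t"])
        assert fwd["cohens_d"] == pytest.approx(-rev["cohens_d"])
        assert fwd["p"] == pytest.approx(rev["p"])

    def test_matches_scipy(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        out = planned_comparison(x, y)
        t, p = sps.ttest_rel(x, y)
        assert out["t"] == pytest.approx(t)
        assert out["p"] == pytest.approx(p)

    def test_type_one_error_calibration(self, rng):
        """Under the null, p < .05 occurs in about 5% of simulations."""
        n_sim, n = 4000, 12
        data = rng.normal(size=(n_sim, n))
        t = data.mean(1) / (data.std(1, ddof=1) / np.sqrt(n))
        p = 2 * sps.t.sf(np.abs(t), n - 1)
        assert abs((p < 0.05).mean() - 0.05) < 0.012


def _diffs_frame(Y, runs_per_group):
    """Y[group, subject, temporal, semantic] -> tidy diffs table."""
    rows = []
    for g, sleep in enumerate(["sleep", "wake"]):
        for s in range(runs_per_group):
            for a, temporal in enumerate(["close", "far"]):
                for b, semantic in enumerate(["related", "unrelated"]):
                    rows.append(
                        dict(
                            run=s + 1,
                            sleep_state=sleep,
                            temporal=temporal,
                            semantic=semantic,
                            diff=Y[g, s, a, b],
                        )
                    )
    return pd.DataFrame(rows)


def _contrast_oracle_three_way(Y):
    """Independent check: for 2x2x2 the three-way interaction F equals
    the squared two-sample t on per-subject temporal x semantic
    contrasts between the sleep groups (pooled variance)."""
    L = (Y[:, :, 1, 1] - Y[:, :, 1, 0] - Y[:, :, 0, 1] + Y[:, :, 0, 0]) / 2
    t, _ = sps.ttest_ind(L[0], L[1])
    return t**2


class TestThreeWayAnova:
    def test_flat_data_gives_zero_F(self):
        Y = np.ones((2, 6, 2, 2))
        Y += np.arange(6)[None, :, None, None] * 0.1  # subject offsets only
        table = three_way_anova(_diffs_frame(Y, 6))
        row = table[table.effect == "temporal:semantic:sleep_state"].iloc[0]
        assert row.F == pytest.approx(0.0, abs=1e-20)

    def test_pure_three_way_signal(self, rng):
        Y = rng.normal(0, 0.05, size=(2, 10, 2, 2))
        Y[0, :, 1, 0] += 2.0  # far/related shift in one group only
        table = three_way_anova(_diffs_frame(Y, 10))
        row = table[table.effect == "temporal:semantic:sleep_state"].iloc[0]
        assert row.F > 50
        assert row.p < 1e-6

    def test_matches_contrast_oracle_on_random_data(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 15))
            Y = rng.normal(size=(2, n, 2, 2))
            table = three_way_anova(_diffs_frame(Y, n))
            row = table[
                table.effect == "temporal:semantic:sleep_state"
            ].iloc[0]
            assert row.F == pytest.approx(
                _contrast_oracle_three_way(Y), rel=1e-9, abs=1e-9
            )
            assert row.df2 == 2 * n - 2

    def test_degrees_of_freedom_with_twenty_runs(self, rng):
        Y = rng.normal(size=(2, 20, 2, 2))
        table = three_way_anova(_diffs_frame(Y, 20))
        assert set(table.df1) == {1}
        assert set(table.df2) == {38}

    def test_eta_p_sq_consistent_with_F(self, rng):
        Y = rng.normal(size=(2, 8, 2, 2))
        table = three_way_anova(_diffs_frame(Y, 8))
        for _, row in table.iterrows():
            want = (row.F * row.df1) / (row.F * row.df1 + row.df2)
            assert row.eta_p_sq == pytest.approx(want, rel=1e-9)

    def test_unbalanced_rejected(self, rng):
        Y = rng.normal(size=(2, 5, 2, 2))
        df = _diffs_frame(Y, 5)
        with pytest.raises(ValueError):
            three_way_anova(df.iloc[:-1])
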