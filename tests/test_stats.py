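"""Statistical-primitive tests: hand-computed examples, brute-force
enumeration oracles for the rank statistics and BH adjustment, and a
projection-matrix oracle for the repeated-measures ANOVA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from carpool.stats import (
    bh_fdr,
    check_normality,
    kruskal_wallis,
    midrank,
    one_sample_z_test,
    rank_average,
    rm_anova,
    spearman,
    stouffer_combine,
    wilcoxon_rank_sum,
    zscore_within_group,
)


class TestZscore:
    def test_one_two_three(self):
        np.testing.assert_allclose(zscore_within_group([1, 2, 3]), [-1, 0, 1])

    def test_constant_group_warns_and_zeros(self):
        with pytest.warns(UserWarning, match="zero variance"):
            z = zscore_within_group([4.0, 4.0, 4.0])
        np.testing.assert_array_equal(z, [0, 0, 0])

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=30).filter(
        lambda v: len(set(v)) > 1))
    def test_output_standardized(self, values):
        z = zscore_within_group(values)
        assert abs(z.mean()) < 1e-7
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-7)

    def test_nan_propagates(self):
        z = zscore_within_group([1.0, np.nan, 3.0])
        assert np.isnan(z[1]) and not np.isnan(z[0])


class TestStouffer:
    def test_four_ones(self):
        assert stouffer_combine([1, 1, 1, 1]) == pytest.approx(2.0)

    def test_single_value_identity(self):
        assert stouffer_combine([1.7]) == pytest.approx(1.7)

    def test_missing_reduces_k(self):
        assert stouffer_combine([2.0, np.nan]) == pytest.approx(2.0)

    def test_all_missing_is_missing(self):
        assert math.isnan(stouffer_combine([np.nan, np.nan]))

    def test_null_distribution_standard_normal(self):
        rng = np.random.default_rng(0)
        zs = rng.standard_normal((10**4, 6))
        combined = zs.sum(axis=1) / math.sqrt(6)
        _, p = sps.kstest(combined, "norm")
        assert p > 0.01


class TestZTest:
    def test_zero_gives_one(self):
        assert one_sample_z_test(0.0) == pytest.approx(1.0)

    def test_critical_value(self):
        assert one_sample_z_test(1.959964) == pytest.approx(0.05, abs=1e-4)

    def test_monotone_decreasing_in_magnitude(self):
        ps = [one_sample_z_test(z) for z in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestBH:
    def test_hand_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.5])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.123]), [0.123])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_nan_excluded_and_reinserted(self):
        q = bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], bh_fdr([0.01, 0.04]))

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=6))
    def test_matches_brute_force_step_up(self, ps):
        """Oracle: q_i = min over j with p_j >= p_i of m*p_j/rank_j."""
        p = np.array(ps)
        m = len(p)
        order = np.argsort(p, kind="stable")
        expected = np.empty(m)
        running_min = 1.0
        for rank_from_top in range(m, 0, -1):
            i = order[rank_from_top - 1]
            running_min = min(running_min, m * p[i] / rank_from_top)
            expected[i] = running_min
        np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)


class TestRanks:
    def test_best_everywhere_rank_one(self):
        m = pd.DataFrame({"a1": [9, 5, 1], "a2": [8, 2, 3]}, index=["X", "Y", "Z"])
        r = rank_average(m)
        assert r["X"] == pytest.approx(1.0)

    def test_tied_values_get_midrank(self):
        m = pd.DataFrame({"a1": [5.0, 5.0, 1.0]}, index=["X", "Y", "Z"])
        r = rank_average(m)
        assert r["X"] == pytest.approx(1.5)
        assert r["Y"] == pytest.approx(1.5)

    def test_three_by_two_matches_enumeration(self):
        m = pd.DataFrame({"a1": [3.0, 1.0, 2.0], "a2": [10.0, 30.0, 20.0]},
                         index=["X", "Y", "Z"])
        # by hand: a1 ranks (high good): X=1, Z=2, Y=3; a2: Y=1, Z=2, X=3
        expected = {"X": 2.0, "Y": 2.0, "Z": 2.0}
        r = rank_average(m)
        for k, v in expected.items():
            assert r[k] == pytest.approx(v)

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.integers(0, 5), min_size=2, max_size=6))
    def test_midrank_matches_brute_force(self, values):
        x = np.array(values, dtype=float)
        expected = np.array([
            np.mean([r + 1 for r, _ in enumerate(sorted(range(len(x)), key=lambda i: x[i]))
                     if x[sorted(range(len(x)), key=lambda j: x[j])[r]] == xi])
            for xi in x
        ])
        np.testing.assert_allclose(midrank(x), expected)


class TestWilcoxon:
    def test_fully_separated(self):
        u, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert u == 0.0
        # enumeration: 2 of 6 assignments are as extreme (U=0 or U=4)
        assert p == pytest.approx(2 / 6)

    def test_all_tied_u_is_half(self):
        u, p = wilcoxon_rank_sum([5, 5], [5, 5])
        assert u == pytest.approx(2.0)  # n_x*n_y/2
        assert p == pytest.approx(1.0)

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.integers(0, 6, size=3).astype(float)
            y = rng.integers(0, 6, size=3).astype(float)
            u, p = wilcoxon_rank_sum(x, y)
            pooled = np.concatenate([x, y])
            mu = len(x) * len(y) / 2
            u_obs = float((x[:, None] > y[None, :]).sum()) + 0.5 * float(
                (x[:, None] == y[None, :]).sum())
            hits = total = 0
            for comb in itertools.combinations(range(6), 3):
                mask = np.zeros(6, dtype=bool)
                mask[list(comb)] = True
                xp, yp = pooled[mask], pooled[~mask]
                up = float((xp[:, None] > yp[None, :]).sum()) + 0.5 * float(
                    (xp[:, None] == yp[None, :]).sum())
                total += 1
                if abs(up - mu) >= abs(u_obs - mu) - 1e-12:
                    hits += 1
            assert u == pytest.approx(u_obs)
            assert p == pytest.approx(hits / total)

    def test_exact_and_normal_agree_at_n6(self):
        rng = np.random.default_rng(2)
        deltas = []
        for _ in range(100):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            _, p_exact = wilcoxon_rank_sum(x, y, exact_limit=12)
            _, p_norm = wilcoxon_rank_sum(x, y, exact_limit=0)
            deltas.append(abs(p_exact - p_norm))
        assert max(deltas) < 0.01


class TestKruskal:
    def test_hand_example(self):
        h, _ = kruskal_wallis([[1, 2], [3, 4]])
        assert h == pytest.approx(2.4)

    def test_identical_groups_zero(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0)

    def test_invariant_to_monotone_transform(self):
        groups = [[1.0, 4.0, 2.5], [3.0, 6.0], [0.5, 5.0]]
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis([[math.exp(v) for v in g] for g in groups])
        assert h1 == pytest.approx(h2)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            groups = [rng.integers(0, 10, size=rng.integers(2, 4)).astype(float)
                      for _ in range(3)]
            pooled = np.concatenate(groups)
            n = len(pooled)
            ranks = midrank(pooled)
            h_expected = 12 / (n * (n + 1)) * sum(
                ranks[sum(len(g) for g in groups[:i]):
                      sum(len(g) for g in groups[: i + 1])].sum() ** 2 / len(g)
                for i, g in enumerate(groups)
            ) - 3 * (n + 1)
            _, tie_counts = np.unique(pooled, return_counts=True)
            correction = 1 - ((tie_counts**3 - tie_counts).sum()) / (n**3 - n)
            if correction == 0:
                continue
            h_expected /= correction
            h, _ = kruskal_wallis(groups)
            assert h == pytest.approx(h_expected, abs=1e-9)


class TestSpearman:
    def test_perfectly_monotone(self):
        rho, _ = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_reversed(self):
        rho, _ = spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_hand_example_point_eight(self):
        rho, _ = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)

    def test_zero_variance_warns(self):
        with pytest.warns(UserWarning):
            rho, _ = spearman([1, 1, 1], [1, 2, 3])
        assert math.isnan(rho)

    def test_matches_pearson_on_midranks(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            x = rng.integers(0, 5, size=6).astype(float)
            y = rng.integers(0, 5, size=6).astype(float)
            if np.unique(x).size == 1 or np.unique(y).size == 1:
                continue
            rho, _ = spearman(x, y)
            expected = np.corrcoef(midrank(x), midrank(y))[0, 1]
            assert rho == pytest.approx(expected, abs=1e-9)


class TestNormalityCheck:
    def test_nominal_level_on_normal_draws(self):
        passes = 0
        for k in range(100):
            x = np.random.default_rng(k).standard_normal(10**4)
            _, passed, _ = check_normality(x)
            passes += bool(passed)
        assert passes >= 94

    def test_rejects_heavy_skew(self):
        x = np.random.default_rng(0).exponential(1.0, size=200)
        _, passed, _ = check_normality(x)
        assert passed is False

    def test_location_scale_invariance(self):
        x = np.random.default_rng(1).standard_normal(500)
        a1, _, _ = check_normality(x)
        a2, _, _ = check_normality(5.0 + 3.0 * x)
        assert a1 == pytest.approx(a2, rel=1e-9)

    def test_small_sample_advisory(self):
        a2, passed, note = check_normality([1.0, 2.0, 3.0])
        assert math.isnan(a2) and passed is None and "insufficient" in note


class TestRMAnova:
    @staticmethod
    def _projection_oracle(df):
        """Direct linear-algebra decomposition via projection matrices."""
        domains = sorted(df["domain"].unique())
        days = sorted(df["day"].unique())
        donors = sorted(df["donor"].unique())
        y = df.sort_values(["domain", "day", "donor"])["y"].to_numpy(dtype=float)
        n = len(y)

        def dummy(col, levels, frame):
            frame = frame.sort_values(["domain", "day", "donor"])
            return np.stack([(frame[col] == l).to_numpy(float) for l in levels], axis=1)

        X0 = np.ones((n, 1))
        Xdom = dummy("domain", domains, df)
        Xday = dummy("day", days, df)
        Xdonor = dummy("donor", donors, df)
        Xcell = np.stack(
            [((df.sort_values(["domain", "day", "donor"])["domain"] == a)
              & (df.sort_values(["domain", "day", "donor"])["day"] == b)).to_numpy(float)
             for a in domains for b in days], axis=1)

        def proj(X):
            return X @ np.linalg.pinv(X.T @ X) @ X.T

        P0 = proj(X0)
        Pdom = proj(np.hstack([X0, Xdom]))
        Pday = proj(np.hstack([X0, Xday]))
        Pdonor = proj(np.hstack([X0, Xdonor]))
        Pcell = proj(np.hstack([X0, Xdom, Xday, Xcell]))
        ss = {
            "domain": y @ (Pdom - P0) @ y,
            "day": y @ (Pday - P0) @ y,
            "donor": y @ (Pdonor - P0) @ y,
        }
        ss["domain:day"] = y @ (Pcell - P0) @ y - ss["domain"] - ss["day"]
        ss_total = y @ (np.eye(n) - P0) @ y
        ss["residual"] = ss_total - sum(ss.values())
        return ss

    def test_matches_projection_oracle_to_1e10(self):
        rng = np.random.default_rng(7)
        rows = [
            (f"dom{a}", f"day{b}", f"don{c}", rng.normal())
            for a in range(3) for b in range(3) for c in range(2)
        ]
        df = pd.DataFrame(rows, columns=["domain", "day", "donor", "y"])
        res = rm_anova(df, "y")
        oracle = self._projection_oracle(df)
        for effect in ("donor", "domain", "day", "domain:day", "residual"):
            assert res.table.loc[effect, "ss"] == pytest.approx(
                oracle[effect], abs=1e-10
            )

    def test_constant_measure_reports_nan_with_note(self):
        rows = [(f"d{a}", f"t{b}", f"n{c}", 5.0)
                for a in range(2) for b in range(2) for c in range(2)]
        df = pd.DataFrame(rows, columns=["domain", "day", "donor", "y"])
        res = rm_anova(df, "y")
        assert math.isnan(res.f("domain"))
        assert "NaN" in res.note or "undefined" in res.note

    def test_additive_effects_zero_interaction(self):
        rows = []
        for a in range(3):
            for b in range(3):
                for c in range(2):
                    rows.append((f"d{a}", f"t{b}", f"n{c}", 2.0 * a + 0.5 * b + 0.1 * c))
        df = pd.DataFrame(rows, columns=["domain", "day", "donor", "y"])
        res = rm_anova(df, "y")
        assert res.table.loc["domain:day", "ss"] == pytest.approx(0.0, abs=1e-10)

    def test_unbalanced_design_raises(self):
        rows = [("d0", "t0", "n0", 1.0), ("d0", "t1", "n0", 2.0),
                ("d1", "t0", "n0", 3.0)]
        df = pd.DataFrame(rows, columns=["domain", "day", "donor", "y"])
        with pytest.raises(ValueError, match="balanced"):
            rm_anova(df, "y")
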