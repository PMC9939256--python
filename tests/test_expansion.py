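"""Relative-expansion tests: size factors against a hand oracle, log2FC
identities, depth invariance, the CD8/CD4 Wald test and the trend slope."""

import math

import numpy as np
import pandas as pd
import pytest

from carpool.expansion import (
    cd8_cd4_ratio_test,
    expansion_trend,
    relative_expansion,
    size_factors,
)


def _tidy(counts_by_series, timepoints):
    """counts_by_series: {(donor, rep, subset, cond): {construct: [counts per tp]}}"""
    rows = []
    for (donor, rep, subset, cond), per_construct in counts_by_series.items():
        for construct, counts in per_construct.items():
            for t, c in zip(timepoints, counts):
                rows.append((construct, donor, rep, subset, cond, t, c))
    return pd.DataFrame(
        rows,
        columns=["construct", "donor", "replicate", "subset", "condition",
                 "timepoint", "count"],
    )


class TestSizeFactors:
    def test_hand_example_sqrt_two(self):
        # geometric-mean reference (sqrt2, sqrt8, sqrt18); each ratio in the
        # first sample is 1/sqrt2 -> factors (0.7071, 1.4142)
        df = pd.DataFrame({"s1": [1, 2, 3], "s2": [2, 4, 6]})
        f = size_factors(df)
        assert f["s1"] == pytest.approx(1 / math.sqrt(2), abs=1e-6)
        assert f["s2"] == pytest.approx(math.sqrt(2), abs=1e-6)

    def test_identical_samples_equal_factors(self):
        df = pd.DataFrame({"a": [5, 9, 2], "b": [5, 9, 2]})
        f = size_factors(df)
        assert f["a"] == pytest.approx(f["b"])

    def test_scale_equivariance(self):
        # factors are defined up to a common scale: doubling one sample
        # doubles its factor relative to the others
        df = pd.DataFrame({"a": [10, 20, 30], "b": [15, 25, 35]})
        f1 = size_factors(df)
        df2 = df.copy()
        df2["a"] = df2["a"] * 2
        f2 = size_factors(df2)
        assert (f2["a"] / f2["b"]) / (f1["a"] / f1["b"]) == pytest.approx(2.0)

    def test_all_zero_sample_raises_with_name(self):
        df = pd.DataFrame({"good": [1, 2], "dead": [0, 0]})
        with pytest.raises(ValueError, match="dead"):
            size_factors(df)

    def test_fallback_to_totals_when_no_common_construct(self):
        df = pd.DataFrame({"a": [10, 0], "b": [0, 10]})
        f = size_factors(df)
        assert f["a"] == pytest.approx(f["b"])


class TestRelativeExpansion:
    def test_doubling_gives_log2fc_one(self):
        tidy = _tidy(
            {("d1", 1, "CD8", "antigen+"): {
                "A": [10000, 20000], "B": [10000, 10000], "C": [10000, 10000]}},
            timepoints=[0, 1],
        )
        res = relative_expansion(tidy)
        a = res.per_replicate.query("construct == 'A' and timepoint == 1")
        # size factors absorb part of the composition; raw ratio check on
        # unnormalized frequencies: log2fc(A) - log2fc(B) ~ 1
        b = res.per_replicate.query("construct == 'B' and timepoint == 1")
        assert a["log2fc"].iloc[0] - b["log2fc"].iloc[0] == pytest.approx(1.0, abs=0.01)

    def test_unchanged_counts_give_zero(self):
        tidy = _tidy(
            {("d1", 1, "CD8", "antigen+"): {"A": [500, 500], "B": [800, 800]}},
            timepoints=[0, 1],
        )
        res = relative_expansion(tidy)
        assert res.per_replicate["log2fc"].abs().max() < 1e-9

    def test_depth_invariance(self):
        base = {"A": [1100, 2500], "B": [1900, 1600], "C": [1500, 1500]}
        tidy1 = _tidy({("d1", 1, "CD8", "antigen+"): base}, [0, 1])
        scaled = {k: [v[0], v[1] * 7] for k, v in base.items()}
        tidy2 = _tidy({("d1", 1, "CD8", "antigen+"): scaled}, [0, 1])
        r1 = relative_expansion(tidy1).per_replicate.set_index(["construct", "timepoint"])
        r2 = relative_expansion(tidy2).per_replicate.set_index(["construct", "timepoint"])
        np.testing.assert_allclose(
            r1["log2fc"].to_numpy(), r2["log2fc"].to_numpy(), atol=1e-3
        )

    def test_library_relative_mean_is_zero(self):
        rng = np.random.default_rng(5)
        per = {f"C{i}": list(rng.integers(500, 5000, size=3)) for i in range(12)}
        tidy = _tidy({("d1", 1, "CD8", "antigen+"): per}, [0, 1, 2])
        res = relative_expansion(tidy)
        for t, grp in res.per_replicate.groupby("timepoint"):
            assert abs(grp["rel_log2fc"].mean()) < 1e-9


class TestCD8CD4:
    def _two_subset_tidy(self, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        series = {}
        for subset in ("CD4", "CD8"):
            for rep in (1, 2, 3):
                per = {}
                for i in range(6):
                    base = 5000
                    mult = 2.0 ** (shift if (subset == "CD8" and i == 0) else 0.0)
                    noise = rng.normal(1.0, 0.02, size=2)
                    per[f"C{i}"] = [
                        int(base * noise[0]),
                        int(base * mult * noise[1]),
                    ]
                series[("d1", rep, subset, "antigen+")] = per
        return _tidy(series, [0, 1])

    def test_identical_subsets_delta_zero_p_one(self):
        tidy_cd4 = self._two_subset_tidy(shift=0.0, seed=1)
        res = relative_expansion(tidy_cd4)
        # force CD8 rows identical to CD4 rows
        per = res.per_replicate.copy()
        cd4 = per[per.subset == "CD4"].copy()
        cd8 = cd4.copy()
        cd8["subset"] = "CD8"
        both = pd.concat([cd4, cd8], ignore_index=True)
        out = cd8_cd4_ratio_test(both, timepoint=1)
        assert np.allclose(out["delta"], 0.0)
        assert np.allclose(out["p"], 1.0)

    def test_z_to_p_normal_quantile(self):
        # Delta = 1.96 * SE_pooled -> p ~ 0.05: build directly
        per = []
        for subset, mean in (("CD4", 0.0), ("CD8", 0.98)):
            for rep, dev in ((1, -1.0), (2, 0.0), (3, 1.0)):
                per.append(("A", "d1", rep, subset, "antigen+", 1, mean + dev, 0.0))
        df = pd.DataFrame(per, columns=["construct", "donor", "replicate",
                                        "subset", "condition", "timepoint",
                                        "log2fc", "rel_log2fc"])
        out = cd8_cd4_ratio_test(df, timepoint=1)
        se_pooled = math.sqrt(2) * 1.0 / math.sqrt(3)
        expected_z = 0.98 / se_pooled
        assert out["z"].iloc[0] == pytest.approx(expected_z, abs=1e-9)
        from scipy.stats import norm
        assert out["p"].iloc[0] == pytest.approx(2 * norm.sf(expected_z), abs=1e-12)

    def test_detects_cd8_advantage(self):
        tidy = self._two_subset_tidy(shift=1.5, seed=3)
        res = relative_expansion(tidy)
        out = cd8_cd4_ratio_test(res.per_replicate, timepoint=1)
        row = out[out.construct == "C0"].iloc[0]
        assert row["delta"] > 0
        assert row["q"] < 0.05

    def test_cd8_advantage_power_over_seeded_runs(self):
        """A CD8-only fitness advantage of 1.2x/round over 8 rounds is
        recovered (q < 0.05, correct sign) in >= 90% of 50 seeded runs."""
        import numpy as np

        from carpool.simulate import DomainTruth, ScreenDesign, make_default_library, simulate_expansion

        base = make_default_library(20, 0, 0, seed=0, jitter=0.0)
        lib = []
        for i, t in enumerate(base):
            fit = {"CD4": {"antigen+": 1.0}, "CD8": {"antigen+": 1.2 if i == 0 else 1.0}}
            lib.append(DomainTruth.from_dict({**t.to_dict(), "fitness": fit}))
        design = ScreenDesign(donors=("d1",), replicates=3, timepoints=(0, 8),
                              conditions=("antigen+",), cells_per_sample=100_000)
        recovered = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            rows = []
            for subset in ("CD4", "CD8"):
                for rep in (1, 2, 3):
                    traj = simulate_expansion(lib, design, rng, subset=subset,
                                              condition="antigen+")
                    for t in design.timepoints:
                        for i, name in enumerate(traj.names):
                            rows.append((name, "d1", rep, subset, "antigen+", t,
                                         int(traj.cell_counts[t][i])))
            tidy = pd.DataFrame(rows, columns=["construct", "donor", "replicate",
                                               "subset", "condition", "timepoint",
                                               "count"])
            res = relative_expansion(tidy)
            out = cd8_cd4_ratio_test(res.per_replicate, timepoint=8)
            row = out[out.construct == lib[0].name].iloc[0]
            if row["q"] < 0.05 and row["delta"] > 0:
                recovered += 1
        assert recovered >= 45


class TestTrend:
    def test_constant_series_zero_slope(self):
        tidy = _tidy(
            {("d1", 1, "CD8", "antigen+"): {"A": [100, 100, 100, 100],
                                            "B": [100, 100, 100, 100]}},
            [0, 1, 2, 3],
        )
        res = relative_expansion(tidy)
        out = expansion_trend(res.per_replicate)
        assert np.allclose(out["slope"], 0.0)

    def test_ols_matches_closed_form_on_four_points(self):
        # hand series: rel_log2fc = (0.0, 0.3, 0.4, 0.9) at t = 0, 1, 2, 3
        y = np.array([0.0, 0.3, 0.4, 0.9])
        x = np.array([0.0, 1, 2, 3])
        expected = ((x - x.mean()) @ (y - y.mean())) / ((x - x.mean()) ** 2).sum()
        rows = [("A", "d1", 1, "CD8", "antigen+", int(t), float(v), float(v))
                for t, v in zip(x, y)]
        df = pd.DataFrame(rows, columns=["construct", "donor", "replicate",
                                         "subset", "condition", "timepoint",
                                         "log2fc", "rel_log2fc"])
        out = expansion_trend(df)
        assert out["slope"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_too_few_timepoints_raise(self):
        df = pd.DataFrame(
            [("A", "d1", 1, "CD8", "antigen+", 0, 0.0, 0.0),
             ("A", "d1", 1, "CD8", "antigen+", 1, 0.1, 0.1)],
            columns=["construct", "donor", "replicate", "subset", "condition",
                     "timepoint", "log2fc", "rel_log2fc"],
        )
        with pytest.raises(ValueError, match="timepoints"):
            expansion_trend(df)
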