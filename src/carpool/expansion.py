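"""Relative expansion of pooled-library members over serial stimulations.

A construct's relative expansion is the fold-change of its library frequency
at a timepoint versus the pre-stimulation baseline.  Counts are depth
normalized with median-of-ratios size factors (total-count scaling as a
stated fallback), log2 fold-changes use a pseudocount so dropouts stay
bounded, and "library-relative" values are centered on the mean over retained
constructs so the average library member sits at zero — the natural reference
in a pooled screen.

The CD8-versus-CD4 comparison tests, per construct, whether expansion differs
between subsets: Delta = mean log2FC(CD8) - mean log2FC(CD4), a Wald z on the
pooled replicate SEs, two-sided normal p, and BH q across constructs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 0.5

SERIES_KEYS = ["donor", "replicate", "subset", "condition"]
ABUNDANCE_COLUMNS = ["construct", *SERIES_KEYS, "timepoint", "count"]


@dataclass
class ExpansionResult:
    """Per-replicate and replicate-aggregated relative expansion tables.

    ``per_replicate`` has one row per (construct, donor, replicate, subset,
    condition, timepoint) with ``log2fc`` and library-relative ``rel_log2fc``;
    ``summary`` aggregates over (donor, replicate) with mean, SE and n.
    """

    per_replicate: pd.DataFrame
    summary: pd.DataFrame
    baseline_timepoint: int = 0
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    notes: list = field(default_factory=list)


def size_factors(count_matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors per sample (column).

    s_j = median_i( count_ij / geomean_i ), with the geometric-mean reference
    taken over constructs positive in every sample.  If no construct is
    positive everywhere, falls back to total-count scaling (normalized to
    geometric mean 1) with a logged notice.
    """
    m = count_matrix.to_numpy(dtype=float)
    zero_samples = m.sum(axis=0) == 0
    if zero_samples.any():
        bad = list(count_matrix.columns[zero_samples])
        raise ValueError(f"sample(s) {bad} have all-zero counts")
    everywhere = (m > 0).all(axis=1)
    if everywhere.any():
        logref = np.log(m[everywhere]).mean(axis=1)
        factors = np.exp(
            np.median(np.log(m[everywhere]) - logref[:, None], axis=0)
        )
    else:
        logger.info(
            "size_factors: no construct positive in all samples; "
            "falling back to total-count scaling"
        )
        totals = m.sum(axis=0)
        factors = totals / np.exp(np.mean(np.log(totals)))
    return pd.Series(factors, index=count_matrix.columns, name="size_factor")


def _series_log2fc(
    wide: pd.DataFrame, baseline: int, pseudocount: float
) -> pd.DataFrame:
    """log2FC vs baseline for one series (constructs x timepoints counts)."""
    s = size_factors(wide)
    norm = wide / s
    base = norm[baseline]
    out = {}
    for t in wide.columns:
        out[t] = np.log2((norm[t] + pseudocount) / (base + pseudocount))
    return pd.DataFrame(out)


def relative_expansion(
    abundance: pd.DataFrame,
    baseline_timepoint: int = 0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    retained: pd.Series | None = None,
) -> ExpansionResult:
    """Compute log2FC vs baseline and library-relative log2FC per series.

    ``abundance`` is a tidy table with columns construct, donor, replicate,
    subset, condition, timepoint, count.  ``retained`` optionally marks
    constructs (index = construct) contributing to the library mean; excluded
    constructs still get their own log2FC.  Replicate mean and SE (over
    donor x replicate) are reported per (construct, subset, condition,
    timepoint).
    """
    missing = [c for c in ABUNDANCE_COLUMNS if c not in abundance.columns]
    if missing:
        raise ValueError(f"abundance table missing columns {missing}")
    if baseline_timepoint not in set(abundance["timepoint"]):
        raise ValueError(f"baseline timepoint {baseline_timepoint} absent")
    notes: list = []
    rows = []
    for keys, grp in abundance.groupby(SERIES_KEYS, sort=True):
        wide = grp.pivot_table(
            index="construct", columns="timepoint", values="count", fill_value=0
        )
        if baseline_timepoint not in wide.columns:
            raise ValueError(
                f"series {dict(zip(SERIES_KEYS, keys))} lacks the baseline timepoint"
            )
        lfc = _series_log2fc(wide, baseline_timepoint, pseudocount)
        if retained is not None:
            keep = lfc.index.intersection(retained.index[retained])
            if len(keep) < len(lfc):
                notes.append(
                    f"series {keys}: {len(lfc) - len(keep)} construct(s) excluded "
                    "from the library mean"
                )
        else:
            keep = lfc.index
        centered = lfc - lfc.loc[keep].mean(axis=0)
        long = lfc.stack().rename("log2fc").reset_index()
        long.columns = ["construct", "timepoint", "log2fc"]
        long["rel_log2fc"] = centered.stack().to_numpy()
        for k, v in zip(SERIES_KEYS, keys):
            long[k] = v
        rows.append(long)
    per_rep = pd.concat(rows, ignore_index=True)[
        ["construct", *SERIES_KEYS, "timepoint", "log2fc", "rel_log2fc"]
    ]
    summary = (
        per_rep.groupby(["construct", "subset", "condition", "timepoint"])
        .agg(
            mean_log2fc=("log2fc", "mean"),
            mean_rel_log2fc=("rel_log2fc", "mean"),
            se_rel_log2fc=("rel_log2fc", lambda x: x.std(ddof=1) / np.sqrt(len(x))),
            n=("rel_log2fc", "size"),
        )
        .reset_index()
    )
    return ExpansionResult(
        per_replicate=per_rep,
        summary=summary,
        baseline_timepoint=baseline_timepoint,
        pseudocount=pseudocount,
        notes=notes,
    )


def cd8_cd4_ratio_test(
    per_replicate: pd.DataFrame,
    timepoint: int,
    condition: str = "antigen+",
) -> pd.DataFrame:
    """Per-construct CD8-minus-CD4 expansion difference with a Wald test.

    Delta_i = mean log2FC(CD8) - mean log2FC(CD4) over donor x replicate;
    z = Delta / sqrt(SE_CD8^2 + SE_CD4^2); two-sided normal p; BH q across
    constructs.  Constructs with fewer than 2 replicates in either subset get
    NaN and are excluded from testing.
    """
    sel = per_replicate[
        (per_replicate["timepoint"] == timepoint)
        & (per_replicate["condition"] == condition)
    ]
    stats = (
        sel.groupby(["construct", "subset"])["log2fc"]
        .agg(["mean", "sem", "size"])
        .unstack("subset")
    )
    out = pd.DataFrame(index=stats.index)
    for subset in ("CD4", "CD8"):
        if ("mean", subset) not in stats.columns:
            raise ValueError(f"subset {subset} missing at timepoint {timepoint}")
    out["delta"] = stats[("mean", "CD8")] - stats[("mean", "CD4")]
    se = np.sqrt(stats[("sem", "CD8")] ** 2 + stats[("sem", "CD4")] ** 2)
    enough = (stats[("size", "CD8")] >= 2) & (stats[("size", "CD4")] >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (out["delta"] / se).to_numpy()
    # identical subsets: 0/0 -> no evidence of difference, z = 0 (p = 1)
    z = np.where((se.to_numpy() == 0) & (out["delta"].to_numpy() == 0), 0.0, z)
    out["z"] = np.where(enough.to_numpy(), z, np.nan)
    out["p"] = 2.0 * sps.norm.sf(np.abs(out["z"]))
    out["q"] = bh_fdr(out["p"].to_numpy())
    out.index.name = "construct"
    return out.reset_index()


def expansion_trend(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Per-construct OLS slope of library-relative log2FC versus timepoint.

    Within each replicate series the slope is fit by ordinary least squares
    over the (>= 3) timepoints; a z statistic comes from the replicate
    mean / SE of the slopes.  This is a deliberately simple trend summary of
    the longitudinal expansion signal.
    """
    n_tp = per_replicate["timepoint"].nunique()
    if n_tp < 3:
        raise ValueError(f"expansion_trend needs >= 3 timepoints, got {n_tp}")
    rows = []
    for (construct, *keys), grp in per_replicate.groupby(
        ["construct", *SERIES_KEYS], sort=True
    ):
        x = grp["timepoint"].to_numpy(dtype=float)
        y = grp["rel_log2fc"].to_numpy(dtype=float)
        xc = x - x.mean()
        slope = float((xc @ (y - y.mean())) / (xc @ xc))
        rows.append((construct, *keys, slope))
    slopes = pd.DataFrame(rows, columns=["construct", *SERIES_KEYS, "slope"])
    out = (
        slopes.groupby(["construct", "subset", "condition"])["slope"]
        .agg(["mean", "sem", "size"])
        .reset_index()
        .rename(columns={"mean": "slope", "sem": "se", "size": "n"})
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        out["z"] = out["slope"] / out["se"]
    return out
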