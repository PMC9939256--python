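"""Integration of all screen assays into a ranked hit table.

Every raw metric (mean divisions, cytokine and activation percent-positive,
relative expansion) is z-scored across domains within each
(assay, donor, replicate, subset) group, so donor- and batch-level shifts
cancel.  Per domain, z-scores are combined with Stouffer's method — first
across donors/replicates into a per-(assay, subset) combined-Z matrix, then
across those columns into one overall Z — followed by a one-sample z-test and
Benjamini-Hochberg FDR across domains.  The combined-Z matrix also drives the
hierarchical clustering and PCA views of the screen, and average ranks
summarize each domain's position across assays.

Measurements removed by the minimum-cell filter are missing throughout: they
are excluded from z-scoring and reduce Stouffer's k, and are imputed as 0
(the library average) only inside clustering/PCA distance computations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch

from .stats import (
    bh_fdr,
    check_normality,
    one_sample_z_test,
    rank_average,
    stouffer_combine,
    zscore_within_group,
)

logger = logging.getLogger(__name__)

GROUP_KEYS = ["assay", "donor", "replicate", "subset"]

METRIC_COLUMNS = ["domain", "assay", "donor", "replicate", "subset", "condition", "value", "filtered"]

#: default assay directionality: +1 means larger raw values are "better".
DEFAULT_DIRECTIONS = {
    "mean_divisions": 1,
    "il2_pct": 1,
    "ifng_pct": 1,
    "cd69_pct": 1,
    "expansion": 1,
}


@dataclass
class AssayMatrix:
    """Tidy z-scores plus the per-(domain, assay, subset) combined-Z matrix."""

    zscores: pd.DataFrame  # tidy; METRIC_COLUMNS + "z"
    combined: pd.DataFrame  # domains x (assay, subset) MultiIndex columns
    normality: pd.DataFrame  # per-group Anderson-Darling diagnostics


def zscore_metrics(
    metrics: pd.DataFrame,
    directions: dict | None = None,
    condition: str = "antigen+",
    check: bool = True,
) -> AssayMatrix:
    """z-score raw metrics within each (assay, donor, replicate, subset) group.

    Only the stimulated condition enters hit scoring.  Filtered measurements
    are excluded from the group moments and stay missing.  Each group is run
    through an advisory Anderson-Darling normality check (logged, never
    blocking).
    """
    directions = {**DEFAULT_DIRECTIONS, **(directions or {})}
    missing = [c for c in METRIC_COLUMNS if c not in metrics.columns]
    if missing:
        raise ValueError(f"metrics table missing columns {missing}")
    df = metrics[metrics["condition"] == condition].copy()
    df["z"] = np.nan
    diag = []
    for keys, grp in df.groupby(GROUP_KEYS, sort=True):
        sign = directions.get(keys[0], 1)
        vals = np.where(grp["filtered"].to_numpy(), np.nan, grp["value"].to_numpy(dtype=float))
        if np.sum(~np.isnan(vals)) < 2:
            logger.warning(
                "group %s has < 2 retained measurements; z-scores missing", keys
            )
            continue
        z = zscore_within_group(vals) * sign
        df.loc[grp.index, "z"] = z
        if check:
            a2, passed, note = check_normality(vals)
            diag.append((*keys, a2, passed, note))
            if passed is False:
                logger.info("normality check failed for group %s (A2=%.3f)", keys, a2)
    normality = pd.DataFrame(
        diag, columns=[*GROUP_KEYS, "A2", "passed", "note"]
    )
    combined = (
        df.groupby(["domain", "assay", "subset"])["z"]
        .apply(lambda s: stouffer_combine(s.to_numpy()))
        .unstack(["assay", "subset"])
        .sort_index(axis=1)
    )
    return AssayMatrix(zscores=df, combined=combined, normality=normality)


# --------------------------------------------------------------------------
# Clustering and PCA
# --------------------------------------------------------------------------


@dataclass
class ClusterResult:
    labels: pd.Series
    linkage: np.ndarray
    order: list
    newick: str


def _tree_to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _tree_to_newick(node.get_left(), labels)
    right = _tree_to_newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def hier_cluster(
    z_matrix: pd.DataFrame,
    method: str = "average",
    cut_height: float | None = None,
) -> ClusterResult:
    """Agglomerative clustering of domains on their combined z-scores.

    Average linkage, Euclidean distance.  Missing cells are imputed as 0 (the
    library average under mean-0 z-scoring) for the distance computation only.
    Flat clusters are cut at ``cut_height`` (default 0.7 x the maximum merge
    distance); the dendrogram is also exported as Newick.
    """
    if len(z_matrix) < 2:
        raise ValueError("hier_cluster needs >= 2 domains")
    x = z_matrix.to_numpy(dtype=float)
    x = np.where(np.isnan(x), 0.0, x)
    link = sch.linkage(x, method=method, metric="euclidean")
    if cut_height is None:
        cut_height = 0.7 * link[:, 2].max() if link[:, 2].max() > 0 else 1.0
    flat = sch.fcluster(link, t=cut_height, criterion="distance")
    tree = sch.to_tree(link)
    newick = _tree_to_newick(tree, list(z_matrix.index)) + ";"
    order = [z_matrix.index[i] for i in sch.leaves_list(link)]
    return ClusterResult(
        labels=pd.Series(flat, index=z_matrix.index, name="cluster"),
        linkage=link,
        order=order,
        newick=newick,
    )


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_fraction: np.ndarray


def pca(metric_matrix: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of a domains x metrics matrix via SVD on scaled columns.

    Columns are centered and scaled to unit SD; missing entries are imputed as
    the column mean (0 after centering); zero-variance columns are dropped
    with a warning.  The sign convention makes each component's
    largest-magnitude loading positive, so scores are deterministic.
    """
    if metric_matrix.shape[0] < 2 or metric_matrix.shape[1] < 2:
        raise ValueError("pca needs >= 2 domains and >= 2 metrics")
    x = metric_matrix.to_numpy(dtype=float)
    mu = np.nanmean(x, axis=0)
    x = np.where(np.isnan(x), mu[None, :], x)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = list(metric_matrix.columns[~keep])
        logger.warning("pca: dropping zero-variance column(s) %s", dropped)
    cols = list(metric_matrix.columns[keep])
    xs = (x[:, keep] - mu[keep]) / sd[keep]
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    k = min(len(s), n_components or len(s))
    # sign convention: largest-|loading| of each component is positive
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    scores = u[:, :k] * s[:k]
    var = s**2
    var_frac = var / var.sum()
    pcs = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=metric_matrix.index, columns=pcs),
        loadings=pd.DataFrame(vt[:k].T, index=cols, columns=pcs),
        variance_fraction=var_frac[:k],
    )


# --------------------------------------------------------------------------
# Hit table
# --------------------------------------------------------------------------


@dataclass
class HitTable:
    """Machine-readable hit ranking: combined Z, p, BH q, ranks, clusters, PCs."""

    table: pd.DataFrame
    assay_matrix: AssayMatrix
    clusters: ClusterResult | None = None
    pca: PCAResult | None = None
    alpha: float = 0.05
    notes: list = field(default_factory=list)


def score_screen(
    metrics: pd.DataFrame,
    directions: dict | None = None,
    alpha: float = 0.05,
    linkage_method: str = "average",
    cut_height: float | None = None,
    condition: str = "antigen+",
) -> HitTable:
    """Full scoring chain: z-scores -> Stouffer -> p -> BH q -> ranks/clusters/PCA."""
    am = zscore_metrics(metrics, directions=directions, condition=condition)
    combined = am.combined
    overall_z = combined.apply(lambda row: stouffer_combine(row.to_numpy()), axis=1)
    p = overall_z.map(lambda z: one_sample_z_test(z) if np.isfinite(z) else np.nan)
    q = pd.Series(bh_fdr(p.to_numpy()), index=p.index)

    # average rank over per-(assay, subset) mean raw metrics
    raw = (
        am.zscores[~am.zscores["filtered"].astype(bool)]
        .groupby(["domain", "assay", "subset"])["value"]
        .mean()
        .unstack(["assay", "subset"])
    )
    dir_map = {**DEFAULT_DIRECTIONS, **(directions or {})}
    col_dirs = {col: dir_map.get(col[0], 1) for col in raw.columns}
    avg_rank = rank_average(raw, directions=col_dirs)

    out = pd.DataFrame(index=combined.index)
    out["combined_z"] = overall_z
    out["p"] = p
    out["q"] = q
    out["significant"] = q < alpha
    out["average_rank"] = avg_rank.reindex(out.index)

    clusters = pca_res = None
    if len(combined) >= 2:
        clusters = hier_cluster(combined, method=linkage_method, cut_height=cut_height)
        out["cluster"] = clusters.labels.reindex(out.index)
        pca_res = pca(combined)
        out["PC1"] = pca_res.scores["PC1"].reindex(out.index)
        if "PC2" in pca_res.scores.columns:
            out["PC2"] = pca_res.scores["PC2"].reindex(out.index)
    for assay_subset in combined.columns:
        out[f"Z_{assay_subset[0]}_{assay_subset[1]}"] = combined[assay_subset]
    out = out.sort_values("average_rank")
    out.index.name = "domain"
    return HitTable(
        table=out, assay_matrix=am, clusters=clusters, pca=pca_res, alpha=alpha
    )
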