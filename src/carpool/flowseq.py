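"""Sort-seq (FlowSeq) phenotype reconstruction from bin-sorted read counts.

A library is FACS-sorted into fluorescence bins and each bin is amplicon
sequenced.  With r_ib reads for construct i in bin b, R_b total reads in the
bin, and N_b sorted cells in the bin, the cells-weighted read fraction

    w_ib = (r_ib / R_b) * N_b

estimates the number of bin-b cells attributable to construct i (the
maximum-likelihood estimate under multinomial read sampling within each bin).
Normalizing w over bins gives the construct's bin-fraction vector f_ib, and
C_i = sum_b w_ib is its effective cell count, on which the minimum-cell
inclusion filter operates.

Downstream summaries re-express f_ib on the fluorescence scale: a geometric
mean over gate log-midpoints (MFI), a percent-positive above a gate-boundary
threshold, and — for generation-aligned CTV gates — a division-number
distribution and mean divisions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bins import BinLayout, LayoutError, LOG10_2

DEFAULT_MIN_CELLS = 500


class DataError(ValueError):
    """Raised when counts and layout disagree (e.g. cells sorted, no reads)."""


@dataclass
class BinFractionEstimate:
    """Per-construct bin fractions f_ib and effective cell counts C_i."""

    fractions: pd.DataFrame  # constructs x bins; rows sum to 1 or are all-NaN
    cells: pd.Series  # C_i >= 0

    def __post_init__(self):
        f = self.fractions.to_numpy(dtype=float)
        ok = ~np.isnan(f).all(axis=1)
        if f[ok].size and (np.nanmin(f[ok]) < -1e-12 or not np.allclose(f[ok].sum(axis=1), 1.0)):
            raise ValueError("bin fractions must be nonnegative and sum to 1")


def estimate_bin_fractions(
    counts: pd.DataFrame, layout: BinLayout, pseudocount: float = 0.0
) -> BinFractionEstimate:
    """Reconstruct f_ib and C_i from a constructs x bins read-count table.

    ``counts`` columns must match ``layout.bin_ids``; ``layout.cell_counts``
    supplies N_b.  A bin with sorted cells but zero reads is a data error
    (the estimator has no information about it).  ``pseudocount`` optionally
    adds a Dirichlet alpha to reads at very low depth (off by default).
    """
    if layout.cell_counts is None:
        raise DataError("layout has no per-bin sorted-cell counts (N_b)")
    missing = [b for b in layout.bin_ids if b not in counts.columns]
    if missing:
        raise DataError(f"count table missing bin columns {missing}")
    r = counts[list(layout.bin_ids)].to_numpy(dtype=float)
    if pseudocount > 0:
        r = r + pseudocount
    N = np.asarray(layout.cell_counts, dtype=float)
    R = r.sum(axis=0)
    bad = (N > 0) & (R == 0)
    if bad.any():
        raise DataError(
            f"bins {[layout.bin_ids[i] for i in np.flatnonzero(bad)]} have sorted "
            "cells but zero reads"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(R > 0, r / np.where(R > 0, R, 1.0), 0.0) * N
    C = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(C[:, None] > 0, w / np.where(C[:, None] > 0, C[:, None], 1.0), np.nan)
    fractions = pd.DataFrame(f, index=counts.index, columns=list(layout.bin_ids))
    cells = pd.Series(C, index=counts.index, name="effective_cells")
    return BinFractionEstimate(fractions=fractions, cells=cells)


def estimate_mfi(fractions: pd.DataFrame, layout: BinLayout) -> pd.Series:
    """Geometric-mean fluorescence: log10(MFI) = sum_b f_ib * midpoint_b.

    The gate log-midpoint is the bin's representative value — unbiased under a
    locally flat density and exact for generation-aligned gates.  Rows of
    all-NaN fractions give NaN with a warning.
    """
    f = fractions[list(layout.bin_ids)].to_numpy(dtype=float)
    nan_rows = np.isnan(f).all(axis=1)
    if nan_rows.any():
        warnings.warn(
            f"{int(nan_rows.sum())} construct(s) have undefined bin fractions; MFI is NaN",
            stacklevel=2,
        )
    log_mfi = f @ layout.midpoints
    return pd.Series(10.0 ** log_mfi, index=fractions.index, name="mfi")


def _generation_map(layout: BinLayout, mfi0: float) -> np.ndarray:
    """Map each gate to the unique division number whose CTV peak it contains.

    Peaks sit at log10(mfi0) - d*log10(2), d = 0..D_max.  A gate holding zero
    or more than one peak makes the deconvolution ill-posed.
    """
    from .simulate import D_MAX

    if mfi0 <= 0:
        raise LayoutError("mfi0 must be positive")
    top = np.log10(mfi0)
    peaks = top - np.arange(D_MAX + 1) * LOG10_2
    d_of_bin = np.empty(layout.n_bins, dtype=int)
    for b, (lo, hi) in enumerate(layout.gates):
        inside = np.flatnonzero((peaks >= lo) & (peaks < hi))
        if inside.size != 1:
            raise LayoutError(
                f"gate ({lo:.4f}, {hi:.4f}) contains {inside.size} generation "
                "peaks; need exactly 1 for division deconvolution"
            )
        d_of_bin[b] = inside[0]
    return d_of_bin


def estimate_division_distribution(
    fractions: pd.DataFrame, layout: BinLayout, mfi0: float
):
    """Re-index bin fractions by division number; returns (distribution, mean).

    Requires generation-aligned gates (each gate holds exactly one CTV peak
    mfi0 * 2**-d).  The distribution is f re-indexed by the gate's division
    number; mean_divisions = sum_d d * f.
    """
    d_of_bin = _generation_map(layout, mfi0)
    f = fractions[list(layout.bin_ids)].to_numpy(dtype=float)
    order = np.argsort(d_of_bin)
    dist = pd.DataFrame(
        f[:, order], index=fractions.index, columns=[int(d) for d in d_of_bin[order]]
    )
    mean = pd.Series(f @ d_of_bin, index=fractions.index, name="mean_divisions")
    return dist, mean


def estimate_percent_positive(
    fractions: pd.DataFrame, layout: BinLayout, threshold: float
) -> pd.Series:
    """100 x the summed fraction in gates at or above a boundary threshold.

    ``threshold`` (log10 units) must coincide with a gate boundary or lie
    outside every gate — there is no sub-bin interpolation.  A threshold below
    every gate returns 100, above every gate returns 0.
    """
    los = np.array([lo for lo, _ in layout.gates])
    his = np.array([hi for _, hi in layout.gates])
    strictly_inside = np.any(
        (threshold > los + 1e-12) & (threshold < his - 1e-12)
    )
    if strictly_inside:
        raise ValueError(
            f"threshold {threshold} falls inside a gate; it must sit on a "
            "gate boundary (no sub-bin interpolation)"
        )
    mask = los >= threshold - 1e-12
    f = fractions[list(layout.bin_ids)].to_numpy(dtype=float)
    pct = 100.0 * f[:, mask].sum(axis=1)
    return pd.Series(pct, index=fractions.index, name="percent_positive")


def apply_min_cell_filter(
    cells: pd.Series, min_cells: float = DEFAULT_MIN_CELLS
) -> pd.Series:
    """Flag constructs whose effective cell count falls below the threshold.

    Strict inequality: a construct with exactly ``min_cells`` effective cells
    is retained.  Flagged measurements are excluded from downstream scoring
    for that replicate.
    """
    return pd.Series(cells.to_numpy() < min_cells, index=cells.index, name="filtered")


def quantify_sample(
    counts: pd.DataFrame,
    layout: BinLayout,
    mfi0: float | None = None,
    positive_threshold: float | None = None,
    min_cells: float = DEFAULT_MIN_CELLS,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """One-stop phenotype table for a single bin-sorted sample.

    Always reports effective cells, MFI and the filter flag; adds
    mean_divisions when ``mfi0`` is given (CTV channel) and percent_positive
    when ``positive_threshold`` is given.
    """
    est = estimate_bin_fractions(counts, layout, pseudocount=pseudocount)
    out = pd.DataFrame(index=counts.index)
    out["effective_cells"] = est.cells
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["mfi"] = estimate_mfi(est.fractions, layout)
    if mfi0 is not None:
        _, mean = estimate_division_distribution(est.fractions, layout, mfi0)
        out["mean_divisions"] = mean
    if positive_threshold is not None:
        out["percent_positive"] = estimate_percent_positive(
            est.fractions, layout, positive_threshold
        )
    out["filtered"] = apply_min_cell_filter(est.cells, min_cells)
    return out
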