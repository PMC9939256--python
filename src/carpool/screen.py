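"""End-to-end simulated screens: raw artifacts -> phenotypes -> metrics.

``simulate_screen`` produces exactly the artifacts a real pooled screen
yields — bin-sorted amplicon read counts with per-bin sorted-cell totals for
each FlowSeq assay, and library-abundance counts over stimulation rounds —
for every (donor, replicate, subset, antigen condition) combination.
``quantify_screen`` runs the sort-seq estimators over those artifacts and
emits the tidy per-replicate metric table that hit scoring consumes, plus the
simulator's ground truth so recovery can be checked.

Donor variability is modeled at two levels: a global per-donor shift of each
channel (cancelled by within-donor z-scoring) and a small per-(donor, domain)
interaction — an exponential tilt of the division profile, additive shifts of
the log cytokine mean and activation logit, and a log-fitness nudge — which
is the biological noise the meta-combination has to average over.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import flowseq
from .bins import (
    BinLayout,
    CD69_POSITIVE_LOG10,
    CYTOKINE_POSITIVE_LOG10,
    cd69_layout,
    ctv_generation_layout,
    cytokine_layout,
)
from .expansion import relative_expansion
from .simulate import (
    CYTOKINE_CHANNELS,
    D_MAX,
    CellSample,
    DomainTruth,
    ScreenDesign,
    draw_cells,
    simulate_expansion,
    simulate_reads,
    simulate_sort,
)

FLOWSEQ_ASSAYS = {
    # assay name -> (channel, metric name)
    "ctv": ("CTV", "mean_divisions"),
    "il2": ("IL2", "il2_pct"),
    "ifng": ("IFNG", "ifng_pct"),
    "cd69": ("CD69", "cd69_pct"),
}

#: per-(donor, domain) interaction noise scales (a priori study conditions)
DONOR_TILT_SD = 0.08  # exponential tilt of the division profile
DONOR_CYT_SD = 0.15  # natural-log cytokine mean shift
DONOR_ACT_SD = 0.20  # activation logit shift
DONOR_FIT_SD = 0.02  # log fitness shift
#: per-donor global channel shifts (removed by within-donor z-scoring)
DONOR_GLOBAL_CYT_SD = 0.30
DONOR_GLOBAL_ACT_SD = 0.20


def default_layouts(design: ScreenDesign, n_ctv_bins: int = 4) -> dict:
    return {
        "ctv": ctv_generation_layout(design.mfi0, n_bins=n_ctv_bins),
        "il2": cytokine_layout("IL2"),
        "ifng": cytokine_layout("IFNG"),
        "cd69": cd69_layout(),
    }


POSITIVE_THRESHOLDS = {
    "il2": CYTOKINE_POSITIVE_LOG10,
    "ifng": CYTOKINE_POSITIVE_LOG10,
    "cd69": CD69_POSITIVE_LOG10,
}


def _tilt_profile(profile: np.ndarray, theta: float) -> tuple:
    """Exponential tilt: p_d ∝ p_d * exp(theta * d); shifts mean smoothly."""
    d = np.arange(len(profile))
    w = profile * np.exp(theta * d)
    w = w / w.sum()
    return tuple(float(x) for x in w)


def perturb_truth_for_donor(
    truth: DomainTruth,
    rng: np.random.Generator,
    global_shifts: dict,
    interaction: float = 1.0,
) -> DomainTruth:
    """Per-(donor, domain) parameter jitter plus donor-global channel shifts.

    ``interaction`` scales the per-(donor, domain) terms; 0 keeps every
    domain biologically exchangeable across donors (global shifts remain).
    """
    d = truth.to_dict()
    theta = interaction * DONOR_TILT_SD * rng.standard_normal()
    d["division_profile_antigen"] = _tilt_profile(
        np.asarray(truth.division_profile_antigen), theta
    )
    d["division_profile_basal"] = _tilt_profile(
        np.asarray(truth.division_profile_basal), theta
    )
    cyt = {}
    for ch, per_cond in truth.cytokine_log_mean.items():
        shift = interaction * DONOR_CYT_SD * rng.standard_normal() + global_shifts[ch]
        cyt[ch] = {cond: mu + shift for cond, mu in per_cond.items()}
    d["cytokine_log_mean"] = cyt
    act_shift = interaction * DONOR_ACT_SD * rng.standard_normal() + global_shifts["CD69"]
    act = {}
    for cond, p in truth.activation_prob.items():
        logit = math.log(p / (1 - p)) + act_shift
        act[cond] = 1.0 / (1.0 + math.exp(-logit))
    d["activation_prob"] = act
    fit_shift = interaction * DONOR_FIT_SD * rng.standard_normal()
    d["fitness"] = {
        subset: {cond: f * math.exp(fit_shift) for cond, f in per_cond.items()}
        for subset, per_cond in truth.fitness.items()
    }
    return DomainTruth.from_dict(d)


@dataclass
class ScreenArtifacts:
    """Raw sequencing-level outputs of one simulated screen."""

    flowseq_counts: pd.DataFrame  # assay, donor, replicate, subset, condition, bin_id, construct, reads
    bin_cells: pd.DataFrame  # assay, donor, replicate, subset, condition, bin_id, cells_sorted
    abundance: pd.DataFrame  # construct, donor, replicate, subset, condition, timepoint, count
    truths: list
    design: ScreenDesign
    layouts: dict
    donor_truths: dict = field(default_factory=dict)  # donor -> list[DomainTruth]


def simulate_screen(
    truths: list,
    design: ScreenDesign,
    rng: np.random.Generator,
    layouts: dict | None = None,
    assays: tuple = tuple(FLOWSEQ_ASSAYS),
    donor_variability: float = 1.0,
) -> ScreenArtifacts:
    """Simulate the full pooled screen at sequencing-count resolution.

    ``donor_variability`` scales the per-(donor, domain) interaction noise;
    0 makes domains exchangeable across donors (used by null calibration).
    """
    layouts = layouts or default_layouts(design)
    names = [t.name for t in truths]
    n = len(truths)

    donor_truths: dict = {}
    for donor in design.donors:
        global_shifts = {
            ch: DONOR_GLOBAL_CYT_SD * rng.standard_normal()
            for ch in CYTOKINE_CHANNELS
        }
        global_shifts["CD69"] = DONOR_GLOBAL_ACT_SD * rng.standard_normal()
        donor_truths[donor] = [
            perturb_truth_for_donor(t, rng, global_shifts, interaction=donor_variability)
            for t in truths
        ]

    fs_rows = []
    cell_rows = []
    ab_rows = []
    assay_round = 1  # FlowSeq assays happen after the first stimulation
    for donor in design.donors:
        d_truths = donor_truths[donor]
        for rep in range(1, design.replicates + 1):
            for subset in design.subsets:
                for condition in design.conditions:
                    traj = simulate_expansion(
                        d_truths, design, rng, subset=subset, condition=condition
                    )
                    for t in design.timepoints:
                        reads_t = simulate_reads(
                            traj.cell_counts[t][:, None],
                            design.read_depth,
                            design.dirichlet_mass,
                            rng,
                        )[:, 0]
                        for i in range(n):
                            ab_rows.append(
                                (names[i], donor, rep, subset, condition, t, int(reads_t[i]))
                            )
                    comp = traj.frequencies[:, assay_round]
                    for assay in assays:
                        layout = layouts[assay]
                        channel = FLOWSEQ_ASSAYS[assay][0]
                        alloc = rng.multinomial(design.cells_per_sample, comp)
                        samples = [
                            draw_cells(
                                d_truths[i],
                                design,
                                condition,
                                assay_round,
                                rng,
                                n_cells=int(alloc[i]),
                                channels=(channel,),
                            )
                            for i in range(n)
                        ]
                        sort = simulate_sort(samples, layout)
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            reads = simulate_reads(
                                sort.counts,
                                design.read_depth,
                                design.dirichlet_mass,
                                rng,
                            )
                        for b, bin_id in enumerate(layout.bin_ids):
                            cell_rows.append(
                                (assay, donor, rep, subset, condition, bin_id,
                                 int(sort.bin_totals[b]))
                            )
                            for i in range(n):
                                fs_rows.append(
                                    (assay, donor, rep, subset, condition, bin_id,
                                     names[i], int(reads[i, b]))
                                )
    flowseq_counts = pd.DataFrame(
        fs_rows,
        columns=["assay", "donor", "replicate", "subset", "condition", "bin_id",
                 "construct", "reads"],
    )
    bin_cells = pd.DataFrame(
        cell_rows,
        columns=["assay", "donor", "replicate", "subset", "condition", "bin_id",
                 "cells_sorted"],
    )
    abundance = pd.DataFrame(
        ab_rows,
        columns=["construct", "donor", "replicate", "subset", "condition",
                 "timepoint", "count"],
    )
    return ScreenArtifacts(
        flowseq_counts=flowseq_counts,
        bin_cells=bin_cells,
        abundance=abundance,
        truths=truths,
        design=design,
        layouts=layouts,
        donor_truths=donor_truths,
    )


SAMPLE_KEYS = ["assay", "donor", "replicate", "subset", "condition"]


def quantify_screen(
    artifacts: ScreenArtifacts,
    min_cells: float = flowseq.DEFAULT_MIN_CELLS,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """FlowSeq estimation over every bin-sorted sample -> tidy metric table.

    Returns one row per (domain, assay, donor, replicate, subset, condition)
    with the assay's metric value, the effective cell count and the
    minimum-cell filter flag.
    """
    layouts = artifacts.layouts
    design = artifacts.design
    bin_cells = {
        keys: grp.set_index("bin_id")["cells_sorted"]
        for keys, grp in artifacts.bin_cells.groupby(SAMPLE_KEYS, sort=True)
    }
    rows = []
    for keys, grp in artifacts.flowseq_counts.groupby(SAMPLE_KEYS, sort=True):
        assay = keys[0]
        layout: BinLayout = layouts[assay]
        counts = grp.pivot_table(
            index="construct", columns="bin_id", values="reads", fill_value=0
        )
        cells = bin_cells[keys].reindex(list(layout.bin_ids))
        ltd = layout.with_cell_counts(cells.to_numpy())
        pheno = flowseq.quantify_sample(
            counts,
            ltd,
            mfi0=design.mfi0 if assay == "ctv" else None,
            positive_threshold=POSITIVE_THRESHOLDS.get(assay),
            min_cells=min_cells,
            pseudocount=pseudocount,
        )
        metric_col = (
            "mean_divisions" if assay == "ctv" else "percent_positive"
        )
        metric_name = FLOWSEQ_ASSAYS[assay][1]
        for construct, r in pheno.iterrows():
            rows.append(
                (construct, metric_name, *keys[1:], r[metric_col],
                 r["effective_cells"], bool(r["filtered"]))
            )
    return pd.DataFrame(
        rows,
        columns=["domain", "assay", "donor", "replicate", "subset", "condition",
                 "value", "effective_cells", "filtered"],
    )


def expansion_metrics(
    artifacts: ScreenArtifacts,
    timepoint: int | None = None,
    pseudocount: float = 0.5,
):
    """Relative-expansion analysis plus tidy 'expansion' metric rows.

    The scoring metric is each construct's library-relative log2 fold-change
    at the final sequenced timepoint, per (donor, replicate, subset,
    condition).
    """
    result = relative_expansion(artifacts.abundance, pseudocount=pseudocount)
    tp = timepoint if timepoint is not None else max(artifacts.design.timepoints)
    sel = result.per_replicate[result.per_replicate["timepoint"] == tp]
    rows = sel.rename(columns={"construct": "domain", "rel_log2fc": "value"})[
        ["domain", "donor", "replicate", "subset", "condition", "value"]
    ].copy()
    rows.insert(1, "assay", "expansion")
    rows["effective_cells"] = np.nan
    rows["filtered"] = False
    return result, rows


def screen_metrics(
    artifacts: ScreenArtifacts,
    min_cells: float = flowseq.DEFAULT_MIN_CELLS,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """All scoring metrics (FlowSeq assays + expansion) in one tidy table."""
    fs = quantify_screen(artifacts, min_cells=min_cells)
    _, exp_rows = expansion_metrics(artifacts, pseudocount=pseudocount)
    return pd.concat([fs, exp_rows], ignore_index=True)


def true_mean_divisions(
    artifacts: ScreenArtifacts, condition: str = "antigen+"
) -> pd.Series:
    """Library-level true mean divisions per domain (averaged over donors)."""
    names = [t.name for t in artifacts.truths]
    vals = np.zeros(len(names))
    for donor in artifacts.design.donors:
        for i, t in enumerate(artifacts.donor_truths[donor]):
            vals[i] += t.mean_divisions(condition)
    vals /= len(artifacts.design.donors)
    return pd.Series(vals, index=names, name="true_mean_divisions")
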