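"""Self-validation experiments: recovery of known simulator ground truth.

Each function runs one complete recovery experiment — simulate with known
parameters, analyze with the package's estimators, compare to truth — and
returns plain numbers.  They power both the validation test suite and the
standalone validation script, so the same experiment definitions are used
everywhere.

Experiment sizes are deliberately moderate (they are repeated many times);
the methods note records the problem sizes used.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .expansion import relative_expansion
from .flowseq import estimate_bin_fractions, estimate_division_distribution
from .bins import ctv_generation_layout
from .scoring import score_screen
from .screen import screen_metrics, simulate_screen
from .simulate import (
    DomainTruth,
    ScreenDesign,
    draw_cells,
    make_default_library,
    simulate_expansion,
    simulate_reads,
    simulate_sort,
)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


# --------------------------------------------------------------------------
# FlowSeq estimator consistency
# --------------------------------------------------------------------------


def division_estimator_consistency(
    seed: int,
    n_domains: int = 40,
    cells_per_construct: int = 10_000,
    read_depth: int = 1_000_000,
) -> dict:
    """Estimated mean divisions vs the drawn cells' true divisions.

    One CTV FlowSeq sample of the default library over the generation-aligned
    4-bin layout.  Reads are taken in the infinite-concentration (multinomial)
    limit: this is the estimator-consistency experiment, whose claim is
    convergence to truth as reads and cells grow; amplification overdispersion
    is exercised separately by the hit-recovery and null-calibration
    experiments.
    """
    rng = np.random.default_rng(seed)
    lib = make_default_library(n_domains, 8, 2, seed=seed)
    design = ScreenDesign(read_depth=read_depth)
    layout = ctv_generation_layout(design.mfi0, 4)
    samples = [
        draw_cells(t, design, "antigen+", 1, rng, n_cells=cells_per_construct,
                   channels=("CTV",))
        for t in lib
    ]
    true_means = np.array([s.divisions.mean() for s in samples])
    sort = simulate_sort(samples, layout)
    reads = simulate_reads(sort.counts, read_depth, np.inf, rng)
    counts = pd.DataFrame(reads, index=[t.name for t in lib],
                          columns=list(layout.bin_ids))
    est = estimate_bin_fractions(counts, layout.with_cell_counts(sort.bin_totals))
    _, est_means = estimate_division_distribution(est.fractions, layout, design.mfi0)
    err = est_means.to_numpy() - true_means
    rho, _ = sps.spearmanr(true_means, est_means.to_numpy())
    return {
        "max_abs_error": float(np.abs(err).max()),
        "mean_abs_error": float(np.abs(err).mean()),
        "spearman": float(rho),
        "n_reads": read_depth,
        "n_domains": n_domains,
    }


# --------------------------------------------------------------------------
# Hit recovery
# --------------------------------------------------------------------------


def hit_recovery_run(seed: int) -> dict:
    """One default end-to-end screen: do the 8 potent truths surface?"""
    lib = make_default_library(40, 8, 2, seed=seed)
    design = ScreenDesign(seed=seed)
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        art = simulate_screen(lib, design, rng)
        metrics = screen_metrics(art)
        hits = score_screen(metrics)
    potent = {t.name for t in lib if t.phenotype_class == "potent"}
    top10 = set(hits.table.index[:10])
    recovered = {
        d for d in potent & top10 if hits.table.loc[d, "q"] < 0.05
    }
    return {
        "n_potent_in_top10": len(potent & top10),
        "n_recovered": len(recovered),
        "passed": len(recovered) >= 7,
    }


def hit_recovery(seed: int, n_runs: int = 20) -> dict:
    results = [hit_recovery_run(s) for s in _spawn_seeds(seed, n_runs)]
    return {
        "pass_fraction": float(np.mean([r["passed"] for r in results])),
        "mean_potent_in_top10": float(np.mean([r["n_potent_in_top10"] for r in results])),
        "mean_recovered": float(np.mean([r["n_recovered"] for r in results])),
        "n_runs": n_runs,
    }


# --------------------------------------------------------------------------
# Null calibration
# --------------------------------------------------------------------------


def _null_design() -> ScreenDesign:
    # reduced problem size: the null is repeated hundreds of times
    return ScreenDesign(
        donors=("donor1", "donor2"),
        replicates=2,
        subsets=("CD4", "CD8"),
        conditions=("antigen+",),
        timepoints=(0, 8),
        cells_per_sample=50_000,
        read_depth=50_000,
    )


def null_screen_qvalues(seed: int) -> tuple[np.ndarray, np.ndarray]:
    """(p, q) vectors from one screen of an all-identical library.

    Under the null every domain is exchangeable, in every donor: per-domain
    biological jitter and donor-interaction variability are both off.
    """
    lib = make_default_library(40, 0, 0, seed=seed, jitter=0.0)
    design = _null_design()
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        art = simulate_screen(lib, design, rng, donor_variability=0.0)
        metrics = screen_metrics(art)
        hits = score_screen(metrics)
    return hits.table["p"].to_numpy(), hits.table["q"].to_numpy()


def null_calibration(seed: int, n_screens: int = 200) -> dict:
    """False-discovery control and p-value uniformity under the global null."""
    ps, qs = [], []
    for s in _spawn_seeds(seed, n_screens):
        p, q = null_screen_qvalues(s)
        ps.append(p)
        qs.append(q)
    p = np.concatenate(ps)
    q = np.concatenate(qs)
    frac = float(np.mean(q < 0.05))
    n = q.size
    ci_low, ci_high = sps.binom.interval(0.95, n, max(frac, 1e-12))
    ks_stat, ks_p = sps.kstest(p, "uniform")
    return {
        "q05_fraction": frac,
        "q05_ci_low": float(ci_low / n),
        "q05_ci_high": float(ci_high / n),
        "ks_p": float(ks_p),
        "n_domains_total": int(n),
        "n_screens": n_screens,
    }


# --------------------------------------------------------------------------
# Expansion recovery
# --------------------------------------------------------------------------


def _uniform_fitness_library(n: int, focal_fitness: float, seed: int) -> list:
    """All-identical library except one focal construct with given fitness."""
    lib = make_default_library(n, 0, 0, seed=seed, jitter=0.0)
    out = []
    for i, t in enumerate(lib):
        f = focal_fitness if i == 0 else 1.0
        d = t.to_dict()
        d["fitness"] = {s: {c: f for c in pc} for s, pc in t.fitness.items()}
        out.append(DomainTruth.from_dict(d))
    return out


def expansion_recovery(
    seed: int,
    focal_fitness: float = 1.1,
    n_rounds: int = 8,
    n_replicates: int = 3,
    n_domains: int = 40,
) -> dict:
    """Recover the closed-form log2 fold-change of a single fitter construct.

    The focal construct grows at ``focal_fitness`` per round against a
    neutral background; after ``n_rounds`` the closed-form library-relative
    log2FC is ~ n_rounds * log2(focal_fitness).  Counts are multinomial cell
    samples of the trajectory.  The SE pools the across-replicate variance
    over all constructs (every construct shares the same noise model), which
    makes the 2-SE comparison well calibrated at 3 replicates.
    """
    rng = np.random.default_rng(seed)
    lib = _uniform_fitness_library(n_domains, focal_fitness, seed)
    design = ScreenDesign(
        donors=("d1",), replicates=n_replicates, timepoints=(0, n_rounds),
        cells_per_sample=100_000,
    )
    rows = []
    for rep in range(1, n_replicates + 1):
        traj = simulate_expansion(lib, design, rng, subset="CD8", condition="antigen+")
        for t in design.timepoints:
            for i, name in enumerate(traj.names):
                rows.append((name, "d1", rep, "CD8", "antigen+", t,
                             int(traj.cell_counts[t][i])))
    tidy = pd.DataFrame(rows, columns=["construct", "donor", "replicate",
                                       "subset", "condition", "timepoint", "count"])
    res = relative_expansion(tidy)
    focal = lib[0].name
    per = res.per_replicate.query("timepoint == @n_rounds")
    mean = per.loc[per.construct == focal, "rel_log2fc"].mean()
    pooled_var = per.groupby("construct")["rel_log2fc"].var(ddof=1).mean()
    se = math.sqrt(pooled_var / n_replicates)
    closed_form = n_rounds * math.log2(focal_fitness)
    return {
        "mean_rel_log2fc": float(mean),
        "se": float(se),
        "closed_form": closed_form,
        "within_2se": bool(abs(mean - closed_form) <= 2 * se),
        "n_replicates": n_replicates,
    }


def fitness_ordering(seed: int, n_series: int = 6) -> dict:
    """Spearman correlation of true fitness with mean relative log2FC.

    Default 40-domain library over the default 8-round horizon, abundance
    measured as multinomial cell counts of the trajectory (the expansion
    module's input contract), averaged over ``n_series`` replicate cultures.
    """
    rng = np.random.default_rng(seed)
    lib = make_default_library(40, 8, 2, seed=seed)
    design = ScreenDesign(timepoints=(0, 8))
    rows = []
    for rep in range(1, n_series + 1):
        traj = simulate_expansion(lib, design, rng, subset="CD8", condition="antigen+")
        for t in design.timepoints:
            for i, name in enumerate(traj.names):
                rows.append((name, "d1", rep, "CD8", "antigen+", t,
                             int(traj.cell_counts[t][i])))
    tidy = pd.DataFrame(rows, columns=["construct", "donor", "replicate",
                                       "subset", "condition", "timepoint", "count"])
    res = relative_expansion(tidy)
    mean_lfc = (
        res.per_replicate.query("timepoint == 8")
        .groupby("construct")["rel_log2fc"].mean()
    )
    true_fit = pd.Series({t.name: t.fitness["CD8"]["antigen+"] for t in lib})
    rho, _ = sps.spearmanr(true_fit, mean_lfc.reindex(true_fit.index))
    return {"spearman": float(rho), "n_series": n_series}
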