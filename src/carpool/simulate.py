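"""Ground-truth simulator for a pooled CAR signaling-domain screen.

The simulator emulates the experiment end to end: a pooled library of CAR
constructs distinguished by short intracellular-domain (ICD) amplicons is
expressed in CD4/CD8 T cells from several donors, stimulated every three days
with antigen-positive or antigen-negative tumor cells, and read out by

* CTV dye dilution (per-cell fluorescence halves at each division),
* lognormal cytokine (IL-2, IFN-gamma) and CD69 activation channels,
* relative library abundance over serial stimulations (per-round
  multiplicative fitness), and
* bin sorting followed by overdispersed (Dirichlet-multinomial) amplicon
  sequencing of each bin.

Every phenotype is phenomenological: latent parameters live in
:class:`DomainTruth` and every downstream estimator can be checked against
them.  All randomness flows through an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as sps

from .bins import BinLayout
from .util import hamming, random_dna

D_MAX = 8  # CTV resolution limit: deeper generations are unresolvable
DIVISIONS_PER_ROUND = 3  # a 3-day stimulation round allows up to 3 divisions

SUBSETS = ("CD4", "CD8")
CONDITIONS = ("antigen+", "antigen-")
CYTOKINE_CHANNELS = ("IL2", "IFNG")

# Per-cell fluorescence building blocks (natural-log units).
_CYT_BASE_LN = 5.3  # unstimulated cytokine-channel background, ~200 a.u.
_CYT_SD_LN = 0.7
_CD69_POS_LN_MEAN, _CD69_POS_LN_SD = 7.6, 0.5  # CD69+ cells, ~2000 a.u.
_CD69_NEG_LN_MEAN, _CD69_NEG_LN_SD = 5.0, 0.5  # CD69- cells, ~150 a.u.

_ICD_LENGTH = 30
_MIN_ICD_HAMMING = 5

DEFAULT_ADAPTER = "ACACGACGCTCTTCCGATCT"


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DomainTruth:
    """Latent ground-truth phenotype parameters for one library member.

    ``division_profile_*`` are probability vectors over divisions
    d in {0..D_MAX} accrued in one stimulation round (the same profile is
    applied at every round).  ``cytokine_log_mean``/``_sd`` are natural-log
    fluorescence parameters per channel and antigen state.  ``fitness`` is the
    per-round multiplicative growth factor per T-cell subset and antigen
    state.  ``tonic_level`` in [0, 1] moves the basal (antigen-negative)
    phenotypes toward the activated ones, emulating antigen-independent
    signaling.
    """

    name: str
    icd_sequence: str
    division_profile_antigen: tuple[float, ...]
    division_profile_basal: tuple[float, ...]
    cytokine_log_mean: dict
    cytokine_log_sd: dict
    activation_prob: dict
    fitness: dict
    tonic_level: float
    phenotype_class: str = "neutral"

    def __post_init__(self):
        for label, prof in (
            ("division_profile_antigen", self.division_profile_antigen),
            ("division_profile_basal", self.division_profile_basal),
        ):
            prof = tuple(float(p) for p in prof)
            object.__setattr__(self, label.split(".")[-1], prof)
            arr = np.asarray(prof)
            if arr.min() < 0 or abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError(f"{label} must be a probability vector")
            if len(arr) != D_MAX + 1:
                raise ValueError(f"{label} must have length {D_MAX + 1}")
        if set(self.icd_sequence) - set("ACGT"):
            raise ValueError("icd_sequence alphabet must be within ACGT")
        for subset, per_cond in self.fitness.items():
            for cond, f in per_cond.items():
                if f <= 0:
                    raise ValueError(f"fitness[{subset}][{cond}] must be > 0")
        for ch, per_cond in self.cytokine_log_sd.items():
            for cond, sd in per_cond.items():
                if sd <= 0:
                    raise ValueError(f"cytokine_log_sd[{ch}][{cond}] must be > 0")
        for cond, p in self.activation_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"activation_prob[{cond}] must be in [0, 1]")
        if self.tonic_level < 0:
            raise ValueError("tonic_level must be >= 0")

    def division_profile(self, condition: str) -> np.ndarray:
        if condition == "antigen+":
            return np.asarray(self.division_profile_antigen)
        return np.asarray(self.division_profile_basal)

    def mean_divisions(self, condition: str) -> float:
        prof = self.division_profile(condition)
        return float(np.arange(D_MAX + 1) @ prof)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DomainTruth":
        d = dict(d)
        d["division_profile_antigen"] = tuple(d["division_profile_antigen"])
        d["division_profile_basal"] = tuple(d["division_profile_basal"])
        return cls(**d)


@dataclass(frozen=True)
class ScreenDesign:
    """Shape and noise settings of one pooled screen."""

    donors: tuple[str, ...] = ("donor1", "donor2")
    replicates: int = 3
    subsets: tuple[str, ...] = SUBSETS
    timepoints: tuple[int, ...] = (0, 1, 6, 8)  # stimulation-round indices
    conditions: tuple[str, ...] = CONDITIONS
    cells_per_sample: int = 100_000
    read_depth: int = 1_000_000
    mfi0: float = 1e4  # undivided-cell CTV fluorescence, a.u.
    sigma_log: float = 0.15  # per-cell natural-log fluorescence noise SD
    dirichlet_mass: float = 200.0  # amplicon overdispersion (conc. mass)
    sigma_fit: float = 0.05  # per-round log-fitness noise SD
    baseline_jitter_sd: float = 0.05  # lognormal pooling error at baseline
    seed: int = 0

    def __post_init__(self):
        if 0 not in self.timepoints:
            raise ValueError("ScreenDesign.timepoints must include baseline round 0")
        for name in ("replicates", "cells_per_sample", "read_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ScreenDesign.{name} must be positive")
        if self.mfi0 <= 0:
            raise ValueError("ScreenDesign.mfi0 must be positive")
        object.__setattr__(self, "donors", tuple(self.donors))
        object.__setattr__(self, "subsets", tuple(self.subsets))
        object.__setattr__(self, "timepoints", tuple(int(t) for t in self.timepoints))
        object.__setattr__(self, "conditions", tuple(self.conditions))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenDesign":
        return cls(**d)


@dataclass
class CellSample:
    """Per-cell records for one construct: division count and fluorescence."""

    name: str
    divisions: np.ndarray  # int, 0..D_MAX
    fluorescence: dict  # channel -> positive float array

    def __post_init__(self):
        d = np.asarray(self.divisions)
        if d.size and (d.min() < 0 or d.max() > D_MAX):
            raise ValueError("divisions must lie in [0, D_MAX]")
        for ch, f in self.fluorescence.items():
            f = np.asarray(f, dtype=float)
            if f.size and f.min() <= 0:
                raise ValueError(f"fluorescence[{ch}] must be positive")
            self.fluorescence[ch] = f

    @property
    def n_cells(self) -> int:
        return int(np.asarray(self.divisions).size)


@dataclass
class TrueAbundanceTrajectory:
    """Ground-truth library composition over stimulation rounds."""

    names: list
    frequencies: np.ndarray  # constructs x (rounds+1), columns sum to 1
    cell_counts: dict  # timepoint -> integer vector over constructs

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        if f.min() < -1e-12:
            raise ValueError("frequencies must be nonnegative")
        if not np.allclose(f.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("per-round frequencies must sum to 1")
        self.frequencies = f


# --------------------------------------------------------------------------
# Library construction
# --------------------------------------------------------------------------


def _binomial_profile(p: float) -> tuple[float, ...]:
    """Division profile for one 3-day round: Binomial(3, p) over d=0..D_MAX."""
    pmf = np.zeros(D_MAX + 1)
    ks = np.arange(DIVISIONS_PER_ROUND + 1)
    pmf[: DIVISIONS_PER_ROUND + 1] = sps.binom.pmf(ks, DIVISIONS_PER_ROUND, p)
    pmf /= pmf.sum()
    return tuple(float(x) for x in pmf)


# Phenotype-class parameter anchors.  Means are the study conditions; the *_sd
# and (lo, hi) entries are per-domain biological variability, scaled by the
# ``jitter`` argument of make_default_library (jitter=0 gives an all-identical
# null library).
_CLASS_PARAMS = {
    "potent": dict(
        p_div=0.65, p_div_sd=0.04, cyt_lift=2.2, cyt_lift_sd=0.25,
        act=0.82, act_sd=0.05, ln_fit=math.log(1.18), ln_fit_sd=0.03,
        tonic=(0.15, 0.40),
    ),
    "neutral": dict(
        p_div=0.40, p_div_sd=0.05, cyt_lift=1.2, cyt_lift_sd=0.30,
        act=0.52, act_sd=0.08, ln_fit=0.0, ln_fit_sd=0.04,
        tonic=(0.05, 0.30),
    ),
    "inhibitory": dict(
        p_div=0.25, p_div_sd=0.03, cyt_lift=0.4, cyt_lift_sd=0.15,
        act=0.22, act_sd=0.05, ln_fit=math.log(0.88), ln_fit_sd=0.03,
        tonic=(0.00, 0.10),
    ),
}

_P_DIV_CLIP = (0.22, 0.80)
_P_DIV_BASAL_FLOOR = 0.08
_ACT_BASAL_FLOOR = 0.05
_CD8_LN_FITNESS_SHIFT = 0.03  # most domains expand slightly more in CD8
_CD8_LN_FITNESS_SD = 0.03
_BASAL_FITNESS_DAMPING = 0.6  # antigen-free growth is tonic-driven and weaker


def _make_truth(name: str, cls: str, rng: np.random.Generator, jitter: float) -> DomainTruth:
    par = _CLASS_PARAMS[cls]
    p_div = float(np.clip(par["p_div"] + jitter * par["p_div_sd"] * rng.standard_normal(), *_P_DIV_CLIP))
    tonic_lo, tonic_hi = par["tonic"]
    tonic = float(tonic_lo + (tonic_hi - tonic_lo) * (rng.uniform() if jitter > 0 else 0.5))
    p_div_basal = _P_DIV_BASAL_FLOOR + tonic * (p_div - _P_DIV_BASAL_FLOOR)

    lift = par["cyt_lift"] + jitter * par["cyt_lift_sd"] * rng.standard_normal()
    cyt_mean, cyt_sd = {}, {}
    for ch in CYTOKINE_CHANNELS:
        ch_lift = max(0.0, lift + jitter * 0.10 * rng.standard_normal())
        cyt_mean[ch] = {
            "antigen+": _CYT_BASE_LN + ch_lift,
            "antigen-": _CYT_BASE_LN + tonic * ch_lift,
        }
        cyt_sd[ch] = {"antigen+": _CYT_SD_LN, "antigen-": _CYT_SD_LN}

    act = float(np.clip(par["act"] + jitter * par["act_sd"] * rng.standard_normal(), 0.02, 0.98))
    activation = {
        "antigen+": act,
        "antigen-": _ACT_BASAL_FLOOR + tonic * (act - _ACT_BASAL_FLOOR),
    }

    ln_fit = par["ln_fit"] + jitter * par["ln_fit_sd"] * rng.standard_normal()
    cd8_shift = _CD8_LN_FITNESS_SHIFT + jitter * _CD8_LN_FITNESS_SD * rng.standard_normal()
    fitness = {}
    for subset in SUBSETS:
        ln_sub = ln_fit + (cd8_shift if subset == "CD8" else 0.0)
        fitness[subset] = {
            "antigen+": math.exp(ln_sub),
            "antigen-": math.exp(_BASAL_FITNESS_DAMPING * tonic * ln_sub),
        }

    return DomainTruth(
        name=name,
        icd_sequence="",  # filled by make_default_library
        division_profile_antigen=_binomial_profile(p_div),
        division_profile_basal=_binomial_profile(p_div_basal),
        cytokine_log_mean=cyt_mean,
        cytokine_log_sd=cyt_sd,
        activation_prob=activation,
        fitness=fitness,
        tonic_level=tonic,
        phenotype_class=cls,
    )


def _distinct_sequences(rng: np.random.Generator, n: int) -> list[str]:
    seqs: list[str] = []
    while len(seqs) < n:
        cand = random_dna(rng, _ICD_LENGTH)
        if all(hamming(cand, s) >= _MIN_ICD_HAMMING for s in seqs):
            seqs.append(cand)
    return seqs


def make_default_library(
    n_domains: int = 40,
    n_potent: int = 8,
    n_inhibitory: int = 2,
    seed: int = 0,
    jitter: float = 1.0,
) -> list[DomainTruth]:
    """Build a seeded ground-truth library.

    ``n_potent`` members get elevated division/fitness/cytokine/activation
    parameters, ``n_inhibitory`` get suppressed ones, and the remainder are
    intermediate.  ICD amplicons are random 30-mers at pairwise Hamming
    distance >= 5.  ``jitter`` scales per-domain biological variability;
    ``jitter=0`` yields an all-identical (null) library.
    """
    if n_domains < 1 or n_potent < 0 or n_inhibitory < 0:
        raise ValueError("library counts must be nonnegative, n_domains >= 1")
    if n_potent + n_inhibitory > n_domains:
        raise ValueError("n_potent + n_inhibitory must not exceed n_domains")
    rng = np.random.default_rng(seed)
    classes = (
        ["potent"] * n_potent
        + ["inhibitory"] * n_inhibitory
        + ["neutral"] * (n_domains - n_potent - n_inhibitory)
    )
    order = rng.permutation(n_domains)
    classes = [classes[i] for i in order]
    seqs = _distinct_sequences(rng, n_domains)
    width = max(2, len(str(n_domains)))
    truths = []
    for i, cls in enumerate(classes):
        t = _make_truth(f"ICD{i + 1:0{width}d}", cls, rng, jitter)
        truths.append(DomainTruth.from_dict({**t.to_dict(), "icd_sequence": seqs[i]}))
    return truths


# --------------------------------------------------------------------------
# Generative operations
# --------------------------------------------------------------------------


def draw_cells(
    truth: DomainTruth,
    design: ScreenDesign,
    condition: str,
    round_index: int,
    rng: np.random.Generator,
    n_cells: int | None = None,
    channels: tuple[str, ...] | None = None,
) -> CellSample:
    """Draw per-cell division counts and channel fluorescence for one construct.

    CTV fluorescence is ``mfi0 * 2**-d * exp(eps)`` with
    ``eps ~ Normal(0, sigma_log^2)``; cytokine channels are lognormal with the
    truth's parameters; CD69 is a two-component lognormal mixture with mixing
    weight ``activation_prob``.  ``channels`` restricts which channels are
    materialized (all by default).
    """
    if condition not in design.conditions:
        raise ValueError(f"unknown condition {condition!r}; design has {design.conditions}")
    if round_index < 0:
        raise ValueError("round_index must be >= 0")
    n = design.cells_per_sample if n_cells is None else int(n_cells)
    profile = truth.division_profile(condition)
    counts = rng.multinomial(n, profile)
    d = np.repeat(np.arange(D_MAX + 1), counts)
    rng.shuffle(d)

    wanted = channels if channels is not None else ("CTV", *CYTOKINE_CHANNELS, "CD69")
    fluor: dict[str, np.ndarray] = {}
    if "CTV" in wanted:
        eps = design.sigma_log * rng.standard_normal(n) if design.sigma_log > 0 else 0.0
        fluor["CTV"] = design.mfi0 * np.exp2(-d.astype(float)) * np.exp(eps)
    for ch in CYTOKINE_CHANNELS:
        if ch in wanted:
            mu = truth.cytokine_log_mean[ch][condition]
            sd = truth.cytokine_log_sd[ch][condition]
            fluor[ch] = np.exp(mu + sd * rng.standard_normal(n))
    if "CD69" in wanted:
        pos = rng.uniform(size=n) < truth.activation_prob[condition]
        ln = np.where(
            pos,
            _CD69_POS_LN_MEAN + _CD69_POS_LN_SD * rng.standard_normal(n),
            _CD69_NEG_LN_MEAN + _CD69_NEG_LN_SD * rng.standard_normal(n),
        )
        fluor["CD69"] = np.exp(ln)
    return CellSample(name=truth.name, divisions=d, fluorescence=fluor)


def simulate_expansion(
    truths: list[DomainTruth],
    design: ScreenDesign,
    rng: np.random.Generator,
    subset: str = "CD8",
    condition: str = "antigen+",
) -> TrueAbundanceTrajectory:
    """Propagate library frequencies over serial stimulation rounds.

    Baseline is equimolar pooling with small lognormal jitter
    (``baseline_jitter_sd``).  Each round multiplies frequencies by the
    construct's fitness times ``exp(eta)``, ``eta ~ Normal(0, sigma_fit^2)``,
    then renormalizes.  Sampled cell counts at each design timepoint are
    multinomial at ``cells_per_sample``.
    """
    n = len(truths)
    fit = np.array([t.fitness[subset][condition] for t in truths])
    n_rounds = max(design.timepoints)
    freq = np.empty((n, n_rounds + 1))
    f0 = np.ones(n) / n
    if design.baseline_jitter_sd > 0:
        f0 = f0 * np.exp(design.baseline_jitter_sd * rng.standard_normal(n))
        f0 /= f0.sum()
    freq[:, 0] = f0
    for r in range(1, n_rounds + 1):
        eta = (
            design.sigma_fit * rng.standard_normal(n)
            if design.sigma_fit > 0
            else np.zeros(n)
        )
        w = freq[:, r - 1] * fit * np.exp(eta)
        freq[:, r] = w / w.sum()
    cell_counts = {
        t: rng.multinomial(design.cells_per_sample, freq[:, t])
        for t in design.timepoints
    }
    return TrueAbundanceTrajectory(
        names=[t.name for t in truths], frequencies=freq, cell_counts=cell_counts
    )


@dataclass
class SortResult:
    """Per-construct, per-bin sorted-cell counts plus out-of-gate discards."""

    names: list
    counts: np.ndarray  # constructs x bins
    discarded: np.ndarray  # per construct

    @property
    def bin_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def simulate_sort(samples: list[CellSample], layout: BinLayout) -> SortResult:
    """Assign each cell to the gate containing its log10 fluorescence.

    Cells outside every gate are discarded (and counted).  Gate assignment is
    deterministic; gates are half-open [lo, hi).
    """
    n_bins = layout.n_bins
    counts = np.zeros((len(samples), n_bins), dtype=np.int64)
    discarded = np.zeros(len(samples), dtype=np.int64)
    for i, s in enumerate(samples):
        f = s.fluorescence[layout.channel]
        idx = layout.assign(np.log10(f))
        inside = idx >= 0
        discarded[i] = int((~inside).sum())
        counts[i] = np.bincount(idx[inside], minlength=n_bins)
    return SortResult(names=[s.name for s in samples], counts=counts, discarded=discarded)


def simulate_reads(
    bin_cell_counts: np.ndarray,
    read_depth: int,
    overdispersion: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Dirichlet-multinomial amplicon reads per bin.

    Per bin b, reads over constructs follow DirMult(read_depth, alpha) with
    alpha proportional to within-bin cell fractions and total concentration
    mass ``overdispersion``.  ``overdispersion=inf`` gives the plain
    multinomial limit (expected read fraction = cell fraction, no
    amplification noise).  Every nonempty bin returns exactly ``read_depth``
    reads; an empty bin yields zero reads with a warning.
    """
    if read_depth <= 0:
        raise ValueError("read_depth must be positive")
    if overdispersion <= 0:
        raise ValueError("overdispersion mass must be positive")
    cells = np.asarray(bin_cell_counts, dtype=float)
    if cells.ndim == 1:
        cells = cells[:, None]
    n, n_bins = cells.shape
    reads = np.zeros((n, n_bins), dtype=np.int64)
    for b in range(n_bins):
        total = cells[:, b].sum()
        if total == 0:
            warnings.warn(f"bin {b} is empty; emitting zero reads", stacklevel=2)
            continue
        nz = np.flatnonzero(cells[:, b])
        frac = cells[nz, b] / total
        if math.isinf(overdispersion):
            p = frac
        else:
            p = rng.dirichlet(overdispersion * frac)
        reads[nz, b] = rng.multinomial(read_depth, p)
    return reads


def emit_fastq(
    handle,
    read_counts: np.ndarray,
    truths: list[DomainTruth],
    sample_ids: list[str],
    rng: np.random.Generator,
    adapter: str = DEFAULT_ADAPTER,
    error_rate: float = 0.0,
    barcodes: dict | None = None,
    quality_char: str = "I",
) -> int:
    """Write Phred+33 FASTQ for a constructs x samples read-count matrix.

    Each record is adapter + ICD amplicon with iid per-base substitution
    errors.  When ``barcodes`` maps sample id -> (i5, i7), the pair is placed
    in the header index field (``1:N:0:I5+I7``) the way demultiplexed Illumina
    headers carry it.  Returns the number of records written.
    """
    counts = np.asarray(read_counts)
    if counts.ndim == 1:
        counts = counts[:, None]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    written = 0
    for j, sample in enumerate(sample_ids):
        index = ""
        if barcodes is not None:
            i5, i7 = barcodes[sample]
            index = f" 1:N:0:{i5}+{i7}"
        for i, truth in enumerate(truths):
            n_reads = int(counts[i, j])
            if n_reads == 0:
                continue
            template = np.frombuffer((adapter + truth.icd_sequence).encode(), dtype=np.uint8)
            L = template.size
            qual = quality_char * L
            for k in range(n_reads):
                seq = template
                if error_rate > 0:
                    hit = rng.uniform(size=L) < error_rate
                    if hit.any():
                        seq = template.copy()
                        # substitute with a uniformly different base
                        repl = bases[(np.searchsorted(bases, seq[hit]) + rng.integers(1, 4, size=int(hit.sum()))) % 4]
                        seq[hit] = repl
                handle.write(
                    f"@{sample}:{truth.name}:{written}{index}\n{seq.tobytes().decode()}\n+\n{qual}\n"
                )
                written += 1
    return written


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------


def cells_to_tsv(handle, samples: list[CellSample]) -> None:
    """Write cell-level records (construct, cell_id, divisions, channels)."""
    channels = sorted({ch for s in samples for ch in s.fluorescence})
    handle.write("construct\tcell_id\tdivisions\t" + "\t".join(channels) + "\n")
    for s in samples:
        for j in range(s.n_cells):
            vals = "\t".join(
                f"{s.fluorescence[ch][j]:.6g}" if ch in s.fluorescence else ""
                for ch in channels
            )
            handle.write(f"{s.name}\t{j}\t{int(s.divisions[j])}\t{vals}\n")


def library_to_json(truths: list[DomainTruth]) -> str:
    return json.dumps([t.to_dict() for t in truths], sort_keys=True, indent=1)


def library_from_json(text: str) -> list[DomainTruth]:
    return [DomainTruth.from_dict(d) for d in json.loads(text)]
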