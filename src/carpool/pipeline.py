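"""Config-driven orchestration of the screen pipeline.

Stages (each runnable independently on the previous stage's on-disk outputs):

* ``simulate`` — ground-truth library + raw screen artifacts (bin-sorted
  amplicon counts, per-bin sorted-cell totals, abundance counts; optionally
  FASTQ).
* ``count``    — FASTQ -> count tables (real-data mode, or simulated FASTQ).
* ``quantify`` — FlowSeq phenotype estimation -> tidy metric table.
* ``expand``   — relative expansion, CD8-vs-CD4 Wald test, trend slopes.
* ``score``    — z-score / Stouffer / BH hit table, clustering, PCA.
* ``report``   — per-stage record accounting as JSON.

All outputs are plain TSV/JSON with stable ordering, so a fixed config+seed
reproduces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bins import BinLayout
from .counting import ReferenceSet, SampleSheet, count_fastq
from .expansion import cd8_cd4_ratio_test, expansion_trend, relative_expansion
from .scoring import score_screen
from .screen import (
    FLOWSEQ_ASSAYS,
    ScreenArtifacts,
    default_layouts,
    expansion_metrics,
    quantify_screen,
    simulate_screen,
    true_mean_divisions,
)
from .simulate import (
    DEFAULT_ADAPTER,
    ScreenDesign,
    emit_fastq,
    library_from_json,
    library_to_json,
    make_default_library,
)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending field."""


DESIGN_FIELDS = {
    "donors", "replicates", "subsets", "timepoints", "conditions",
    "cells_per_sample", "read_depth", "mfi0", "sigma_log", "dirichlet_mass",
    "sigma_fit", "baseline_jitter_sd", "seed",
}

ESTIMATOR_DEFAULTS = {
    "min_cells": 500,
    "pseudocount": 0.5,
    "max_mismatch": 2,
    "max_bc_mismatch": 1,
    "linkage": "average",
    "cut_height": None,
    "alpha": 0.05,
}

LIBRARY_DEFAULTS = {"n_domains": 40, "n_potent": 8, "n_inhibitory": 2, "jitter": 1.0}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config file must contain a mapping")
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    mode = cfg.get("mode")
    if mode not in ("simulate", "real"):
        raise ConfigError("field 'mode' must be 'simulate' or 'real'")
    if "outdir" not in cfg:
        raise ConfigError("field 'outdir' is required")
    if mode == "simulate":
        if cfg.get("seed") is None:
            raise ConfigError("field 'seed' is mandatory in simulate mode")
        design = cfg.get("design", {})
        unknown = set(design) - DESIGN_FIELDS
        if unknown:
            raise ConfigError(f"unknown design field(s) {sorted(unknown)}")
    else:
        real = cfg.get("real", {})
        for key in ("fastq", "reference", "samplesheet"):
            if key not in real:
                raise ConfigError(f"field 'real.{key}' is required in real mode")
            paths = real[key] if isinstance(real[key], list) else [real[key]]
            for p in paths:
                if not Path(p).exists():
                    raise ConfigError(f"real.{key}: file {p} does not exist")
    est = {**ESTIMATOR_DEFAULTS, **cfg.get("estimator", {})}
    unknown = set(est) - set(ESTIMATOR_DEFAULTS)
    if unknown:
        raise ConfigError(f"unknown estimator field(s) {sorted(unknown)}")
    cfg["estimator"] = est
    cfg["library"] = {**LIBRARY_DEFAULTS, **cfg.get("library", {})}
    return cfg


def config_hash(cfg: dict) -> str:
    """Hash of the scientific configuration (output location excluded)."""
    stable = {k: v for k, v in cfg.items() if k != "outdir"}
    return hashlib.sha256(
        json.dumps(stable, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def _design_from_config(cfg: dict) -> ScreenDesign:
    block = dict(cfg.get("design", {}))
    block.setdefault("seed", cfg["seed"])
    try:
        return ScreenDesign(**block)
    except TypeError as exc:
        raise ConfigError(f"design: {exc}") from exc


class RunReport:
    """Per-stage record accounting, serialized to report.json."""

    def __init__(self, cfg: dict, seed):
        self.data = {
            "version": __version__,
            "config_hash": config_hash(cfg),
            "seed": seed,
            "stages": {},
            "warnings": [],
        }

    def stage(self, name: str, **counts) -> None:
        self.data["stages"][name] = counts

    def warn(self, msg: str) -> None:
        logger.warning(msg)
        self.data["warnings"].append(msg)

    def write(self, outdir: Path) -> None:
        (outdir / "report.json").write_text(
            json.dumps(self.data, sort_keys=True, indent=1) + "\n"
        )

    @classmethod
    def load(cls, outdir: Path) -> dict:
        return json.loads((outdir / "report.json").read_text())


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------


def stage_simulate(cfg: dict, outdir: Path, report: RunReport) -> ScreenArtifacts:
    lib_cfg = cfg["library"]
    seed = int(cfg["seed"])
    truths = make_default_library(
        n_domains=lib_cfg["n_domains"],
        n_potent=lib_cfg["n_potent"],
        n_inhibitory=lib_cfg["n_inhibitory"],
        seed=seed,
        jitter=lib_cfg["jitter"],
    )
    design = _design_from_config(cfg)
    rng = np.random.default_rng(seed)
    art = simulate_screen(truths, design, rng)

    (outdir / "truths.json").write_text(library_to_json(truths) + "\n")
    (outdir / "design.json").write_text(
        json.dumps(design.to_dict(), sort_keys=True, indent=1) + "\n"
    )
    (outdir / "layouts.json").write_text(
        json.dumps(
            {k: v.to_dict() for k, v in art.layouts.items()}, sort_keys=True, indent=1
        )
        + "\n"
    )
    _write_tsv(art.flowseq_counts, outdir / "flowseq_counts.tsv")
    _write_tsv(art.bin_cells, outdir / "bin_cells.tsv")
    _write_tsv(art.abundance, outdir / "abundance.tsv")
    _write_tsv(
        true_mean_divisions(art).rename_axis("domain").reset_index(),
        outdir / "true_mean_divisions.tsv",
    )
    if cfg.get("emit_fastq"):
        _emit_simulated_fastq(cfg, art, outdir, rng)
    report.stage(
        "simulate",
        domains=len(truths),
        flowseq_rows=len(art.flowseq_counts),
        abundance_rows=len(art.abundance),
    )
    return art


def _emit_simulated_fastq(cfg, art: ScreenArtifacts, outdir: Path, rng) -> None:
    """Small FASTQ emission for exercising the counting stage end to end."""
    depth = int(cfg.get("fastq_depth", 2000))
    error_rate = float(cfg.get("fastq_error_rate", 0.0))
    fastq_dir = outdir / "fastq"
    fastq_dir.mkdir(exist_ok=True)
    # one FASTQ per flowseq sample-bin, resampled at reduced depth
    rows = []
    with open(fastq_dir / "screen.fastq", "w") as fh:
        for keys, grp in art.flowseq_counts.groupby(
            ["assay", "donor", "replicate", "subset", "condition", "bin_id"], sort=True
        ):
            sample_id = "_".join(str(k) for k in keys)
            counts = grp.set_index("construct")["reads"]
            total = counts.sum()
            if total == 0:
                continue
            sub = rng.multinomial(depth, counts.to_numpy() / total)
            order = {t.name: t for t in art.truths}
            truths = [order[c] for c in counts.index]
            emit_fastq(
                fh,
                sub[:, None],
                truths,
                [sample_id],
                rng,
                adapter=DEFAULT_ADAPTER,
                error_rate=error_rate,
            )
            rows.append((sample_id, *keys))
    pd.DataFrame(
        rows,
        columns=["sample_id", "assay", "donor", "replicate", "subset", "condition", "bin_id"],
    ).to_csv(fastq_dir / "samples.tsv", sep="\t", index=False)


def _load_artifacts(cfg: dict, outdir: Path) -> ScreenArtifacts:
    design = ScreenDesign.from_dict(
        json.loads((outdir / "design.json").read_text())
    )
    layouts = {
        k: BinLayout.from_dict(v)
        for k, v in json.loads((outdir / "layouts.json").read_text()).items()
    }
    truths = library_from_json((outdir / "truths.json").read_text())
    return ScreenArtifacts(
        flowseq_counts=pd.read_csv(outdir / "flowseq_counts.tsv", sep="\t"),
        bin_cells=pd.read_csv(outdir / "bin_cells.tsv", sep="\t"),
        abundance=pd.read_csv(outdir / "abundance.tsv", sep="\t"),
        truths=truths,
        design=design,
        layouts=layouts,
    )


def stage_count(cfg: dict, outdir: Path, report: RunReport) -> None:
    """FASTQ -> count table (real mode, or simulated FASTQ when present)."""
    est = cfg["estimator"]
    if cfg["mode"] == "real":
        real = cfg["real"]
        refs = ReferenceSet.from_fasta(
            real["reference"], adapter=real.get("adapter", "")
        )
        sheet = SampleSheet.from_tsv(real["samplesheet"])
        fastq = real["fastq"]
    else:
        fastq_dir = outdir / "fastq"
        if not fastq_dir.exists():
            report.warn("count: no FASTQ present (emit_fastq not set); skipped")
            return
        truths = library_from_json((outdir / "truths.json").read_text())
        refs = ReferenceSet(
            sequences={t.name: t.icd_sequence for t in truths},
            adapter=DEFAULT_ADAPTER,
        )
        samples = pd.read_csv(fastq_dir / "samples.tsv", sep="\t")
        sheet_df = samples.assign(
            i5=[f"BC{i:04d}" for i in range(len(samples))],
            i7=[f"BC{i:04d}" for i in range(len(samples))],
            timepoint=1,
            cells_sorted=np.nan,
        )[["sample_id", "i5", "i7", "donor", "replicate", "subset", "assay",
           "timepoint", "bin_id", "cells_sorted"]]
        sheet = SampleSheet(sheet_df)
        fastq = [fastq_dir / "screen.fastq"]
        # simulated headers carry no index pair: route by read-name prefix
        ct = _count_by_read_name(fastq, refs, sheet, est)
        ct.to_tsv(outdir / "count_table.tsv")
        (outdir / "count_report.json").write_text(
            json.dumps(ct.report, sort_keys=True, indent=1) + "\n"
        )
        report.stage("count", **{
            "reads_in": ct.report["reads_in_total"],
            "assigned": int(ct.assigned().to_numpy().sum()),
        })
        return
    ct = count_fastq(
        fastq, refs, sheet,
        max_mismatch=est["max_mismatch"],
        max_bc_mismatch=est["max_bc_mismatch"],
    )
    ct.to_tsv(outdir / "count_table.tsv")
    (outdir / "count_report.json").write_text(
        json.dumps(ct.report, sort_keys=True, indent=1) + "\n"
    )
    report.stage("count", **{
        "reads_in": ct.report["reads_in_total"],
        "assigned": int(ct.assigned().to_numpy().sum()),
    })


def _count_by_read_name(fastq_paths, refs, sheet, est):
    """Count simulated FASTQ whose read names encode the sample id."""
    from .counting import CountTable, build_count_table, parse_fastq, trim_adapter, assign_read

    assignments = {sid: [] for sid in sheet.sample_ids}
    total = 0
    for p in fastq_paths:
        for read_id, _, seq in parse_fastq(p):
            total += 1
            sid = read_id.rsplit(":", 2)[0]
            payload, _ = trim_adapter(seq, refs.adapter, est["max_mismatch"])
            name = (
                assign_read(payload, refs, est["max_mismatch"])
                if payload is not None
                else None
            )
            assignments.setdefault(sid, []).append((name, seq))
    ct = build_count_table(assignments, sheet)
    ct.report = {"reads_in_total": total, "samples": {}}
    return ct


def stage_quantify(cfg: dict, outdir: Path, report: RunReport) -> pd.DataFrame:
    art = _load_artifacts(cfg, outdir)
    est = cfg["estimator"]
    metrics = quantify_screen(art, min_cells=est["min_cells"])
    _write_tsv(metrics, outdir / "phenotype_metrics.tsv")
    report.stage(
        "quantify",
        rows=len(metrics),
        filtered=int(metrics["filtered"].sum()),
    )
    return metrics


def stage_expand(cfg: dict, outdir: Path, report: RunReport) -> pd.DataFrame:
    art = _load_artifacts(cfg, outdir)
    est = cfg["estimator"]
    result, exp_rows = expansion_metrics(art, pseudocount=est["pseudocount"])
    _write_tsv(result.per_replicate, outdir / "expansion_per_replicate.tsv")
    _write_tsv(result.summary, outdir / "expansion_summary.tsv")
    final_tp = max(art.design.timepoints)
    if {"CD4", "CD8"} <= set(art.design.subsets) and art.design.replicates >= 2:
        wald = cd8_cd4_ratio_test(result.per_replicate, timepoint=final_tp)
        _write_tsv(wald, outdir / "cd8_cd4_wald.tsv")
    if len(art.design.timepoints) >= 3:
        trend = expansion_trend(result.per_replicate)
        _write_tsv(trend, outdir / "expansion_trend.tsv")
    _write_tsv(exp_rows, outdir / "expansion_metric_rows.tsv")
    report.stage("expand", rows=len(result.per_replicate), notes=len(result.notes))
    return exp_rows


def stage_score(cfg: dict, outdir: Path, report: RunReport) -> None:
    est = cfg["estimator"]
    metrics = pd.read_csv(outdir / "phenotype_metrics.tsv", sep="\t")
    exp_rows = pd.read_csv(outdir / "expansion_metric_rows.tsv", sep="\t")
    allm = pd.concat([metrics, exp_rows], ignore_index=True)
    hits = score_screen(
        allm,
        alpha=est["alpha"],
        linkage_method=est["linkage"],
        cut_height=est["cut_height"],
    )
    _write_tsv(hits.table.reset_index(), outdir / "hit_table.tsv")
    _write_tsv(
        hits.assay_matrix.combined.rename_axis("domain").reset_index(),
        outdir / "combined_z.tsv",
    )
    _write_tsv(hits.assay_matrix.normality, outdir / "normality_checks.tsv")
    if hits.clusters is not None:
        (outdir / "dendrogram.nwk").write_text(hits.clusters.newick + "\n")
    report.stage(
        "score",
        domains=len(hits.table),
        significant=int(hits.table["significant"].sum()),
    )


STAGES = ("simulate", "count", "quantify", "expand", "score", "report")


def run(cfg: dict, stages=("all",)) -> Path:
    """Execute pipeline stages; returns the output directory."""
    cfg = validate_config(dict(cfg))
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    wanted = list(STAGES) if "all" in stages else list(stages)
    report = RunReport(cfg, cfg.get("seed"))
    if (outdir / "report.json").exists() and "simulate" not in wanted:
        report.data = RunReport.load(outdir)
    for stage in wanted:
        if stage == "simulate":
            if cfg["mode"] != "simulate":
                report.warn("simulate stage skipped in real mode")
                continue
            stage_simulate(cfg, outdir, report)
        elif stage == "count":
            stage_count(cfg, outdir, report)
        elif stage == "quantify":
            stage_quantify(cfg, outdir, report)
        elif stage == "expand":
            stage_expand(cfg, outdir, report)
        elif stage == "score":
            stage_score(cfg, outdir, report)
        elif stage == "report":
            pass
        else:
            raise ConfigError(f"unknown stage {stage!r}")
    report.write(outdir)
    return outdir
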