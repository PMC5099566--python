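"""End-to-end orchestration: QC -> candidate screen -> stability ranking ->
relative quantification -> biomarker evaluation, driven by one YAML config,
with a machine-readable run manifest recording every parameter and exclusion.

Samples failing QC are excluded from every downstream stage. The reference
gene for quantification defaults to the comprehensive rank-1 gene from the
stability stage unless ``refs`` is given explicitly; disabling the stability
stage therefore requires explicit references.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .biomarker import adjusted_correlation, group_compare, roc_analysis
from .io import (CqMatrix, SampleAnnotation, read_annotation, read_cq_table,
                 read_intensity_table, write_report)
from .qc import filter_samples, run_qc
from .quantify import delta_delta_ct
from .screen import differential_expression, select_candidates
from .stability import ReferenceGeneStability

__all__ = ["PipelineConfig", "PipelineError", "load_pipeline_config", "run_pipeline"]

log = logging.getLogger("mirnorm.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    cq_path: str
    annotation_path: str
    out_dir: str
    intensity_path: str | None = None
    seed: int = 0
    missing_policy: str = "drop"
    qc: dict = field(default_factory=dict)         # enabled, gene_23a, gene_451a,
                                                   # hemolysis_threshold, spikein_gene,
                                                   # spikein_max_dev
    screen: dict = field(default_factory=dict)     # enabled, mode params
    stability: dict = field(default_factory=dict)  # enabled, genes, efficiency, v_threshold
    quantify: dict = field(default_factory=dict)   # enabled, targets, refs, calibrator
    biomarker: dict = field(default_factory=dict)  # enabled, control, covariates

    def stage_enabled(self, stage: str, default: bool = True) -> bool:
        return bool(getattr(self, stage).get("enabled", default))


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    inputs = raw.get("inputs", {})
    stages = raw.get("stages", {})
    return PipelineConfig(
        cq_path=inputs["cq"],
        annotation_path=inputs["annotation"],
        intensity_path=inputs.get("intensity"),
        out_dir=raw.get("out_dir", "mirnorm_out"),
        seed=int(raw.get("seed", 0)),
        missing_policy=raw.get("missing_policy", "drop"),
        qc=stages.get("qc", {}),
        screen=stages.get("screen", {}),
        stability=stages.get("stability", {}),
        quantify=stages.get("quantify", {}),
        biomarker=stages.get("biomarker", {}),
    )


def _stage(manifest: dict, name: str, status: str, params: dict | None = None,
           **info) -> None:
    entry = {"name": name, "status": status, "params": params or {}}
    entry.update(info)
    manifest["stages"].append(entry)
    log.info("stage %-10s %s %s", name, status, info or "")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages; returns (and writes) the run manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package": "mirnorm",
        "version": __version__,
        "seed": config.seed,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "inputs": {"cq": config.cq_path, "annotation": config.annotation_path,
                   "intensity": config.intensity_path},
        "stages": [],
        "qc_exclusions": [],
    }

    def fail(stage: str, exc: Exception):
        _stage(manifest, stage, "failed", notes=str(exc))
        _write_manifest(manifest, out_dir)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    cq = read_cq_table(config.cq_path, missing_policy=config.missing_policy)
    ann = read_annotation(config.annotation_path)
    qc_gene_names: set[str] = set()

    # ---- qc ----------------------------------------------------------------
    if config.stage_enabled("qc"):
        p = config.qc
        params = dict(gene_23a=p.get("gene_23a", "miR-23a-3p"),
                      gene_451a=p.get("gene_451a", "miR-451a"),
                      hemolysis_threshold=float(p.get("hemolysis_threshold", 7.0)),
                      spikein_gene=p.get("spikein_gene", "cel-miR-39"),
                      spikein_max_dev=float(p.get("spikein_max_dev", 1.5)))
        try:
            report = run_qc(cq, **params)
        except Exception as exc:
            fail("qc", exc)
        write_report(report, out_dir / "qc_report.tsv")
        excluded = report.failed_samples
        manifest["qc_exclusions"] = excluded
        n_before = len(cq.sample_ids)
        cq = filter_samples(cq, report)
        ann = ann.subset(cq.sample_ids)
        qc_gene_names = {params["gene_23a"], params["gene_451a"], params["spikein_gene"]}
        _stage(manifest, "qc", "complete", params,
               samples_in=n_before, samples_out=len(cq.sample_ids),
               excluded=excluded, outputs=["qc_report.tsv"])
    else:
        _stage(manifest, "qc", "skipped")

    # ---- candidate screen --------------------------------------------------
    if config.stage_enabled("screen", default=config.intensity_path is not None):
        if config.intensity_path is None:
            _stage(manifest, "screen", "skipped", notes="no intensity matrix supplied")
        else:
            p = config.screen
            try:
                expr = read_intensity_table(config.intensity_path)
                keep = [s for s in expr.sample_ids if s in set(cq.sample_ids)]
                expr.values = expr.values[keep]
                sel = select_candidates(
                    expr, ann.subset(keep),
                    min_detect_frac=float(p.get("min_detect_frac", 1.0)),
                    expr_quantile=float(p.get("expr_quantile", 0.75)),
                    de_p_floor=float(p.get("de_p_floor", 0.05)),
                    cv_rank_k=int(p.get("cv_rank_k", 10)))
                de = differential_expression(
                    expr, ann.subset(keep),
                    fc_thresh=float(p.get("fc_thresh", 2.0)),
                    p_thresh=float(p.get("p_thresh", 0.05)))
            except Exception as exc:
                fail("screen", exc)
            write_report(sel, out_dir / "candidates.tsv")
            write_report(de, out_dir / "diff_expr.tsv")
            _stage(manifest, "screen", "complete", dict(p),
                   candidates=sel.candidates,
                   n_significant=len(de.significant_genes),
                   outputs=["candidates.tsv", "diff_expr.tsv"])
    else:
        _stage(manifest, "screen", "skipped")

    # ---- stability ---------------------------------------------------------
    stab_res = None
    if config.stage_enabled("stability"):
        p = config.stability
        genes = p.get("genes")
        if genes is None:
            genes = [g for g in cq.gene_ids if g not in qc_gene_names]
        try:
            model = ReferenceGeneStability(
                cq, ann, genes=genes,
                efficiency=float(p.get("efficiency", 2.0)),
                v_threshold=float(p.get("v_threshold", 0.15)))
            stab_res = model.fit()
        except Exception as exc:
            fail("stability", exc)
        write_report(stab_res, out_dir / "stability.tsv")
        write_report(stab_res, out_dir / "stability.json")
        _stage(manifest, "stability", "complete",
               dict(genes=list(genes), efficiency=model.efficiency,
                    v_threshold=model.v_threshold),
               recommended_reference=stab_res.recommended_reference,
               most_stable_pair=list(stab_res.genorm.most_stable_pair),
               recommended_n=stab_res.recommended_n,
               outputs=["stability.tsv", "stability.json"])
    else:
        _stage(manifest, "stability", "skipped")

    # ---- quantify ----------------------------------------------------------
    rel = None
    if config.stage_enabled("quantify"):
        p = config.quantify
        refs = p.get("refs")
        if refs is None:
            if stab_res is None:
                fail("quantify", ValueError(
                    "no reference genes: stability stage is disabled, so "
                    "'refs' must be given explicitly"))
            refs = [stab_res.recommended_reference]
        calibrator = p.get("calibrator") or ann.groups[0]
        targets = p.get("targets")
        if targets is None:
            targets = [g for g in cq.gene_ids
                       if g not in qc_gene_names and g not in set(refs)]
        try:
            rel = delta_delta_ct(cq, targets, list(refs), ann, calibrator,
                                 efficiency=float(p.get("efficiency", 2.0)))
        except Exception as exc:
            fail("quantify", exc)
        write_report(rel, out_dir / "rel_expr.tsv")
        _stage(manifest, "quantify", "complete",
               dict(targets=list(targets), refs=list(refs), calibrator=calibrator),
               outputs=["rel_expr.tsv"])
    else:
        _stage(manifest, "quantify", "skipped")

    # ---- biomarker evaluation ---------------------------------------------
    if config.stage_enabled("biomarker", default=rel is not None):
        if rel is None:
            _stage(manifest, "biomarker", "skipped", notes="no relative expression")
        else:
            p = config.biomarker
            control = p.get("control") or ann.groups[0]
            try:
                tests = group_compare(rel, ann, control)
                roc_out = {}
                for gene in rel.rel_expr.index:
                    for grp in ann.groups:
                        if grp == control:
                            continue
                        pair = [s for s in rel.rel_expr.columns
                                if rel.groups[s] in (control, grp)]
                        labels = [rel.groups[s] == grp for s in pair]
                        roc = roc_analysis(rel.rel_expr.loc[gene, pair].to_numpy(),
                                           labels)
                        roc_out[f"{gene}|{grp}_vs_{control}"] = roc.to_dict()
                corr_rows = []
                if ann.outcome is not None:
                    covars = ann.frame[ann.covariate_columns].loc[rel.rel_expr.columns]
                    y = ann.frame.loc[rel.rel_expr.columns, ann.outcome]
                    for gene in rel.rel_expr.index:
                        ac = adjusted_correlation(rel.rel_expr.loc[gene], y, covars)
                        corr_rows.append({"gene": gene, **ac.to_dict(),
                                          "covariates": ",".join(ac.covariates)})
            except Exception as exc:
                fail("biomarker", exc)
            write_report(tests, out_dir / "group_tests.tsv")
            write_report(roc_out, out_dir / "roc.json", format="json")
            if corr_rows:
                write_report(pd.DataFrame(corr_rows), out_dir / "correlations.tsv")
            _stage(manifest, "biomarker", "complete", dict(control=control),
                   n_roc=len(roc_out),
                   outputs=["group_tests.tsv", "roc.json"]
                           + (["correlations.tsv"] if corr_rows else []))
    else:
        _stage(manifest, "biomarker", "skipped")

    _write_manifest(manifest, out_dir)
    return manifest


def _write_manifest(manifest: dict, out_dir: Path) -> None:
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
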