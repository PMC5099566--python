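"""Sample-level quality control for serum qPCR panels.

Two checks, both on raw Cq (the markers are themselves miRNAs, so QC must
precede any normalization):

* **Hemolysis index**: ``ΔCq = Cq(miR-23a-3p) − Cq(miR-451a)``. miR-451a is
  highly abundant in red blood cells, so erythrocyte lysis inflates the gap.
  A sample passes iff ΔCq is strictly below the threshold (default 7 cycles).
* **Spike-in consistency**: a synthetic exogenous control (cel-miR-39) added at
  fixed quantity before RNA isolation should give near-constant Cq; a sample
  passes iff its spike-in Cq is within ``max_abs_dev`` cycles of the
  cross-sample median (default 1.5 — robust to single outliers; the underlying
  idea is only that "stable" spike-in Cq indicates successful isolation, so the
  numeric rule is configurable).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CqMatrix, MissingGeneError

__all__ = ["QcReport", "hemolysis_index", "spikein_check", "run_qc", "filter_samples"]


@dataclass
class QcReport:
    """Per-sample QC outcomes; ``frame`` is indexed by sample id.

    Columns present depend on which checks ran: ``hemolysis_delta`` (cycles),
    ``hemolysis_pass``, ``spikein_cq``, ``spikein_dev``, ``spikein_pass`` and
    the combined ``pass`` flag (AND over the checks that ran). A sample failing
    any check must be excluded from all downstream group statistics.
    """

    frame: pd.DataFrame
    hemolysis_threshold: float | None = None
    spikein_max_dev: float | None = None
    spikein_median: float | None = None
    spikein_sd: float | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def passed_samples(self) -> list[str]:
        return list(self.frame.index[self.frame["pass"]])

    @property
    def failed_samples(self) -> list[str]:
        return list(self.frame.index[~self.frame["pass"]])

    def summary(self) -> dict:
        out = {
            "n_samples": int(len(self.frame)),
            "n_pass": int(self.frame["pass"].sum()),
            "n_fail": int((~self.frame["pass"]).sum()),
        }
        if "hemolysis_pass" in self.frame:
            out["n_hemolysis_fail"] = int((~self.frame["hemolysis_pass"]).sum())
        if "spikein_pass" in self.frame:
            out["n_spikein_fail"] = int((~self.frame["spikein_pass"]).sum())
            out["spikein_median"] = self.spikein_median
            out["spikein_sd"] = self.spikein_sd
        if self.warnings:
            out["warnings"] = list(self.warnings)
        return out

    def to_frame(self) -> pd.DataFrame:
        out = self.frame.reset_index().rename(columns={"index": "sample"})
        if out.columns[0] != "sample":
            out = out.rename(columns={out.columns[0]: "sample"})
        return out

    def to_dict(self) -> dict:
        return {"samples": self.to_frame(), "summary": self.summary()}


def _gene_row(cq: CqMatrix, gene: str) -> pd.Series:
    if gene not in cq.values.index:
        raise MissingGeneError(gene, cq.values.index)
    row = cq.values.loc[gene]
    if row.isna().any():
        bad = list(row.index[row.isna()])
        raise ValueError(f"gene {gene!r} has missing Cq in sample(s) {bad}; "
                         "QC needs a value in every sample")
    return row


def hemolysis_index(cq: CqMatrix, gene_23a: str = "miR-23a-3p",
                    gene_451a: str = "miR-451a",
                    threshold: float = 7.0) -> QcReport:
    """Hemolysis ΔCq per sample; pass iff ΔCq < threshold (strict)."""
    a = _gene_row(cq, gene_23a)
    b = _gene_row(cq, gene_451a)
    delta = a - b
    frame = pd.DataFrame({
        "hemolysis_delta": delta,
        "hemolysis_pass": delta < threshold,
    })
    frame["pass"] = frame["hemolysis_pass"]
    return QcReport(frame, hemolysis_threshold=threshold)


def spikein_check(cq: CqMatrix, spikein_gene: str = "cel-miR-39",
                  max_abs_dev: float = 1.5) -> QcReport:
    """Spike-in consistency: pass iff |Cq − median(Cq)| <= max_abs_dev."""
    row = _gene_row(cq, spikein_gene)
    warns: list[str] = []
    med = float(np.median(row.to_numpy()))
    sd = float(np.std(row.to_numpy(), ddof=1)) if len(row) > 1 else 0.0
    dev = row - med
    if len(row) < 3:
        msg = (f"spike-in check with {len(row)} sample(s): median is unstable; "
               "all samples pass")
        warnings.warn(msg, stacklevel=2)
        warns.append(msg)
        passed = pd.Series(True, index=row.index)
    else:
        passed = dev.abs() <= max_abs_dev
    frame = pd.DataFrame({
        "spikein_cq": row,
        "spikein_dev": dev,
        "spikein_pass": passed,
    })
    frame["pass"] = frame["spikein_pass"]
    return QcReport(frame, spikein_max_dev=max_abs_dev, spikein_median=med,
                    spikein_sd=sd, warnings=warns)


def run_qc(cq: CqMatrix, gene_23a: str = "miR-23a-3p", gene_451a: str = "miR-451a",
           hemolysis_threshold: float = 7.0,
           spikein_gene: str | None = "cel-miR-39",
           spikein_max_dev: float = 1.5) -> QcReport:
    """Run hemolysis and (optionally) spike-in checks; combined pass = AND."""
    hem = hemolysis_index(cq, gene_23a, gene_451a, hemolysis_threshold)
    frame = hem.frame.drop(columns=["pass"])
    warns = list(hem.warnings)
    spike_med = spike_sd = None
    if spikein_gene is not None and spikein_gene in cq.values.index:
        spk = spikein_check(cq, spikein_gene, spikein_max_dev)
        frame = frame.join(spk.frame.drop(columns=["pass"]))
        warns += spk.warnings
        spike_med, spike_sd = spk.spikein_median, spk.spikein_sd
        frame["pass"] = frame["hemolysis_pass"] & frame["spikein_pass"]
    else:
        frame["pass"] = frame["hemolysis_pass"]
    return QcReport(frame, hemolysis_threshold=hemolysis_threshold,
                    spikein_max_dev=spikein_max_dev, spikein_median=spike_med,
                    spikein_sd=spike_sd, warnings=warns)


def filter_samples(cq: CqMatrix, report: QcReport) -> CqMatrix:
    """Drop samples failing QC. Idempotent: re-filtering removes nothing new."""
    keep = [s for s in cq.sample_ids if s not in set(report.failed_samples)]
    return cq.subset(samples=keep)
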