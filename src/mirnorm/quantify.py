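"""Relative quantification of target miRNAs by the 2^-ddCt method.

Per sample, the reference Cq is the arithmetic mean of the reference genes'
Cq (equivalent to a geometric-mean normalization factor in linear space);
``dCq = Cq_target - Cq_ref``. The calibrator reference point is either the
calibrator group's mean dCq (default — so the calibrator group's relative
expression has geometric mean exactly 1 per gene) or a single named sample.
``rel_expr = E**(-ddCq)``; with E = 2, ``log2(rel_expr) = -ddCq`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CqMatrix, SampleAnnotation

__all__ = ["RelativeExpressionTable", "delta_delta_ct"]


@dataclass
class RelativeExpressionTable:
    """Per-gene per-sample dCq, ddCq (cycles) and linear relative expression."""

    delta_cq: pd.DataFrame          # targets x samples
    delta_delta_cq: pd.DataFrame
    rel_expr: pd.DataFrame
    reference_genes: list[str]
    calibrator: str
    efficiency: float
    groups: pd.Series | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene in self.rel_expr.index:
            for sample in self.rel_expr.columns:
                rows.append({
                    "gene": gene,
                    "sample": sample,
                    "group": (self.groups[sample] if self.groups is not None else ""),
                    "delta_cq": self.delta_cq.at[gene, sample],
                    "delta_delta_cq": self.delta_delta_cq.at[gene, sample],
                    "rel_expr": self.rel_expr.at[gene, sample],
                })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "reference_genes": list(self.reference_genes),
            "calibrator": self.calibrator,
            "efficiency": self.efficiency,
            "values": self.to_frame(),
        }


def delta_delta_ct(cq: CqMatrix, targets: list[str], refs: list[str],
                   ann: SampleAnnotation, calibrator: str,
                   efficiency: float = 2.0,
                   calibrator_sample: str | None = None) -> RelativeExpressionTable:
    """Relative expression of ``targets`` normalized to ``refs``.

    Parameters
    ----------
    calibrator
        Group whose mean dCq anchors ddCq (its rel_expr then has geometric
        mean 1 per gene).
    calibrator_sample
        If given, anchor to this single sample's dCq instead (per-sample
        calibration); ``calibrator`` is then only recorded for bookkeeping.
    """
    targets, refs = list(targets), list(refs)
    overlap = set(targets) & set(refs)
    if overlap:
        raise ValueError(f"gene(s) listed as both target and reference: {sorted(overlap)}")
    if not targets or not refs:
        raise ValueError("need at least one target and one reference gene")
    sub = cq.subset(genes=targets + refs)
    if sub.values.isna().any().any():
        bad = list(sub.values.index[sub.values.isna().any(axis=1)])
        raise ValueError(f"missing Cq for gene(s) {bad}; ddCt needs complete profiles")

    groups = ann.group_of(sub.sample_ids)
    ref_cq = sub.values.loc[refs].mean(axis=0)
    dcq = sub.values.loc[targets].sub(ref_cq, axis=1)

    if calibrator_sample is not None:
        if calibrator_sample not in dcq.columns:
            raise ValueError(f"calibrator sample {calibrator_sample!r} not in matrix")
        baseline = dcq[calibrator_sample]
    else:
        cal_samples = [s for s in dcq.columns if groups[s] == calibrator]
        if not cal_samples:
            raise ValueError(f"calibrator group {calibrator!r} has no samples "
                             f"(groups present: {sorted(set(groups))})")
        baseline = dcq[cal_samples].mean(axis=1)

    ddcq = dcq.sub(baseline, axis=0)
    rel = np.power(efficiency, -ddcq)
    return RelativeExpressionTable(dcq, ddcq, rel, refs, calibrator,
                                   float(efficiency), groups)
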