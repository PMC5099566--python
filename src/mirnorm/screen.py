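"""Candidate reference-gene selection and differential expression on
microarray-style linear intensity matrices.

Candidate screening applies three criteria to a two-group study:

1. *Highly expressed*: detected (intensity > 0) in at least ``min_detect_frac``
   of samples AND pooled mean at or above the ``expr_quantile`` quantile of
   gene means.
2. *No differential expression*: two-sided Welch t on log2 intensities gives
   p > ``de_p_floor``.
3. *Low variation*: the gene's worst coefficient of variation (max of pooled
   and per-group CV = SD/mean, linear scale) ranks within the ``cv_rank_k``
   smallest among genes passing 1-2.

Differential expression flags genes with linear fold change >= ``fc_thresh``
(or <= 1/fc_thresh) AND raw Welch p <= ``p_thresh``; a Benjamini-Hochberg
column is reported for transparency but does not enter the filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import IntensityMatrix, SampleAnnotation

__all__ = ["CandidateSelection", "DiffExprTable", "select_candidates",
           "differential_expression"]


@dataclass
class CandidateSelection:
    """Per-gene screening metrics, criterion flags and the final candidate list."""

    frame: pd.DataFrame            # indexed by gene
    candidates: list[str]          # sorted by worst CV ascending
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return self.frame.reset_index().rename(columns={"index": "gene"})

    def to_dict(self) -> dict:
        return {"genes": self.to_frame(), "candidates": list(self.candidates),
                "params": dict(self.params)}


@dataclass
class DiffExprTable:
    """Fold changes (case/control, linear), Welch p, BH q and pass flags."""

    frame: pd.DataFrame            # indexed by gene
    case: str
    control: str
    params: dict = field(default_factory=dict)

    @property
    def significant_genes(self) -> list[str]:
        return list(self.frame.index[self.frame["significant"]])

    @property
    def up_genes(self) -> list[str]:
        f = self.frame
        return list(f.index[f["significant"] & (f["direction"] == "up")])

    @property
    def down_genes(self) -> list[str]:
        f = self.frame
        return list(f.index[f["significant"] & (f["direction"] == "down")])

    def to_frame(self) -> pd.DataFrame:
        return self.frame.reset_index().rename(columns={"index": "gene"})

    def to_dict(self) -> dict:
        return {"genes": self.to_frame(), "case": self.case, "control": self.control,
                "params": dict(self.params)}


def _two_group_arrays(expr: IntensityMatrix, ann: SampleAnnotation,
                      case: str | None, control: str | None):
    samples = expr.sample_ids
    groups = ann.group_of(samples)
    levels = [g for g in ann.groups if g in set(groups)]
    if len(levels) != 2:
        raise ValueError(f"exactly 2 groups required, found {levels}")
    if control is None:
        control = levels[0]
    if case is None:
        case = next(g for g in levels if g != control)
    if case == control or case not in levels or control not in levels:
        raise ValueError(f"invalid case/control {case!r}/{control!r} among {levels}")
    a = expr.values.loc[:, groups == case]
    b = expr.values.loc[:, groups == control]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples")
    return a, b, case, control


def _welch_log2(a: np.ndarray, b: np.ndarray, pseudocount: float) -> np.ndarray:
    """Vectorized two-sided Welch t on log2(x + pseudocount), rows = genes.

    Degenerate rows (zero variance in both groups) get p = 0 when the means
    differ and p = 1 when they do not, rather than NaN.
    """
    la, lb = np.log2(a + pseudocount), np.log2(b + pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(la, lb, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    flat = np.isnan(p)
    if flat.any():
        same = np.isclose(la.mean(axis=1), lb.mean(axis=1))
        p[flat & same] = 1.0
        p[flat & ~same] = 0.0
    return p


def select_candidates(expr: IntensityMatrix, ann: SampleAnnotation,
                      min_detect_frac: float = 1.0, expr_quantile: float = 0.75,
                      de_p_floor: float = 0.05, cv_rank_k: int = 10,
                      pseudocount: float = 1.0) -> CandidateSelection:
    """Screen for candidate reference genes by the three criteria above.

    Ties in worst CV are broken by input order (stable sort), so a constant
    matrix yields the first ``cv_rank_k`` genes in input order.
    """
    a, b, case, control = _two_group_arrays(expr, ann, None, None)
    v = expr.values
    if (v.to_numpy() == 0).all():
        raise ValueError("degenerate intensity matrix: all values zero")

    pooled_mean = v.mean(axis=1)
    detect_frac = (v > 0).mean(axis=1)
    qcut = float(np.quantile(pooled_mean.to_numpy(), expr_quantile))
    crit_expr = (detect_frac >= min_detect_frac) & (pooled_mean >= qcut)

    p_de = pd.Series(_welch_log2(a.to_numpy(), b.to_numpy(), pseudocount), index=v.index)
    crit_no_de = p_de > de_p_floor

    def _cv(df: pd.DataFrame) -> pd.Series:
        m = df.mean(axis=1)
        s = df.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = s / m
        cv[m <= 0] = np.nan
        return cv

    cv_pooled = _cv(v)
    cv_case, cv_control = _cv(a), _cv(b)
    cv_worst = pd.concat([cv_pooled, cv_case, cv_control], axis=1).max(axis=1, skipna=False)

    eligible = crit_expr & crit_no_de & cv_worst.notna()
    order = cv_worst[eligible].sort_values(kind="mergesort")  # stable: input order ties
    candidates = list(order.index[:cv_rank_k])
    crit_cv = pd.Series(False, index=v.index)
    crit_cv[candidates] = True

    frame = pd.DataFrame({
        "mean_pooled": pooled_mean,
        f"mean_{case}": a.mean(axis=1),
        f"mean_{control}": b.mean(axis=1),
        "detect_frac": detect_frac,
        "p_de": p_de,
        "cv_pooled": cv_pooled,
        f"cv_{case}": cv_case,
        f"cv_{control}": cv_control,
        "cv_worst": cv_worst,
        "pass_expression": crit_expr,
        "pass_no_de": crit_no_de,
        "pass_cv": crit_cv,
    })
    frame["candidate"] = crit_expr & crit_no_de & crit_cv
    frame.index.name = "gene"
    params = dict(min_detect_frac=min_detect_frac, expr_quantile=expr_quantile,
                  de_p_floor=de_p_floor, cv_rank_k=cv_rank_k,
                  expr_cutoff=qcut, case=case, control=control)
    return CandidateSelection(frame, candidates, params)


def differential_expression(expr: IntensityMatrix, ann: SampleAnnotation,
                            case: str | None = None, control: str | None = None,
                            fc_thresh: float = 2.0, p_thresh: float = 0.05,
                            pseudocount: float = 1.0) -> DiffExprTable:
    """Per-gene fold change and Welch t differential-expression filter.

    FC = mean(case)/mean(control) on the linear scale; boundary values are
    significant (``>=``/``<=``). Genes with a zero-mean group are flagged
    ``fc_undefined`` and excluded from the significant set.
    """
    a, b, case, control = _two_group_arrays(expr, ann, case, control)
    mean_case, mean_control = a.mean(axis=1), b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_case / mean_control
        log2fc = np.log2(fc)
    fc_undefined = ~np.isfinite(fc) | (fc <= 0)

    p = pd.Series(_welch_log2(a.to_numpy(), b.to_numpy(), pseudocount), index=expr.values.index)
    p_adj = pd.Series(multipletests(p.to_numpy(), method="fdr_bh")[1], index=p.index)

    direction = pd.Series("none", index=fc.index)
    direction[fc > 1] = "up"
    direction[fc < 1] = "down"
    passes_fc = (fc >= fc_thresh) | (fc <= 1.0 / fc_thresh)
    significant = passes_fc & (p <= p_thresh) & ~fc_undefined

    frame = pd.DataFrame({
        f"mean_{case}": mean_case,
        f"mean_{control}": mean_control,
        "fc": fc,
        "log2_fc": log2fc,
        "p": p,
        "p_adj": p_adj,
        "direction": direction,
        "fc_undefined": fc_undefined,
        "significant": significant,
    })
    frame.index.name = "gene"
    params = dict(fc_thresh=fc_thresh, p_thresh=p_thresh, pseudocount=pseudocount)
    return DiffExprTable(frame, case, control, params)
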