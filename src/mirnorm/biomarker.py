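"""Diagnostic evaluation of candidate biomarkers: group comparison (one-way
ANOVA with Welch/Holm post-hoc), empirical ROC analysis with DeLong
confidence intervals and Youden-optimal cutoffs, and covariate-adjusted
(partial) correlation with a continuous outcome such as bone mineral density.

The ROC is fully empirical: thresholds sweep the distinct scores, the AUC is
the trapezoid integral of the curve (identically the Mann-Whitney estimator
with ties counted 1/2), and the optimal cutoff maximizes Youden
J = sensitivity + specificity - 1 over midpoints between adjacent distinct
scores (ties: higher sensitivity, then lower cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import SampleAnnotation
from .quantify import RelativeExpressionTable

__all__ = [
    "GroupTestTable", "RocResult", "CutoffResult", "AdjustedCorrelation",
    "CollinearityError", "group_compare", "roc_analysis", "optimal_cutoff",
    "adjusted_correlation", "mann_whitney_auc",
]


class CollinearityError(ValueError):
    """Covariate design matrix is rank-deficient; names the dependent column."""


# ---------------------------------------------------------------------------
# group comparison

def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class GroupTestTable:
    """Per-gene group summaries, one-way ANOVA, and Holm-adjusted pairwise tests."""

    summary: pd.DataFrame     # gene, group, n, mean, sd
    anova: pd.DataFrame       # gene, F, p
    pairwise: pd.DataFrame    # gene, group, t, p_raw, p_adj, stars
    control: str

    def to_frame(self) -> pd.DataFrame:
        return self.pairwise.merge(self.anova, on="gene", suffixes=("", "_anova"))

    def to_dict(self) -> dict:
        return {"summary": self.summary, "anova": self.anova,
                "pairwise": self.pairwise, "control": self.control}


def _welch_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        return np.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def group_compare(rel: RelativeExpressionTable, ann: SampleAnnotation,
                  control: str) -> GroupTestTable:
    """One-way ANOVA across groups per gene plus Welch t vs control, Holm-adjusted
    within gene. Constant data yield F = 0, p = 1."""
    values = rel.rel_expr
    groups = ann.group_of(list(values.columns))
    levels = [g for g in ann.groups if g in set(groups)]
    if control not in levels:
        raise ValueError(f"control group {control!r} not among {levels}")
    if len(levels) < 2:
        raise ValueError("group comparison needs >= 2 groups")
    for g in levels:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")

    sum_rows, anova_rows, pw_rows = [], [], []
    for gene in values.index:
        by_group = {g: values.loc[gene, groups.index[groups == g]].to_numpy()
                    for g in levels}
        for g in levels:
            x = by_group[g]
            sum_rows.append({"gene": gene, "group": g, "n": len(x),
                             "mean": float(x.mean()),
                             "sd": float(x.std(ddof=1))})
        pooled = np.concatenate(list(by_group.values()))
        if np.ptp(pooled) == 0:
            F, p = 0.0, 1.0
        else:
            F, p = stats.f_oneway(*by_group.values())
        anova_rows.append({"gene": gene, "F": float(F), "p": float(p)})

        others = [g for g in levels if g != control]
        raw = []
        for g in others:
            t, pr = _welch_p(by_group[g], by_group[control])
            raw.append((g, t, pr))
        adj = multipletests([r[2] for r in raw], method="holm")[1]
        for (g, t, pr), pa in zip(raw, adj):
            pw_rows.append({"gene": gene, "group": g, "t": t, "p_raw": pr,
                            "p_adj": float(pa), "stars": _stars(float(pa))})
    return GroupTestTable(pd.DataFrame(sum_rows), pd.DataFrame(anova_rows),
                          pd.DataFrame(pw_rows), control)


# ---------------------------------------------------------------------------
# ROC

def mann_whitney_auc(cases: np.ndarray, controls: np.ndarray) -> float:
    """AUC as the Mann-Whitney U statistic with ties counted 1/2."""
    cases = np.asarray(cases, float)
    controls = np.asarray(controls, float)
    n1, n0 = len(cases), len(controls)
    ranks = stats.rankdata(np.concatenate([cases, controls]))
    return float((ranks[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _delong_variance(cases: np.ndarray, controls: np.ndarray) -> float:
    """DeLong variance of the empirical AUC from placement values."""
    n1, n0 = len(cases), len(controls)
    # V10_i: fraction of controls below case i (ties 1/2); V01_j symmetric
    v10 = np.array([(np.sum(controls < c) + 0.5 * np.sum(controls == c)) / n0
                    for c in cases])
    v01 = np.array([(np.sum(cases > c) + 0.5 * np.sum(cases == c)) / n1
                    for c in controls])
    s10 = v10.var(ddof=1) if n1 > 1 else 0.0
    s01 = v01.var(ddof=1) if n0 > 1 else 0.0
    return float(s10 / n1 + s01 / n0)


@dataclass
class RocResult:
    """Empirical ROC with AUC, DeLong 95% CI, p vs 0.5 and optimal cutoff.

    ``orientation`` records whether high ('high') or low ('low') scores
    predict case status; cutoffs are in original score units, with the
    decision rule "case if score >= cutoff" ('high') or "<= cutoff" ('low').
    """

    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    se: float
    curve: pd.DataFrame                  # fpr, tpr, threshold (oriented scores)
    orientation: str
    n_case: int
    n_control: int
    cutoff: float | None = None
    sensitivity: float | None = None     # percent
    specificity: float | None = None     # percent
    youden_j: float | None = None
    _cases: np.ndarray | None = field(default=None, repr=False)
    _controls: np.ndarray | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "auc": self.auc, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p": self.p_value, "cutoff": self.cutoff,
            "sensitivity_pct": self.sensitivity, "specificity_pct": self.specificity,
            "youden_j": self.youden_j, "orientation": self.orientation,
            "n_case": self.n_case, "n_control": self.n_control,
        }])

    def to_dict(self) -> dict:
        d = self.to_frame().iloc[0].to_dict()
        d["curve"] = self.curve
        return d

    def plot(self, ax=None, label: str | None = None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        lbl = label or f"AUC = {self.auc:.3f}"
        ax.plot(self.curve["fpr"], self.curve["tpr"], drawstyle="steps-post", label=lbl)
        ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right")
        return ax


@dataclass
class CutoffResult:
    cutoff: float
    sensitivity: float   # percent
    specificity: float   # percent
    youden_j: float


def _split_scores(scores, labels, positive_label):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    if positive_label is None:
        uniq = pd.unique(labels)
        if labels.dtype == bool or set(map(bool, uniq)) <= {True, False} and labels.dtype != object:
            pos_mask = labels.astype(bool)
        elif len(uniq) == 2:
            raise ValueError(
                f"labels have levels {list(uniq)}; specify positive_label")
        else:
            raise ValueError("labels must be binary")
    else:
        pos_mask = labels == positive_label
    cases, controls = scores[pos_mask], scores[~pos_mask]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both classes must be present for ROC analysis")
    return cases, controls


def roc_analysis(scores, labels, orientation: str = "auto",
                 positive_label=None, ci_method: str = "delong",
                 alpha: float = 0.05, n_boot: int = 2000,
                 rng: np.random.Generator | int | None = None,
                 find_cutoff: bool = True) -> RocResult:
    """Empirical ROC analysis of a continuous score against binary labels.

    ``orientation='auto'`` flips the score when the raw high-predicts-case AUC
    is below 0.5 (the panel's biomarkers decrease in disease) and records the
    flip; 'high'/'low' force a direction. CI and p vs AUC = 0.5 use the DeLong
    variance by default; ``ci_method='bootstrap'`` gives a stratified
    percentile CI for tiny samples.
    """
    if orientation not in ("auto", "high", "low"):
        raise ValueError("orientation must be auto|high|low")
    cases, controls = _split_scores(scores, labels, positive_label)
    if orientation == "auto":
        orientation = "high" if mann_whitney_auc(cases, controls) >= 0.5 else "low"
    sign = 1.0 if orientation == "high" else -1.0
    oc, ok = sign * cases, sign * controls

    auc = mann_whitney_auc(oc, ok)
    var = _delong_variance(oc, ok)
    se = float(np.sqrt(var))
    z = stats.norm.ppf(1 - alpha / 2)
    if ci_method == "delong":
        if 0.0 < auc < 1.0 and se > 0:
            # logit transform: respects (0,1) and markedly improves
            # small-sample calibration of the Wald interval
            lo = np.log(auc / (1.0 - auc))
            se_logit = se / (auc * (1.0 - auc))
            ci_low = 1.0 / (1.0 + np.exp(-(lo - z * se_logit)))
            ci_high = 1.0 / (1.0 + np.exp(-(lo + z * se_logit)))
        else:
            ci_low = max(0.0, auc - z * se)
            ci_high = min(1.0, auc + z * se)
    elif ci_method == "bootstrap":
        gen = np.random.default_rng(rng)
        boots = np.empty(n_boot)
        for i in range(n_boot):
            boots[i] = mann_whitney_auc(gen.choice(oc, len(oc), replace=True),
                                        gen.choice(ok, len(ok), replace=True))
        ci_low, ci_high = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
        ci_low, ci_high = min(float(ci_low), auc), max(float(ci_high), auc)
    else:
        raise ValueError("ci_method must be 'delong' or 'bootstrap'")
    if se > 0:
        p = float(2 * stats.norm.sf(abs(auc - 0.5) / se))
    else:
        p = 1.0 if np.isclose(auc, 0.5) else 0.0

    # empirical curve on oriented scores: predict case if score >= threshold
    thresholds = np.unique(np.concatenate([oc, ok]))[::-1]
    tpr = [0.0]
    fpr = [0.0]
    thr = [np.inf]
    for t in thresholds:
        tpr.append(float(np.mean(oc >= t)))
        fpr.append(float(np.mean(ok >= t)))
        thr.append(float(t))
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})

    res = RocResult(auc=auc, ci_low=float(ci_low), ci_high=float(ci_high),
                    p_value=p, se=se, curve=curve, orientation=orientation,
                    n_case=len(cases), n_control=len(controls),
                    _cases=cases, _controls=controls)
    if find_cutoff:
        cut = optimal_cutoff(res)
        res.cutoff, res.sensitivity = cut.cutoff, cut.sensitivity
        res.specificity, res.youden_j = cut.specificity, cut.youden_j
    return res


def optimal_cutoff(roc: RocResult) -> CutoffResult:
    """Youden-optimal cutoff by exhaustive scan over threshold midpoints.

    Candidate thresholds sit between adjacent distinct (oriented) scores;
    ties on J are resolved by higher sensitivity, then by lower cutoff (in
    oriented-score space). If every score is identical the degenerate
    all-positive rule is reported: J = 0, sensitivity 100%, specificity 0%.
    """
    if roc._cases is None or roc._controls is None:
        raise ValueError("RocResult lacks stored scores; run roc_analysis first")
    sign = 1.0 if roc.orientation == "high" else -1.0
    oc, ok = sign * roc._cases, sign * roc._controls
    pooled = np.unique(np.concatenate([oc, ok]))
    if len(pooled) == 1:
        cut = float(pooled[0])
        return CutoffResult(sign * cut, 100.0, 0.0, 0.0)
    mids = (pooled[:-1] + pooled[1:]) / 2.0
    best = None
    for t in mids:
        sens = float(np.mean(oc >= t))
        spec = float(np.mean(ok < t))
        j = sens + spec - 1.0
        key = (j, sens, -t)  # maximize J, then sensitivity, then prefer lower t
        if best is None or key > best[0]:
            best = (key, t, sens, spec, j)
    _, t, sens, spec, j = best
    return CutoffResult(float(sign * t), 100.0 * sens, 100.0 * spec, float(j))


# ---------------------------------------------------------------------------
# covariate-adjusted correlation

@dataclass
class AdjustedCorrelation:
    """Partial correlation of x and y given covariates (residual method)."""

    r: float
    p: float
    n: int
    df: int
    covariates: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"r": self.r, "p": self.p, "n": self.n,
                              "df": self.df,
                              "covariates": ",".join(self.covariates)}])

    def to_dict(self) -> dict:
        return {"r": self.r, "p": self.p, "n": self.n, "df": self.df,
                "covariates": list(self.covariates)}


def _check_collinearity(design: np.ndarray, names: list[str]) -> None:
    full_rank = np.linalg.matrix_rank(design)
    if full_rank == design.shape[1]:
        return
    for k in range(1, design.shape[1]):
        if np.linalg.matrix_rank(design[:, :k + 1]) == np.linalg.matrix_rank(design[:, :k]):
            raise CollinearityError(
                f"covariate {names[k - 1]!r} is linearly dependent on the "
                "preceding covariates (plus intercept)")
    raise CollinearityError("covariate design matrix is rank deficient")


def adjusted_correlation(x, y, covars: pd.DataFrame | None = None) -> AdjustedCorrelation:
    """Partial correlation between x and y adjusting for covariates.

    Both x and y are regressed on the covariates (with intercept); the
    residuals are Pearson-correlated, and p comes from
    ``t = r sqrt(df / (1 - r^2))`` with ``df = n - 2 - k`` (two-sided).
    With no covariates this is exactly the Pearson correlation.
    """
    x = pd.Series(np.asarray(x, float))
    y = pd.Series(np.asarray(y, float))
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if covars is not None:
        covars = pd.DataFrame(covars).reset_index(drop=True).astype(float)
        if len(covars) != len(x):
            raise ValueError("covariates must align with x and y")
        names = list(covars.columns)
    else:
        covars = pd.DataFrame(index=range(len(x)))
        names = []

    mask = x.notna() & y.notna()
    if names:
        mask &= covars.notna().all(axis=1)
    xv, yv = x[mask].to_numpy(), y[mask].to_numpy()
    n, k = len(xv), len(names)
    df = n - 2 - k
    if df <= 0:
        raise ValueError(f"not enough complete cases (n={n}) for {k} covariates")

    design = np.column_stack([np.ones(n)] + [covars.loc[mask, c].to_numpy() for c in names])
    _check_collinearity(design, names)
    rx = xv - design @ np.linalg.lstsq(design, xv, rcond=None)[0]
    ry = yv - design @ np.linalg.lstsq(design, yv, rcond=None)[0]
    denom = float(np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))
    if denom == 0:
        raise ValueError("zero residual variance; correlation undefined")
    r = float(np.clip((rx * ry).sum() / denom, -1.0, 1.0))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r ** 2))
        p = float(2 * stats.t.sf(abs(t), df))
    return AdjustedCorrelation(r, p, n, df, names)
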