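"""Reference-gene stability ranking: geNorm, NormFinder and a comprehensive
aggregate, exposed both as functions and as a statsmodels-style model
(:class:`ReferenceGeneStability` -> :class:`StabilityResults`).

geNorm
------
Cq values are first transformed to relative quantities
``Q_gj = E**(min_j Cq_gj - Cq_gj)`` (per-gene maximum 1, E = amplification
efficiency, 2 for perfect doubling). For a gene pair (j, k) the pairwise
variation ``V_jk`` is the sample standard deviation (n-1 denominator) of
``log2(Q_j / Q_k)`` across samples; a gene's stability ``M_j`` is the mean of
``V_jk`` over all other candidates. Low M = stable. Ranking removes the
highest-M gene iteratively until two remain (the most stable pair). The
pairwise variation ``V_{n/n+1}`` between normalization factors (geometric mean
of the top n and top n+1 genes) decides how many reference genes suffice:
the smallest n with ``V_{n/n+1}`` below a threshold (0.15 by convention).

NormFinder
----------
A model-based variance decomposition of log-scale expression. Each sample is
centered by its mean over the candidate genes (removing global load), then per
group the intragroup variance of each gene and its intergroup deviation
(gene x group interaction d_ig) are estimated; d_ig is shrunk toward zero in
empirical-Bayes fashion, and the stability value combines |d_ig| with the
sampling variance contribution, averaged over groups. Low values = stable.
With a single group the stability value reduces to the (bias-corrected)
intragroup SD.

The comprehensive rank aggregates the two methods by the geometric mean of
their ranks (ties broken by lower geNorm M, then input order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CqMatrix, SampleAnnotation

__all__ = [
    "RelativeQuantityMatrix", "cq_to_quantity", "genorm_m", "genorm_rank",
    "pairwise_variation", "recommend_n_from_v", "normfinder_stability",
    "aggregate_rank", "GeNormRanking", "PairwiseVariation", "NormFinderResult",
    "ReferenceGeneStability", "StabilityResults",
]


@dataclass
class RelativeQuantityMatrix:
    """Linear relative quantities Q (genes x samples), per-gene max 1."""

    values: pd.DataFrame
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(float)
        if not np.isfinite(arr).all() or (arr <= 0).any():
            raise ValueError("relative quantities must be finite and > 0")


def cq_to_quantity(cq: CqMatrix, efficiency: float = 2.0) -> RelativeQuantityMatrix:
    """Transform Cq to relative quantities ``Q = E**(Cq_min - Cq)`` per gene."""
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must exceed 1 per cycle")
    v = cq.values
    if v.isna().any().any():
        bad = list(v.index[v.isna().any(axis=1)])
        raise ValueError(
            f"missing Cq for gene(s) {bad}; stability analysis needs complete "
            "profiles — drop these genes or use missing_policy='max_cycle' "
            "when reading the table"
        )
    q = np.power(efficiency, v.min(axis=1).to_numpy()[:, None] - v.to_numpy())
    return RelativeQuantityMatrix(pd.DataFrame(q, index=v.index, columns=v.columns),
                                  efficiency)


def _q_frame(Q) -> pd.DataFrame:
    if isinstance(Q, RelativeQuantityMatrix):
        return Q.values
    if isinstance(Q, CqMatrix):
        return cq_to_quantity(Q).values
    return pd.DataFrame(Q).astype(float)


def genorm_m(Q) -> pd.Series:
    """geNorm stability M per gene: mean pairwise SD of log2 expression ratios."""
    v = _q_frame(Q)
    if len(v) < 2:
        raise ValueError("geNorm needs >= 2 genes")
    if v.shape[1] < 3:
        raise ValueError("geNorm needs >= 3 samples for stable pairwise SDs")
    arr = v.to_numpy(float)
    if (arr <= 0).any() or not np.isfinite(arr).all():
        raise ValueError("relative quantities must be finite and > 0")
    logq = np.log2(arr)
    # D[j, k, s] = log2(Q_j/Q_k) for sample s; V = SD over samples (ddof=1)
    diff = logq[:, None, :] - logq[None, :, :]
    V = diff.std(axis=2, ddof=1)
    G = len(v)
    M = V.sum(axis=1) / (G - 1)  # V_jj = 0
    return pd.Series(M, index=v.index, name="M")


@dataclass
class GeNormRanking:
    """Iterative geNorm exclusion result.

    ``ranks`` is a permutation of 1..G; the final surviving pair holds ranks
    1 and 2 (assigned in input order). ``m_values`` are the M values on the
    full starting set; ``m_at_exclusion`` the M each gene had in the round it
    was removed (for the pair: the final 2-gene round).
    """

    ranks: pd.Series
    exclusion_order: list[str]          # first removed first
    most_stable_pair: tuple[str, str]
    m_values: pd.Series
    m_at_exclusion: pd.Series


def genorm_rank(Q) -> GeNormRanking:
    """Iteratively exclude the least stable (highest M) gene.

    Ties on M are broken by excluding the gene occurring first in input
    order. With only 2 genes no iteration happens: both form the pair.
    """
    v = _q_frame(Q)
    genes = list(v.index)
    m_full = genorm_m(v)
    m_at_exclusion = pd.Series(index=v.index, dtype=float)
    exclusion: list[str] = []
    surviving = list(genes)
    while len(surviving) > 2:
        m = genorm_m(v.loc[surviving])
        worst = m.index[int(np.argmax(m.to_numpy()))]  # first occurrence on ties
        m_at_exclusion[worst] = m[worst]
        exclusion.append(worst)
        surviving.remove(worst)
    m_pair = genorm_m(v.loc[surviving]) if len(surviving) >= 2 else m_full[surviving]
    for g in surviving:
        m_at_exclusion[g] = m_pair[g]
    pair = tuple(g for g in genes if g in set(surviving))  # input order
    ranks = pd.Series(index=v.index, dtype=int, name="genorm_rank")
    ranks[pair[0]], ranks[pair[1]] = 1, 2
    for i, g in enumerate(reversed(exclusion)):
        ranks[g] = 3 + i
    return GeNormRanking(ranks.astype(int), exclusion, (pair[0], pair[1]),
                         m_full, m_at_exclusion)


@dataclass
class PairwiseVariation:
    """V_{n/n+1} series (indexed by n = 2..G-1) and the recommended n."""

    v: pd.Series
    recommended_n: int
    threshold: float


def recommend_n_from_v(v: pd.Series, threshold: float = 0.15) -> int:
    """Smallest n with V_{n/n+1} < threshold; else G (= last n + 1)."""
    for n, val in v.items():
        if val < threshold:
            return int(n)
    return int(v.index[-1]) + 1


def pairwise_variation(Q, ranked_genes: Sequence[str],
                       v_threshold: float = 0.15) -> PairwiseVariation:
    """Pairwise variation between normalization factors of n and n+1 genes.

    ``NF_n`` per sample is the geometric mean of Q over the n top-ranked
    genes; ``V_{n/n+1}`` is the SD over samples of ``log2(NF_n/NF_{n+1})``.
    """
    v = _q_frame(Q)
    ranked = list(ranked_genes)
    G = len(ranked)
    if G < 3:
        raise ValueError("pairwise variation needs >= 3 ranked genes")
    logq = np.log2(v.loc[ranked].to_numpy(float))
    vals, idx = [], []
    for n in range(2, G):
        log_nf_n = logq[:n].mean(axis=0)
        log_nf_n1 = logq[:n + 1].mean(axis=0)
        vals.append(float(np.std(log_nf_n - log_nf_n1, ddof=1)))
        idx.append(n)
    series = pd.Series(vals, index=pd.Index(idx, name="n"), name="V")
    return PairwiseVariation(series, recommend_n_from_v(series, v_threshold),
                             v_threshold)


@dataclass
class NormFinderResult:
    """NormFinder stability values and diagnostics.

    ``stability`` (rho) per gene, lower = more stable; ``sigma2`` intragroup
    variance estimates (genes x groups, floored at 0); ``d`` shrunk intergroup
    deviations and ``d_raw`` before shrinkage (empty in single-group mode);
    ``tau2`` the estimated variance of the true intergroup deviations.
    """

    stability: pd.Series
    ranks: pd.Series
    sigma2: pd.DataFrame
    d: pd.DataFrame
    d_raw: pd.DataFrame
    tau2: float
    groups: list[str]
    single_group: bool


def normfinder_stability(log_expr: pd.DataFrame,
                         ann: SampleAnnotation | pd.Series | None = None
                         ) -> NormFinderResult:
    """Model-based stability of candidate reference genes (NormFinder).

    Parameters
    ----------
    log_expr
        Log-scale expression, genes x samples (e.g. ``log2`` of relative
        quantities; for Cq data with perfect efficiency this is just ``-Cq``
        up to a per-gene constant, which the algorithm is invariant to).
    ann
        Group labels (annotation object or a Series indexed by sample).
        ``None`` or a single level selects single-group mode, where the
        stability value is the bias-corrected intragroup SD.
    """
    y = pd.DataFrame(log_expr).astype(float)
    I, n_total = y.shape
    if I < 3:
        raise ValueError("NormFinder needs >= 3 genes (bias correction requires it)")
    if isinstance(ann, SampleAnnotation):
        groups = ann.group_of(y.columns)
    elif ann is None:
        groups = pd.Series("all", index=y.columns)
    else:
        groups = pd.Series(ann).reindex(y.columns)
        if groups.isna().any():
            raise ValueError("group labels missing for some samples")
    levels = list(dict.fromkeys(groups))
    single = len(levels) == 1

    # center each sample by its mean over genes (removes per-sample load)
    z = y - y.mean(axis=0)

    gamma2 = pd.DataFrame(index=y.index, columns=levels, dtype=float)
    zbar = pd.DataFrame(index=y.index, columns=levels, dtype=float)
    n_g: dict[str, int] = {}
    for g in levels:
        cols = groups.index[groups == g]
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has {len(cols)} sample(s); need >= 2")
        zg = z[cols]
        n_g[g] = len(cols)
        zbar[g] = zg.mean(axis=1)
        gamma2[g] = zg.var(axis=1, ddof=1)

    # Small-sample bias correction for the per-sample centering: with I genes,
    # E[gamma2_ig] = sigma2_ig (1 - 2/I) + mean_i(sigma2_ig)/I, giving the
    # unbiased estimator below; negative estimates are floored at 0.
    sigma2 = (gamma2 - gamma2.sum(axis=0) / (I * (I - 1))) * (I / (I - 2))
    sigma2 = sigma2.clip(lower=0.0)

    if single:
        g = levels[0]
        sd = np.sqrt(sigma2[g])
        stability = pd.Series(sd, index=y.index, name="normfinder_stability")
        ranks = stability.rank(method="first").astype(int)
        ranks.name = "normfinder_rank"
        empty = pd.DataFrame(index=y.index, columns=levels, dtype=float)
        return NormFinderResult(stability, ranks, sigma2, empty, empty, 0.0,
                                levels, True)

    G = len(levels)
    # gene x group interaction: deviation of the gene's group mean from its
    # cross-group mean (sum over genes is 0 by the sample centering)
    d_raw = zbar.sub(zbar.mean(axis=1), axis=0)

    # empirical-Bayes shrinkage toward 0: estimate the variance tau2 of the
    # true deviations and scale each d by tau2 / (tau2 + sampling variance)
    samp_var = pd.DataFrame({g: sigma2[g] / n_g[g] for g in levels})
    tau2 = float((d_raw.to_numpy() ** 2).sum() / ((I - 1) * (G - 1))
                 - samp_var.to_numpy().mean())
    tau2 = max(tau2, 0.0)
    shrink = tau2 / (tau2 + samp_var) if tau2 > 0 else samp_var * 0.0
    d = d_raw * shrink

    # stability: |shrunk deviation| plus the posterior uncertainty of the
    # deviation estimate, averaged over groups
    post_var = samp_var + (tau2 * samp_var) / (tau2 + samp_var) if tau2 > 0 else samp_var
    rho = (d.abs() + np.sqrt(post_var)).mean(axis=1)
    stability = pd.Series(rho, index=y.index, name="normfinder_stability")
    ranks = stability.rank(method="first").astype(int)
    ranks.name = "normfinder_rank"
    return NormFinderResult(stability, ranks, sigma2, d, d_raw, tau2, levels, False)


def aggregate_rank(genorm_ranks: pd.Series, normfinder_ranks: pd.Series,
                   m_values: pd.Series | None = None) -> pd.DataFrame:
    """Comprehensive ranking: geometric mean of the two ranks, ascending.

    Ties are broken by lower geNorm M (when supplied), then by input order.
    """
    g = pd.Series(genorm_ranks).astype(float)
    n = pd.Series(normfinder_ranks).astype(float)
    if set(g.index) != set(n.index):
        raise ValueError("geNorm and NormFinder rankings cover different gene sets")
    n = n.reindex(g.index)
    score = np.sqrt(g * n)
    frame = pd.DataFrame({"genorm_rank": g.astype(int),
                          "normfinder_rank": n.astype(int),
                          "comprehensive_score": score})
    if m_values is not None:
        frame["M"] = pd.Series(m_values).reindex(g.index)
        tiebreak = frame["M"]
    else:
        tiebreak = pd.Series(0.0, index=g.index)
    order = sorted(range(len(frame)),
                   key=lambda i: (score.iloc[i], tiebreak.iloc[i], i))
    ranks = pd.Series(index=g.index, dtype=int)
    for r, i in enumerate(order, start=1):
        ranks.iloc[i] = r
    frame["comprehensive_rank"] = ranks
    frame.index.name = "gene"
    return frame


# ---------------------------------------------------------------------------
# model / results interface

class ReferenceGeneStability:
    """Stability model for a candidate reference-gene panel.

    Built from a Cq matrix (and optionally a sample annotation providing group
    labels for NormFinder); ``fit()`` runs geNorm and NormFinder and returns a
    :class:`StabilityResults`.

    Parameters
    ----------
    cq
        Complete Cq matrix. Genes with missing wells raise; restrict with
        ``genes=`` or impute at read time.
    annotation
        Optional group labels; without them (or with one group) NormFinder
        runs in single-group mode.
    genes
        Candidate subset (default: all genes in ``cq``).
    efficiency
        Amplification efficiency per cycle (default 2.0, perfect doubling).
    v_threshold
        geNorm pairwise-variation cutoff for the recommended number of
        reference genes (default 0.15).
    """

    def __init__(self, cq: CqMatrix, annotation: SampleAnnotation | None = None,
                 genes: Sequence[str] | None = None, efficiency: float = 2.0,
                 v_threshold: float = 0.15):
        if genes is not None:
            cq = cq.subset(genes=list(genes))
        self.cq = cq
        self.annotation = annotation
        self.efficiency = float(efficiency)
        self.v_threshold = float(v_threshold)

    @classmethod
    def from_frames(cls, cq_frame: pd.DataFrame,
                    annotation_frame: pd.DataFrame | None = None,
                    **kwargs) -> "ReferenceGeneStability":
        ann = SampleAnnotation(annotation_frame) if annotation_frame is not None else None
        return cls(CqMatrix(cq_frame), ann, **kwargs)

    def fit(self) -> "StabilityResults":
        Q = cq_to_quantity(self.cq, self.efficiency)
        ranking = genorm_rank(Q)
        ranked = sorted(ranking.ranks.index, key=lambda g: ranking.ranks[g])
        pv = (pairwise_variation(Q, ranked, self.v_threshold)
              if len(ranked) >= 3 else None)
        nf = normfinder_stability(np.log2(Q.values), self.annotation)
        agg = aggregate_rank(ranking.ranks, nf.ranks, ranking.m_values)
        return StabilityResults(self, Q, ranking, pv, nf, agg)


@dataclass
class StabilityResults:
    """Fitted stability ranking with per-method diagnostics."""

    model: ReferenceGeneStability
    quantities: RelativeQuantityMatrix
    genorm: GeNormRanking
    variation: PairwiseVariation | None
    normfinder: NormFinderResult
    aggregate: pd.DataFrame

    @property
    def recommended_reference(self) -> str:
        """Gene with comprehensive rank 1."""
        return self.aggregate.index[self.aggregate["comprehensive_rank"] == 1][0]

    @property
    def recommended_n(self) -> int | None:
        return self.variation.recommended_n if self.variation is not None else None

    def recommended_references(self) -> list[str]:
        """Top genes by comprehensive rank, as many as the V criterion suggests."""
        n = self.recommended_n or 1
        order = self.aggregate.sort_values("comprehensive_rank")
        return list(order.index[:n])

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "gene": self.aggregate.index,
            "M": self.genorm.m_values.reindex(self.aggregate.index).to_numpy(),
            "normfinder_stability": self.normfinder.stability.reindex(
                self.aggregate.index).to_numpy(),
            "genorm_rank": self.aggregate["genorm_rank"].to_numpy(),
            "normfinder_rank": self.aggregate["normfinder_rank"].to_numpy(),
            "comprehensive_rank": self.aggregate["comprehensive_rank"].to_numpy(),
        })
        return out.sort_values("comprehensive_rank").reset_index(drop=True)

    def to_dict(self) -> dict:
        d = {
            "ranking": self.to_frame(),
            "most_stable_pair": list(self.genorm.most_stable_pair),
            "exclusion_order": list(self.genorm.exclusion_order),
            "recommended_reference": self.recommended_reference,
            "normfinder": {
                "tau2": self.normfinder.tau2,
                "groups": self.normfinder.groups,
                "single_group": self.normfinder.single_group,
                "sigma2": {g: self.normfinder.sigma2[g].to_dict()
                           for g in self.normfinder.sigma2.columns},
            },
            "efficiency": self.model.efficiency,
        }
        if self.variation is not None:
            d["pairwise_variation"] = {str(n): v for n, v in self.variation.v.items()}
            d["recommended_n"] = self.variation.recommended_n
        return d

    def summary(self) -> str:
        lines = ["Reference-gene stability ranking",
                 "=" * 56,
                 f"{'gene':<16}{'M':>8}{'rho':>8}{'geNorm':>8}{'NormF':>8}{'overall':>8}"]
        for _, row in self.to_frame().iterrows():
            lines.append(f"{row['gene']:<16}{row['M']:>8.3f}"
                         f"{row['normfinder_stability']:>8.3f}"
                         f"{int(row['genorm_rank']):>8d}"
                         f"{int(row['normfinder_rank']):>8d}"
                         f"{int(row['comprehensive_rank']):>8d}")
        lines.append("-" * 56)
        lines.append(f"most stable pair (geNorm): {', '.join(self.genorm.most_stable_pair)}")
        if self.variation is not None:
            vtxt = ", ".join(f"V{n}/{n+1}={v:.3f}" for n, v in self.variation.v.items())
            lines.append(f"pairwise variation: {vtxt}")
            lines.append(f"recommended number of reference genes: "
                         f"{self.variation.recommended_n} "
                         f"(threshold {self.variation.threshold})")
        lines.append(f"recommended reference (comprehensive): {self.recommended_reference}")
        return "\n".join(lines)

    def plot_ranking(self, ax=None):
        """Bar plot of geNorm M (ascending stability), matplotlib axes returned."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3.5))
        m = self.genorm.m_values.sort_values()
        ax.bar(range(len(m)), m.to_numpy(), color="#4878a8")
        ax.set_xticks(range(len(m)))
        ax.set_xticklabels(m.index, rotation=45, ha="right", fontsize=8)
        ax.set_ylabel("geNorm M")
        ax.set_title("Candidate reference-gene stability")
        return ax
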