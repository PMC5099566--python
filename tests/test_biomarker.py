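import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from mirnorm.biomarker import (CollinearityError, adjusted_correlation,
                               group_compare, mann_whitney_auc, optimal_cutoff,
                               roc_analysis)
from mirnorm.quantify import delta_delta_ct

from conftest import make_annotation, make_cq


# ---------------------------------------------------------------------------
# group comparison

def _rel_table(values_by_group, gene="g"):
    """Build a RelativeExpressionTable-like object via a tiny ddCt study."""
    samples, groups, cqs = [], {}, []
    for g, vals in values_by_group.items():
        groups[g] = []
        for i, v in enumerate(vals):
            s = f"{g}{i}"
            samples.append(s)
            groups[g].append(s)
            cqs.append(v)
    ann = make_annotation(groups)
    # choose Cq so that rel_expr equals the requested values exactly:
    # ref = 20 everywhere; dCq = -log2(v); calibrate to a single sample with v=1
    cq = make_cq({"ref": [20.0] * len(samples),
                  "tgt": [20.0 - np.log2(v) for v in cqs]}, samples=samples)
    first_group = list(values_by_group)[0]
    rel = delta_delta_ct(cq, ["tgt"], ["ref"], ann, first_group,
                         calibrator_sample=samples[0])
    scale = values_by_group[first_group][0]
    rel.rel_expr *= scale  # undo calibration so values match exactly
    return rel, ann


def test_anova_matches_textbook_sums_of_squares(rng):
    vals = {
        "a": list(1 + rng.normal(0, 0.25, 10)),
        "b": list(1 + rng.normal(0, 0.25, 7)),
        "c": list(1 - 0.2 + rng.normal(0, 0.25, 10)),  # -0.8 SD effect
    }
    rel, ann = _rel_table(vals)
    out = group_compare(rel, ann, control="a")
    F, p = out.anova.iloc[0][["F", "p"]]

    groups = [np.array(v) for v in vals.values()]
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = 2, sum(len(g) for g in groups) - 3
    F_expect = (ss_between / df_b) / (ss_within / df_w)
    p_expect = stats.f.sf(F_expect, df_b, df_w)
    assert F == pytest.approx(F_expect, abs=1e-8)
    assert p == pytest.approx(p_expect, abs=1e-8)


def test_anova_constant_data_null():
    rel, ann = _rel_table({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]})
    out = group_compare(rel, ann, control="a")
    assert out.anova.iloc[0]["F"] == 0.0
    assert out.anova.iloc[0]["p"] == 1.0


def test_holm_adjustment_step_down():
    from statsmodels.stats.multitest import multipletests

    adj = multipletests([0.01, 0.04], method="holm")[1]
    assert np.allclose(adj, [0.02, 0.04])
    # and the pairwise table uses it within gene
    rel, ann = _rel_table({"a": [1.0, 1.1, 0.9, 1.05],
                           "b": [0.5, 0.55, 0.45, 0.52],
                           "c": [0.97, 1.03, 1.0, 0.99]})
    out = group_compare(rel, ann, control="a")
    pw = out.pairwise.set_index("group")
    raw = pw["p_raw"]
    expect = multipletests(raw.to_numpy(), method="holm")[1]
    assert np.allclose(pw["p_adj"].to_numpy(), expect)


# ---------------------------------------------------------------------------
# ROC / AUC

def test_auc_exhaustive_pair_count_with_ties():
    # cases {3,4,5} vs controls {1,2,3}: 8 wins + 1 tie of 9 pairs
    res = roc_analysis([3, 4, 5, 1, 2, 3], [1, 1, 1, 0, 0, 0], orientation="high")
    assert res.auc == pytest.approx(8.5 / 9)


def test_auc_perfect_and_null():
    perfect = roc_analysis([10, 11, 12, 1, 2, 3], [1, 1, 1, 0, 0, 0])
    assert perfect.auc == 1.0
    null = roc_analysis([1, 2, 3, 1, 2, 3], [1, 1, 1, 0, 0, 0], orientation="high")
    assert null.auc == 0.5


def test_trapezoid_equals_mann_whitney_and_sklearn(rng):
    for _ in range(200):
        n1, n0 = rng.integers(3, 12, 2)
        scores = np.round(rng.normal(0, 1, n1 + n0), 1)  # force ties
        labels = np.array([1] * n1 + [0] * n0)
        res = roc_analysis(scores, labels, orientation="high")
        trap = np.trapezoid(res.curve["tpr"], res.curve["fpr"])
        assert abs(trap - res.auc) < 1e-12
        assert res.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


def test_auc_flip_symmetry(rng):
    scores = rng.normal(0, 1, 30)
    labels = rng.integers(0, 2, 30)
    labels[0], labels[1] = 0, 1
    a = roc_analysis(scores, labels, orientation="high").auc
    b = roc_analysis(-scores, labels, orientation="high").auc
    assert a + b == pytest.approx(1.0, abs=1e-12)


def test_auto_orientation_flips_decreasing_marker(rng):
    cases = rng.normal(-1.0, 1.0, 20)   # biomarker decreases in disease
    controls = rng.normal(1.0, 1.0, 20)
    res = roc_analysis(np.concatenate([cases, controls]),
                       [1] * 20 + [0] * 20)
    assert res.orientation == "low"
    assert res.auc > 0.5


def test_delong_ci_and_p_sane():
    res = roc_analysis([3, 4, 5, 6, 1, 2, 3, 4], [1, 1, 1, 1, 0, 0, 0, 0])
    assert 0 <= res.ci_low <= res.auc <= res.ci_high <= 1
    assert 0 <= res.p_value <= 1
    boot = roc_analysis([3, 4, 5, 6, 1, 2, 3, 4], [1, 1, 1, 1, 0, 0, 0, 0],
                        ci_method="bootstrap", rng=0, n_boot=200)
    assert boot.ci_low <= boot.auc <= boot.ci_high


def test_single_class_rejected():
    with pytest.raises(ValueError, match="both classes"):
        roc_analysis([1, 2, 3], [1, 1, 1])


# ---------------------------------------------------------------------------
# Youden cutoff

def test_cutoff_perfect_separation():
    res = roc_analysis([10, 11, 12, 1, 2, 3], [1, 1, 1, 0, 0, 0])
    assert res.youden_j == pytest.approx(1.0)
    assert res.sensitivity == 100.0 and res.specificity == 100.0


def test_cutoff_tie_rule_prefers_sensitivity():
    # two thresholds tie at J = 2/3; the rule picks sens 100%, spec 66.7%
    res = roc_analysis([3, 4, 5, 1, 2, 3], [1, 1, 1, 0, 0, 0], orientation="high")
    assert res.youden_j == pytest.approx(2 / 3)
    assert res.sensitivity == pytest.approx(100.0)
    assert res.specificity == pytest.approx(200 / 3)
    assert res.cutoff == pytest.approx(2.5)


def test_cutoff_degenerate_identical_scores():
    res = roc_analysis([5, 5, 5, 5], [1, 1, 0, 0], orientation="high")
    assert res.youden_j == 0.0
    assert (res.sensitivity, res.specificity) == (100.0, 0.0)


def test_cutoff_matches_midpoint_brute_force(rng):
    for _ in range(200):
        n1, n0 = rng.integers(3, 10, 2)
        scores = np.round(rng.normal(0, 1, n1 + n0), 1)
        labels = np.array([1] * n1 + [0] * n0)
        res = roc_analysis(scores, labels, orientation="high")
        cases, controls = scores[labels == 1], scores[labels == 0]
        pooled = np.unique(scores)
        best = None
        for t in (pooled[:-1] + pooled[1:]) / 2:
            sens = (cases >= t).mean()
            spec = (controls < t).mean()
            key = (sens + spec - 1, sens, -t)
            if best is None or key > best[0]:
                best = (key, t, sens, spec)
        assert res.cutoff == pytest.approx(best[1])
        assert res.youden_j == pytest.approx(best[0][0])


# ---------------------------------------------------------------------------
# adjusted correlation

def test_no_covariates_reduces_to_pearson(rng):
    x, y = rng.normal(0, 1, 15), rng.normal(0, 1, 15)
    res = adjusted_correlation(x, y)
    r, p = stats.pearsonr(x, y)
    assert res.r == pytest.approx(r, abs=1e-12)
    assert res.p == pytest.approx(p, abs=1e-12)
    assert res.df == 13


def test_identical_vectors_fully_correlated(rng):
    x = rng.normal(0, 1, 10)
    cov = pd.DataFrame({"age": rng.normal(60, 5, 10)})
    res = adjusted_correlation(x, x, cov)
    assert res.r == pytest.approx(1.0)
    assert res.p == 0.0


def test_partial_correlation_matches_matrix_inversion(rng):
    """Residual-method partial r must equal the correlation-matrix-inversion
    formula; cross-checked against pingouin as an independent implementation."""
    import pingouin as pg

    n = 8
    z1, z2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
    x = 0.5 * z1 - 0.3 * z2 + rng.normal(0, 1, n)
    y = -0.4 * z1 + 0.2 * z2 + rng.normal(0, 1, n)
    cov = pd.DataFrame({"z1": z1, "z2": z2})
    res = adjusted_correlation(x, y, cov)

    corr = np.corrcoef(np.column_stack([x, y, z1, z2]), rowvar=False)
    prec = np.linalg.inv(corr)
    r_expect = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
    assert res.r == pytest.approx(r_expect, abs=1e-10)

    df = pd.DataFrame({"x": x, "y": y, "z1": z1, "z2": z2})
    pgres = pg.partial_corr(df, x="x", y="y", covar=["z1", "z2"])
    assert res.r == pytest.approx(float(pgres["r"].iloc[0]), abs=1e-8)
    assert res.p == pytest.approx(float(pgres["p_val"].iloc[0]), abs=1e-8)


def test_partial_correlation_invariant_to_affine_covariates(rng):
    n = 20
    z = rng.normal(0, 1, n)
    x = z + rng.normal(0, 1, n)
    y = z + rng.normal(0, 1, n)
    r1 = adjusted_correlation(x, y, pd.DataFrame({"z": z})).r
    r2 = adjusted_correlation(x, y, pd.DataFrame({"z": 3.0 * z - 7.0})).r
    assert r1 == pytest.approx(r2, abs=1e-12)


def test_collinear_covariates_named(rng):
    n = 12
    a = rng.normal(0, 1, n)
    cov = pd.DataFrame({"a": a, "b": 2 * a + 1})
    with pytest.raises(CollinearityError, match="'b'"):
        adjusted_correlation(rng.normal(0, 1, n), rng.normal(0, 1, n), cov)


def test_insufficient_df_rejected(rng):
    cov = pd.DataFrame(rng.normal(0, 1, (4, 3)), columns=list("abc"))
    with pytest.raises(ValueError, match="complete cases"):
        adjusted_correlation(rng.normal(0, 1, 4), rng.normal(0, 1, 4), cov)
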