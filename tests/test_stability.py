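import numpy as np
import pandas as pd
import pytest

from mirnorm.io import CqMatrix, SampleAnnotation
from mirnorm.simulate import reference_screen_config, simulate_cq_study
from mirnorm.stability import (ReferenceGeneStability, aggregate_rank,
                               cq_to_quantity, genorm_m, genorm_rank,
                               normfinder_stability, pairwise_variation,
                               recommend_n_from_v)

from conftest import make_cq


# ---------------------------------------------------------------------------
# independent oracles

def brute_force_m(q: pd.DataFrame) -> pd.Series:
    """geNorm M by an explicit double loop over gene pairs and samples."""
    genes = list(q.index)
    out = {}
    for j in genes:
        vs = []
        for k in genes:
            if k == j:
                continue
            ratios = [np.log2(q.at[j, s] / q.at[k, s]) for s in q.columns]
            mean = sum(ratios) / len(ratios)
            var = sum((r - mean) ** 2 for r in ratios) / (len(ratios) - 1)
            vs.append(var ** 0.5)
        out[j] = sum(vs) / len(vs)
    return pd.Series(out)


def brute_force_v(q: pd.DataFrame, ranked: list) -> list:
    vals = []
    for n in range(2, len(ranked)):
        nf_n = [np.prod([q.at[g, s] for g in ranked[:n]]) ** (1 / n) for s in q.columns]
        nf_n1 = [np.prod([q.at[g, s] for g in ranked[:n + 1]]) ** (1 / (n + 1))
                 for s in q.columns]
        lr = np.log2(np.array(nf_n) / np.array(nf_n1))
        vals.append(lr.std(ddof=1))
    return vals


def random_q(rng, genes=5, samples=10) -> pd.DataFrame:
    cq = 20 + rng.uniform(0, 8, (genes, samples))
    q = 2.0 ** (cq.min(axis=1)[:, None] - cq)
    return pd.DataFrame(q, index=[f"g{i}" for i in range(genes)],
                        columns=[f"s{j}" for j in range(samples)])


# ---------------------------------------------------------------------------
# Cq -> quantity transform

def test_quantity_constant_cq_gives_one():
    cq = make_cq({"a": [25.0, 25.0, 25.0], "b": [30.0, 30.0, 30.0]})
    assert (cq_to_quantity(cq).values == 1.0).all().all()


def test_quantity_one_cycle_halves():
    cq = make_cq({"a": [20.0, 21.0, 20.0]})
    assert cq_to_quantity(cq).values.at["a", "s2"] == pytest.approx(0.5)


def test_quantity_general_efficiency():
    cq = make_cq({"a": [20.0, 22.0, 20.0]})
    q = cq_to_quantity(cq, efficiency=1.9).values.at["a", "s2"]
    assert q == pytest.approx(1.9 ** -2, abs=1e-12)
    # cross-check via the log domain
    assert np.log(q) == pytest.approx(-2 * np.log(1.9), abs=1e-12)


def test_quantity_missing_cq_rejected():
    cq = CqMatrix(pd.DataFrame({"s1": [20.0], "s2": [np.nan]}, index=["a"]))
    with pytest.raises(ValueError, match="missing_policy"):
        cq_to_quantity(cq)


# ---------------------------------------------------------------------------
# geNorm M

def test_proportional_genes_have_zero_m():
    q = pd.DataFrame({"s1": [1.0, 0.5], "s2": [0.25, 0.125], "s3": [0.5, 0.25]},
                     index=["a", "b"])  # b = 0.5 * a
    m = genorm_m(q)
    assert np.allclose(m, 0.0)


def test_genorm_m_matches_brute_force(rng):
    q = random_q(rng, genes=3, samples=4)
    assert np.allclose(genorm_m(q), brute_force_m(q), atol=1e-10)


def test_genorm_m_scale_and_permutation_invariant(rng):
    q = random_q(rng)
    m = genorm_m(q)
    scaled = q.copy()
    scaled.iloc[0] *= 10.0
    assert np.allclose(genorm_m(scaled), m, atol=1e-12)
    perm = list(rng.permutation(q.columns))
    assert np.allclose(genorm_m(q[perm]), m, atol=1e-12)


# ---------------------------------------------------------------------------
# geNorm ranking and V

def test_rank_two_genes_degenerate(rng):
    q = random_q(rng, genes=2, samples=5)
    r = genorm_rank(q)
    assert r.most_stable_pair == ("g0", "g1")
    assert list(r.ranks) == [1, 2]


def test_rank_constant_matrix_input_order_ties():
    q = pd.DataFrame(np.ones((4, 5)), index=list("abcd"))
    r = genorm_rank(q)
    assert r.exclusion_order == ["a", "b"]  # first-in-input excluded on ties
    assert r.most_stable_pair == ("c", "d")


def test_noisiest_gene_excluded_first_and_iterations_match_oracle(rng):
    cq = 25 + rng.normal(0, 0.3, (5, 12))
    cq[2] = 25 + rng.normal(0, 1.5, 12)  # 5x the noise
    q = pd.DataFrame(2.0 ** (cq.min(axis=1)[:, None] - cq),
                     index=[f"g{i}" for i in range(5)])
    r = genorm_rank(q)
    assert r.exclusion_order[0] == "g2"
    # replay the full iteration independently
    surviving = list(q.index)
    for excluded in r.exclusion_order:
        m = brute_force_m(q.loc[surviving])
        assert m.idxmax() == excluded
        surviving.remove(excluded)
    assert set(surviving) == set(r.most_stable_pair)


def test_pairwise_variation_zero_when_gene_duplicates_nf(rng):
    q = random_q(rng, genes=2, samples=8)
    nf2 = np.sqrt(q.iloc[0] * q.iloc[1])
    q3 = pd.concat([q, (0.3 * nf2).rename("dup").to_frame().T])
    pv = pairwise_variation(q3, ["g0", "g1", "dup"])
    assert pv.v.loc[2] == pytest.approx(0.0, abs=1e-12)


def test_pairwise_variation_matches_brute_force(rng):
    q = random_q(rng, genes=6, samples=9)
    ranked = list(genorm_rank(q).ranks.sort_values().index)
    pv = pairwise_variation(q, ranked)
    assert np.allclose(pv.v.to_numpy(), brute_force_v(q, ranked), atol=1e-10)


def test_recommended_n_rule():
    v = pd.Series([0.21, 0.12, 0.09], index=[2, 3, 4])
    assert recommend_n_from_v(v, 0.15) == 3
    assert recommend_n_from_v(v, 0.05) == 5  # none below -> all G genes


# ---------------------------------------------------------------------------
# NormFinder

def test_single_group_ranks_by_residual_sd(rng):
    n = 40
    y = pd.DataFrame(
        [rng.normal(0, 0.1, n), rng.normal(0, 0.5, n), rng.normal(0, 1.0, n),
         rng.normal(0, 0.7, n)],
        index=["g1", "g2", "g3", "g4"])
    res = normfinder_stability(y, None)
    assert res.single_group
    # ranking equals ranking by centered residual SD (closed-form limit)
    z = y - y.mean(axis=0)
    sd = z.std(axis=1, ddof=1)
    assert list(res.stability.sort_values().index) == list(sd.sort_values().index)
    assert res.ranks["g1"] == 1


def test_constant_centered_gene_is_most_stable(rng):
    groups = pd.Series(["a"] * 6 + ["b"] * 6, index=[f"s{i}" for i in range(12)])
    y = pd.DataFrame(rng.normal(0, 0.8, (4, 12)), columns=groups.index,
                     index=["g1", "g2", "g3", "flat"])
    # make 'flat' exactly the per-sample mean of the others plus a constant:
    # after sample-centering its values are constant within and across groups
    y.loc["flat"] = 0.0
    y.loc["flat"] = y.mean(axis=0) * (4 / 3) + 2.0  # solves flat = colmean + c
    res = normfinder_stability(y, groups)
    assert res.sigma2.loc["flat"].max() == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(res.d.loc["flat"], 0.0, atol=1e-10)
    assert res.ranks["flat"] == 1


def test_group_with_one_sample_rejected(rng):
    groups = pd.Series(["a"] * 5 + ["b"], index=[f"s{i}" for i in range(6)])
    y = pd.DataFrame(rng.normal(0, 1, (3, 6)), columns=groups.index)
    with pytest.raises(ValueError, match="need >= 2"):
        normfinder_stability(y, groups)


def test_normfinder_recovers_designed_stable_gene():
    """One sigma = 0.1 gene with no group bias among sigma = 0.5 genes with
    biases up to 1 cycle must rank first in nearly every seeded study."""
    hits = 0
    for seed in range(25):
        cfg = reference_screen_config(seed)
        cq, ann, truth = simulate_cq_study(cfg)
        q = cq_to_quantity(cq.subset(genes=[g.name for g in cfg.genes]))
        res = normfinder_stability(np.log2(q.values), ann)
        hits += res.ranks["miR-ref"] == 1
    assert hits >= 23


# ---------------------------------------------------------------------------
# aggregate ranking

def test_aggregate_unanimity():
    g = pd.Series({"a": 1, "b": 2, "c": 3})
    n = pd.Series({"a": 1, "b": 3, "c": 2})
    out = aggregate_rank(g, n)
    assert out.loc["a", "comprehensive_rank"] == 1


def test_aggregate_tie_broken_by_lower_m():
    g = pd.Series({"a": 1, "b": 2})
    n = pd.Series({"a": 2, "b": 1})
    m = pd.Series({"a": 0.5, "b": 0.3})
    out = aggregate_rank(g, n, m)
    assert out.loc["b", "comprehensive_rank"] == 1  # equal sqrt(2), lower M wins


def test_aggregate_matches_brute_force_sort(rng):
    genes = [f"g{i}" for i in range(9)]
    gr = pd.Series(rng.permutation(range(1, 10)), index=genes)
    nr = pd.Series(rng.permutation(range(1, 10)), index=genes)
    m = pd.Series(rng.uniform(0.2, 1.0, 9), index=genes)
    out = aggregate_rank(gr, nr, m)
    expected = sorted(genes, key=lambda g: (np.sqrt(gr[g] * nr[g]), m[g]))
    got = list(out.sort_values("comprehensive_rank").index)
    assert got == expected


def test_aggregate_mismatched_gene_sets_rejected():
    with pytest.raises(ValueError, match="different gene sets"):
        aggregate_rank(pd.Series({"a": 1}), pd.Series({"b": 1}))


# ---------------------------------------------------------------------------
# model/results interface

def test_model_fit_deterministic_and_sample_reinsertion_stable(rng):
    cfg = reference_screen_config(3)
    cq, ann, _ = simulate_cq_study(cfg)
    genes = [g.name for g in cfg.genes]
    fit1 = ReferenceGeneStability(cq, ann, genes=genes).fit()
    fit2 = ReferenceGeneStability(cq, ann, genes=genes).fit()
    pd.testing.assert_frame_equal(fit1.to_frame(), fit2.to_frame())
    # removing a sample and re-adding it changes nothing (no hidden state)
    cols = cq.sample_ids
    reordered = cq.subset(samples=cols[1:] + cols[:1])
    fit3 = ReferenceGeneStability(reordered, ann, genes=genes).fit()
    assert fit3.recommended_reference == fit1.recommended_reference
    assert np.allclose(fit3.genorm.m_values[genes], fit1.genorm.m_values[genes])


def test_summary_mentions_pair_and_reference():
    cfg = reference_screen_config(5)
    cq, ann, _ = simulate_cq_study(cfg)
    res = ReferenceGeneStability(cq, ann, genes=[g.name for g in cfg.genes]).fit()
    text = res.summary()
    assert "most stable pair" in text and res.recommended_reference in text
    ranks = res.aggregate["comprehensive_rank"].sort_values()
    assert list(ranks) == list(range(1, len(ranks) + 1))
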