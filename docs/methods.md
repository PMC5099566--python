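# Methods

`mirnorm` implements the statistical workflow behind circulating-miRNA
biomarker studies in serum: sample quality control, selection and stability
ranking of endogenous reference genes, relative quantification of targets, and
diagnostic evaluation. This note documents the models, the defaults and why,
the numerical choices, and what the synthetic-data generator does and does not
emulate.

## Quality control

Serum miRNA measurements are fragile to two technical artifacts.

**Hemolysis.** miR-451a is highly abundant in erythrocytes while miR-23a-3p is
comparatively unaffected by red-cell lysis, so the gap
`ΔCq = Cq(miR-23a-3p) − Cq(miR-451a)` grows when a sample is hemolysed. A
sample is retained iff `ΔCq < 7` cycles — the inequality is strict, so a
sample at exactly 7.0 fails. Both the marker names and the threshold are
configurable (panels differ in whether they assay miR-451a or miR-451a-5p; the
package treats the name as data and performs no alias resolution).

**Spike-in consistency.** A synthetic exogenous control (cel-miR-39) added at
fixed quantity before RNA isolation should yield near-constant Cq across
samples. There is no canonical numeric rule — "stable" spike-in Cq is the
requirement — so the package uses a robust default: a sample passes iff its
spike-in Cq lies within 1.5 cycles of the cross-sample median. The median
makes the check insensitive to the very outliers it is meant to catch; with
fewer than 3 samples the median itself is unstable, so the check warns and
passes everyone. QC runs on raw Cq (the hemolysis markers are themselves
miRNAs, so it must precede normalization), and a sample failing any check is
excluded from every downstream stage.

## Candidate screening (intensity matrices)

Candidates for reference genes are drawn from a two-group expression screen by
three criteria: (1) *highly expressed* — detected in all samples (fraction
configurable) and pooled mean at or above the 75th percentile of gene means;
(2) *not differentially expressed* — two-sided Welch t on log2 intensities
with p > 0.05; (3) *low variation* — the worst coefficient of variation
(max of pooled and per-group SD/mean on the linear scale) ranks among the
`cv_rank_k` (default 10) smallest of the genes passing 1–2. "Highly
expressed" has no field-standard cutoff; the 75th-percentile rule is this
package's operationalization and is exposed as a parameter, as is the choice
of linear-scale CVs. Welch rather than Student t is used wherever a two-group
test appears: it costs little under equal variances and is robust otherwise.

The differential-expression filter flags genes with linear fold change
`FC = mean(case)/mean(control)` at or beyond 2 (or 1/2) AND raw Welch
p ≤ 0.05, computed on `log2(intensity + 1)` (the pseudocount guards zeros).
The boundary is inclusive. No multiplicity correction enters the filter —
this mirrors how such screens are typically thresholded — but
Benjamini–Hochberg adjusted p-values are reported alongside for transparency.
Genes with a zero-mean group have undefined fold change; they are flagged and
excluded from the significant set rather than silently ranked.

## geNorm

Cq values are mapped to relative quantities `Q_gj = E^(Cq_g,min − Cq_gj)` with
amplification efficiency E = 2.0 by default (perfect doubling; per-assay
efficiencies are rarely available for serum panels, and the ranking is
invariant to per-gene rescaling anyway). For genes j, k the pairwise variation
`V_jk` is the sample SD (n−1) of `log2(Q_j/Q_k)` over samples, and the
stability `M_j` is the mean of `V_jk` over all k ≠ j. The ranking excludes the
highest-M gene iteratively, recomputing M on the survivors, until two genes
remain — the most stable pair (they receive ranks 1 and 2 in input order,
since their mutual M is identical by construction). Ties on M anywhere are
broken by excluding the gene earlier in input order; all tie rules are
deterministic.

How many reference genes are enough is decided by the pairwise variation
`V_{n/n+1}`: the SD over samples of `log2(NF_n/NF_{n+1})`, where `NF_n` is the
geometric mean of Q over the top n genes. The recommended n is the smallest
with `V_{n/n+1} < 0.15` (the conventional heuristic; configurable), else all
G genes. Requirements: ≥ 2 genes and ≥ 3 samples for M, ≥ 3 genes for the
iterative ranking and the V series.

## NormFinder

A model-based variance decomposition of log-scale expression (the package
feeds it `log2 Q`, which for E = 2 is Cq up to sign and a per-gene constant —
the algorithm is invariant to both). With I genes, groups g of size `n_g`:

1. Each sample is centered by its mean over the I genes, removing per-sample
   load. Centering couples the genes, so the naive per-gene variance
   `γ²_ig` of the centered residuals is biased; the unbiased estimator is
   `σ²_ig = (γ²_ig − Σ_i' γ²_i'g / (I(I−1))) · I/(I−2)` (derived from
   `E[γ²] = σ²(1−2/I) + mean(σ²)/I`), floored at zero — the floor is a
   small-sample artifact and requires I ≥ 3.
2. The gene×group interaction `d_ig` (the gene's centered group mean minus
   its cross-group mean) measures intergroup bias; it is shrunk toward zero
   empirical-Bayes style: the variance `τ²` of the true interactions is
   estimated by moments (`Σ d²/((I−1)(G−1))` minus the mean sampling variance
   `σ²_ig/n_g`, floored at 0) and each d is scaled by `τ²/(τ² + σ²_ig/n_g)`.
3. The stability value is `ρ_i = mean_g( |d̃_ig| + sqrt(σ²_ig/n_g +
   τ²·(σ²_ig/n_g)/(τ² + σ²_ig/n_g)) )`; lower is more stable. With a single
   group, `ρ_i` is simply the bias-corrected intragroup SD.

The estimator was validated by parameter recovery on simulated studies
(10 genes × 2 groups × 12 samples): the designed stable gene is ranked first
essentially always, and seed-averaged `σ²_ig` estimates sit well inside 25%
relative error of the generating values (the acceptance script reports the
observed numbers). Groups of size 1 are rejected.

## Comprehensive ranking

geNorm and NormFinder ranks are aggregated by the geometric mean of the two
ranks (the RefFinder convention), sorted ascending; ties break by lower geNorm
M, then input order. The rank-1 gene is the recommended single reference and
is the default normalizer for the quantification stage.

## Relative quantification (2^−ΔΔCt)

Per sample, the reference Cq is the arithmetic mean of the selected reference
genes' Cq — identical to using the geometric mean of their linear quantities
as a normalization factor. `ΔCq = Cq_target − Cq_ref`;
`ΔΔCq = ΔCq − mean(ΔCq over calibrator-group samples)`;
`rel_expr = E^−ΔΔCq`. Group-mean calibration makes the calibrator group's
relative expression have *geometric* mean exactly 1 per gene (the arithmetic
mean exceeds 1 by Jensen's inequality); calibrating to a single named sample
is available as an option. With E = 2, `log2(rel_expr) = −ΔΔCq` exactly, and
a constant added to every Cq of one sample cancels — the normalization
contract the simulation tests exercise.

## Biomarker evaluation

**Group tests.** One-way ANOVA across all groups per gene on relative
expression, plus Welch t of each non-control group against the control with
Holm adjustment within gene (the post-hoc procedure is a package choice; no
field standard exists for these small panels). Constant data return F = 0,
p = 1 rather than NaN.

**ROC.** Fully empirical: thresholds sweep the distinct scores; the AUC is
the trapezoid integral of the curve, identically the Mann–Whitney estimator
with ties counted ½. Because circulating biomarkers often *decrease* in
disease, orientation is auto-detected (the score is negated when the raw AUC
is below 0.5) and always reported. The CI and the p-value against AUC = 0.5
use the DeLong paired nonparametric variance; the 95% CI is built on the
logit scale (`logit(AUC) ± 1.96·se/(AUC(1−AUC))`, back-transformed), which
respects (0,1) and has distinctly better small-sample calibration than the
plain Wald interval — at n = 20/20 simulated binormal scores the observed
coverage is ~96% versus ~93%. At AUC exactly 0 or 1 the logit is undefined
and the clipped Wald interval is used. A stratified bootstrap percentile CI
is available for very small samples.

**Optimal cutoff.** Youden's J = sensitivity + specificity − 1, maximized by
exhaustive scan over midpoints between adjacent distinct scores. Ties prefer
higher sensitivity, then the lower cutoff (in oriented-score space). If all
scores are identical the degenerate all-positive rule is reported
(J = 0, sensitivity 100%, specificity 0%). Sensitivity/specificity are
reported in percent.

**Adjusted correlation.** Association between expression and a continuous
outcome (BMD) adjusting for age, weight and height is computed as a partial
correlation by the residual method: regress both variables on the covariates
(with intercept), Pearson-correlate the residuals, and test with
`t = r√(df/(1−r²))`, `df = n − 2 − k`. This coincides with the
correlation-matrix-inversion formula and, at k = 0, with plain Pearson.
Rank-deficient covariate sets raise an error naming the dependent column
rather than returning a silently unstable estimate. (The phrase "multiple
correlation with adjustment" is ambiguous between partial correlation and a
multiple-regression R; partial correlation is implemented as the primary
reading because it yields the signed per-miRNA coefficients such studies
report.)

## Synthetic data

The generator draws `Cq_gj = base_g + effect_g(group_j) + load_j +
latent_coef_g·b_j + ε_gj`, with gene noise `ε ~ N(0, σ_g²)` and per-sample
load `load_j ~ N(0, load_sigma²)` shared by all endogenous genes — the
multiplicative error model qPCR assumes, on the log2-abundance (Cq) scale.
Defaults: load_sigma 0.5 cycles (typical serum input variation), hemolysis
modeled as a 3–8-cycle drop of the RBC-marker gene only (isolating the QC
check), clean-sample marker gap 5 cycles, spike-in at Cq 25 ± 0.15 cycles
independent of load (it monitors isolation, not input). The optional latent
per-sample variable couples biomarker levels to the simulated BMD outcome so
covariate-adjusted correlations have signal. Group effects are in cycles
added to Cq (positive = down-regulated). The intensity generator draws
log-normal intensities (log2 SD 0.3) with configured linear folds in the case
group.

Three presets pin the study designs used in demos and end-to-end tests: an
estrogen-deficiency rodent design (2 groups, n = 8/8), a clinical
three-group design (normal/osteopenia/osteoporosis, n = 19/7/10, with
age/weight/height and BMD means 1.06/0.79/0.58 g/cm²), and a
mechanical-unloading primate design (n = 9/6). The designed reference-gene
recovery study places one stable gene (σ = 0.1 cycles, no group effect) among
nine candidates with σ = 0.5 cycles and case-group biases spanning ±1 cycle.

What the generator does **not** emulate: plate/positional effects, probe
cross-hybridization, amplification-curve artifacts, non-Gaussian heavy-tailed
Cq noise, missing-well mechanisms correlated with expression, and biological
correlation structure among miRNAs beyond the single latent factor. Passing
tests therefore demonstrate correctness of the statistics under the stated
error model, not robustness to every artifact of real serum panels.

## Numerical and degenerate-input choices

- Missing ("Undetermined") wells are NaN; stability and ΔΔCt demand complete
  profiles and direct the user to either drop genes or impute the maximum
  cycle count (default 40) at read time. Neither policy is applied silently.
- All SDs use the n−1 denominator; geNorm needs ≥ 3 samples.
- Welch t on two constant equal groups returns p = 1 (p = 0 if means differ).
- Negative variance estimates (NormFinder, τ²) are floored at zero.
- Every tie rule (geNorm exclusion, candidate CV ranks, aggregate ranking,
  Youden cutoff) is deterministic with input order as the final fallback.
- Reports serialize floats at 6 significant digits; results round-trip within
  that precision.

## Problem sizes

The simulation-backed checks use 100 seeded studies for NormFinder recovery,
200 for the end-to-end comprehensive-ranking recovery, 500 binormal
replicates for CI coverage, 1000 random instances for the AUC/cutoff oracle
equivalences, and 2000 null genes for the type-I-error check of the
differential-expression filter — sizes at which the binomial noise of the
estimated rates is comfortably inside the asserted tolerances.

## Known limitations

- Amplification efficiency is global, not per-assay; the Pfaffl
  standard-curve correction is out of scope.
- geNorm's final pair is reported in input order; the method cannot order the
  last two genes.
- The DeLong p-value is asymptotic; at n of a few per class the bootstrap CI
  is the more honest uncertainty statement.
- The pipeline evaluates one miRNA at a time; multivariable panels and
  longitudinal designs are out of scope.
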