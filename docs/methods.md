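# Methods

`methspec` implements a pan-cancer DNA-methylation specificity analysis: from
per-cancer tumor/normal beta-value matrices to gene biomarkers that each mark
exactly one cancer type, with downstream classification, survival screening,
cross-cohort validation and drug-sensitivity correlation. Because the real
inputs of such a study (450K array cohorts, external validation series, drug
panels) are large and access-controlled, the package ships a synthetic-data
generator with planted ground truth, and every claim the test suite makes is a
claim about recovering that planted structure.

## The specificity model

All quantities are computed on gene-level beta values (unweighted mean of a
gene's promoter-window probes, window [TSS−2000, TSS+500) strand-aware,
0-based, half-open) over **tumor** samples only. For gene *i* and cancer *N*
with S_N tumor samples:

- m_iN — mean beta of gene *i* over cancer *N*'s samples.
- p_iN = m_iN / Σ_N m_iN — the gene's methylation mass distribution across
  cancers (row-stochastic).
- H_i = −Σ_N p_iN log2 p_iN — Shannon entropy of that distribution, in bits,
  with 0·log2 0 := 0. H_i ∈ [0, log2 N]; a point mass gives 0, the uniform
  distribution gives log2 N.
- m̄_N — mean of m_iN over the analysis gene set within cancer *N*.
- SD_iN — sample standard deviation (n−1) of gene *i*'s beta across cancer
  *N*'s samples; C_iN = SD_iN / m̄_N × 100 is the coefficient of variation
  relative to the cancer's gene-average methylation.
- T_iN = (H_i · m_iN) / (C_iN · m̄_N) — the specificity value. The numerator
  rewards high methylation; the denominator penalizes within-cancer
  heterogeneity.
- X̄_i = mean_N T_iN and M_iN = (T_iN − X̄_i) / (T_i,max − T_i,min) — the
  dissociation score. Per gene, Σ_N M_iN = 0 and |M_iN| ≤ 1; the maximizing
  cancer (equivalently argmax T) is the gene's unique assignment.

Two properties deserve honesty. First, the entropy factor points the "wrong"
way for a pure specificity index (a gene equally methylated everywhere has
maximal H); the formula is nevertheless applied exactly as stated, and its
ability to recover planted cancer-specific genes is established empirically —
at default conditions ~96–99% of planted genes are assigned to their planted
cancer, because the m_iN contrast dominates. Second, the C_iN denominator can
occasionally hand the argmax to a cancer where the gene happens to be unusually
homogeneous rather than unusually methylated; this accounts for essentially
all residual assignment misses.

Degenerate inputs: genes with zero total methylation are excluded (p
undefined); genes with a constant T profile are excluded as non-specific;
C_iN is floored at a configurable ε (default 1e−6) so near-constant genes cap
rather than blow up T. A single cancer type is rejected outright — specificity
across cancers needs N ≥ 2.

## Surrounding pipeline

**Preprocessing.** Probes outside the promoter window are dropped; probes with
missing fraction strictly greater than 0.7 are removed (the boundary case, 7
missing of 10, is kept); remaining gaps are filled by KNN imputation over
probes — plain Euclidean distance on jointly observed samples, unweighted mean
of the k = 10 nearest donor probes observed at that sample, ties broken by
probe order. Batch harmonization is a per-probe location-scale adjustment
(standardize within batch, rescale to the pooled mean/SD, clip to [0, 1]): it
removes additive and multiplicative batch offsets and preserves within-batch
ranks, and is deliberately simpler than empirical-Bayes batch correction — no
information sharing across probes, no hierarchical prior, which is adequate
for the constant-offset batch structure the generator produces and is the
documented simplification for real data. Samples are split 7:3 train/test,
stratified within cancer × tissue, half-up rounding, deterministic per seed.

**Differential methylation.** Per cancer, per probe: two-sided Welch t-test
(Satterthwaite df) of tumor vs normal on the training split; zero-variance
probes follow a fixed convention (equal means → t=0, p=1; unequal → p=0
flagged degenerate). Benjamini–Hochberg adjustment runs within each cancer;
a site is significant iff p < 0.05 AND FDR < 0.05 (the conjunction as the
screening rule; the FDR condition dominates). A generic one-sided
hypergeometric gene-set test (BH across sets) stands in for pathway
enrichment; pathway database content is out of scope.

**Feature selection.** Boruta, implemented natively: each iteration appends an
independently permuted shadow copy of every surviving feature, fits a random
forest (200 trees), and scores a hit for each real feature whose
mean-decrease-in-impurity importance exceeds the best shadow's. Accumulated
hits feed two-sided binomial tests (p = 0.5) with Bonferroni correction over
the features still undecided; confirmed features stay in the forest, rejected
ones leave, and features still tentative after 100 iterations are resolved by
comparing their median importance history with the median best-shadow
importance. The forest uses `max_features=1` (fully random split-candidate
choice): with the conventional sqrt(p) sampling, mutually redundant relevant
features split the importance mass and can individually fall below the
max-shadow threshold, which makes an all-relevant selector drop true
positives; single-feature sampling spreads importance across redundant
features and removes that failure mode. Per-cancer confirmed probes map to
genes; the union over cancers intersected with the GPCR-related gene list is
the characteristic gene set scored by the specificity model. A CART decision
tree (Gini, unlimited depth) on each cancer's confirmed probes provides the
tumor-vs-normal test-set AUC.

**Downstream.** Kruskal–Wallis (tie-corrected, χ²_{N−1}) gives the per-gene
pan-cancer overview. Cancer-type diagnosis uses a 500-tree random forest on
the assigned genes with one-vs-rest AUC per class and an unweighted macro
average. Survival screening splits each assigned gene's cancer at the gene's
train-split mean beta and runs a two-group log-rank test (prognostic at
p < 0.05). Cross-cohort validation calls a gene consistent iff its
validation-cohort mean beta peaks in its assigned cancer and a one-vs-rest
Wilcoxon rank-sum test gives p < 1e−4. Drug sensitivity: per drug, ridge
regression (closed form, intercept unpenalized, λ default 1.0) of cell-line
IC50 on gene-wise standardized cell-line expression; coefficients transfer to
sample expression standardized with the cell-line statistics. Gene methylation
is then screened against predicted IC50 by Spearman correlation — t
approximation for n ≥ 10, exact permutation p below that — and a (gene, drug)
pair is a hit iff rho < −0.4 AND p < 0.05, both strict, so rho = −0.4 exactly
is not a hit.

## The synthetic study

Defaults (the study conditions): 8 cancer types, 30 tumor + 15 normal samples
each, 500 genes × 4 probes, 90% of probes inside the promoter window, a
40-gene GPCR panel, 3 planted specific genes per cancer (all inside the GPCR
panel; +0.4 beta in their cancer's tumors), 20 extra differential probes per
cancer (+0.3 tumor vs normal, planted outside the GPCR panel so planted and
noise sets stay disjoint), per-gene baselines uniform on [0.15, 0.45],
Gaussian noise SD 0.05 on the beta scale with clipping to [0, 1], 2% missing
entries, and an independent validation cohort with a +0.1 global batch shift
and a fresh noise draw. Clipping bias is negligible at these settings
(baselines sit ≥ 2 SD from the boundaries) but grows if effects push means
near 0 or 1. Survival times are exponential proportional hazards — hazard
0.05 · exp(γ · r) with r the mean centered beta of the risk genes (one per
cancer), γ default 2, independent exponential censoring — the simplest
generator with known log-rank behavior. The drug panel plants, per drug, a
sparse linear expression→IC50 model over the panel genes plus one designated
specific gene whose methylation negatively drives an effector's expression,
so the designated (gene, drug) Spearman correlation is negative by
construction and all other pairs are null.

What the generator does *not* emulate: probe-type chemistry, SNP-overlapping
probes, copy-number confounding, correlated probe noise within a gene,
non-additive batch effects, informative censoring, and non-linear
drug-response surfaces. Passing tests therefore demonstrate that the
algorithms recover the structure they claim to recover under clean,
well-specified conditions — not that they are robust to every artifact of
real array data.

One power property worth knowing: the survival screen conditions on a single
cancer, where a risk gene's beta varies only by noise (SD ≈ 0.025 at gene
level), so the mean-split hazard contrast is exp(γ·Δ) ≈ 1.1 and few genes are
flagged at default settings. The log-rank machinery itself is calibrated
(type-I ≈ 5% at γ = 0) and powerful when beta genuinely varies (≥90% flag
rate at γ = 2 with betas spread over [0.1, 0.9], n = 200).

## Numerical choices

- Coordinates 0-based; promoter window half-open with the lower bound closed:
  TSS−2000 is in, TSS+500 is out; mirrored via the transcription-direction
  offset on the − strand.
- "Exceeding 70% missing" is strictly greater-than.
- Batch-adjust treats within-batch SD < 1e−12 as constant (scale 1) to avoid
  explosive scale factors from float round-off.
- KNN distance ties break by probe order; donors must be observed at the
  target sample.
- BH via statsmodels; Welch/KW/Spearman/hypergeometric via scipy; log-rank/KM
  via lifelines; forests and trees via scikit-learn. The specificity chain,
  Boruta loop, KNN imputer and closed-form ridge are authored here.
- All randomness flows from integer seeds through `numpy.random.default_rng`;
  independent child streams are spawned per artifact, so the generator is
  byte-reproducible and pipeline stages are individually deterministic.

## Problem sizes

The default configuration (2,000 probes × 720 samples across both cohorts)
runs the full pipeline in about a minute on one core; the repeated-seed
recovery and calibration experiments in the test suite use 20 seeds or 500
replicates and complete in a few minutes. These sizes were chosen as the
smallest at which the binomial error bars of the recovery and type-I checks
are meaningfully tight.
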