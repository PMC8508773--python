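# Methods

This note records the statistical definitions the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that make results
deterministic.

## Input model

The universal input is a genes × samples matrix of quantification-cycle
values (Ct, cycles) with a sample annotation carrying the design factors
cultivar, sample class (tissue or fruit developmental stage) and
biological replicate. Ct must lie in (0, 45] — a 40-cycle protocol plus
headroom; values outside are data errors and are never clipped or imputed
silently. Missing cells are rejected by default; an explicit
`missing="impute"` fills a hole with the gene's replicate mean within the
same (cultivar, sample class) cell, because silent imputation biases every
variance-based statistic downstream. Replicates are individual samples
throughout: stability is assessed on all samples, never on
replicate-averaged profiles (averaging is available upstream if a user
wants it, but it shrinks the very variance the methods measure).

geNorm and NormFinder operate on relative quantities
`Q_gs = E_g^(min_s' Ct_gs' − Ct_gs)` with per-gene calibrator the minimum
Ct, so `max_s Q_gs = 1` exactly. The amplification efficiency E defaults
to 2.0 (perfect doubling) for every gene, the standard assumption when no
dilution-series estimates exist; per-gene values in [1.5, 2.2] are
accepted. BestKeeper operates on raw Ct by construction.

## geNorm

`V_jk = SD_s[log2(Q_js/Q_ks)]` (sample SD, n−1 denominator, as
everywhere in the package) and `M_j = mean_{k≠j} V_jk`. Ranking is by
stepwise elimination: recompute M on the remaining panel, remove the gene
with the largest M, until two genes remain; the final pair is mutually
unresolvable (their M values are identical by symmetry on a 2-gene panel)
and shares rank 1, giving dense ranks 1, 1, 2, …, k−1. Ties in the
maximal M are broken by removing the lexicographically last gene name — a
pure determinism rule with no statistical content, relevant only for
degenerate (e.g. constant) panels.

`NF_n,s` is the geometric mean of the n most stable genes' quantities in
sample s, genes entering in order of ascending full-panel initial M (ties
alphabetical); `V_{n/n+1} = SD_s[log2(NF_n,s/NF_{n+1,s})]` for
n = 2 … k−1, and the optimal reference count is the smallest n with V
below the conventional 0.15 cutoff (reported as "none passes" otherwise,
never silently defaulted). M < 1.5 is reported as an acceptability flag
per gene; no gene is ever dropped because of it.

## NormFinder

Log2 expression is modelled as `y_ij = alpha_i + beta_j + eps_ij` with a
shared per-sample loading beta and gene-specific noise variance σ²_i.
Ungrouped estimator: two-way centering residuals
`r_ij = y_ij − ȳ_i· − ȳ_·j + ȳ_··`, naive variance
`v_i = Σ_j r²_ij/(n−1)`, and the corrected
`σ̂²_i = max(0, k/(k−2)·(v_i − Σ_l v_l/(k(k−1))))`; stability
`S_i = σ̂_i`. The correction removes both the deflation from centering by
means the gene itself contributes to and the leak of other genes' noise
into v_i; the test suite verifies first-order unbiasedness by simulation
(mean σ̂² within a few percent of σ² at k = 12, n = 72) and rank recovery
(Spearman ≥ 0.9 against true σ at k = 10, n = 60).

Grouped estimator: σ̂²_ig per group by the same machinery; gene-by-group
contrasts `d_ig = (ȳ_ig· − ȳ_·g·) − mean_g(·)`; the between-group
variance component `γ² = max(0, Σ d²/((k−1)(G−1)) − mean(σ̂²_ig/n_g))` by
method of moments; shrinkage `d̃_ig = d_ig·γ²/(γ² + σ̂²_ig/n_g)` (zero
when the denominator vanishes); and
`S_i = mean_g(|d̃_ig| + √(σ̂²_ig/n_g))`. Negative variance estimates are
floored at 0 before square roots. k ≥ 3 genes are required (the
correction factor is undefined below); ungrouped mode needs n ≥ 4,
grouped mode ≥ 2 groups of ≥ 2 samples. A zero-variance panel yields all
S = 0 with a warning rather than an error.

Log base 2 is used so S is commensurate with geNorm's log2 ratios; any
base gives identical ranks. Which annotation factor to group by is a user
choice (`normfinder_factor`, default `sample_class`); when a group's
factor degenerates (fewer than two usable levels) the ungrouped model is
used with a warning rather than failing the group.

## BestKeeper

Per-gene n, arithmetic mean, geometric mean, min, max, SD and
CV = 100·SD/mean on raw Ct. The dispersion statistic is the sample SD by
default; the original tool's mean absolute deviation from the arithmetic
mean is available as `sd_mode="mean_abs_dev"` for cross-tool
comparability (for Gaussian noise with distinct σ the two agree on
ranks — asserted in tests). Genes with SD > 1 cycle are excluded from the
index but never from the report; the index is the per-sample geometric
mean Ct of the retained genes, and each gene's Pearson r against the
index comes with a two-sided t-distribution p (scipy). Fewer than two
retained genes is a hard error advising manual selection. Ranks are dense
by ascending SD, row order breaking ties by CV then name.

## Comprehensive ranking

`S_sum = G + N + B` over the three methods' dense ranks (geNorm's shared
top pair contributes 1 each). The plain sum — not a geometric mean of
ranks — is used deliberately: it is the aggregation the screening
literature reports alongside the three columns. Final rank is the dense
rank of S_sum; row order within ties uses ascending geNorm initial M,
then name, and the rule is stated in the output rather than hidden. The
aggregation is permutation-equivariant over gene labels and monotone: a
gene that improves in one method's rank can never worsen in final rank
(both property-tested).

## 2^−ΔΔCt validation

Per sample, `ΔCt = Ct_target − mean(Ct_references)` (arithmetic mean on
the Ct scale = geometric mean on the quantity scale, the field-standard
multi-reference combination); group ΔCt is the mean over the group's
replicates, `ΔΔCt = group ΔCt − calibrator ΔCt`, fold = 2^−ΔΔCt with
perfect doubling assumed (no Pfaffl efficiency correction). Replicate
dispersion is the SD of per-replicate ΔCt, propagated to the fold range
2^−(ΔΔCt ∓ SD). The calibrator defaults to the first fruit stage
(`green_fruit`) and is configurable; it is labelled in every output since
different choices rescale all folds. Divergence between two reference
sets is the maximum over groups of |log2(fold_A/fold_B)| — zero when the
references track loading identically, and approximately the injected
shift when a reference carries a condition-dependent expression change.

## Synthetic screens and what they show

`Ct_is = b_i + δ_i,class(s) − u_s + ε_is` with baselines b_i, fixed
class-specific shifts δ (systematic instability), shared per-sample
loading `u_s ~ N(0, τ²)` entering with a minus sign (more template →
earlier Ct) and gene noise `ε_is ~ N(0, σ²_i)`. Noise is Normal on the
Ct scale (log-scale multiplicative on quantities), the standard qPCR
error model. The loading vector is drawn before the per-gene noise, so
two specs differing only in τ share every ε draw for a given seed —
this makes the method-contrast experiments exactly paired.

The default screen (`default_paper_mimic`) is 12 candidate genes across
4 cultivars × 6 sample classes (3 fruit stages, leaf, stem, stem apex) ×
3 biological replicates = 72 samples. Baselines span 23.5–29.5 cycles so
the generated data cover roughly 22–31 observed cycles; two
designed-stable genes have σ = 0.1, noise grades up through the panel,
and the designed-unstable gene has σ = 1.2 plus a 1.5-cycle
fruit-ripening shift; two mid-panel genes carry smaller tissue shifts so
condition dependence is not confined to the worst gene. The shared
loading SD default is τ = 0.15 cycles, calibrated so the total SD of a
designed-stable gene (≈ 0.18) and its 72-sample Ct range (≈ 0.9 cycles)
match the dispersion that published screens report for their best genes;
larger τ values are exercised explicitly in the loading-contrast tests.
A differentially expressed validation target (ripening-induced, flagged
so it never enters candidate rankings) can be appended for ΔΔCt
demonstrations.

What passing tests on these data do show: correct implementation of each
statistic (verified against independent brute-force oracles), correct
ground-truth recovery under the generative model, and the designed
methodological contrasts (loading cancels in ratio/model-based methods
but not in BestKeeper). What they do not show: robustness to non-Gaussian
error (pipetting outliers, inhibition), technical-replicate structure,
efficiency heterogeneity between genes, or real biological co-regulation
among candidates — none of which the generator emulates.

## Numerical conventions and problem sizes

Sample SD uses the n−1 denominator everywhere. Dense ranking throughout;
every tie-break is deterministic and documented (lexicographic last-out
in geNorm elimination, alphabetical elsewhere). Relative-quantity
exponents are exactly zero at the calibrator sample, so per-gene maxima
are exactly 1. Table round-trips use full float precision
(`float_precision="round_trip"` on read).

Simulation-based checks use 20–100 seeded replicates at the native
12 × 72 screen size (a full three-method run takes ~40 ms), and
parameter-recovery checks use k = 10, n = 60; these sizes give the
recovery rates comfortable margins over their thresholds while keeping
the whole suite under a minute. All random draws flow through
`numpy.random.default_rng` with explicit seeds.

## Known limitations

- NormFinder's grouped contrasts are noisy for very small groups
  (n_g = 3); the estimator remains defined but group-shift detection
  power is limited there, exactly as with the original tool.
- The geNorm optimal-n rule reports "none passes" when no V clears the
  cutoff; it never recommends using all genes implicitly.
- BestKeeper's index correlation is undefined for zero-variance genes;
  such genes are reported as missing with a warning.
- No melt-curve, efficiency-from-dilution, or instrument-format parsing:
  the package starts from a clean Ct table.
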