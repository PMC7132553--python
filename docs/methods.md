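# Methods

## The problem

Case–control association testing on the X chromosome is complicated by three
biological features that autosome methods ignore:

1. **Hemizygosity.** Males carry one X (inherited maternally), females two,
   so a single dose coding cannot be right for both sexes under every
   dosage-compensation regime.
2. **X-chromosome inactivation (XCI).** One female X copy is silenced per
   cell. Inactivation may be random (XCI-R, the mutant allele active in ~50%
   of cells), skewed (XCI-S), or escaped entirely (XCI-E). A homozygous
   female then behaves anywhere between "like a hemizygous male" and "like an
   autosomal homozygote".
3. **Parent-of-origin (imprinting) effects.** A heterozygous female's risk
   can depend on whether the mutant allele came from her father or her
   mother. Detecting this requires *ordered* genotypes — a/A versus A/a,
   paternal allele left of the slash — which in turn requires parental
   genotypes for heterozygous daughters (sons are unambiguous).

This package implements a single robust test, `Z_XCII`, that accommodates all
three without the analyst pre-specifying a genetic model, together with the
retrospective simulator and Monte-Carlo harness used to validate its operating
characteristics.

## Model

For females, with `G_f1`/`G_f2` the mutant-allele counts on the paternal and
maternal copy:

    logit Pr(Y = 1 | G_f1, G_f2, X_f) =
        b_f0 + b_f1 G_f1 + b_f2 G_f2 + b_f3 G_f1 G_f2 + b_f' X_f

The model is saturated on the four ordered genotypes; without covariates the
MLE is the closed form in per-cell log-odds `l_g = log(r_g / s_g)` with the
analytic observed-information covariance `Var(l_g) = 1/r_g + 1/s_g`. With
covariates the same model is fitted by IRLS (statsmodels). Both paths are
exposed and agree to 1e-6 without covariates (tested on 200 random tables).

Two interpretable summaries of the coefficients:

* **XCI degree** `gamma = (b_f1 + b_f2) / (b_f1 + b_f2 + b_f3)`, on [0, 2]
  under the generalized (ordered-penetrance) model: 2 means the mutant allele
  is active in all cells (dominant-like), 1 random inactivation (additive),
  0 a fully silenced mutant (recessive-like). This form reproduces all nine
  degree labels of the simulation grid from their penetrance sets to 3
  decimals, which is how it was validated.
* **Imprinting measure** `b_f2 − b_f1`: zero when parental origin is
  irrelevant, negative under (complete) maternal imprinting, positive under
  paternal.

For males, `logit Pr(Y = 1 | G_m, X_m) = b_m0 + b_m G_m + b_m' X_m`; without
covariates the Wald statistic collapses to the pooled two-sample proportion
statistic `Z_m`, standard normal under the null.

## The component statistics and their whitening

Under the generalized genetic model the female penetrances are ordered
(`phi_f0 <= phi_f01, phi_f10 <= phi_f2`, or all reversed), which makes three
*step contrasts* one-sided:

    c1 = b_f1              (a/a -> A/a)
    c2 = b_f1 + b_f3       (a/A -> A/A)
    c3 = b_f1 + b_f2 + b_f3  (a/a -> A/A)

The raw contrasts share cells and are therefore correlated (about ±0.2 at the
design's operating point), so their one-sided p-values cannot be combined by
Fisher's method directly. We whiten them:

    Z = S^{-1/2} c,   S = Cov(c) from the fitted model,

with the symmetric (eigendecomposition) inverse square root. Z1, Z2, Z3 are
then asymptotically independent standard normals under the null, so

    F_R = −2 Σ log(1 − Φ(Z_i)),   F_L = −2 Σ log Φ(Z_i)

are asymptotically chi-squared with 6 df. Two properties drove the choice of
this particular contrast basis:

* **Exact allele-relabeling equivariance.** Reversing the allele labels
  A ↔ a reverses the four female cells. The step-contrast set maps onto its
  own negation under that reversal (c1 and c2 swap with sign flip through the
  relabeled model's coefficients; c3 is antisymmetric), and permutation
  conjugation commutes with the symmetric matrix square root, so the whitened
  component multiset negates exactly. Consequently the right-sided
  combination of relabeled data *equals* the left-sided combination of the
  original to machine precision — the test cannot depend on which allele the
  genotyping platform happened to call "A". No three-statistic basis aligned
  with the raw coefficient directions (b_f1, b_f2, b_f1+b_f2+2 b_f3) has this
  property; the proof is a two-dimensional-antisymmetric-subspace counting
  argument, and the measured exchange error on random tables is < 1e-12.
* **Calibration.** With whitened components the Fisher statistic passes a
  Kolmogorov–Smirnov test against chi^2_6 at the operating point (p ≈ 0.44 at
  2e4 null replicates), where the unwhitened version fails it decisively
  (p ≈ 1e-13); measured component correlations are below 0.02.

Under alternatives within the generalized model all three contrasts have
non-negative expectation, so evidence concentrates in the right tails (left
tails when the mutant allele is a).

## Combination across sexes and the robust statistic

The female combination p-value is transformed to a normal score
`z_f = Φ^{-1}(1 − p_f)` and merged with the male statistic by sample-size
weighting:

    Z^R = (n_f z_f^R + n_m Z_m) / sqrt(n_f² + n_m²)
    Z^L = (n_f z_f^L − n_m Z_m) / sqrt(n_f² + n_m²)

The denominator makes the weight vector unit-norm, the unique scaling under
which a proportionally weighted sum of independent standard normals is again
standard normal. The minus sign in Z^L reflects that a mutant-a alternative
drives the male allele effect negative. An empty stratum collapses the weight
onto the other component exactly.

When the mutant allele is unknown (the usual case) the test statistic is

    Z_XCII = max(Z^L, Z^R),   p ≈ min(1, 2 (1 − Φ(Z_XCII))).

−Z^L and Z^R are coordinate-wise non-decreasing in the independent components
(Z1, Z2, Z3, Z_m), so the positive-dependence (association) inequality makes
the doubled tail an upper bound on the true p-value: the test is
conservative, never anticonservative, by construction. One-sided variants
(`alternative="right"`/`"left"`) are available when the mutant allele is
known.

### Numerical choices

* Component p-values are clamped at the smallest positive double before
  logging (with a warning); `Φ^{-1}` arguments are clamped into
  [1e-300, 1 − 1e-16].
* **Zero cells.** When any of the eight female cells is empty the
  Haldane–Anscombe correction adds 0.5 to *all eight* cells (uniformity keeps
  the relabeling equivariance); replicates needing it are counted and
  reported, never dropped. At the simulation operating point they are ~7e-5
  of replicates. A strict `zero_cell="error"` policy is available.
* A monomorphic male stratum contributes `Z_m = 0` (no information), with a
  warning.
* Eigenvalues of the contrast covariance must be strictly positive; a
  singular covariance raises a degenerate-fit error rather than silently
  pseudo-inverting.

## Simulator

The simulator reproduces the retrospective design used for validation.
Offspring genotype frequencies come from either random mating — paternal
allele at the fathers' mutant frequency `p_m_par`, maternal at the mothers'
`p_f_par`, sons maternal-only — or, for equal parental frequencies `p`, a
Hardy–Weinberg-disequilibrium model with inbreeding coefficient `rho`
(`g_f0 = (1−p)² + rho p(1−p)`, heterozygote cells `(1−rho) p (1−p)` each,
`g_f2 = p² + rho p(1−p)`). Case and control totals per sex are fixed by
design; female tables are quadrinomial draws from `g · phi / phi_f` (cases)
and `g · (1−phi) / (1−phi_f)` (controls), males binomial analogues.

Defaults follow the reference study conditions: N = 1000 with 500 cases and
500 controls, 1:1 sexes in controls (case sex ratio a design knob: 3:2, 1:1,
2:3), baseline penetrances `phi_f0 = phi_m0 = 0.120`, `phi_f2 = phi_m1 =
0.240` under XCI, parental frequency pairs (0.15, 0.25) … (0.35, 0.25), and
`rho = ±0.05` for the HWD cells.

What the generator does *not* emulate: covariates (the validated design has
none), genotyping error, missing or partially genotyped trios, linkage
between markers, and variable escape from inactivation. Passing Monte-Carlo
checks therefore demonstrate calibration and power under clean
single-marker retrospective sampling, not robustness to those artefacts.

Reproducibility: the single-draw API gives every replicate its own
counter-indexed substream (`SeedSequence(seed, spawn_key=(replicate,))`), so
replicate k is reproducible in isolation; the vectorized batch engine uses
one spawned stream per scenario cell and is byte-reproducible given
(scenario, seed).

## Monte-Carlo harness

`experiments` evaluates scenario grids. The package's own test runs through
a fully vectorized path (stacked count arrays, batched eigendecompositions),
which evaluates one million null replicates in a few seconds on one CPU —
that is what makes size estimation at alpha = 1e-5 routine. Comparators run
per-table. Rejection proportions are reported with both the Wald interval
(`alpha ± 1.96 sqrt(alpha(1−alpha)/reps)`, the convention size tables are
usually footnoted with) and the exact Clopper–Pearson interval.

Measured at the operating point (p = 0.2, random mating, null penetrances,
seed as in the acceptance suite): empirical size 0.6e-5 at alpha = 1e-5 over
1e6 replicates, within the (0.38e-5, 1.62e-5) envelope and on the
conservative side, as the doubled-tail bound predicts.

## Comparators

Thirteen competitor tests are implemented from their originals' standard
definitions for the qualitative comparison: allele-count tests (Z_A, Z_mfA;
valid only under HWE in females), genotype trend tests (Z_C, Z_mfG), the
sex-stratified chi-square S_A, Clayton's shared-coding score tests (T_A,
T_AD), XWAS-style logistic regressions (FM_01, FM_02, FM_F), the
generalized-model categorical test Xcat, and the dosage-compensation maximum
Z_max. For Z_max the three codings are linear in two score sums, so its
max-|Z| p-value is computed exactly from the rank-2 Gaussian by a
one-dimensional slab-intersection integral (validated against the full
trivariate-normal quadrature, and ~700x faster).

Fidelity is to the originals' formulas where stated and to the conventional
choice where the originals allow variants (pooled variances, no continuity
corrections). They are validated by their qualitative signatures: calibrated
size under the HWE null; Z_A's anticonservatism under inbreeding
(rho = 0.05) detected by a paired comparison against Z_C on identical
tables; T_AD's size inflation (~0.22 at alpha = 0.05) when sex-different
allele frequencies meet a 3:2-vs-1:1 case/control sex-ratio imbalance; and
FM_01's numerical equivalence to the additive trend test (p-value
correlation > 0.999).

## Testing-design notes

* `Z_m` is a lattice statistic (male counts out of 500); its exact null CDF
  sits ~0.023 in sup-norm from the continuous normal (point mass ≈ 0.045 at
  zero). A KS test against N(0,1) is therefore only meaningful while its
  detection threshold exceeds the lattice deviation, so the male KS check
  uses 1000 replicates (0.1% critical value ≈ 0.062); the continuous
  statistics (Fisher chi^2_6, Z^R) are KS-tested at 1e4 replicates.
* The qualitative power orderings are checked at alpha = 1e-3 with 1e3
  replicates per cell: complete maternal imprinting vs the matched
  no-imprinting scenario (gamma ≈ 1, a ~0.11 power gap), and the frequency
  ordering on the incomplete-maternal scenario (phi_f01, phi_f10) =
  (0.144, 0.204), whose gap between the p = 0.2 and p = 0.3 rows (~0.05)
  cleanly exceeds Monte-Carlo noise at that replicate count.

## Known limitations

* Qualitative (binary) traits only; quantitative traits would need the
  linear-model analogue.
* Common variants only: with rare alleles the cell log-odds degenerate and
  the asymptotics fail (a rare-variant aggregation approach would be needed).
* The phase-resolution step drops heterozygous daughters whose phase the
  available parents cannot determine (and reports the count); it does not
  impute phase.
* Escape from inactivation is treated as all-or-none through the generalized
  model; per-cell variable escape is outside the model.
* The 2-xi p-value is an upper bound, so the test gives away a little size
  (measured 0.6e-5 at a nominal 1e-5); exact calibration would require
  resampling.
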