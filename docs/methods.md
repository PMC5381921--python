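# Methods

## Model and estimation

The phenotype of individual i (a de-regressed breeding value, DRP) is
modelled as y = 1μ + Zu + Zw + e with Var(u) = Gσu², Var(w) = Qσw²,
Var(e) = Iσe², Z = I (one record per individual).  G and Q are IBS kinship
matrices on the half-dosage coding (0/0.5/1): the pairwise kinship is
f_ij = (1/n)Σ_k (g_ik − p_k)(g_jk − p_k)/(p_k(1 − p_k)) with p_k the
major-allele frequency; the mixed-model matrices carry 2f_ij off the
diagonal and 2f_ii on it.  Since the coding's Hardy–Weinberg variance is
p(1−p)/2, E[2f_ii] = 1 + F, so the diagonal is "one plus the inbreeding
coefficient" without importing an external inbreeding estimator — a
self-consistent choice that also makes 2f algebraically identical to the
VanRaden-standardised 0/1/2 cross-product (verified element-wise in the
test suite).  Allele frequencies for both G and Q are the post-QC
whole-sample frequencies (frequencies are defined once, not per window);
missing genotypes are mean-imputed (centred contribution zero) inside the
GRM only.  G includes the window SNPs by default even when Q is fitted
alongside; an exclude-region option exists (see "Parameter recovery"
below for when it matters).

Restricted likelihood (intercept profiled out):

    logL_R = −½[(n−1)log 2π + log|V| + log|1'V⁻¹1| + y'Py]

with V = σu²G + σw²Q + σe²I.  Constants are kept so nested-model
differences are valid LRT statistics.  Optimisation is average-information
REML: AI update with step halving (25 halvings max), EM-REML fallback when
the AI step fails or does not improve, convergence when the log-likelihood
change is < 1e-6 (with a relative-parameter-change check at 1e-8), at most
200 iterations.  Negative variance proposals are projected to zero;
components pinned at zero with a non-positive score are frozen and the
rest re-optimised — this boundary handling is what makes the 50:50 mixture
the correct null.  Single-genomic-component (null) fits take an exact path
through the eigendecomposition of G, profiling σe² and optimising the
variance ratio on a log grid plus bounded refinement, with the ratio-zero
boundary checked explicitly; the two paths agree to ~1e-7 and the null fit
is computed once per trait and reused across windows.  Starting values:
σe² = half the phenotypic variance, genomic components splitting the
remainder equally; window fits start from the null estimates with a small
positive regional variance.  BLUPs are û = σ̂u²G·Py etc., so
û + ŵ + ê = y − 1μ̂ holds exactly.  A configurable ridge (default 1e-6)
is added to GRM diagonals before REML for numerical safety.  Degenerate
input (zero-variance y) is rejected, not fitted.

## Scan, testing, thresholds

Windows of w SNPs (defaults 100, 20, 10) slide by w/2 within chromosomes;
if the regular grid does not end at the chromosome's last SNP, one
end-anchored window covering the final w SNPs is appended; chromosomes
shorter than w yield a single whole-chromosome window.  On the 29-autosome
array layout (40,646 post-QC SNPs) this yields exactly 798 size-100
windows.  LRT = 2(logL1 − logL0), clamped at zero (raw negatives beyond
−1e-6 are logged; values below 1e-8 are treated as the point mass).  The
mixture survival simplifies to 0.5·Pr(χ²₁ > x) = Φ(−√x), so the
Bonferroni threshold is ndtri(α/N)² in closed form and genome-wide
−log10 P = −[log N + log Φ(−√LRT)]/ln 10 is computed via the log-space
normal tail, which stays accurate far below double-precision underflow
(LRT = 210.9 → p ≈ 1e-48).  Bonferroni N defaults to the actual window
count; an override reproduces the rounded 800/4,000/8,000 convention.
The regional share is reported as 100·σ̂w²/(σ̂u² + σ̂w²).

## QC and single-SNP association

Markers are removed when MAF < 1%, call rate < 95%, or HWE p < 1e-6 —
strictly-below comparisons, complete-case per SNP.  The HWE test is the
exact conditional test (enumeration of heterozygote counts given allele
counts, two-sided by summing tables no more probable than the observed); a
chi-square variant is available behind a flag.  The exact test was chosen
because it is the array-QC field standard and fully enumerable for test
oracles; the call-rate filter is per-SNP (a per-individual variant would be
a separate pass and is not applied by default).

GRAMMAR association regresses the null-model residuals ê = y − 1μ̂ − û on
each SNP dosage (complete-case), F on (1, n_complete − 2) df.  Residuals
are not re-scaled (no GRAMMAR-gamma), so tests are mildly conservative —
accepted, documented behaviour of the original two-step procedure.  The
per-SNP −log10 p switches to the log-space normal tail when the F survival
function underflows.  Genome-wide cutoffs are −log10(α/m) over the m
tested SNPs.

## Synthetic data

The generator emulates a progeny-tested dairy-sire dataset, not any real
accession: 29 chromosomes with SNP counts proportional to the 50K-array
layout (desk-scale default ~2,000 SNPs, n = 1,000), allele (minor)
frequencies uniform on [0.05, 0.5], Hardy–Weinberg genotypes, optional
first-order Markov LD via a Gaussian copula on haplotypes (off by default:
linkage equilibrium does not affect the model-fitting contracts, but the
option lets a regional signal spread over neighbours as in real data),
and optional missingness.  Trait architecture: per-SNP effects drawn
multivariate-normal across traits — correlation +0.85 for the polygenic
background over all non-window SNPs, and a signed structure (−0.9 between
FAT and MLK/PRT) for the 20-SNP window on chromosome 14 — then genetic
values are rescaled so each trait's realized variance equals its target
exactly, removing one source of Monte-Carlo noise from recovery tests.
Default variance magnitudes follow the mapped dairy window (whole 5009.6 /
485.6 / 393.2; regional 240.9 / 42.7 / 6.0 kg²).  Residual noise is
homoskedastic with default variance (whole + regional)/9, i.e. DRP
reliability ≈ 0.9, appropriate for sires averaged over > 50 daughters;
reliabilities are not reported per sire, so heteroskedastic weighting is
deliberately unmodelled.  What the generator does **not** emulate: real LD
decay and allele-frequency spectra, selection-induced negative LD (the
antagonism is injected through the regional effect correlation, not
evolved), pedigree/half-sib family structure.  Passing tests therefore
certify the estimator's statistical properties under the assumed
architecture, not reproduction of any real dataset's values.

## Calibration and recovery experiments (tests/test_acceptance.py)

Problem sizes were chosen to keep the whole suite at desk scale.

* **Null calibration** — 200 replicates, n = 500, a 500-SNP chromosome,
  one 20-SNP window, no regional signal: the LRT's point mass at zero must
  lie in 0.5 ± 0.08 and the positive part must match χ²₁ (KS at 1%).
* **Parameter recovery** — 50 replicates, n = 1,000, 1,000 SNPs, a 20-SNP
  window generating an 8.1% regional share: mean absolute bias of the
  fitted share < 2 points.  These fits exclude the window SNPs from G: at
  this scaled-down SNP count the window is 2% of an all-SNP G, which
  absorbs regional variance and biases the share by ≈ −3 points — a
  small-m artifact (0.05% at the real array's 40,646 SNPs), so recovery is
  assessed under the well-specified model.  The scan default keeps the
  all-SNP G.
* **Sign recovery** — 20 replicates, n = 1,000, ~800 SNPs, regional
  correlation ±0.9, polygenic +0.85, and a common ~8% regional share per
  trait: the BLUP correlation matrix must show negative regional
  FAT-vs-others entries and an all-positive whole-genome block in ≥ 90% of
  replicates.  The common share (rather than the unequal defaults, under
  which the smallest component is ~1.5% and collapses to the boundary at
  desk-scale n) makes every trait's window estimable, mirroring the real
  study where all three windows were decisively significant at n = 2,590.
* **Oracle equivalence** — restricted likelihoods against the direct
  projection-matrix formula and BLUPs against explicitly solved
  mixed-model equations on n ≤ 30 instances, to 1e-6.

## Known limitations

Univariate REML only (the effect correlations are correlations of
univariate BLUPs, by design); fixed effects beyond the intercept are not
supported; no permutation or FDR thresholds (Bonferroni within the mixture
null only); BLUP effect correlations are attenuated by shrinkage relative
to true effect correlations (visible in the worked example: a −0.9
generating regional correlation yields BLUP correlations around −0.2 to
−0.8 depending on window signal strength); per-window fits are sequential
(they are embarrassingly parallel, but identical results regardless of
execution order are guaranteed by construction).
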