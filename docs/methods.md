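# Methods

This note documents the models, conventions and numerical choices behind
`lmp2ms`, and what the synthetic generators do and do not emulate.

## Digestion kinetics

Substrate decay is modelled as a first-order reaction, S(t) = S₀·e^(−K₁t),
with K₁ in min⁻¹. The fit is ordinary least squares of ln S(t) on t over
timepoints with positive signal. With multiplicative (lognormal) measurement
error this log-linear fit is the maximum-likelihood estimator, it has a
closed form, and it cannot fail to converge — which is why no nonlinear
refinement is offered. K₁ is reported with the regression standard error of
the slope and the R² of the log-linear fit.

Conventions and edge cases:

* K₁ is constrained to be non-negative; an upward signal drift fits as
  "no decay" (K₁ = 0) with a logged warning.
* Timepoints with zero signal are dropped from the log fit (the log is
  undefined) but retained for consumption calculations; at least three
  positive-signal timepoints are required.
* The fraction of substrate consumed at time t is 1 − S(t)/S(0) using
  *observed* signals, clamped to [0, 1]. Using the observed S(0) rather than
  the fitted S₀ keeps the quantity model-free, and makes the per-set
  detector factor cancel exactly.

## Specific production

SP = 1000 · fragment_signal / (S(0) − S(t)). Because numerator and
denominator come from the same run, the detector scale of the degradation
set cancels; SP estimates a fragment-per-consumed-substrate yield up to a
fragment-specific ionization factor. The factor of 1000 is cosmetic.

Samples are compared only at matched substrate consumption, in half-open
bins [0, 0.25), [0.25, 0.35), [0.35, 0.50); samples at ≥50% consumption are
excluded so that re-entry of products into the proteasome core stays
negligible (excluded, not modelled). The boundary convention (0.25 falls in
the middle bin, 0.50 is excluded) makes the bins a partition of [0, 1].

Cross-set comparisons go through within-set standardization: a z-score per
degradation set × fragment using the sample (n−1) standard deviation. Sets
with fewer than two estimates, or zero variance, pass through
unstandardized with a warning rather than failing the run. Group
comparisons can run on raw or standardized SP (both surfaces exist); the
*percent decrease*, 100·(1 − mean SP of H-carriers / mean SP of
non-carriers), is always computed from raw SP so it reads directly as a
yield ratio.

Tests: two-sided Student t with pooled variance for the H-carrier contrast
(Levene's mean-centred test is run first and its p recorded; a Welch variant
sits behind a flag), permutation one-way ANOVA for the three-genotype
contrast, and Mann–Whitney U for the PA28 effect with one value per
preparation (its mean retained-bin SP).

## Permutation and exact tests

The permutation ANOVA shuffles group labels and counts arrangements with
F* ≥ F. When the number of distinct label arrangements is at most 10⁶ it
enumerates all of them (p = hits/total, no estimator bias); otherwise it
draws 10,000 permutations by default and uses the add-one estimator
(1 + hits)/(n + 1), which cannot return zero. Numerical ties in F are
resolved with a relative tolerance of 1e−12 so that exact-null data give
p = 1 rather than a float accident.

The Mann–Whitney test enumerates all C(n, n₁) group assignments of the
pooled observed values for total n ≤ 24, which handles ties naturally
because tied ranks are permuted along with the values; the two-sided p
counts assignments with |U₁ − n₁n₂/2| at least the observed deviation.
The reported U is min(U₁, U₂), the conventional tabled statistic. Larger
samples use the tie-corrected normal approximation.

The Monte Carlo χ² test samples contingency tables with exactly the
observed margins (Patefield's sequential conditional algorithm, via
`scipy.stats.random_table`) and applies the same add-one estimator,
reporting the Monte Carlo standard error √(p(1−p)/n).

## Association conventions

* Odds ratios use the (case_g1 · control_g2)/(case_g2 · control_g1)
  convention with Woolf log-scale CIs at z = 1.959964. Woolf intervals are
  the package's single CI method; exact conditional intervals are
  deliberately not offered, keeping one well-defined convention.
* If any 2×2 cell is zero, Haldane's +0.5 is added to all four cells and
  the result is flagged. Real genotype tables never trigger it; synthetic
  edge cases must behave deterministically.
* Pearson χ² is uncorrected (no Yates continuity correction) with
  df = (r−1)(c−1); the Hardy–Weinberg test compares observed genotype
  counts with p², 2pq, q² at the observed allele frequency, df = 1.
  A monomorphic sample is reported as trivially in equilibrium.
* Display rounding (ORs/CIs to 3 decimals, percentages to 1, ages to 2) is
  applied only at the reporting surface; tests and intermediate computation
  keep full precision.

## Linkage disequilibrium

Haplotype frequencies for two biallelic loci are estimated by EM over the
single ambiguous genotype class, the double heterozygote: the E-step splits
it between coupling (AB|ab) and repulsion (Ab|aB) phases in proportion to
the current frequency products, the M-step recounts haplotypes. Iteration
starts from linkage-equilibrium frequencies, stops when the log-likelihood
improves by less than 1e−10 (or at 1000 iterations), and asserts the EM
monotonicity property at every step. The two-locus likelihood in this
parametrization is well behaved, so a single deterministic start suffices.

From fitted frequencies: D = p_AB − p_A·p_B; D′ = D/D_max with D_max the
usual sign-dependent bound, and D′ defined as 0 when D = 0 so the statistic
is total; r² = D²/(p_A p_a p_B p_b). Significance uses χ² = 2n·r² on one
degree of freedom, treating the 2n estimated gametes as chromosomes.

Carrier-status markers (HLA-A*02, DRB1*15 carried yes/no) are dominant:
they do not reveal allele counts. They are coded as single-copy
heterozygotes (yes → 1, no → 0), an approximation that is reasonable at
moderate allele frequencies where most carriers are heterozygous; D′ and r²
against such a marker should be read as order-of-magnitude statements.

## Synthetic generators

**Genotype populations.** Subjects are drawn i.i.d.: sex and the two HLA
carrier flags as Bernoulli variables, the LMP2 genotype as two binomial
allele draws (hence Hardy–Weinberg proportions at the configured H-allele
frequency), and disease status from a logistic model whose log-odds add a
baseline to the logs of the configured odds ratios — DRB1\*15 (default
OR 2.525, risk), A\*02 (0.671, protective), and the HH-genotype effect
(0.443) applied only inside the female × A\*02-carrier stratum. Defaults
(H-allele frequency 0.36, ~48% female, ~50% A\*02 carriers, 25% DRB1\*15
carriers) match the control population the association arm analyses. Onset
ages for cases are normal (mean 30.5 y, SD 10, truncated at 18). A
rejection-sampling wrapper (`simulate_case_control`) samples by status for
fixed case/control totals, the way a case-control study actually recruits.
Because the configured ORs are conditional logistic effects, the realized
*marginal* stratum OR is very slightly attenuated by mixing over DRB1\*15;
at the default effect sizes this is well under the sampling noise of any
desk-scale run.

**Digestion experiments.** Each preparation × PA28 condition is one
degradation set with a lognormal detector factor B (σ = 0.3 by default).
Substrate follows B·S₀·e^(−K₁t) with K₁ = 0.005 min⁻¹, tripled when PA28 is
present; fragments follow B·y·S₀(1−e^(−K₁t))·ε with fragment yields y
(flank 1–9: 0.30, epitope 10–18: 0.25, flank 19–28: 0.20) and multiplicative
lognormal noise ε (σ = 0.15) on the fragment channel. PA28 doubles the
epitope yield; the H-carrier ratio (default 0.712, i.e. a 28.8% decrease)
attenuates the epitope yield of RH/HH preparations only when PA28 is
present — exactly the effect structure the SP pipeline is built to detect.
Default sampling times (0–120 min) place samples in all three consumption
bins under both rate regimes. Nine preparations are simulated by default,
3 per genotype: the real study's genotype breakdown among its nine cell
lines is not public, so 3/3/3 is a declared default, not an inference.

Noise is multiplicative and lognormal because mass-spectrometry signal CVs
scale with intensity and signals must stay positive; placing the per-signal
noise on the fragment channel (the substrate curve carries only the batch
factor) reflects that substrate quantification is the better-conditioned
measurement and keeps consumption-bin assignment well defined. What the
generator deliberately does *not* emulate: raw spectra, fragment-specific
ionization beyond a static yield factor, product re-entry kinetics (the
≥50% exclusion exists precisely so this can be ignored), or correlated
drifts within a run. Passing recovery tests therefore show that the
pipeline estimates what the model injects — not that real digests satisfy
the model.

All randomness descends from a single user seed through named
`SeedSequence` substreams (sex, genotype, status, batch, noise, …), so each
stage is reproducible independently of how many draws the others consume.

## Problem sizes

Default analyses run at the study's own scale (hundreds of subjects per
stratum; 9 preparations × 2 conditions × 7 timepoints). Calibration checks
use what each estimate needs: recovery of the epitope-SP decrease averages
a few hundred replicate simulations (the per-replicate spread at nine
preparations is several percentage points); type-I calibrations use 500
replicates, putting three binomial standard errors at about ±2.9 points
around the nominal 5%.

## Known limitations

* The pooled-variance t test is the default even though Levene's check is
  only recorded, not acted on; switch to Welch explicitly where variances
  differ.
* Exact Mann–Whitney enumeration is O(C(n, n₁)) and capped at n = 24.
* The EM LD estimator assumes random mating within the sample used
  (controls, in the reporting pipeline) and gives no per-subject phase.
* The logistic disease model has no interactions beyond the stratum-gated
  HH effect and no covariate correlation; it is a calibration instrument,
  not an epidemiological model of multiple sclerosis.
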