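# lmp2ms

Analysis toolkit for the immunoproteasome **LMP2 R60H** polymorphism: how it
changes the in-vitro generation of the multiple-sclerosis–associated myelin
basic protein epitope MBP₁₁₁₋₁₁₉, and how the LMP2 60HH genotype associates
with multiple sclerosis in a stratified case-control study.

It is aimed at researchers in immunogenetics and antigen-processing who want
a reproducible, tested implementation of both analysis arms — plus synthetic
generators for each data kind, so every stage can be exercised without access
to patient data or mass-spectrometry runs.

## What it computes

**Digestion arm.** A 28-mer MBP substrate (MBP₁₀₂₋₁₂₉,
`PSQGKGRGLSLSRFSWGAEGQRPGFGYG`) is digested by purified 20S
immunoproteasomes with or without the PA28-αβ activator. The toolkit fits
first-order kinetics

> S(t) = S₀ · e^(−K₁ t)

by log-linear least squares, and quantifies epitope generation with the
*specific production* statistic

> SP = 1000 · (fragment signal) / (signal of substrate consumed),

an estimate of epitope molecules produced per digested substrate molecule.
Samples are matched on the fraction of substrate consumed (bins <25%,
25–35%, 35–50%; ≥50% excluded to keep product re-entry negligible), MS
signals are z-scored within each degradation set, and groups are compared
with Student *t* (H-carrier vs RR, after Levene's homogeneity check),
permutation one-way ANOVA (RR/RH/HH), and an exact Mann–Whitney *U*
(PA28 effect).

**Genetics arm.** Stratified case-control tables (status × RR/RH/HH, by sex
and HLA-A\*02 carriage) are analysed with odds ratios and Woolf
log-scale 95% CIs

> OR = (a·d)/(b·c),  CI = exp(ln OR ± 1.96·√(1/a + 1/b + 1/c + 1/d)),

Pearson χ² with Monte Carlo p-values (tables resampled with fixed margins),
Hardy–Weinberg χ² tests, cohort-homogeneity checks, permutation ANOVA of
onset age, and pairwise linkage disequilibrium (EM haplotype frequencies,
Lewontin's D′ and r²).

## Worked example

```python
import pandas as pd
from lmp2ms import CaseControlAssociation

counts = pd.DataFrame([[26, 146, 165], [32, 80, 90]],
                      index=["case", "control"], columns=["HH", "RH", "RR"])
res = CaseControlAssociation.from_counts(
    counts, stratum={"sex": "female", "a02": "yes"}).fit(n_reps=100_000, seed=1)
print(res.summary())
```

```
Case-control association (sex=female, a02=yes)

  HH: cases 26 (7.7%)  controls 32 (15.8%)
  RH: cases 146 (43.3%)  controls 80 (39.6%)
  RR: cases 165 (49.0%)  controls 90 (44.6%)
  overall chi2 = 8.686 (df 2), p = 0.013, MC p = 0.0133 (n_reps 100000, seed 1)
  HH vs RR: OR = 0.443 (0.249-0.790), p = 0.005
  HH vs RH: OR = 0.445 (0.248-0.799), p = 0.006
  RH vs RR: OR = 0.995 (0.684-1.448), p = 0.981
  HWE: cases chi2 = 0.655 (p = 0.418); controls chi2 = 3.778 (p = 0.052)
```

Read: among HLA-A\*02-carrier women, the HH genotype is about half as common
in cases as the odds model expects (OR 0.443, CI excluding 1, p = 0.005) —
a protective association — while RH vs RR shows nothing (OR ≈ 1); both
status groups are compatible with Hardy–Weinberg proportions.

The digestion arm works the same way from a model object:

```python
from lmp2ms import DigestionSimConfig, DigestionStudy, simulate_digestion

sim = simulate_digestion(DigestionSimConfig(seed=1))   # 9 preparations, ±PA28
print(DigestionStudy(list(sim)).fit(seed=1).summary())
```

```
Digestion study

K1 by genotype (PA28 present): F = 0.000, p = 1.000
PA28 effect on SP(1-9): U = 35, p = 0.6665 [exhaustive]
PA28 effect on SP(10-18): U = 0, p = 4.114e-05 [exhaustive]
PA28 effect on SP(19-28): U = 22, p = 0.1135 [exhaustive]
H-carrier effect, pa28_present, bin lt25: t = -1.47, p = 0.1843, decrease = 12.9%
H-carrier effect, pa28_present, bin b25_35: t = -2.13, p = 0.07033, decrease = 22.7%
H-carrier effect, pa28_present, bin b35_50: t = -8.95, p = 1.26e-07, decrease = 42.8%
H-carrier effect, pa28_absent, bin lt25: t = 0.49, p = 0.6251, decrease = -2.7%
H-carrier effect, pa28_absent, bin b25_35: t = 3.05, p = 0.01862, decrease = -27.3%
H-carrier effect, pa28_absent, bin b35_50: t = 0.27, p = 0.7936, decrease = -2.9%
```

Read: the degradation rate K₁ does not differ by genotype; PA28 raises the
epitope's specific production (complete rank separation, exact U = 0); and
with PA28 present the H-carrier preparations show a lower epitope SP. With
only nine preparations a single synthetic experiment fluctuates bin by bin
(the generator's true decrease here is 28.8% in every bin); averaging over
replicate simulations recovers it — that is what `scripts/acceptance.py`
does.

A `lmp2ms` command-line interface wraps the same pipelines
(`simulate-genotypes`, `simulate-digestion`, `associate`, `digest`, `hwe`,
`ld`, `report`).

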