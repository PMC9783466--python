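# Methods

This note documents the models, estimators, numerical choices and synthetic-data
design behind `cagefit`, and what the test suite does and does not establish.

## Reproduction–selection model (`cagefit.popgen`)

One locus, two alleles (R1, R2), three genotypes. Generation 0 is the F1 adult
cohort (100% R1R2, gamete p₁ = 0.5). For each generation i ≥ 1:

1. larval frequencies = Hardy–Weinberg expansion of the previous gamete pool;
2. viability selection with w = (1, 1 + h·s, 1 + s);
3. gamete frequencies from the post-selection adults.

Assumptions: discrete non-overlapping generations, random mating, no drift
(infinite effective size), no mutation or migration, constant fitnesses. h and s
are each constrained to [−1, 1]; within that box all fitnesses are non-negative,
and any pair implying a negative heterozygote fitness is rejected.

**Sampling stage.** Observed counts are matched to the *larval* (pre-selection)
frequencies, because genotyping is done on second-instar larvae while selection is
modelled between the larval and adult stages. Generation indices in input tables
are 1-based on this scheme: generation 1 larvae are always at HWE(0.5), so a lone
generation-1 sample carries no information about selection (a property the tests
exploit). Missing generations simply contribute nothing to the likelihood.

**Likelihood.** L(h,s) = Σ_g Σ_i n_gi ln f_gi over observed records, summed across
cages, which share one (h, s) and the same founding state. A genotype observed
where the model predicts frequency zero returns −∞ rather than raising: the random
search must be able to discard impossible parameter pairs silently.

**Closed-form equilibrium.** For over/underdominant fitnesses the internal
equilibrium p₁* = (w₁₂ − w₂₂)/(2w₁₂ − w₁₁ − w₂₂) serves as an independent oracle
for trajectory convergence tests. In the (h, s) parametrization the overdominant
sector is exactly {h < 0, s < 0}.

**Endpoint test.** The final-generation allele frequency is tested against 0.5
with a one-sample chi-square proportion test (2 alleles per individual, 1 df).
The default applies no continuity correction; a flag enables the Yates-corrected
variant, which is also what the exact-binomial oracle test uses (at n = 200
alleles the corrected statistic tracks the exact two-sided binomial tail within
10%, the uncorrected one does not).

## Maximum-likelihood fit (`cagefit.mlfit`)

Two-stage uniform random search: stage 1 draws (h, s) uniformly over the
admissible box (default the full [−1,1]²), stage 2 redraws in a ±0.1 box around
the stage-1 optimum, clipped to the global bounds. Defaults are 100,000 + 1,000,000
evaluations; `SearchConfig.fast()` (10,000 + 100,000) is the desk-scale setting
used throughout the test suite. The ±0.1 half-width is wide enough to contain the
1.96 level set at the study's design sizes while concentrating most evaluations
near the optimum; it is configurable.

One master seed is split into independent child streams for the two stages
(`numpy` `SeedSequence.spawn`), so changing one stage's evaluation count never
changes the other stage's draws. Argmax ties break by first occurrence in draw
order. The batch likelihood is evaluated in 65,536-pair chunks to bound memory.

**Support limits** are per-parameter extremes over the pooled sampled cloud among
points with logL ≥ max − 1.96 (the χ²(1)/2 profile approximation to a 95% CI).
They are marginal, not a joint confidence region. Limits for the derived
fitnesses w₁₂ = 1 + h·s and w₂₂ = 1 + s are the extremes of those transformed
values over the same qualifying cloud.

**Estimator behaviour.** The likelihood surface is a curved ridge in (h, s):
trajectories mostly constrain the equilibrium frequency and approach rate, so
single-experiment point estimates scatter substantially along the ridge (sampling
SD ≈ 0.06 on w₂₂ at 3 cages × 11 generations × 100 larvae) while support limits
remain well calibrated (≈95% coverage in the recovery tests). Conclusions should
rest on the support limits, not the point estimate alone. The acceptance script
therefore reports replicate-averaged estimates over ten simulated experiments.

## Probit dose–mortality analysis (`cagefit.doseresponse`)

Replicate cups at the same dose are pooled into binomial totals. Control (dose 0)
mortality is pooled per strain and removed with Abbott's correction,
p_corr = (p_obs − c)/(1 − c), clamped to [0, 1]; 100% control mortality aborts the
analysis. The dose–response is a binomial-likelihood GLM with probit link on
log₁₀(dose), fitted to the corrected proportions with the pooled group sizes as
weights (the modern GLM formulation rather than Finney's transformed least
squares). A Pearson chi-square against the fitted line with df = (#dose groups −
2) reports linearity. Complete separation (no dose group with partial mortality)
raises a named error.

log₁₀(LD50) = (probit(0.5) − a)/b. CIs use the delta method on the log₁₀ scale
and are back-transformed, so they are always positive; this is stable at the
design's group sizes (80 larvae per dose). RR50 divides two LD50s; its CI adds the
two delta-method variances (independent assays), and the equality test is the
squared standardized log-ratio against χ²(1). These formulas are the standard
dialect; other software may differ in the last digit of CIs. LD50s are
scale-equivariant in the dose unit and RRs/chi-squares unit-invariant (tested to
1e−8); the µg/ml label is cosmetic.

## qPCR copy number and linear models (`cagefit.quant`)

Per locus, a standard curve Cq = intercept + slope·log₁₀(dilution) is fitted by
OLS to a tenfold dilution series (≥3 points; slope must be negative). Amplification
efficiency E = 10^(−1/slope) is flagged when outside (1, 2.2]. Per well, relative
quantity q = 10^((Cq − intercept)/slope); technical replicates are averaged on the
quantity scale by default (ratios are defined on quantities; Cq-scale averaging is
available and identical at zero noise), and the copy-number estimate is
q(ace-1)/q(ace-2) per individual. Individuals missing a locus are excluded and
listed. No calibrator normalization is applied by default (the susceptible
reference strain sits at ratio ≈ 1 without it); enabling it rescales all ratios by
one constant and leaves between-strain comparisons unchanged.

Two supporting linear models, both fitted by OLS:

- **copy number:** ratio ~ strain, with per-strain t contrasts against a reference
  strain and an overall strain F test (full vs intercept-only);
- **activity:** activity ~ strain + sex + plate (all categorical), strain tested by
  an F likelihood-ratio test of full vs strain-dropped model. A design in which
  strain adds no rank to the sex+plate design (perfect aliasing) is rejected.

Breusch–Pagan (heteroskedasticity) and Shapiro–Wilk (residual normality)
statistics are reported as diagnostics only — they never switch models.

## RFLP genotyping (`cagefit.rflp`)

Fragment patterns are predicted from amplicon length and per-allele cut offsets;
a heterozygote's pattern is the union of its two alleles' fragment sets
(co-migrating equal lengths collapse). Two diagnostic assays are built in for the
597-bp *ace-1* amplicon: AluI (S: uncut → 597; R: → 496+101) and BfaI (R1: uncut;
R2: → 73+132+392). Only the fragment multisets are published contracts; the
stored cut coordinates are any positions reproducing them. Observed gel lengths
are matched with a ±5 bp tolerance (configurable); calls are unique labels,
explicit ambiguity lists, or no-call.

## Synthetic data (`cagefit.synthetic`)

Every generator is a pure function of (scenario, seed); per-generator fixed
stream tags make the tables independent of generation order. Defaults encode the
study design:

- **cages:** true h = −0.605, s = −0.38 (w₁₂ ≈ 1.23, w₂₂ = 0.62), 3 cages × 11
  generations × 100 genotyped larvae; counts multinomial around the deterministic
  larval frequencies. Optional Wright–Fisher allele resampling at a finite census
  size is available (off by default, matching the fitted model) because realistic
  recovery experiments may want transmission noise; the real experiment's census
  size is unknown.
- **bioassays:** probit slope 4.0 per log₁₀ dose (typical for temephos in culicine
  larvae); true LD50s 0.0016 µg/ml (SLAB) with the resistant strains at 4.6× and
  15×, placing all three within the 0–0.07 µg/ml dose grid (8 positive doses plus
  controls, 4 replicate cups of 20 larvae). Control mortality defaults to 0;
  when set, it is mixed in by inverting Abbott's formula.
- **qPCR:** both loci share slope −3.3219 (E = 2), intercepts 24/25; ace-2
  quantity 1, ace-1 quantity = copy number (1/1/3 for SLAB/SR/SRQ); Cq noise SD
  0.15 cycles on sample wells. Standard-curve points lie exactly on the true
  line: curves are treated as high-precision calibrations, since shared curve
  error would shift all individuals of a dataset coherently and is not the
  within-assay noise the generator models.
- **activity:** strain means 6.3 (SR) and 10.8 (SRQ), residual SD 1.3, a 0.3 sex
  effect and small plate effects; 48 individuals per strain in a fully crossed,
  balanced sex × plate layout (consecutive F/M pairs walking through the plates —
  an earlier layout that assigned sex and plate from the same index parity would
  alias the two).

What the generators deliberately do **not** emulate: overdispersion beyond
binomial/multinomial sampling, genotyping error, cage-to-cage environmental
variation, extra-binomial mortality between replicate cups, pipetting/plate
effects in qPCR, or linkage to background loci. Passing recovery tests therefore
demonstrate correctness of the estimators under their own model assumptions, not
robustness to the full messiness of real cage or assay data.

## Problem sizes in the test suite

Recovery and coverage suites run at the study's design sizes with fixed seeds:
20 cage experiments for fitness recovery (fast search), 100 seeded bioassays for
LD50 coverage, 100 qPCR datasets for ratio recovery, 200 null activity datasets
for the F test's type-I error (accepted band 0.02–0.08). The likelihood oracle is
a pure-Python recursion sharing no code with the vectorised implementation; the
probit oracle is a hand-coded IRLS; the linear-model oracle solves the normal
equations directly.

## Known limitations

- The random search gives no gradient-based polish; the argmax is accurate to the
  sampling density (the oracle test allows 0.02 per axis against an exhaustive
  grid at desk scale).
- Support limits are sampled-cloud approximations of profile-likelihood
  intervals; with very few qualifying points they shrink toward the ML point.
- The probit CIs default to the delta method; Fieller intervals are available
  (`lethal_dose(..., ci_method="fieller")`) and coincide with delta when the
  slope is well determined, but the two differ for poorly determined slopes.
- Copy-number ratios assume equal amplification efficiency stability across the
  dilution range; efficiency drift within a run is not modelled.
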