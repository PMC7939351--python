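# Methods

This note documents the models, parameter choices and numerical
decisions behind the package, and what the synthetic-data studies do
and do not demonstrate about real data.

## Study design being modelled

The pipeline targets a two-visit protocol in adults with severe obesity
(BMI ≥ 35): a 600-kcal mixed-meal test sampled fasting and half-hourly
to 150 min, and a hyperinsulinemic euglycemic clamp with a
[6,6-²H₂]glucose tracer — 170 mg prime plus 1.7 mg/min constant
infusion from time 0, a basal measurement window at 100–120 min,
low-dose insulin (0.3 mU·kg⁻¹·min⁻¹) from 120 to 240 min, and a 20%
dextrose infusion spiked with tracer at 8 mg per g glucose, adjusted
every 5 min to hold plasma glucose at 4.5 mmol/L (centre of the
4.0–5.0 mmol/L euglycemic range). Samples are drawn at minutes 0, 100,
110, 115, 120, 150, 180, 210, 220, 230, 240. Genotype is a biallelic
SNP coded codominantly (T/T, A/T, A/A = 0, 1, 2 risk alleles) with
minor-allele frequency 0.44, and recruitment has a second phase that
preferentially admits homozygotes so the three groups end up similar in
size. Analyses are always stratified by sex.

## Clamp simulator

One glucose compartment of volume pV·W (pV = 0.22 L/kg) holds total
glucose concentration C (mmol/L) and enrichment E (TTR). With total
fluxes in µmol/min,

    pV·W·dC/dt = EGP + GINF + F_tr − Rd
    pV·W·C·dE/dt = F_tr + E_inf·GINF − E·(EGP + GINF + F_tr)

where F_tr is the tracer infusion, GINF the dextrose infusion and
E_inf = 0.008 its enrichment (8 mg/g). This TTR form conserves the
tracer pool V·C·E exactly (d(V·C·E)/dt = F_tr + E_inf·GINF − E·Rd),
which the tests verify against the cumulative infusion record. The
tracer prime enters as the initial enrichment E(0) = prime/(V·C₀).

Insulin action is phenomenological but captures the two regulated arms:

* production: EGP = EGP_b · max(0, 1 − s·ΔI/(I50 + ΔI)), a saturable
  suppression in the insulin increment ΔI = I − I_b;
* disposal: Rd = (Rd_b + S_I·ΔI)·C/C_b, linear in ΔI and proportional
  to glucose (so clearance, not uptake, is what insulin scales);
  Rd_b = EGP_b + F_tr/W closes the basal mass balance.

Plasma insulin relaxes first-order (τ = 15 min) to the infusion-implied
steady state; the increment gain is 567 pmol·L⁻¹ per mU·kg⁻¹·min⁻¹, so
the 0.3 mU dose raises insulin by ≈170 pmol/L — a low-dose clamp
reaching ≈260 pmol/L total in an obese, hyperinsulinemic subject
(basal 90 pmol/L). The dextrose pump is a discrete proportional-
integral controller in velocity form (K_p = 25 µmol·kg⁻¹·min⁻¹ per
mmol/L, K_i = 6 per 5-min update, output floored at 0), updated every
5 min from minute 120, mirroring the clinical adjustment cadence.
Integration is fixed-step RK4 at 0.25 min with pump and insulin inputs
held constant within steps; measurement noise is multiplicative
Gaussian at the protocol sample times (defaults: 1.5% CV for glucose
and TTR, 5% for insulin) and the noise-free trajectories are retained
as ground truth.

Default physiology: basal EGP 10 µmol·kg⁻¹·min⁻¹ (≈1.8 mg·kg⁻¹·min⁻¹,
textbook fasting production), basal glucose 4.6 mmol/L (the cohort this
emulates clamped within −3%/+7% of 4.5 mmol/L), maximal fractional
suppression s = 0.8 with half-effect at ΔI = 60 pmol/L (≈59% EGP
suppression at the clamp increment), S_I = 0.05 µmol·kg⁻¹·min⁻¹ per
pmol/L (clamped Rd ≈ 18 µmol·kg⁻¹·min⁻¹, GIR ≈ 2.5 mg·kg⁻¹·min⁻¹).
With basal glucose 4.6 mmol/L the 170 mg prime is within ~1% of the
ideal prime F_tr·(pool/turnover), so basal enrichment is nearly flat —
as the protocol intends — while remaining genuinely non-steady.

## Steele inversion

The estimator is the single-pool Steele non-steady-state form for
stable isotopes with the spiked-infusate term in the numerator:

    Ra_total = [F_tr + E_inf·GINF − pV·W·C·dE/dt]/E
    EGP = Ra_total − GINF − F_tr
    Rd  = Ra_total − pV·W·dC/dt
    MCR = Rd/C

No pool-fraction multiplier is applied beyond pV = 0.22 L/kg. C and E
are smoothed by a cubic smoothing spline with the roughness penalty
chosen by generalized cross-validation (`lambda="auto"`); derivatives
are the spline's analytic derivatives, never finite differences of raw
samples. The smoother is this package's substitute for "optimal
segments" smoothing, whose exact algorithm is not publicly
reconstructable; it is well-defined, differentiable and exposes its one
tuning constant. Kinetics are evaluated on the sample grid from 100 min
on (after tracer equilibration); negative computed EGP values are
retained but flagged, since truncation would bias suppression
estimates. Basal EGP/Rd average the sample times in 100–120 min; basal
insulin averages exactly minutes 100/110/115/120; GIR averages the
pump-implied delivery at minutes 220/230/240. QC ratios divide window
means by 4.5 mmol/L and pass within ±10%, boundaries inclusive (a
1e-12 epsilon absorbs float rounding at exactly ±10%).

Forward-inverse calibration: over a 3×3×3 grid (EGP suppression
30/50/80%, S_I 0.03–0.09, basal EGP 8–12) the noise-free
window-summarized EGP and Rd recover the generative truth within 5%
(typically <2%), and 50% suppression is recovered within ±0.05. With
1.5–2% measurement CV the median window error stays within 15%.

## Indices

Matsuda = 10000/√(G₀·I₀·Ḡ·Ī) with means over all six time points
including fasting. The default unit mode evaluates the formula on
mmol/L and pmol/L as measured (`si`), because the genotype contrasts
this pipeline reproduces are on that scale; `conventional` converts to
mg/dL and µU/mL (1 µU/mL = 6.0 pmol/L) first for literature
comparability. HIR multiplies basal Ra per kg body weight by basal
insulin. The AUC window is a parameter defaulting to 0–150 min for both
analytes; reports of this protocol differ on whether the glucose AUC
starts at minute 0 or 1, and 0 is used here.

## Inference

Genotype is always a three-level factor; pairwise contrasts A/T−T/T,
A/A−A/T, A/A−T/T telescope exactly by construction. Models are fitted
separately per sex. Significance of any contrast is a 99% bootstrap CI
excluding zero; that stringent level is itself the multiplicity
control, and no further correction is applied.

*Robust linear models.* Huber IRLS with c = 1.345 (95% Gaussian
efficiency) and MAD scale re-estimated each iteration, iterated to a
1e-10 relative coefficient change. Confidence intervals come from the
residual bootstrap (centred residuals resampled onto fitted values,
B = 50000 by default) with BCa correction: z₀ from the bootstrap CDF at
the point estimate (mid-rank tie handling, clipped to (1/(B+1),
B/(B+1))), acceleration from jackknife influence values; a degenerate
bootstrap distribution yields a zero-width interval with a warning.
All bootstrap quantiles — BCa and percentile alike — use normal-scale
interpolation of order statistics at (B+1)·α, the convention of the R
`boot` interval machinery; at extreme tails this is slightly wider, and
better calibrated, than linear-interpolation quantiles.

*Mixed models.* Random-intercept LMMs (response ~ time×genotype +
(1|subject)) by REML. The criterion is profiled over the variance ratio
θ = τ²/σ², a one-dimensional problem solved by a log-spaced grid search
plus golden-section refinement, with τ² floored at zero at the
boundary; fixed effects follow by GLS at θ̂. The implementation stores
only per-group sufficient statistics, so bootstrap refits are batched
linear algebra across replicates (the 50000-replicate default takes
seconds, not hours). The parametric residual bootstrap simulates new
intercepts ~ N(0, τ̂²) and residuals ~ N(0, σ̂²), refits — re-estimating
the variance components every replicate — and takes percentile
intervals. The repeated factor defaults to the two reported levels
(30/150 min for the meal; basal/clamped for the clamp), configurable to
all six meal times. The intraclass correlation is τ²/(τ²+σ²).

*Group tests.* Kruskal-Wallis (tie-adjusted), Wilcoxon-Mann-Whitney
(asymptotic two-sided) and the chi-squared test of proportions (no
continuity correction) wrap scipy.stats.

Calibration studies (in `isoglyco.validation`, run by the acceptance
script and tests at scaled-down sizes chosen as the package's own
defaults): the parametric percentile interval at nominal 99% achieves
98–100% empirical coverage for a genotype×time contrast (200 replicates
of 40 subjects × 2 times, B = 500); the 99%-CI rule's type-I error
under a true null lies in 0.5–2% (1000 datasets of 3×20 subjects,
B = 500).

## Meal simulator

Glucose and insulin follow fasting + amplitude·(t/30)·exp(1 − t/30) — a
gamma-shaped excursion peaking at 30 min and still slightly elevated at
150 min. Genotype/sex effects are additive on the 30- and 150-min
values; the defaults encode the male-specific risk-allele pattern the
analysis is designed to detect (A/T−T/T +1.36 mmol/L at 30 min,
+1.16 at 150 min; A/A−T/T +0.48/+0.79; near-null female effects), used
as generative settings for recovery tests, not as claims about any real
cohort. Subject heterogeneity enters through the fasting levels and a
log-normal amplitude multiplier; measurement noise is multiplicative
(3% glucose, 8% insulin). Non-positive generated values are floored (or
resampled) and logged.

## Cohort generator

Phase 1 draws genotypes from Hardy-Weinberg equilibrium at q = 0.44
(probabilities 0.3136/0.4928/0.1936); phase 2 emulates the external
balancing controller by a greedy rule — each new subject joins the
smallest genotype group, ties preferring homozygotes — or fills
explicit target totals. Body composition is drawn from sex-specific
log-normal/normal distributions centred on the cohort's published
medians (male weight ≈ 145 kg, FFM fraction 0.58; female ≈ 118 kg,
0.52), with BMI truncated at 35 and genotype-shifted male visceral fat
and android:gynoid ratio. All randomness flows from one seed through
numpy Generators; noise-free outputs are seed-invariant.

## What the synthetic studies do not show

The generator's clamp model is one-compartment with phenomenological
insulin action: it cannot probe errors from fast glucose-pool
heterogeneity (the classical motivation for a pool-fraction
correction), model mismatch in EGP dynamics, analytical drift in GC-MS
enrichment, or real biological outliers beyond the log-normal
heterogeneity built in. Passing recovery tests therefore demonstrates
that the inversion is the forward model's inverse under the stated
noise — not that the clamp estimates are unbiased for human physiology.
Likewise the bootstrap calibrations assume correctly specified models;
they quantify the procedures' nominal behaviour, not robustness to
model violation (which is the motivation for the robust M-estimation
route on the one-time endpoints).

## Problem sizes

Default simulator sizes mirror the emulated study (97 subjects, 79
clamps). The calibration studies use 200 replicates × B = 500 (coverage)
and 1000 × B = 500 (type-I): sizes chosen so Monte-Carlo error is small
relative to the acceptance bands (binomial SE ≈ 0.7 pp at 99% coverage
with n = 200; ≈ 0.3 pp at 1% type-I with n = 1000).

## Known limitations

* Single-pool Steele only; no two-compartment or regularized-
  deconvolution EGP estimation, no glucagon kinetics.
* The GCV smoothing spline is a declared substitute for the original
  "optimal segments" smoother; with only 11 clamp samples the GCV
  penalty choice can be variable at high noise.
* The balanced-phase-2 greedy rule is one plausible reading of
  "mainly homozygotes were included".
* REML supports a single random intercept only (no random slopes or
  crossed effects), matching the target analysis.
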