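# isoglyco

A tested, reusable Python pipeline from raw stable-isotope glucose
clamp and mixed-meal time-series to insulin-sensitivity endpoints and
sex-stratified genotype contrasts — paired with a forward simulator of
the whole study, so every stage can be validated by parameter recovery
without any clinical data.

## Who this is for

Groups running (or re-analyzing) hyperinsulinemic euglycemic clamps
with a [6,6-²H₂]glucose tracer and standardized meal tests in
genotype-stratified cohorts — e.g. obesity/diabetes genetics studies —
who need the full chain: tracer kinetics → per-subject indices →
robust/bootstrap group inference, with explicit quality control and
reproducible seeds.

## What it computes

**Tracer kinetics** (`isoglyco.tracer_kinetics`). Single-pool Steele
non-steady-state equations adapted for stable isotopes, with the
tracer-spiked ("hot") dextrose infusate correction:

    Ra_total(t) = [F_tr(t) + E_inf·GINF(t) − pV·W·C(t)·dE/dt] / E(t)
    EGP(t) = Ra_total − GINF − F_tr        (endogenous production)
    Rd(t)  = Ra_total − pV·W·dC/dt         (disposal)
    MCR(t) = Rd/C                          (clearance)

with enrichment E as tracer-to-tracee ratio, distribution volume
pV = 0.22 L/kg body weight, and C/E curves smoothed by a GCV-penalized
cubic spline whose analytic derivative feeds the dE/dt and dC/dt terms.
Window summaries follow the clamp protocol (basal 100–120 min, clamped
220–240 min, GIR averaged at minutes 220/230/240, basal insulin at
100/110/115/120), clamp success requires mean basal and clamped glucose
within ±10% of the 4.5 mmol/L target, and fluxes are reported per kg
body weight and per kg fat-free mass.

**Indices** (`isoglyco.indices`). Matsuda whole-body sensitivity index
`10000/√(G₀·I₀·Ḡ·Ī)` over the six meal samples (0–150 min, half-hourly),
hepatic insulin-resistance index `HIR = basal Ra × basal insulin`, and
trapezoid AUCs.

**Inference** (`isoglyco.stats`). Genotype enters as a codominant
three-level factor (T/T, A/T, A/A). One-time endpoints are analyzed by
Huber M-estimation (c = 1.345, MAD scale) with residual-bootstrap BCa
intervals; repeated endpoints (pre/post meal, basal/clamped) by
random-intercept linear mixed models fitted by REML with parametric
residual-bootstrap percentile intervals, including genotype×time
("difference in change") contrasts. Significance = a 99% bootstrap CI
excluding zero. Bootstrap refits are vectorized, so the 50 000-replicate
default is practical.

**Simulator** (`isoglyco.synthetic_data`). Hardy-Weinberg genotype
sampling (q = 0.44) with a homozygote-enriched second recruitment
phase; sex/genotype-dependent body composition; a one-compartment
glucose/tracer system under the clamp protocol (170 mg prime,
1.7 mg/min tracer, insulin 0.3 mU·kg⁻¹·min⁻¹ from minute 120, 20%
dextrose spiked at 8 mg/g with a 5-min PI glucose controller); and
gamma-shaped postprandial excursions peaking at 30 min.

## Worked example

```python
from isoglyco import (ClampSimParams, PipelineConfig, run_pipeline,
                      sample_cohort, simulate_clamp, analyze_clamp)

subject = sample_cohort(n_phase1=0, n_phase2=1, seed=1)[0]
series, truth = simulate_clamp(
    subject, ClampSimParams(cv_glucose=0, cv_ttr=0, cv_insulin=0), seed=2)
res = analyze_clamp(series, subject)
print(f"basal EGP {res.basal_egp:.2f} umol/kg/min "
      f"(truth {truth.window_mean(truth.egp_umol_kg_min, (100, 120)):.2f})")
print(f"clamped EGP {res.clamped_egp:.2f}, GIR {res.gir:.2f}, "
      f"QC pass: {res.qc_pass}")
```

prints

```
basal EGP 9.86 umol/kg/min (truth 10.00)
clamped EGP 4.08, GIR 14.05, QC pass: True
```

— the inversion recovers the generative basal production within ~1%,
shows insulin suppressing EGP by ~59% under the low-dose clamp, and the
controller held euglycemia (QC pass). A full cohort analysis:

```python
report = run_pipeline(PipelineConfig(seed=7, n_boot=500))
print(report.contrasts.head())     # stratum x endpoint x contrast + 99% CI
```

yields per-sex tables whose rows are genotype contrasts (A/T−T/T,
A/A−A/T, A/A−T/T, plus genotype×time) with estimate, 99% CI and a
significance flag, alongside median (Q1, Q3) descriptives and the QC
summary. The same pipeline is available from the shell:

```bash
isoglyco simulate --seed 1 --out data/
isoglyco analyze --seed 1 --boot 500 --out results/
```

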