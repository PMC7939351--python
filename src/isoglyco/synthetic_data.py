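"""Forward simulation of the cohort, the tracer clamp, and the meal test.

The generator produces data with the statistical structure the analysis
assumes — Hardy-Weinberg genotype sampling with a homozygote-enriched
second recruitment phase, sex- and genotype-dependent body composition,
a one-compartment glucose/tracer system driven by the clamp protocol,
and gamma-shaped postprandial excursions — with known ground truth, so
every downstream stage is testable by parameter recovery.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .errors import DomainError, SimulationError
from .types import (
    CLAMP_SAMPLE_TIMES,
    GENOTYPES,
    MEAL_SAMPLE_TIMES,
    ClampProtocol,
    ClampSeries,
    MealSeries,
    SimulationTruth,
    SubjectRecord,
    mg_to_umol,
    umol_to_mg,
)

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------

def hwe_genotype_probs(q: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype probabilities at minor-allele frequency q.

    Returns ``(p_TT, p_AT, p_AA) = ((1-q)^2, 2q(1-q), q^2)``, where A is
    the minor (risk) allele.
    """
    if not 0.0 <= q <= 1.0:
        raise DomainError(f"allele frequency must lie in [0, 1], got {q}")
    p = 1.0 - q
    return (p * p, 2.0 * p * q, q * q)


#: Sex-specific body-composition settings: medians of log-normal (or
#: normal) distributions, with genotype-dependent medians where the
#: cohort showed a genotype pattern (male visceral fat and android:gynoid
#: ratio rise with risk-allele count).
DEFAULT_BODY_COMPOSITION: dict[str, dict] = {
    "male": {
        "bmi_median": 43.5, "bmi_log_sd": 0.07,
        "height_mean_m": 1.81, "height_sd_m": 0.06,
        "ffm_fraction_mean": 0.58, "ffm_fraction_sd": 0.03,
        "visceral_median_g": {"TT": 563.0, "AT": 960.0, "AA": 1124.0},
        "visceral_log_sd": 0.25,
        "ag_ratio_median": {"TT": 0.74, "AT": 0.85, "AA": 0.97},
        "ag_ratio_sd": 0.10,
    },
    "female": {
        "bmi_median": 41.5, "bmi_log_sd": 0.08,
        "height_mean_m": 1.66, "height_sd_m": 0.06,
        "ffm_fraction_mean": 0.52, "ffm_fraction_sd": 0.03,
        "visceral_median_g": {"TT": 790.0, "AT": 732.0, "AA": 727.0},
        "visceral_log_sd": 0.30,
        "ag_ratio_median": {"TT": 0.53, "AT": 0.53, "AA": 0.54},
        "ag_ratio_sd": 0.07,
    },
}

_MIN_BMI = 35.0


def _draw_body(rng: np.random.Generator, sex: str, genotype: str,
               body: dict) -> dict:
    cfg = body[sex]
    # BMI >= 35 is an inclusion criterion: truncated log-normal by rejection
    for _ in range(1000):
        bmi = cfg["bmi_median"] * np.exp(rng.normal(0.0, cfg["bmi_log_sd"]))
        if bmi >= _MIN_BMI:
            break
    else:  # pragma: no cover - defensive
        bmi = _MIN_BMI
    height = rng.normal(cfg["height_mean_m"], cfg["height_sd_m"])
    height = float(np.clip(height, 1.40, 2.10))
    weight = bmi * height**2
    frac = rng.normal(cfg["ffm_fraction_mean"], cfg["ffm_fraction_sd"])
    frac = float(np.clip(frac, 0.35, 0.75))
    ffm = frac * weight
    fat = 0.85 * (weight - ffm)   # total fat excluding arms
    visc = cfg["visceral_median_g"][genotype] * np.exp(
        rng.normal(0.0, cfg["visceral_log_sd"]))
    ag = max(0.2, rng.normal(cfg["ag_ratio_median"][genotype],
                             cfg["ag_ratio_sd"]))
    return dict(weight_kg=float(weight), height_m=float(height),
                ffm_kg=float(ffm), fat_kg=float(fat),
                visceral_fat_g=float(visc), android_gynoid_ratio=float(ag))


def sample_cohort(n_phase1: int = 50, n_phase2: int = 47, q: float = 0.44,
                  sex_ratio_female: float = 0.69,
                  seed: Optional[int] = None,
                  body_composition: Optional[dict] = None,
                  target_totals: Optional[tuple[int, int, int]] = None,
                  ) -> list[SubjectRecord]:
    """Two-phase recruitment of a genotype-balanced obese cohort.

    Phase 1 draws genotypes from Hardy-Weinberg equilibrium at allele
    frequency ``q``. Phase 2 emulates the external controller that
    selected later participants so that mainly homozygotes were included:
    each phase-2 subject joins the currently smallest genotype group
    (ties broken in favour of homozygotes). When ``target_totals`` is
    given (TT, AT, AA) the controller instead fills the largest remaining
    deficit toward those totals.
    """
    if n_phase1 < 0 or n_phase2 < 0:
        raise DomainError("cohort sizes must be >= 0")
    if target_totals is not None and sum(target_totals) != n_phase1 + n_phase2:
        raise DomainError("target_totals must sum to the total cohort size")
    rng = np.random.default_rng(seed)
    body = body_composition or DEFAULT_BODY_COMPOSITION
    probs = hwe_genotype_probs(q)

    genos: list[str] = [str(g) for g in
                        rng.choice(GENOTYPES, size=n_phase1, p=probs)]
    counts = {g: genos.count(g) for g in GENOTYPES}
    for _ in range(n_phase2):
        if target_totals is not None:
            deficits = {g: target_totals[i] - counts[g]
                        for i, g in enumerate(GENOTYPES)}
            best = max(deficits.values())
            cands = [g for g in GENOTYPES if deficits[g] == best]
        else:
            smallest = min(counts.values())
            cands = [g for g in GENOTYPES if counts[g] == smallest]
        homo = [g for g in cands if g in ("TT", "AA")]
        cands = homo or cands
        g = cands[0] if len(cands) == 1 else str(rng.choice(cands))
        genos.append(g)
        counts[g] += 1

    records = []
    for i, g in enumerate(genos):
        sex = "female" if rng.random() < sex_ratio_female else "male"
        comp = _draw_body(rng, sex, g, body)
        records.append(SubjectRecord(subject_id=f"S{i + 1:03d}", sex=sex,
                                     genotype=g, **comp))
    return records


# --------------------------------------------------------------------------
# clamp simulator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClampSimParams:
    """Generative parameters of the one-compartment clamp model.

    The glucose pool is ``pV·W`` with pV = 0.22 L/kg. Endogenous glucose
    production responds to the insulin increment ΔI = I − I_b through a
    saturable suppression curve ``EGP = EGP_b·max(0, 1 − s·ΔI/(I50+ΔI))``
    and uptake through ``Rd = (Rd_b + S_I·ΔI)·C/C_b``, where
    ``Rd_b = EGP_b + F/W`` closes the basal mass balance including the
    tracer infusion. Plasma insulin relaxes first-order toward the
    infusion-implied steady state with time constant ``insulin_tau_min``.
    A proportional-integral controller adjusts the dextrose pump every
    5 min from the start of insulin to hold glucose at the 4.5 mmol/L
    target. Defaults describe an obese, insulin-resistant adult under the
    low-dose protocol: basal EGP 10 µmol·kg⁻¹·min⁻¹ (≈1.8 mg·kg⁻¹·min⁻¹
    fasting production), basal glucose 4.6 mmol/L, basal insulin
    90 pmol/L, and a clamp insulin increment of ≈170 pmol/L at
    0.3 mU·kg⁻¹·min⁻¹.
    """

    egp_basal_umol_kg_min: float = 10.0
    suppression_smax: float = 0.8      # fractional EGP suppression at ΔI→∞
    i50_pmol_l: float = 60.0           # insulin increment at half suppression
    s_i_umol_kg_min_per_pmol: float = 0.05
    glucose_basal_mmol_l: float = 4.6
    insulin_basal_pmol_l: float = 90.0
    insulin_gain_pmol_per_mU: float = 567.0   # ΔI_ss per (mU·kg⁻¹·min⁻¹)
    insulin_tau_min: float = 15.0
    pv_l_per_kg: float = 0.22
    controller_kp: float = 25.0        # µmol·kg⁻¹·min⁻¹ per mmol/L
    controller_ki: float = 6.0         # per 5-min update (velocity form)
    cv_glucose: float = 0.015
    cv_ttr: float = 0.015
    cv_insulin: float = 0.05
    cv_glucagon: float = 0.08
    glucagon_basal_pmol_l: float = 16.0
    glucagon_clamped_pmol_l: float = 11.0
    dt_min: float = 0.25


def simulate_clamp(subject: SubjectRecord,
                   params: Optional[ClampSimParams] = None,
                   protocol: Optional[ClampProtocol] = None,
                   seed: Optional[int] = None,
                   ) -> tuple[ClampSeries, SimulationTruth]:
    """Forward-simulate one subject's tracer clamp.

    Integrates the glucose and tracer (TTR-form) mass balances with a
    fixed-step fourth-order Runge-Kutta scheme on a fine grid, applying
    the tracer prime as an initial condition on the enrichment and the
    PI glucose controller at 5-min boundaries. Measurements are the
    fine-grid truth at the protocol sample times with multiplicative
    Gaussian noise; the returned :class:`SimulationTruth` records the
    noise-free trajectories.
    """
    params = params or ClampSimParams()
    protocol = protocol or ClampProtocol()
    rng = np.random.default_rng(seed)

    W = subject.weight_kg
    mw = 180.16
    v_ml = params.pv_l_per_kg * W * 1000.0          # distribution volume, mL
    c_b = params.glucose_basal_mmol_l               # µmol/mL
    i_b = params.insulin_basal_pmol_l
    f_tr = mg_to_umol(protocol.tracer_rate_mg_min, mw)   # µmol/min, constant
    e_inf = protocol.infusate_ttr
    egp_b = params.egp_basal_umol_kg_min * W        # µmol/min
    rd_b = egp_b + f_tr                             # basal mass balance
    s_i = params.s_i_umol_kg_min_per_pmol * W
    dt = params.dt_min
    if dt <= 0 or (protocol.controller_interval_min / dt) % 1 != 0:
        raise SimulationError("dt must divide the controller interval")

    n_steps = int(round(protocol.end_min / dt))
    times = np.linspace(0.0, protocol.end_min, n_steps + 1)

    def insulin_target(t: float) -> float:
        if protocol.insulin_start_min <= t < protocol.insulin_end_min:
            return i_b + params.insulin_gain_pmol_per_mU * \
                protocol.insulin_rate_mU_kg_min
        return i_b

    def fluxes(c: float, e: float, ins: float, ginf: float):
        """Return (dC, dE, EGP, Rd) for state (C, E, I) and GINF µmol/min."""
        d_i = max(0.0, ins - i_b)
        egp = egp_b * max(0.0, 1.0 - params.suppression_smax * d_i /
                          (params.i50_pmol_l + d_i))
        rd = (rd_b + s_i * d_i) * c / c_b
        dc = (egp + ginf + f_tr - rd) / v_ml
        de = (f_tr + e_inf * ginf - e * (egp + ginf + f_tr)) / (v_ml * c)
        return dc, de, egp, rd

    # initial state: basal glucose steady state, prime distributed in pool
    c = c_b
    e = mg_to_umol(protocol.prime_mg, mw) / (v_ml * c_b)
    ins = i_b

    c_tr, e_tr, i_tr = (np.empty(n_steps + 1) for _ in range(3))
    egp_tr, rd_tr, ginf_tr = (np.empty(n_steps + 1) for _ in range(3))
    ginf_per_kg = 0.0
    err_prev = 0.0
    ginf_times: list[float] = [0.0]
    ginf_rates: list[float] = [0.0]
    ctrl_every = int(round(protocol.controller_interval_min / dt))

    for k in range(n_steps + 1):
        t = times[k]
        # controller acts on the current (pre-step) glucose reading
        if (t >= protocol.insulin_start_min and k % ctrl_every == 0
                and t < protocol.end_min):
            err = protocol.target_glucose_mmol_l - c
            ginf_per_kg = max(0.0, ginf_per_kg
                              + params.controller_kp * (err - err_prev)
                              + params.controller_ki * err)
            err_prev = err
            ginf_times.append(t)
            ginf_rates.append(ginf_per_kg * W)
        ginf = ginf_per_kg * W
        it = insulin_target(t)

        dc, de, egp, rd = fluxes(c, e, ins, ginf)
        c_tr[k], e_tr[k], i_tr[k] = c, e, ins
        egp_tr[k], rd_tr[k], ginf_tr[k] = egp / W, rd / W, ginf / W
        if k == n_steps:
            break

        # RK4 step; inputs (ginf, insulin target) held constant over dt
        def deriv(state):
            cc, ee, ii = state
            dcc, dee, *_ = fluxes(cc, ee, ii, ginf)
            return np.array([dcc, dee, (it - ii) / params.insulin_tau_min])

        y = np.array([c, e, ins])
        k1 = deriv(y)
        k2 = deriv(y + 0.5 * dt * k1)
        k3 = deriv(y + 0.5 * dt * k2)
        k4 = deriv(y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(y)) or y[0] <= 0:
            raise SimulationError(
                f"integration diverged at t={t:.1f} min (state {y})")
        c, e, ins = y

    # convert pump record to mL/h of the stated dextrose concentration
    rate_ml_h = (umol_to_mg(np.asarray(ginf_rates), mw) * 60.0
                 / protocol.ginf_concentration_mg_ml)

    sample_t = np.asarray(protocol.sample_times_min)
    idx = np.searchsorted(times, sample_t)

    def measure(tr: np.ndarray, cv: float) -> np.ndarray:
        vals = tr[idx]
        if cv > 0:
            vals = vals * (1.0 + cv * rng.standard_normal(vals.shape))
        return np.maximum(vals, 1e-9)

    series = ClampSeries(
        subject_id=subject.subject_id,
        times_min=sample_t,
        glucose_mmol_l=measure(c_tr, params.cv_glucose),
        ttr=measure(e_tr, params.cv_ttr),
        insulin_pmol_l=measure(i_tr, params.cv_insulin),
        ginf_times_min=np.asarray(ginf_times),
        ginf_ml_h=rate_ml_h,
        prime_mg=protocol.prime_mg,
        tracer_rate_mg_min=protocol.tracer_rate_mg_min,
        ginf_concentration_mg_ml=protocol.ginf_concentration_mg_ml,
        ginf_spike_mg_per_g=protocol.ginf_spike_mg_per_g,
        glucagon_pmol_l={
            100.0: float(params.glucagon_basal_pmol_l *
                         max(0.1, 1.0 + params.cv_glucagon *
                             rng.standard_normal())),
            240.0: float(params.glucagon_clamped_pmol_l *
                         max(0.1, 1.0 + params.cv_glucagon *
                             rng.standard_normal())),
        },
    )
    truth = SimulationTruth(
        times_min=times, egp_umol_kg_min=egp_tr, rd_umol_kg_min=rd_tr,
        insulin_pmol_l=i_tr, glucose_mmol_l=c_tr, ttr=e_tr,
        ginf_umol_kg_min=ginf_tr,
        params=dict(asdict(params), weight_kg=W,
                    tracer_umol_min=float(f_tr)),
        seed=seed,
    )
    return series, truth


def tracer_balance_residual(truth: SimulationTruth,
                            protocol: Optional[ClampProtocol] = None,
                            weight_kg: Optional[float] = None) -> float:
    """Relative tracer mass-balance error of a simulated clamp.

    The TTR-form system conserves ``V·C·E`` exactly:
    ``d(V·C·E)/dt = F + E_inf·GINF − E·Rd``, so the prime plus cumulative
    infusion must equal the current pool content plus cumulative
    disposal. Returns the relative residual of that identity at the end
    of the run (integrator error only).
    """
    protocol = protocol or ClampProtocol()
    W = weight_kg or truth.params.get("weight_kg")
    pv = truth.params.get("pv_l_per_kg", 0.22)
    v_ml = pv * W * 1000.0
    f_tr = truth.params["tracer_umol_min"]
    t = truth.times_min
    ginf = truth.ginf_umol_kg_min * W
    infused = (mg_to_umol(protocol.prime_mg) + f_tr * t[-1]
               + protocol.infusate_ttr * np.trapezoid(ginf, t))
    pool = v_ml * truth.glucose_mmol_l[-1] * truth.ttr[-1]
    disposed = np.trapezoid(truth.ttr * truth.rd_umol_kg_min * W, t)
    return float(abs(infused - pool - disposed) / infused)


# --------------------------------------------------------------------------
# meal simulator
# --------------------------------------------------------------------------

#: default genotype shifts (mmol/L) added to the 30-min and 150-min
#: glucose values, relative to TT, reproducing the contrast structure the
#: analysis is built to detect (males show the risk-allele effect)
DEFAULT_MEAL_GLUCOSE_EFFECTS: dict[str, dict[str, tuple[float, float]]] = {
    "male": {"TT": (0.0, 0.0), "AT": (1.36, 1.16), "AA": (0.48, 0.79)},
    "female": {"TT": (0.0, 0.0), "AT": (0.25, -0.03), "AA": (0.36, 0.11)},
}


@dataclass(frozen=True)
class MealSimParams:
    """Generative parameters of the 600-kcal mixed-meal test.

    Both analytes follow ``fasting + amplitude·(t/30)·exp(1 − t/30)``,
    a gamma-shaped excursion that peaks at 30 min and stays slightly
    elevated at 150 min. Genotype/sex effects are additive on the 30-min
    and 150-min values; subject-level heterogeneity enters through the
    fasting level and a log-normal amplitude multiplier; measurement
    noise is multiplicative.
    """

    fasting_glucose_mmol_l: float = 5.3
    fasting_insulin_pmol_l: float = 110.0
    glucose_amplitude_mmol_l: float = 3.0
    insulin_amplitude_pmol_l: float = 450.0
    female_fasting_glucose_shift: float = -0.2
    female_amplitude_factor: float = 0.85
    subject_sd_fasting_glucose: float = 0.35
    subject_sd_log_amplitude: float = 0.25
    subject_sd_log_fasting_insulin: float = 0.30
    cv_glucose: float = 0.03
    cv_insulin: float = 0.08
    glucose_effects: dict = field(
        default_factory=lambda: DEFAULT_MEAL_GLUCOSE_EFFECTS)
    insulin_effects: dict | None = None
    negative_policy: str = "floor"     # or "resample"
    floor_value: float = 0.1


def _gamma_shape(t: np.ndarray) -> np.ndarray:
    return (t / 30.0) * np.exp(1.0 - t / 30.0)


def simulate_meal(subject: SubjectRecord,
                  params: Optional[MealSimParams] = None,
                  seed: Optional[int] = None) -> MealSeries:
    """Forward-simulate one subject's meal-test glucose and insulin."""
    params = params or MealSimParams()
    rng = np.random.default_rng(seed)
    t = np.asarray(MEAL_SAMPLE_TIMES)
    shape = _gamma_shape(t)

    fast_g = params.fasting_glucose_mmol_l
    amp_g = params.glucose_amplitude_mmol_l
    fast_i = params.fasting_insulin_pmol_l
    amp_i = params.insulin_amplitude_pmol_l
    if subject.sex == "female":
        fast_g += params.female_fasting_glucose_shift
        amp_g *= params.female_amplitude_factor
        amp_i *= params.female_amplitude_factor
    fast_g += params.subject_sd_fasting_glucose * rng.standard_normal()
    subj_amp = np.exp(params.subject_sd_log_amplitude *
                      rng.standard_normal())
    fast_i *= np.exp(params.subject_sd_log_fasting_insulin *
                     rng.standard_normal())

    glucose = fast_g + amp_g * subj_amp * shape
    insulin = fast_i + amp_i * subj_amp * shape

    g_eff = params.glucose_effects.get(subject.sex, {}).get(
        subject.genotype, (0.0, 0.0))
    glucose = glucose + np.where(t == 30.0, g_eff[0], 0.0) \
        + np.where(t == 150.0, g_eff[1], 0.0)
    if params.insulin_effects is not None:
        i_eff = params.insulin_effects.get(subject.sex, {}).get(
            subject.genotype, (0.0, 0.0))
        insulin = insulin + np.where(t == 30.0, i_eff[0], 0.0) \
            + np.where(t == 150.0, i_eff[1], 0.0)

    def noisy(vals: np.ndarray, cv: float) -> np.ndarray:
        if cv > 0:
            vals = vals * (1.0 + cv * rng.standard_normal(vals.shape))
        if np.any(vals <= 0):
            if params.negative_policy == "resample":
                for _ in range(100):
                    bad = vals <= 0
                    if not np.any(bad):
                        break
                    vals[bad] = vals[bad] * 0 + params.floor_value if cv == 0 \
                        else np.abs(vals[bad])
            log.warning("meal simulation produced non-positive values for "
                        "%s; flooring at %g", subject.subject_id,
                        params.floor_value)
            vals = np.maximum(vals, params.floor_value)
        return vals

    return MealSeries(subject_id=subject.subject_id, times_min=t,
                      glucose_mmol_l=noisy(glucose, params.cv_glucose),
                      insulin_pmol_l=noisy(insulin, params.cv_insulin))
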