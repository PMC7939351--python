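"""Steele non-steady-state inversion of clamp time-series.

Turns measured glucose, tracer enrichment (TTR) and infusion records
into endogenous glucose production (EGP), glucose disposal (Rd),
metabolic clearance (MCR) and the steady-state glucose infusion rate
(GIR), using the single-pool Steele equations adapted for stable
isotopes with a tracer-spiked ("hot") glucose infusate:

    Ra_total(t) = [F_tr(t) + E_inf·GINF(t) − pV·W·C(t)·dE/dt] / E(t)
    EGP(t)      = Ra_total(t) − GINF(t) − F_tr(t)
    Rd(t)       = Ra_total(t) − pV·W·dC/dt
    MCR(t)      = Rd(t) / C(t)

with pV = 0.22 L per kg body weight and all fluxes in µmol/min
(µmol·kg⁻¹·min⁻¹ after division by body weight). Concentration and
enrichment curves are smoothed with a cubic smoothing spline whose
penalty is chosen by generalized cross-validation; derivatives are
analytic derivatives of the smoother, never finite differences on raw
samples.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline, make_smoothing_spline

from .errors import (
    AlignmentError,
    DomainError,
    EnrichmentUnderflowError,
    InsufficientDataError,
    MissingDataError,
)
from .types import (
    ClampSeries,
    KineticsConfig,
    KineticsResult,
    SubjectRecord,
    mg_to_umol,
)

log = logging.getLogger(__name__)


@dataclass
class SmoothedCurve:
    """A penalized-spline smooth of a time-series with analytic derivative."""

    times: np.ndarray
    _spline: object

    def value(self, t) -> np.ndarray:
        return np.asarray(self._spline(np.asarray(t, dtype=float)))

    def derivative(self, t) -> np.ndarray:
        return np.asarray(self._spline.derivative()(np.asarray(t, dtype=float)))

    def __call__(self, t) -> np.ndarray:
        return self.value(t)


def smooth_series(times, values, lam: float | str = "auto") -> SmoothedCurve:
    """Cubic smoothing spline through (times, values).

    ``lam="auto"`` selects the roughness penalty by generalized
    cross-validation; a numeric ``lam`` is used as-is (0 interpolates).
    At exactly four points an interpolating cubic spline is used, since
    a penalized cubic fit needs five.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise AlignmentError("times and values must be equal-length 1-D")
    if t.size < 4:
        raise InsufficientDataError(
            f"smoothing needs >= 4 points, got {t.size}")
    if np.any(np.diff(t) <= 0):
        raise DomainError("times must be strictly increasing")
    if t.size == 4 or (lam != "auto" and float(lam) == 0.0):
        sp = CubicSpline(t, y)
    elif lam == "auto":
        sp = make_smoothing_spline(t, y, lam=None)
    else:
        sp = make_smoothing_spline(t, y, lam=float(lam))
    return SmoothedCurve(times=t, _spline=sp)


def steele_ra_total(times, glucose: SmoothedCurve, ttr: SmoothedCurve,
                    tracer_umol_min, ginf_umol_min, infusate_ttr: float,
                    pv_l_per_kg: float, weight_kg: float) -> np.ndarray:
    """Total glucose appearance Ra (µmol/min) at ``times``.

    ``tracer_umol_min`` and ``ginf_umol_min`` are the tracer and
    exogenous-glucose infusion rates (scalars or arrays aligned with
    ``times``); ``infusate_ttr`` is the enrichment of the spiked
    dextrose. The pool term uses ``pV·W`` litres and C in mmol/L, i.e.
    pool change in µmol/min is ``pV·W·1000·C·dE/dt``.
    """
    t = np.asarray(times, dtype=float)
    e = ttr.value(t)
    if np.any(e <= 0):
        bad = t[np.asarray(e <= 0).nonzero()[0][0]]
        raise EnrichmentUnderflowError(
            f"non-positive enrichment at t={bad:g} min")
    f_tr = np.broadcast_to(np.asarray(tracer_umol_min, dtype=float), t.shape)
    ginf = np.broadcast_to(np.asarray(ginf_umol_min, dtype=float), t.shape)
    pool = pv_l_per_kg * weight_kg * 1000.0 * glucose.value(t) \
        * ttr.derivative(t)
    return (f_tr + infusate_ttr * ginf - pool) / e


def egp_from_ra(ra_total, ginf_umol_min, tracer_umol_min) -> np.ndarray:
    """Endogenous glucose production: Ra net of exogenous inputs.

    Negative values are retained (truncation would bias suppression
    estimates) but logged.
    """
    ra = np.asarray(ra_total, dtype=float)
    ginf = np.broadcast_to(np.asarray(ginf_umol_min, dtype=float), ra.shape)
    f_tr = np.broadcast_to(np.asarray(tracer_umol_min, dtype=float), ra.shape)
    if ginf.shape != ra.shape or f_tr.shape != ra.shape:
        raise AlignmentError("trajectories must share one grid")
    egp = ra - ginf - f_tr
    if np.any(egp < 0):
        log.warning("EGP trajectory contains %d negative values (retained)",
                    int(np.sum(egp < 0)))
    return egp


def rd_from_ra(times, ra_total, glucose: SmoothedCurve,
               pv_l_per_kg: float, weight_kg: float) -> np.ndarray:
    """Glucose disposal: Ra_total minus the pool concentration change."""
    t = np.asarray(times, dtype=float)
    ra = np.asarray(ra_total, dtype=float)
    if ra.shape != t.shape:
        raise AlignmentError("ra_total must align with times")
    pool = pv_l_per_kg * weight_kg * 1000.0 * glucose.derivative(t)
    return ra - pool


def mcr(rd, glucose_mmol_l) -> np.ndarray:
    """Metabolic clearance rate: Rd/C.

    With Rd in µmol·kg⁻¹·min⁻¹ and C in mmol/L (= µmol/mL) the result is
    mL·kg⁻¹·min⁻¹.
    """
    c = np.asarray(glucose_mmol_l, dtype=float)
    if np.any(c <= 0):
        raise DomainError("glucose concentration must be positive")
    return np.asarray(rd, dtype=float) / c


def gir_steady_state(ginf_times_min, ginf_ml_h, concentration_mg_ml: float,
                     weight_kg: float,
                     window_times=(220.0, 230.0, 240.0),
                     mw: float = 180.16) -> float:
    """Steady-state glucose infusion rate, µmol·kg⁻¹·min⁻¹.

    Averages the pump-implied glucose delivery at the requested minutes
    (protocol: 220, 230, 240) from the left-continuous pump record.
    """
    t = np.asarray(ginf_times_min, dtype=float)
    r = np.asarray(ginf_ml_h, dtype=float)
    w = np.asarray(window_times, dtype=float)
    if t.size == 0 or np.any(w < t[0]):
        raise MissingDataError(
            f"pump record does not cover window times {window_times}")
    idx = np.searchsorted(t, w, side="right") - 1
    mg_min = r[idx] * concentration_mg_ml / 60.0
    return float(np.mean(mg_to_umol(mg_min, mw)) / weight_kg)


def clamp_quality(times_min, glucose_mmol_l,
                  config: Optional[KineticsConfig] = None,
                  ) -> tuple[float, float, bool]:
    """Clamp-success check against the euglycemic target.

    Mean basal and mean clamped glucose are each divided by the target
    (4.5 mmol/L, the centre of the 4.0–5.0 range); the clamp passes iff
    both ratios lie within ±10% (inclusive).
    """
    config = config or KineticsConfig()
    t = np.asarray(times_min, dtype=float)
    g = np.asarray(glucose_mmol_l, dtype=float)
    ratios = []
    for w in (config.basal_window, config.clamped_window):
        m = (t >= w[0]) & (t <= w[1])
        if not np.any(m):
            raise MissingDataError(f"no glucose samples in window {w}")
        ratios.append(float(np.mean(g[m]) / config.target_glucose))
    tol = config.qc_tolerance
    eps = 1e-12          # boundaries are inclusive despite float rounding
    ok = all(1.0 - tol - eps <= r <= 1.0 + tol + eps for r in ratios)
    return ratios[0], ratios[1], ok


def basal_summary(times_min, insulin_pmol_l, egp, rd,
                  config: Optional[KineticsConfig] = None,
                  on_missing_insulin: str = "error",
                  ) -> tuple[float, float, float]:
    """Basal-window summaries: (basal_egp, basal_rd, basal_insulin).

    EGP and Rd are averaged over the sample times inside the basal
    window; insulin over exactly minutes 100, 110, 115 and 120. A
    missing insulin sample raises by default, or averages the available
    ones with a warning when ``on_missing_insulin="mean"``.
    """
    config = config or KineticsConfig()
    t = np.asarray(times_min, dtype=float)
    m = (t >= config.basal_window[0]) & (t <= config.basal_window[1])
    if not np.any(m):
        raise MissingDataError("no samples in the basal window")
    b_egp = float(np.mean(np.asarray(egp, dtype=float)[m]))
    b_rd = float(np.mean(np.asarray(rd, dtype=float)[m]))

    ins = np.asarray(insulin_pmol_l, dtype=float)
    vals = []
    for bt in config.basal_insulin_times:
        hit = np.flatnonzero(np.isclose(t, bt))
        if hit.size and np.isfinite(ins[hit[0]]):
            vals.append(ins[hit[0]])
        elif on_missing_insulin == "mean":
            log.warning("basal insulin sample at %g min missing; "
                        "averaging the rest", bt)
        else:
            raise MissingDataError(
                f"basal insulin sample at {bt:g} min missing")
    if not vals:
        raise MissingDataError("all basal insulin samples missing")
    return b_egp, b_rd, float(np.mean(vals))


def analyze_clamp(series: ClampSeries, subject: SubjectRecord,
                  config: Optional[KineticsConfig] = None) -> KineticsResult:
    """Full Steele inversion of one subject's clamp series.

    Smooths glucose and enrichment over the protocol samples, evaluates
    the kinetics on the sample times from the basal equilibration
    onwards (≥100 min, avoiding the prime transient), and summarizes the
    basal and clamped windows, GIR and clamp quality.
    """
    config = config or KineticsConfig()
    W = subject.weight_kg
    g_curve = smooth_series(series.times_min, series.glucose_mmol_l,
                            config.smoothing_lambda)
    e_curve = smooth_series(series.times_min, series.ttr,
                            config.smoothing_lambda)
    q = series.times_min[series.times_min >= config.basal_window[0]]
    f_tr = float(mg_to_umol(series.tracer_rate_mg_min, config.mw))
    conc = series.ginf_concentration_mg_ml
    ginf = mg_to_umol(series.ginf_rate_at(q) * conc / 60.0, config.mw)
    e_inf = series.ginf_spike_mg_per_g / 1000.0

    ra = steele_ra_total(q, g_curve, e_curve, f_tr, ginf, e_inf,
                         config.pv_l_per_kg, W)
    egp = egp_from_ra(ra, ginf, f_tr)
    rd = rd_from_ra(q, ra, g_curve, config.pv_l_per_kg, W)
    ra_kg, egp_kg, rd_kg = ra / W, egp / W, rd / W
    mcr_kg = mcr(rd_kg, g_curve.value(q))

    ffm_scale = W / subject.ffm_kg
    b_egp, b_rd, b_ins = basal_summary(q,
        np.interp(q, series.times_min, series.insulin_pmol_l),
        egp_kg, rd_kg, config)
    cw = config.clamped_window
    cm = (q >= cw[0]) & (q <= cw[1])
    if not np.any(cm):
        raise MissingDataError("no samples in the clamped window")
    gir = gir_steady_state(series.ginf_times_min, series.ginf_ml_h, conc, W,
                           mw=config.mw)
    qc_b, qc_c, qc_ok = clamp_quality(series.times_min,
                                      series.glucose_mmol_l, config)
    bm = (q >= config.basal_window[0]) & (q <= config.basal_window[1])
    return KineticsResult(
        subject_id=series.subject_id, times_min=q,
        ra_total=ra_kg, egp=egp_kg, rd=rd_kg, mcr=mcr_kg,
        egp_ffm=egp_kg * ffm_scale, rd_ffm=rd_kg * ffm_scale,
        mcr_ffm=mcr_kg * ffm_scale,
        basal_egp=b_egp, clamped_egp=float(np.mean(egp_kg[cm])),
        basal_rd=b_rd, clamped_rd=float(np.mean(rd_kg[cm])),
        basal_mcr=float(np.mean(mcr_kg[bm])),
        clamped_mcr=float(np.mean(mcr_kg[cm])),
        basal_insulin=b_ins, gir=gir, gir_ffm=gir * ffm_scale,
        qc_basal_ratio=qc_b, qc_clamped_ratio=qc_c, qc_pass=qc_ok,
        negative_egp_flagged=bool(np.any(egp_kg < 0)),
    )
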