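"""Meal- and clamp-derived insulin-sensitivity indices.

* Matsuda index — whole-body insulin sensitivity from the fasting and
  mean post-load glucose/insulin of the six meal-test samples
  (0, 30, 60, 90, 120, 150 min): ``10000/√(G₀·I₀·Ḡ·Ī)``.
* HIR — hepatic insulin-resistance index, the product of basal glucose
  Ra (µmol·min⁻¹·kg⁻¹) and basal insulin (pmol/L); higher = more
  resistant.
* Trapezoid AUC over the meal-test window.
"""
from __future__ import annotations

import math

import numpy as np

from .errors import DomainError, MissingDataError
from .types import ISIndices, MealSeries

#: conversion factors for "conventional" Matsuda units
_MMOL_L_TO_MG_DL = 18.016     # glucose
_PMOL_L_PER_UU_ML = 6.0       # insulin


def matsuda_index(meal: MealSeries, unit_mode: str = "si") -> float:
    """Matsuda whole-body insulin-sensitivity index of one meal test.

    ``unit_mode="si"`` evaluates the formula directly on mmol/L and
    pmol/L as measured; ``"conventional"`` first converts glucose to
    mg/dL (×18.016) and insulin to µU/mL (÷6.0) for comparability with
    the index's original scale. The means include the fasting (t=0)
    sample.
    """
    g = np.asarray(meal.glucose_mmol_l, dtype=float)
    i = np.asarray(meal.insulin_pmol_l, dtype=float)
    if g.size != 6 or i.size != 6:
        raise MissingDataError("Matsuda needs all six meal time points")
    if np.any(g <= 0) or np.any(i <= 0):
        raise DomainError("glucose and insulin must be positive")
    if unit_mode == "conventional":
        g = g * _MMOL_L_TO_MG_DL
        i = i / _PMOL_L_PER_UU_ML
    elif unit_mode != "si":
        raise DomainError(f"unknown unit_mode {unit_mode!r}")
    return 10000.0 / math.sqrt(g[0] * i[0] * g.mean() * i.mean())


def hir(basal_ra: float, basal_insulin: float) -> float:
    """Hepatic insulin-resistance index: basal Ra × basal insulin.

    Basal Ra is per kg body weight (µmol·min⁻¹·kg⁻¹), insulin in pmol/L.
    """
    if not (np.isfinite(basal_ra) and np.isfinite(basal_insulin)):
        raise DomainError("HIR inputs must be finite")
    return float(basal_ra) * float(basal_insulin)


def auc_trapezoid(times, values) -> float:
    """Area under the curve by the trapezoid rule."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 2 or t.shape != v.shape:
        raise DomainError("AUC needs >= 2 aligned points")
    if np.any(np.diff(t) <= 0):
        raise DomainError("times must be strictly increasing")
    return float(np.trapezoid(v, t))


def meal_indices(meal: MealSeries, unit_mode: str = "si",
                 auc_window: tuple[float, float] = (0.0, 150.0)) -> ISIndices:
    """Matsuda and AUCs for one meal series.

    The AUC integration window is exposed because supplements of this
    protocol report glucose over minutes 1–150 and insulin over 0–150;
    the default integrates both over 0–150.
    """
    t = meal.times_min
    m = (t >= auc_window[0]) & (t <= auc_window[1])
    return ISIndices(
        subject_id=meal.subject_id,
        matsuda=matsuda_index(meal, unit_mode),
        auc_glucose=auc_trapezoid(t[m], meal.glucose_mmol_l[m]),
        auc_insulin=auc_trapezoid(t[m], meal.insulin_pmol_l[m]),
    )
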