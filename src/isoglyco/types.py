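"""Domain types shared across the pipeline.

Units follow clinical tracer-kinetics convention throughout: glucose in
mmol/L (numerically equal to µmol/mL), insulin in pmol/L, fluxes in
µmol·kg⁻¹·min⁻¹, enrichment as tracer-to-tracee ratio (TTR,
dimensionless), pump rates in mL/h, masses in kg or mg as named.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import DomainError

#: molar mass of glucose, g/mol; the tracer's extra 2 Da is ignored
#: (relative error < 1.2%, standard practice in stable-isotope work)
MW_GLUCOSE = 180.16

GENOTYPES = ("TT", "AT", "AA")
#: codominant coding: number of minor (risk) alleles
RISK_ALLELES = {"TT": 0, "AT": 1, "AA": 2}
SEXES = ("male", "female")

#: protocol sampling grid for the clamp, minutes from tracer start
CLAMP_SAMPLE_TIMES = (0.0, 100.0, 110.0, 115.0, 120.0, 150.0,
                      180.0, 210.0, 220.0, 230.0, 240.0)
#: meal-test sampling grid, minutes from meal start
MEAL_SAMPLE_TIMES = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)


def mg_to_umol(mg: float | np.ndarray, mw: float = MW_GLUCOSE):
    """Convert a glucose mass in mg to µmol."""
    return np.asarray(mg, dtype=float) * 1000.0 / mw


def umol_to_mg(umol: float | np.ndarray, mw: float = MW_GLUCOSE):
    """Convert a glucose amount in µmol to mg."""
    return np.asarray(umol, dtype=float) * mw / 1000.0


@dataclass(frozen=True)
class SubjectRecord:
    """One participant: sex, genotype and DXA-style body composition."""

    subject_id: str
    sex: str
    genotype: str
    weight_kg: float
    height_m: float
    ffm_kg: float            # lean mass excluding arms
    fat_kg: float
    visceral_fat_g: float
    android_gynoid_ratio: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise DomainError(f"unknown sex {self.sex!r}")
        if self.genotype not in GENOTYPES:
            raise DomainError(f"unknown genotype {self.genotype!r}")
        if not self.weight_kg > 0:
            raise DomainError("weight_kg must be positive")
        if not 0 < self.ffm_kg < self.weight_kg:
            raise DomainError("need 0 < ffm_kg < weight_kg")

    @property
    def risk_allele_count(self) -> int:
        return RISK_ALLELES[self.genotype]

    @property
    def bmi(self) -> float:
        return self.weight_kg / self.height_m**2


@dataclass(frozen=True)
class ClampProtocol:
    """Infusion schedule of the hyperinsulinemic euglycemic tracer clamp.

    Defaults encode the low-insulin protocol: a 170 mg tracer prime
    followed by 1.7 mg/min constant tracer infusion from time 0, insulin
    at 0.3 mU·kg⁻¹·min⁻¹ from minute 120 to 240, and a variable 20%
    dextrose infusion spiked with 8 mg tracer per g glucose, adjusted
    every 5 min to hold plasma glucose at 4.5 mmol/L.
    """

    prime_mg: float = 170.0
    tracer_rate_mg_min: float = 1.7
    insulin_rate_mU_kg_min: float = 0.3
    insulin_start_min: float = 120.0
    insulin_end_min: float = 240.0
    ginf_concentration_mg_ml: float = 200.0
    ginf_spike_mg_per_g: float = 8.0
    basal_window_min: tuple[float, float] = (100.0, 120.0)
    clamped_window_min: tuple[float, float] = (220.0, 240.0)
    controller_interval_min: float = 5.0
    target_glucose_mmol_l: float = 4.5
    sample_times_min: tuple[float, ...] = CLAMP_SAMPLE_TIMES
    end_min: float = 270.0   # glucose infusion continues 30 min past insulin

    def __post_init__(self) -> None:
        rates = (self.prime_mg, self.tracer_rate_mg_min,
                 self.insulin_rate_mU_kg_min, self.ginf_concentration_mg_ml,
                 self.ginf_spike_mg_per_g)
        if any(r < 0 for r in rates):
            raise DomainError("all protocol rates and doses must be >= 0")
        for w in (self.basal_window_min, self.clamped_window_min):
            if not (0 <= w[0] < w[1] <= 240):
                raise DomainError(f"window {w} must lie within [0, 240]")
        t = np.asarray(self.sample_times_min)
        if np.any(np.diff(t) <= 0):
            raise DomainError("sample_times_min must be sorted ascending")

    @property
    def infusate_ttr(self) -> float:
        """TTR of the spiked dextrose infusate (mg tracer per mg glucose)."""
        return self.ginf_spike_mg_per_g / 1000.0


@dataclass
class ClampSeries:
    """Measured clamp time-series for one subject.

    ``ginf_times_min``/``ginf_ml_h`` encode the pump record as a left-
    continuous step function: rate ``ginf_ml_h[i]`` applies on
    ``[ginf_times_min[i], ginf_times_min[i+1])``.
    """

    subject_id: str
    times_min: np.ndarray
    glucose_mmol_l: np.ndarray       # tracee + tracer
    ttr: np.ndarray
    insulin_pmol_l: np.ndarray
    ginf_times_min: np.ndarray
    ginf_ml_h: np.ndarray
    prime_mg: float
    tracer_rate_mg_min: float
    ginf_concentration_mg_ml: float
    ginf_spike_mg_per_g: float
    glucagon_pmol_l: Optional[dict[float, float]] = None  # min 100 and 240

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.glucose_mmol_l = np.asarray(self.glucose_mmol_l, dtype=float)
        self.ttr = np.asarray(self.ttr, dtype=float)
        self.insulin_pmol_l = np.asarray(self.insulin_pmol_l, dtype=float)
        self.ginf_times_min = np.asarray(self.ginf_times_min, dtype=float)
        self.ginf_ml_h = np.asarray(self.ginf_ml_h, dtype=float)
        if np.any(self.glucose_mmol_l <= 0):
            raise DomainError("glucose must be positive")
        if np.any((self.ttr < 0) | (self.ttr >= 1)):
            raise DomainError("ttr must lie in [0, 1)")
        if np.any(self.ginf_ml_h < 0):
            raise DomainError("pump rates must be >= 0")
        if np.any((self.times_min < 0) | (self.times_min > 270)):
            raise DomainError("times must lie within [0, 270]")

    def ginf_rate_at(self, t: np.ndarray) -> np.ndarray:
        """Pump rate (mL/h) at times ``t`` from the step record."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.ginf_times_min, t, side="right") - 1
        out = np.where(idx >= 0, self.ginf_ml_h[np.clip(idx, 0, None)], 0.0)
        return out

    def ginf_umol_min_at(self, t: np.ndarray,
                         mw: float = MW_GLUCOSE) -> np.ndarray:
        """Glucose delivery (µmol/min) implied by the pump record at ``t``."""
        mg_min = self.ginf_rate_at(t) * self.ginf_concentration_mg_ml / 60.0
        return mg_to_umol(mg_min, mw)


@dataclass
class SimulationTruth:
    """Noise-free ground truth recorded by the clamp simulator."""

    times_min: np.ndarray
    egp_umol_kg_min: np.ndarray
    rd_umol_kg_min: np.ndarray
    insulin_pmol_l: np.ndarray
    glucose_mmol_l: np.ndarray
    ttr: np.ndarray
    ginf_umol_kg_min: np.ndarray
    params: dict
    seed: Optional[int] = None

    def window_mean(self, values: np.ndarray,
                    window: tuple[float, float]) -> float:
        m = (self.times_min >= window[0]) & (self.times_min <= window[1])
        return float(np.mean(np.asarray(values)[m]))


@dataclass
class MealSeries:
    """Meal-test glucose and insulin at the six protocol times."""

    subject_id: str
    times_min: np.ndarray
    glucose_mmol_l: np.ndarray
    insulin_pmol_l: np.ndarray

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.glucose_mmol_l = np.asarray(self.glucose_mmol_l, dtype=float)
        self.insulin_pmol_l = np.asarray(self.insulin_pmol_l, dtype=float)
        if self.times_min.shape != (6,):
            raise DomainError("a meal series has exactly six time points")
        if not np.array_equal(self.times_min, np.asarray(MEAL_SAMPLE_TIMES)):
            raise DomainError(f"meal times must be {MEAL_SAMPLE_TIMES}")
        if np.any(self.glucose_mmol_l <= 0) or np.any(self.insulin_pmol_l <= 0):
            raise DomainError("meal glucose and insulin must be positive")


@dataclass(frozen=True)
class KineticsConfig:
    """Settings of the Steele inversion."""

    pv_l_per_kg: float = 0.22            # glucose distribution volume fraction
    mw: float = MW_GLUCOSE
    smoothing_lambda: float | str = "auto"   # "auto" -> GCV
    basal_window: tuple[float, float] = (100.0, 120.0)
    clamped_window: tuple[float, float] = (220.0, 240.0)
    basal_insulin_times: tuple[float, ...] = (100.0, 110.0, 115.0, 120.0)
    target_glucose: float = 4.5
    qc_tolerance: float = 0.10

    def __post_init__(self) -> None:
        if not self.pv_l_per_kg > 0:
            raise DomainError("pv_l_per_kg must be positive")
        for w in (self.basal_window, self.clamped_window):
            if not w[0] < w[1]:
                raise DomainError("windows must be ordered")
        if not 0 < self.qc_tolerance < 1:
            raise DomainError("qc_tolerance must lie in (0, 1)")


@dataclass
class KineticsResult:
    """Steele-inversion output for one subject.

    Trajectories are per kg body weight; ``*_ffm`` variants rescale by
    weight/FFM. Window summaries follow the protocol: basal = minutes
    100–120, clamped = minutes 220–240, GIR averaged at 220/230/240.
    """

    subject_id: str
    times_min: np.ndarray
    ra_total: np.ndarray                  # µmol·kg⁻¹·min⁻¹
    egp: np.ndarray
    rd: np.ndarray
    mcr: np.ndarray                       # mL·kg⁻¹·min⁻¹
    egp_ffm: np.ndarray
    rd_ffm: np.ndarray
    mcr_ffm: np.ndarray
    basal_egp: float
    clamped_egp: float
    basal_rd: float
    clamped_rd: float
    basal_mcr: float
    clamped_mcr: float
    basal_insulin: float
    gir: float                            # µmol·kg⁻¹·min⁻¹
    gir_ffm: float
    qc_basal_ratio: float
    qc_clamped_ratio: float
    qc_pass: bool
    negative_egp_flagged: bool = False

    def per_ffm(self, value: float, weight_kg: float, ffm_kg: float) -> float:
        return value * weight_kg / ffm_kg


@dataclass
class ISIndices:
    """Per-subject insulin-sensitivity indices."""

    subject_id: str
    matsuda: Optional[float] = None
    hir: Optional[float] = None           # (µmol·min⁻¹·kg⁻¹)·(pmol·L⁻¹)
    auc_glucose: Optional[float] = None   # mmol·L⁻¹·min over 0–150
    auc_insulin: Optional[float] = None   # pmol·L⁻¹·min
    gir: Optional[float] = None


@dataclass
class ContrastEstimate:
    """A genotype (or genotype×time) contrast with its bootstrap CI."""

    label: str
    estimate: float
    ci_low: float
    ci_high: float
    level: float = 0.99
    method: str = "lmm_parametric_percentile"
    n_boot: int = 0
    null_value: float = 0.0

    @property
    def significant(self) -> bool:
        """True iff the CI excludes the hypothesized (null) value."""
        return not (self.ci_low <= self.null_value <= self.ci_high)
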