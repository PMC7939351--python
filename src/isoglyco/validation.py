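"""Monte-Carlo calibration studies of the inference machinery.

These studies check, by simulation from known truth, that the bootstrap
procedures achieve their nominal operating characteristics: empirical
coverage of the parametric-bootstrap percentile interval for a mixed-
model contrast, the type-I error of the 99%-CI significance rule under
a true null, and the accuracy of the Steele inversion as the forward
simulator's inverse. They are used by the test suite and the
reproduction script; sizes are arguments so studies scale from quick
checks to publication-grade runs.
"""
from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np
import pandas as pd

from .stats import (
    Contrast,
    bootstrap_lmm_percentile,
    bootstrap_rlm_bca,
    fit_rlm,
    genotype_contrasts,
    genotype_design,
    fit_lmm_reml,
    lmm_contrasts,
)
from .synthetic_data import ClampSimParams, simulate_clamp
from .tracer_kinetics import analyze_clamp
from .types import GENOTYPES, SubjectRecord


def lmm_coverage_study(n_replicates: int = 200, n_subjects: int = 40,
                       B: int = 500, level: float = 0.99,
                       seed: Optional[int] = None,
                       intercept: float = 5.0, time_effect: float = 2.0,
                       interaction: float = 1.0,
                       tau2: float = 1.0, sigma2: float = 1.0,
                       ) -> dict:
    """Empirical coverage of the LMM parametric percentile interval.

    Simulates replicate datasets of ``n_subjects`` × 2 time points from
    a correctly specified random-intercept model in which the A/T
    genotype changes over time by ``interaction`` more than T/T, fits
    each by REML, bootstraps the A/T−T/T difference-in-change contrast,
    and reports the percentage of intervals covering the true value.
    """
    rng = np.random.default_rng(seed)
    base = n_subjects // 3
    genos = np.repeat(GENOTYPES, [n_subjects - 2 * base, base, base])
    subj = np.repeat(np.arange(n_subjects), 2)
    geno_long = np.repeat(genos, 2)
    tim = np.tile([0.0, 1.0], n_subjects)
    mean = (intercept + time_effect * tim
            + interaction * ((geno_long == "AT") & (tim == 1.0)))
    label = "A/T-T/T change 0.0->1.0"
    covered = 0
    for _ in range(n_replicates):
        b = rng.normal(0.0, np.sqrt(tau2), n_subjects)
        y = mean + b[subj] + rng.normal(0.0, np.sqrt(sigma2), 2 * n_subjects)
        df = pd.DataFrame(dict(subject_id=subj, time=tim,
                               genotype=geno_long, value=y))
        fit = fit_lmm_reml(df, "value")
        cons = [c for c in lmm_contrasts(fit) if c.label == label]
        ce = bootstrap_lmm_percentile(fit, cons, B=B, level=level,
                                      seed=int(rng.integers(2**31)))[0]
        covered += ce.ci_low <= interaction <= ce.ci_high
    return dict(coverage_pct=100.0 * covered / n_replicates,
                n_replicates=n_replicates, n_subjects=n_subjects, B=B,
                level=level, true_contrast=interaction)


def rlm_null_type1_study(n_sims: int = 1000, n_per_group: int = 20,
                         B: int = 500, level: float = 0.99,
                         seed: Optional[int] = None) -> dict:
    """Type-I error of the 99%-CI significance rule under a true null.

    Each simulated dataset has three genotype groups with identical
    Gaussian response distributions; the A/T−T/T contrast is tested by
    RLM with residual-bootstrap BCa. Returns the percentage of datasets
    whose CI excludes zero.
    """
    rng = np.random.default_rng(seed)
    genos = np.repeat(GENOTYPES, n_per_group)
    X, names = genotype_design(genos)
    false_pos = 0
    for _ in range(n_sims):
        y = rng.standard_normal(genos.size)
        fit = fit_rlm(X, y)
        con = genotype_contrasts(fit.coef, names)[0]      # A/T - T/T
        ce = bootstrap_rlm_bca(fit, [con], B=B, level=level,
                               seed=int(rng.integers(2**31)))[0]
        false_pos += ce.significant
    return dict(type1_pct=100.0 * false_pos / n_sims, n_sims=n_sims,
                n_per_group=n_per_group, B=B, level=level)


def kinetics_recovery_study(suppressions=(0.3, 0.5, 0.8),
                            s_i_values=(0.03, 0.05, 0.09),
                            egp_basals=(8.0, 10.0, 12.0),
                            seed: Optional[int] = None,
                            base_params: Optional[ClampSimParams] = None,
                            ) -> pd.DataFrame:
    """Noise-free forward-inverse recovery across a parameter grid.

    For each grid point, a clamp is simulated without measurement noise
    and inverted; the table reports relative errors of the window-
    summarized EGP and Rd against the generative truth, and the
    recovered suppression fraction.
    """
    subj = SubjectRecord("GRID", "male", "TT", 100.0, 1.80, 58.0, 35.0,
                         900.0, 0.90)
    base = base_params or ClampSimParams(cv_glucose=0.0, cv_ttr=0.0,
                                         cv_insulin=0.0)
    d_i = base.insulin_gain_pmol_per_mU * 0.3
    frac = d_i / (base.i50_pmol_l + d_i)
    rows = []
    for supp in suppressions:
        for s_i in s_i_values:
            for eb in egp_basals:
                p = replace(base, suppression_smax=supp / frac,
                            s_i_umol_kg_min_per_pmol=s_i,
                            egp_basal_umol_kg_min=eb)
                series, truth = simulate_clamp(subj, p, seed=seed)
                res = analyze_clamp(series, subj)
                tb = truth.window_mean(truth.egp_umol_kg_min, (100, 120))
                tc = truth.window_mean(truth.egp_umol_kg_min, (220, 240))
                rb = truth.window_mean(truth.rd_umol_kg_min, (100, 120))
                rc = truth.window_mean(truth.rd_umol_kg_min, (220, 240))
                rows.append(dict(
                    suppression=supp, s_i=s_i, egp_basal=eb,
                    err_basal_egp=abs(res.basal_egp - tb) / tb,
                    err_clamped_egp=abs(res.clamped_egp - tc) / max(tc, 1e-12),
                    err_basal_rd=abs(res.basal_rd - rb) / rb,
                    err_clamped_rd=abs(res.clamped_rd - rc) / rc,
                    suppression_recovered=1.0 - res.clamped_egp
                    / res.basal_egp,
                    suppression_true=1.0 - tc / tb))
    return pd.DataFrame(rows)
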