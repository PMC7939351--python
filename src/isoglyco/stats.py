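"""Inference machinery for sex-stratified genotype contrasts.

Two model families, matching how the endpoints are analyzed:

* one-time responses (Matsuda, HIR, GIR, AUCs): robust linear models by
  Huber M-estimation, with residual-bootstrap bias-corrected accelerated
  (BCa) confidence intervals;
* repeated measures (meal glucose/insulin at 30/150 min; basal vs
  clamped EGP/Rd/MCR): random-intercept linear mixed models by REML,
  with parametric residual-bootstrap percentile intervals for genotype
  and genotype×time contrasts.

Genotype always enters as a codominant three-level factor (TT reference)
— never a numeric allele dose. Significance of a contrast is declared
iff its 99% bootstrap CI excludes the hypothesized value; no further
multiplicity correction is applied.

The REML fit exploits the random-intercept structure: the criterion is
profiled over the variance ratio θ = τ²/σ², a one-dimensional problem
solved by a vectorized grid-plus-golden-section search. All bootstrap
refits run as batched linear algebra across replicates, which makes the
50000-replicate default tractable.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DesignError, DomainError, FitError
from .types import ContrastEstimate, GENOTYPES

log = logging.getLogger(__name__)

HUBER_C_DEFAULT = 1.345      # 95% Gaussian efficiency
_MAD_CONST = 0.6744897501960817   # Phi^{-1}(0.75): MAD -> sigma


@dataclass(frozen=True)
class DesignSpec:
    """Declarative description of one endpoint analysis.

    ``repeated`` lists the within-subject factor levels (e.g. (30, 150)
    for postprandial sampling or ("basal", "clamped") for the clamp);
    ``None`` marks a one-time response handled by the robust linear
    model. Genotype always enters as a three-level codominant factor —
    two indicator columns against the T/T reference — never as a
    numeric allele dose.
    """

    response: str
    stratum: str = "sex"
    repeated: Optional[tuple] = None
    covariates: tuple[str, ...] = ()
    genotype_levels: tuple[str, str, str] = GENOTYPES

    def __post_init__(self) -> None:
        if tuple(self.genotype_levels) != GENOTYPES:
            raise DesignError("genotype must be the three-level factor "
                              f"{GENOTYPES}")


# ==========================================================================
# robust linear model (Huber IRLS)
# ==========================================================================

@dataclass
class RLMFit:
    """A Huber M-estimation fit."""

    coef: np.ndarray
    scale: float
    fitted: np.ndarray
    resid: np.ndarray
    converged: bool
    n_iter: int
    X: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    c: float = HUBER_C_DEFAULT


def _irls_huber(X: np.ndarray, Y: np.ndarray, c: float,
                tol: float = 1e-10, max_iter: int = 200,
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Huber IRLS for one design and many responses.

    ``Y`` is (n, B); returns (beta (p, B), scale (B,), converged (B,),
    iterations). Scale is the median absolute deviation about zero of
    the residuals, rescaled for Gaussian consistency and re-estimated
    each iteration. A zero scale (exact fit) short-circuits to OLS.
    """
    n, p = X.shape
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ Y)          # OLS start
    done = np.zeros(Y.shape[1], dtype=bool)
    it = 0
    for it in range(1, max_iter + 1):
        R = Y - X @ beta
        scale = np.median(np.abs(R), axis=0) / _MAD_CONST
        tiny = scale <= 1e-12 * (1.0 + np.median(np.abs(Y), axis=0))
        safe = np.where(tiny, 1.0, scale)
        U = np.abs(R) / safe
        W = np.minimum(1.0, c / np.maximum(U, 1e-300))
        W[:, tiny] = 1.0
        A = np.einsum("nb,np,nq->bpq", W, X, X, optimize=True)
        rhs = np.einsum("np,nb->bp", X, W * Y, optimize=True)
        new = np.linalg.solve(A, rhs[..., None])[..., 0].T
        step = np.max(np.abs(new - beta), axis=0)
        done = step < tol * (1.0 + np.max(np.abs(new), axis=0))
        done |= tiny
        beta = new
        if np.all(done):
            break
    R = Y - X @ beta
    scale = np.median(np.abs(R), axis=0) / _MAD_CONST
    return beta, scale, done, it


def fit_rlm(X, y, c: float = HUBER_C_DEFAULT, tol: float = 1e-10,
            max_iter: int = 200) -> RLMFit:
    """Robust linear regression by Huber M-estimation (IRLS).

    Default tuning ``c = 1.345`` gives 95% efficiency at the Gaussian;
    scale is the MAD of the residuals. As ``c → ∞`` the estimate
    coincides with ordinary least squares.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise DesignError("X must be (n, p) and y length n")
    n, p = X.shape
    if n <= p:
        raise DesignError(f"need n > p, got n={n}, p={p}")
    if np.linalg.matrix_rank(X) < p:
        raise DesignError("design matrix is rank deficient")
    beta, scale, conv, it = _irls_huber(X, y[:, None], c, tol, max_iter)
    if not conv[0]:
        log.warning("Huber IRLS did not converge in %d iterations", max_iter)
    coef = beta[:, 0]
    fitted = X @ coef
    return RLMFit(coef=coef, scale=float(scale[0]), fitted=fitted,
                  resid=y - fitted, converged=bool(conv[0]), n_iter=it,
                  X=X, y=y, c=c)


class Contrast(NamedTuple):
    label: str
    vector: np.ndarray
    estimate: float


def bootstrap_quantile(draws: np.ndarray, alpha: float) -> float:
    """Bootstrap quantile by normal-scale interpolation of order
    statistics at (B+1)·alpha — the convention of the R ``boot``
    package's interval machinery, slightly wider in the extreme tails
    than linear interpolation."""
    t = np.sort(np.asarray(draws, dtype=float))
    B = t.size
    k = (B + 1.0) * alpha
    if k <= 1.0:
        return float(t[0])
    if k >= B:
        return float(t[-1])
    k1 = int(np.floor(k))
    z = sps.norm.ppf(alpha)
    z1 = sps.norm.ppf(k1 / (B + 1.0))
    z2 = sps.norm.ppf((k1 + 1.0) / (B + 1.0))
    w = 0.0 if z2 == z1 else (z - z1) / (z2 - z1)
    return float((1.0 - w) * t[k1 - 1] + w * t[k1])


def _bca_interval(theta_hat: float, boot: np.ndarray, jack: np.ndarray,
                  level: float) -> tuple[float, float]:
    """BCa endpoints from bootstrap draws and jackknife replicates."""
    B = boot.size
    if np.ptp(boot) == 0.0:
        log.warning("degenerate bootstrap distribution; zero-width interval")
        return float(boot[0]), float(boot[0])
    p0 = (np.sum(boot < theta_hat) + 0.5 * np.sum(boot == theta_hat)) / B
    p0 = np.clip(p0, 1.0 / (B + 1), B / (B + 1.0))
    z0 = sps.norm.ppf(p0)
    d = jack.mean() - jack
    denom = 6.0 * (np.sum(d**2) ** 1.5)
    a = float(np.sum(d**3) / denom) if denom > 0 else 0.0
    alpha = 1.0 - level
    out = []
    for za in (sps.norm.ppf(alpha / 2), sps.norm.ppf(1 - alpha / 2)):
        adj = z0 + (z0 + za) / (1.0 - a * (z0 + za))
        out.append(bootstrap_quantile(boot, float(sps.norm.cdf(adj))))
    return out[0], out[1]


def bootstrap_rlm_bca(fit: RLMFit, contrasts: Sequence[Contrast] | None = None,
                      B: int = 50000, level: float = 0.99,
                      seed: Optional[int] = None,
                      ) -> list[ContrastEstimate]:
    """Residual-bootstrap BCa intervals for RLM contrasts.

    Centred residuals are resampled onto the fitted values and the model
    refitted ``B`` times; the bias correction z₀ comes from the
    bootstrap CDF at the point estimate and the acceleration from
    jackknife influence values.
    """
    if B < 100:
        raise DomainError("B must be >= 100")
    if not 0.0 < level < 1.0:
        raise DomainError("level must lie in (0, 1)")
    if contrasts is None:
        contrasts = [Contrast(f"b{j}", np.eye(len(fit.coef))[j],
                              float(fit.coef[j]))
                     for j in range(len(fit.coef))]
    rng = np.random.default_rng(seed)
    n = fit.X.shape[0]
    rc = fit.resid - fit.resid.mean()
    idx = rng.integers(0, n, size=(B, n))
    Ystar = fit.fitted[:, None] + rc[idx].T
    betas, _, _, _ = _irls_huber(fit.X, Ystar, fit.c)

    # jackknife (leave-one-out) refits for the acceleration constant
    jack_coef = np.empty((n, len(fit.coef)))
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        b, _, _, _ = _irls_huber(fit.X[mask], fit.y[mask, None], fit.c)
        jack_coef[i] = b[:, 0]
        mask[i] = True

    out = []
    for con in contrasts:
        v = np.asarray(con.vector, dtype=float)
        boot = v @ betas
        lo, hi = _bca_interval(con.estimate, boot, jack_coef @ v, level)
        out.append(ContrastEstimate(label=con.label, estimate=con.estimate,
                                    ci_low=lo, ci_high=hi, level=level,
                                    method="rlm_residual_bca", n_boot=B))
    return out


def genotype_design(genotypes: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Codominant one-time design: intercept + AT and AA indicators."""
    g = np.asarray(genotypes)
    X = np.column_stack([np.ones(g.size),
                         (g == "AT").astype(float),
                         (g == "AA").astype(float)])
    return X, ["Intercept", "geno[AT]", "geno[AA]"]


def genotype_contrasts(coef: np.ndarray,
                       names: Sequence[str]) -> list[Contrast]:
    """The three pairwise genotype contrasts for a one-time design."""
    iat, iaa = names.index("geno[AT]"), names.index("geno[AA]")
    p = len(names)

    def vec(plus=None, minus=None):
        v = np.zeros(p)
        if plus is not None:
            v[plus] += 1.0
        if minus is not None:
            v[minus] -= 1.0
        return v

    spec = [("A/T-T/T", vec(iat)), ("A/A-A/T", vec(iaa, iat)),
            ("A/A-T/T", vec(iaa))]
    return [Contrast(lbl, v, float(v @ coef)) for lbl, v in spec]


# ==========================================================================
# random-intercept linear mixed model (REML)
# ==========================================================================

_THETA_GRID = np.concatenate([[0.0], np.logspace(-4, 3, 29)])


def _reml_crit(theta, XtX, Sx, n_i, XtY, SY, YtY, N):
    """REML profile criterion, beta and RSS at variance ratio(s) theta.

    ``theta`` may be a scalar (shared by all B response columns) or a
    length-B vector (one ratio per column). Returns arrays over B.
    """
    p = XtX.shape[0]
    B = XtY.shape[1]
    th = np.broadcast_to(np.asarray(theta, dtype=float), (B,))
    c = th[None, :] * n_i[:, None] / (1.0 + n_i[:, None] * th[None, :])
    c = c / n_i[:, None]          # c_g = theta/(1+n_g*theta)
    A = XtX[None, :, :] - np.einsum("gb,gp,gq->bpq", c, Sx, Sx,
                                    optimize=True)
    r = XtY.T - np.einsum("gb,gp->bp", c * SY, Sx, optimize=True)
    q = YtY - np.sum(c * SY**2, axis=0)
    beta = np.linalg.solve(A, r[..., None])[..., 0]
    rss = np.maximum(q - np.einsum("bp,bp->b", beta, r), 1e-300)
    _, logdet = np.linalg.slogdet(A)
    pen = np.sum(np.log1p(np.outer(n_i, th)), axis=0)
    crit = (N - p) * np.log(rss) + pen + logdet
    return crit, beta, rss


def _reml_profile(XtX, Sx, n_i, XtY, SY, YtY, N,
                  n_golden: int = 40):
    """Profile the REML criterion over θ for each response column.

    Grid search over a log-spaced set of variance ratios followed by a
    vectorized golden-section refinement within the bracketing cells.
    """
    B = XtY.shape[1]
    crits = np.empty((_THETA_GRID.size, B))
    for i, th in enumerate(_THETA_GRID):
        crits[i], _, _ = _reml_crit(th, XtX, Sx, n_i, XtY, SY, YtY, N)
    best = np.argmin(crits, axis=0)
    lo = _THETA_GRID[np.maximum(best - 1, 0)]
    hi = _THETA_GRID[np.minimum(best + 1, _THETA_GRID.size - 1)]
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo.copy(), hi.copy()
    x1 = b - phi * (b - a)
    x2 = a + phi * (b - a)
    f1, _, _ = _reml_crit(x1, XtX, Sx, n_i, XtY, SY, YtY, N)
    f2, _, _ = _reml_crit(x2, XtX, Sx, n_i, XtY, SY, YtY, N)
    for _ in range(n_golden):
        left = f1 < f2
        b = np.where(left, x2, b)
        a = np.where(left, a, x1)
        x1c = b - phi * (b - a)
        x2c = a + phi * (b - a)
        probe = np.where(left, x1c, x2c)   # the one new point per column
        fp, _, _ = _reml_crit(probe, XtX, Sx, n_i, XtY, SY, YtY, N)
        x1, x2, f1, f2 = (np.where(left, x1c, x2),
                          np.where(left, x1, x2c),
                          np.where(left, fp, f2),
                          np.where(left, f1, fp))
    theta = 0.5 * (a + b)
    theta = np.where(best == 0, np.minimum(theta, _THETA_GRID[1]), theta)
    crit, beta, rss = _reml_crit(theta, XtX, Sx, n_i, XtY, SY, YtY, N)
    # boundary: compare against theta exactly 0
    crit0, beta0, rss0 = _reml_crit(0.0, XtX, Sx, n_i, XtY, SY, YtY, N)
    at0 = crit0 <= crit
    theta = np.where(at0, 0.0, theta)
    crit = np.where(at0, crit0, crit)
    rss = np.where(at0, rss0, rss)
    beta = np.where(at0[:, None], beta0, beta)
    return theta, beta, rss, crit


@dataclass
class LMMFit:
    """A fitted random-intercept linear mixed model."""

    params: np.ndarray
    names: list[str]
    tau2: float                 # between-subject (random intercept) variance
    sigma2: float               # residual variance
    reml_loglik: float
    X: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    groups: np.ndarray = field(repr=False, default=None)
    n_groups: int = 0
    time_levels: tuple = ()
    genotype_levels: tuple = ()

    @property
    def icc(self) -> float:
        """Intraclass correlation: τ²/(τ²+σ²)."""
        tot = self.tau2 + self.sigma2
        return self.tau2 / tot if tot > 0 else 0.0


def lmm_design(data: pd.DataFrame, response: str,
               subject: str = "subject_id", time: str = "time",
               genotype: str = "genotype",
               time_levels: Optional[Sequence] = None,
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str],
                          tuple, tuple]:
    """Fixed-effects design for ``response ~ time * genotype`` with a
    subject random intercept. Reference cell: genotype TT at the
    earliest time level."""
    for col in (response, subject, time, genotype):
        if col not in data.columns:
            raise DesignError(f"column {col!r} missing from data")
    df = data.dropna(subset=[response]).copy()
    tl = tuple(time_levels) if time_levels is not None \
        else tuple(sorted(df[time].unique()))
    df = df[df[time].isin(tl)]
    gl = tuple(g for g in GENOTYPES if g in set(df[genotype]))
    cols = [np.ones(len(df))]
    names = ["Intercept"]
    for t in tl[1:]:
        cols.append((df[time] == t).to_numpy(float))
        names.append(f"time[{t}]")
    for g in gl[1:]:
        cols.append((df[genotype] == g).to_numpy(float))
        names.append(f"geno[{g}]")
    for g in gl[1:]:
        for t in tl[1:]:
            cols.append(((df[genotype] == g) & (df[time] == t))
                        .to_numpy(float))
            names.append(f"geno[{g}]:time[{t}]")
    X = np.column_stack(cols)
    y = df[response].to_numpy(float)
    codes, _ = pd.factorize(df[subject])
    return X, y, codes, names, tl, gl


def fit_lmm_reml(data: pd.DataFrame, response: str,
                 subject: str = "subject_id", time: str = "time",
                 genotype: str = "genotype",
                 time_levels: Optional[Sequence] = None) -> LMMFit:
    """REML fit of ``response ~ time*genotype + (1|subject)``.

    The criterion is profiled over θ = τ²/σ² (one-dimensional) and τ² is
    floored at zero on the boundary.
    """
    X, y, groups, names, tl, gl = lmm_design(data, response, subject, time,
                                             genotype, time_levels)
    return _fit_reml_arrays(X, y, groups, names, tl, gl)


def _aggregates(X, groups):
    G = int(groups.max()) + 1
    p = X.shape[1]
    Sx = np.zeros((G, p))
    np.add.at(Sx, groups, X)
    n_i = np.bincount(groups, minlength=G).astype(float)
    return X.T @ X, Sx, n_i, G


def _fit_reml_arrays(X, y, groups, names, tl=(), gl=()) -> LMMFit:
    N, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise DesignError("fixed-effects design is rank deficient; "
                          "check that requested cells are populated")
    XtX, Sx, n_i, G = _aggregates(X, groups)
    XtY = X.T @ y[:, None]
    SY = np.zeros((G, 1))
    np.add.at(SY, groups, y[:, None])
    YtY = np.array([y @ y])
    theta, beta, rss, crit = _reml_profile(XtX, Sx, n_i, XtY, SY, YtY, N)
    if not np.all(np.isfinite(crit)):
        raise FitError("REML profile criterion is not finite")
    sigma2 = float(rss[0] / (N - p))
    tau2 = float(theta[0] * sigma2)
    loglik = -0.5 * float(crit[0] - (N - p) * np.log(N - p)
                          + (N - p) * (1.0 + np.log(2.0 * np.pi)))
    return LMMFit(params=beta[0], names=list(names), tau2=tau2,
                  sigma2=sigma2, reml_loglik=loglik, X=X, y=y,
                  groups=groups, n_groups=G, time_levels=tuple(tl),
                  genotype_levels=tuple(gl))


_PAIR_LABELS = {("AT", "TT"): "A/T-T/T", ("AA", "AT"): "A/A-A/T",
                ("AA", "TT"): "A/A-T/T"}


def _geno_vec(fit: LMMFit, g: str, t, at_time: bool) -> np.ndarray:
    v = np.zeros(len(fit.names))
    if g != fit.genotype_levels[0]:
        v[fit.names.index(f"geno[{g}]")] = 1.0
        if at_time and t != fit.time_levels[0]:
            v[fit.names.index(f"geno[{g}]:time[{t}]")] = 1.0
    return v


def lmm_contrasts(fit: LMMFit,
                  at_times: Optional[Sequence] = None,
                  genotype_pairs: Optional[Sequence[tuple]] = None,
                  include_interaction: bool = True) -> list[Contrast]:
    """Genotype contrasts at each time, plus difference-in-change
    (genotype×time interaction) contrasts.

    The interaction contrast is the between-genotype difference in the
    change from the reference time to ``t`` — e.g. the difference in
    insulin-induced suppression when the levels are basal/clamped. The
    three pairwise contrasts telescope exactly:
    (A/T−T/T) + (A/A−A/T) = (A/A−T/T).
    """
    pairs = list(genotype_pairs) if genotype_pairs is not None else \
        [p for p in _PAIR_LABELS if p[0] in fit.genotype_levels
         and p[1] in fit.genotype_levels]
    times = list(at_times) if at_times is not None else list(fit.time_levels)
    out: list[Contrast] = []
    for g2, g1 in pairs:
        for g in (g2, g1):
            if g not in fit.genotype_levels:
                raise DesignError(f"genotype {g} absent from the fit")
        lbl = _PAIR_LABELS.get((g2, g1), f"{g2}-{g1}")
        for t in times:
            if t not in fit.time_levels:
                raise DesignError(f"time level {t!r} absent from the fit")
            v = _geno_vec(fit, g2, t, True) - _geno_vec(fit, g1, t, True)
            out.append(Contrast(f"{lbl} at {t}", v,
                                float(v @ fit.params)))
        if include_interaction and len(fit.time_levels) > 1:
            for t in fit.time_levels[1:]:
                v = (_geno_vec(fit, g2, t, True) - _geno_vec(fit, g2, t, False)
                     - _geno_vec(fit, g1, t, True)
                     + _geno_vec(fit, g1, t, False))
                out.append(Contrast(
                    f"{lbl} change {fit.time_levels[0]}->{t}", v,
                    float(v @ fit.params)))
    return out


def bootstrap_lmm_percentile(fit: LMMFit,
                             contrasts: Optional[Sequence[Contrast]] = None,
                             B: int = 50000, level: float = 0.99,
                             seed: Optional[int] = None,
                             batch: int = 2000) -> list[ContrastEstimate]:
    """Parametric residual bootstrap with percentile intervals.

    Each replicate simulates new random intercepts ~ N(0, τ̂²) and
    residuals ~ N(0, σ̂²) around the fitted fixed effects, then refits
    the model by REML (variance components re-estimated every
    replicate). Intervals are percentile intervals of the contrast
    draws.
    """
    if not 0.0 < level < 1.0:
        raise DomainError("level must lie in (0, 1)")
    if contrasts is None:
        contrasts = lmm_contrasts(fit)
    if fit.tau2 == 0.0 and fit.sigma2 == 0.0:
        log.warning("degenerate fit (zero variances): zero-width intervals")
        return [ContrastEstimate(label=c.label, estimate=c.estimate,
                                 ci_low=c.estimate, ci_high=c.estimate,
                                 level=level,
                                 method="lmm_parametric_percentile",
                                 n_boot=B) for c in contrasts]
    rng = np.random.default_rng(seed)
    N, p = fit.X.shape
    XtX, Sx, n_i, G = _aggregates(fit.X, fit.groups)
    fitted = fit.X @ fit.params
    V = np.stack([np.asarray(c.vector, dtype=float) for c in contrasts])
    draws = np.empty((len(contrasts), B))
    for start in range(0, B, batch):
        nb = min(batch, B - start)
        b_re = rng.standard_normal((G, nb)) * np.sqrt(fit.tau2)
        eps = rng.standard_normal((N, nb)) * np.sqrt(fit.sigma2)
        Y = fitted[:, None] + b_re[fit.groups] + eps
        XtY = fit.X.T @ Y
        SY = np.zeros((G, nb))
        np.add.at(SY, fit.groups, Y)
        YtY = np.sum(Y * Y, axis=0)
        _, beta, _, _ = _reml_profile(XtX, Sx, n_i, XtY, SY, YtY, N)
        draws[:, start:start + nb] = V @ beta.T
    alpha = 1.0 - level
    lo = np.array([bootstrap_quantile(d, alpha / 2) for d in draws])
    hi = np.array([bootstrap_quantile(d, 1 - alpha / 2) for d in draws])
    return [ContrastEstimate(label=c.label, estimate=c.estimate,
                             ci_low=float(lo[i]), ci_high=float(hi[i]),
                             level=level,
                             method="lmm_parametric_percentile", n_boot=B)
            for i, c in enumerate(contrasts)]


# ==========================================================================
# nonparametric group tests
# ==========================================================================

def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis one-way test with tie adjustment."""
    _check_groups(groups, 2)
    if _all_identical(groups):
        log.warning("all values identical across groups; p = 1")
        return 0.0, 1.0
    stat, p = sps.kruskal(*groups)
    return float(stat), float(p)


def wilcoxon_mann_whitney(x, y) -> tuple[float, float]:
    """Wilcoxon-Mann-Whitney two-sample test (asymptotic, two-sided)."""
    _check_groups((x, y), 2)
    if _all_identical((x, y)):
        log.warning("all values identical across groups; p = 1")
        return float(len(np.atleast_1d(x)) * len(np.atleast_1d(y)) / 2), 1.0
    stat, p = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic")
    return float(stat), float(p)


def chi_squared_proportions(table) -> tuple[float, float]:
    """Chi-squared comparison of proportions on a contingency table
    (no continuity correction)."""
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise DomainError("need a 2-D contingency table")
    res = sps.chi2_contingency(tab, correction=False)
    return float(res.statistic), float(res.pvalue)


def _check_groups(groups, k_min):
    if len(groups) < k_min:
        raise DomainError(f"need >= {k_min} groups")
    for g in groups:
        if len(np.atleast_1d(g)) < 1:
            raise DomainError("every group needs >= 1 observation")


def _all_identical(groups) -> bool:
    allv = np.concatenate([np.atleast_1d(np.asarray(g, float))
                           for g in groups])
    return bool(np.all(allv == allv[0]))
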