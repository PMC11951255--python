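"""Two-sample MR estimators: IVW (multiplicative random effects), LD-adjusted
IVW, MR-Egger, weighted median, contamination mixture, MR-PRESSO, and
multivariable IVW.

All estimators consume a :class:`~cismr.summary_stats.HarmonizedSet`.  The IVW
family are weighted least-squares fits of variant-outcome on variant-exposure
associations (through the origin, weights 1/se_Y^2); "multiplicative random
effects" inflates the fixed-effect standard error by sqrt(Q/df) floored at 1,
so heterogeneity can widen but never shrink confidence intervals.  The robust
methods each relax the exclusion-restriction assumption in a different way:
Egger allows a directional pleiotropy intercept; the weighted median is
consistent while valid instruments carry a weight majority; the contamination
mixture profiles a two-component valid/invalid likelihood over candidate
effects; MR-PRESSO tests for and removes residual outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import linalg as sla
from scipy import stats as sps

from .summary_stats import LOG_ODDS, HarmonizedSet

Z975 = 1.959964  # standard normal 97.5% quantile used for all 95% CIs
CHI2_1_95_HALF = 1.920729  # chi2(1) 95% critical value / 2 (profile-CI cut)


class EstimationError(ValueError):
    """Fatal estimation failure (irrelevant instruments, singular LD, ...)."""


@dataclass
class MREstimate:
    """A causal-effect estimate with uncertainty and heterogeneity metadata.

    ``theta`` is the effect per 1 SD of the exposure (log-odds per SD when the
    outcome is binary).
    """

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    q_stat: float = float("nan")
    scale_factor: float = 1.0
    exposure_name: str = "exposure"
    outcome_scale: str = "sd_units"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("negative se")
        if self.scale_factor < 1.0 - 1e-12:
            raise ValueError("scale_factor below 1")
        if not (self.ci_low - 1e-12 <= self.theta <= self.ci_high + 1e-12):
            raise ValueError("point estimate outside its CI")

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.theta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    def flipped(self) -> "MREstimate":
        """The same estimate reported per 1 SD *decrease* of the exposure."""
        return replace(self, theta=-self.theta, ci_low=-self.ci_high,
                       ci_high=-self.ci_low)

    def rescaled(self, divisor: float, method: str | None = None) -> "MREstimate":
        """Divide effect and uncertainty by a positive scale (e.g. trait SD
        in natural units, to express the effect per unit instead of per SD)."""
        if divisor <= 0:
            raise ValueError("rescale divisor must be positive")
        return replace(self, theta=self.theta / divisor, se=self.se / divisor,
                       ci_low=self.ci_low / divisor,
                       ci_high=self.ci_high / divisor,
                       method=method or self.method)


@dataclass
class RatioEstimates:
    """Per-variant Wald ratios theta_j = beta_Yj / beta_Xj with first-order
    standard errors se_Yj / |beta_Xj|."""

    ratio: np.ndarray
    se: np.ndarray


def _finalize(method: str, theta: float, se: float, j: int, q: float,
              scale: float, h: HarmonizedSet, exposure_name: str) -> MREstimate:
    pval = 2.0 * sps.norm.sf(abs(theta) / se) if se > 0 else (0.0 if theta else 1.0)
    return MREstimate(method=method, theta=float(theta), se=float(se),
                      ci_low=float(theta - Z975 * se),
                      ci_high=float(theta + Z975 * se),
                      pval=float(pval), n_snps=j, q_stat=float(q),
                      scale_factor=float(scale), exposure_name=exposure_name,
                      outcome_scale=h.outcome_scale)


def _single_exposure(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, str]:
    if h.n_exposures != 1:
        raise EstimationError("univariable estimator requires a single exposure")
    return h.beta_exposure[:, 0], h.se_exposure[:, 0], h.exposure_names[0]


def ratio_estimates(h: HarmonizedSet) -> RatioEstimates:
    x, _, _ = _single_exposure(h)
    if np.any(x == 0):
        raise EstimationError("ratio estimates undefined for beta_X = 0")
    return RatioEstimates(h.beta_outcome / x, h.se_outcome / np.abs(x))


# ---------------------------------------------------------------------------
# IVW family
# ---------------------------------------------------------------------------

def ivw(h: HarmonizedSet) -> MREstimate:
    """Inverse-variance-weighted estimate with multiplicative random effects.

    WLS of beta_Y on beta_X through the origin with weights 1/se_Y^2; the
    fixed-effect SE is inflated by max(1, sqrt(Q/(J-1))) when J >= 2.
    """
    x, _, name = _single_exposure(h)
    y, sy = h.beta_outcome, h.se_outcome
    if np.all(x == 0):
        raise EstimationError("irrelevant_instruments: all beta_X are zero")
    j = len(x)
    w = 1.0 / sy ** 2
    sxx = float(np.sum(w * x * x))
    theta = float(np.sum(w * x * y)) / sxx
    se_fixed = sxx ** -0.5
    q = float(np.sum(w * (y - theta * x) ** 2))
    scale = max(1.0, np.sqrt(q / (j - 1))) if j >= 2 else 1.0
    return _finalize("ivw_mre", theta, scale * se_fixed, j, q, scale, h, name)


def ivw_ld(h: HarmonizedSet) -> MREstimate:
    """IVW accounting for residual correlation between instruments via
    generalized least squares with Omega = diag(se_Y) rho diag(se_Y)."""
    if h.ld is None:
        raise EstimationError("ivw_ld requires an LD matrix")
    x, _, name = _single_exposure(h)
    y, sy = h.beta_outcome, h.se_outcome
    if np.all(x == 0):
        raise EstimationError("irrelevant_instruments: all beta_X are zero")
    j = len(x)
    omega = sy[:, None] * h.ld.r * sy[None, :]
    eigs = np.linalg.eigvalsh(h.ld.r)
    if eigs.min() < 1e-10 * max(eigs.max(), 1.0):
        raise EstimationError("singular_ld: LD matrix is not invertible")
    cho = sla.cho_factor(omega)
    oinv_x = sla.cho_solve(cho, x)
    oinv_y = sla.cho_solve(cho, y)
    sxx = float(x @ oinv_x)
    theta = float(x @ oinv_y) / sxx
    se_fixed = sxx ** -0.5
    resid = y - theta * x
    q = float(resid @ sla.cho_solve(cho, resid))
    scale = max(1.0, np.sqrt(q / (j - 1))) if j >= 2 else 1.0
    return _finalize("ivw_ld", theta, scale * se_fixed, j, q, scale, h, name)


def egger(h: HarmonizedSet) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: WLS of beta_Y on beta_X *with* an intercept
    (directional-pleiotropy term), after orienting every variant to
    beta_X >= 0.  Returns (slope, intercept) estimates; SEs carry the
    multiplicative overdispersion factor max(1, sqrt(Q/(J-2)))."""
    x, _, name = _single_exposure(h)
    y, sy = h.beta_outcome.copy(), h.se_outcome
    j = len(x)
    if j < 3:
        raise EstimationError("egger requires at least 3 instruments")
    flip = np.sign(x)
    flip[flip == 0] = 1.0
    x = x * flip
    y = y * flip
    if np.ptp(x) == 0:
        raise EstimationError("unidentified: no variation in beta_X")
    w = 1.0 / sy ** 2
    design = np.column_stack([np.ones(j), x])
    gram = design.T @ (design * w[:, None])
    coef = np.linalg.solve(gram, design.T @ (w * y))
    resid = y - design @ coef
    q = float(np.sum(w * resid ** 2))
    scale = max(1.0, np.sqrt(q / (j - 2))) if j > 2 else 1.0
    cov = np.linalg.inv(gram) * scale ** 2
    slope = _finalize("egger", coef[1], np.sqrt(cov[1, 1]), j, q, scale, h, name)
    intercept = _finalize("egger_intercept", coef[0], np.sqrt(cov[0, 0]),
                          j, q, scale, h, name)
    return slope, intercept


# ---------------------------------------------------------------------------
# Robust estimators
# ---------------------------------------------------------------------------

def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v = values[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, v))


def weighted_median(h: HarmonizedSet, n_boot: int = 5000,
                    seed: int | None = None) -> MREstimate:
    """Weighted median of the per-variant Wald ratios (weights proportional to
    inverse ratio variance); consistent when valid instruments carry more than
    half the weight.  SE by seeded parametric bootstrap over the summary
    associations."""
    x, sx, name = _single_exposure(h)
    if len(x) < 3:
        raise EstimationError("weighted_median requires at least 3 instruments")
    r = ratio_estimates(h)
    weights = 1.0 / r.se ** 2
    theta = _weighted_median(r.ratio, weights)
    rng = np.random.default_rng(seed)
    bx = rng.normal(x, sx, size=(n_boot, len(x)))
    by = rng.normal(h.beta_outcome, h.se_outcome, size=(n_boot, len(x)))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        xb = bx[b]
        xb[xb == 0] = np.finfo(float).tiny
        rb = by[b] / xb
        wb = (xb / h.se_outcome) ** 2
        boots[b] = _weighted_median(rb, wb)
    se = float(np.std(boots, ddof=1))
    est = _finalize("weighted_median", theta, se, len(x), float("nan"),
                    1.0, h, name)
    return est


def conmix(h: HarmonizedSet, psi: float | None = None,
           grid_halfwidth_se: float = 5.0,
           grid_points: int = 1001) -> MREstimate:
    """Contamination-mixture estimate.

    Each variant's Wald ratio is modelled as either valid, N(theta, se_j^2),
    or invalid, N(0, psi^2 + se_j^2); the profile log-likelihood over a grid
    of candidate theta sums the better of the two terms per variant.  The 95%
    CI is the likelihood region within chi2(1,0.95)/2 of the maximum; a
    non-contiguous region is flagged multimodal and its enclosing hull is
    reported.
    """
    x, _, name = _single_exposure(h)
    if len(x) < 3:
        raise EstimationError("conmix requires at least 3 instruments")
    r = ratio_estimates(h)
    spread = float(np.std(r.ratio, ddof=1)) if len(x) > 1 else 0.0
    degenerate = spread <= 1e-12 * max(1.0, float(np.max(np.abs(r.ratio))))
    if psi is None:
        psi = 1.5 * spread
    if degenerate or psi == 0.0:
        # degenerate consensus: all ratios identical
        theta = float(r.ratio[0])
        est = _finalize("conmix", theta, 0.0, len(x), 0.0, 1.0, h, name)
        est.extra.update(valid=np.ones(len(x), bool), multimodal=False, psi=psi)
        return est
    pad = grid_halfwidth_se * float(np.max(r.se))
    grid = np.linspace(r.ratio.min() - pad, r.ratio.max() + pad, grid_points)
    ll_valid = -0.5 * ((r.ratio[None, :] - grid[:, None]) / r.se[None, :]) ** 2 \
        - np.log(r.se)[None, :]
    var_inv = psi ** 2 + r.se ** 2
    ll_invalid = (-0.5 * r.ratio ** 2 / var_inv - 0.5 * np.log(var_inv))[None, :]
    profile = np.maximum(ll_valid, ll_invalid).sum(axis=1)
    best = int(np.argmax(profile))
    theta = float(grid[best])
    in_region = profile >= profile[best] - CHI2_1_95_HALF
    idx = np.flatnonzero(in_region)
    ci_low, ci_high = float(grid[idx[0]]), float(grid[idx[-1]])
    multimodal = bool(np.any(np.diff(idx) > 1))
    se = (ci_high - ci_low) / (2 * Z975) if ci_high > ci_low else 0.0
    pval = 2.0 * sps.norm.sf(abs(theta) / se) if se > 0 else (0.0 if theta else 1.0)
    est = MREstimate(method="conmix", theta=theta, se=se, ci_low=ci_low,
                     ci_high=ci_high, pval=float(pval), n_snps=len(x),
                     exposure_name=name, outcome_scale=h.outcome_scale)
    est.extra.update(valid=ll_valid[best] >= ll_invalid[0], multimodal=multimodal,
                     psi=psi)
    if multimodal:
        warnings.warn("conmix: multimodal confidence region; hull reported")
    return est


def _loo_ivw_thetas(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sxy = np.sum(w * x * y)
    sxx = np.sum(w * x * x)
    return (sxy - w * x * y) / (sxx - w * x * x)


def presso(h: HarmonizedSet, n_sim: int = 1000, outlier_alpha: float = 0.05,
           seed: int | None = None) -> tuple[float, np.ndarray, MREstimate]:
    """MR-PRESSO global heterogeneity and outlier test.

    The observed residual sum of squares uses leave-one-out IVW fits; its null
    distribution comes from parametric simulation of outcome associations
    around the leave-one-out predictions.  Per-variant outlier p-values are
    Bonferroni-corrected by the instrument count; the corrected estimate is
    IVW on the unflagged variants.  Returns (global_p, outlier_flags,
    corrected_estimate).
    """
    x, _, name = _single_exposure(h)
    y, sy = h.beta_outcome, h.se_outcome
    j = len(x)
    if j < 4:
        raise EstimationError("presso requires at least 4 instruments")
    w = 1.0 / sy ** 2
    theta_loo = _loo_ivw_thetas(x, y, w)
    obs_terms = w * (y - theta_loo * x) ** 2
    rss_obs = float(obs_terms.sum())

    rng = np.random.default_rng(seed)
    y_sim = rng.normal(theta_loo * x, sy, size=(n_sim, j))
    sxx = np.sum(w * x * x)
    sxy_sim = y_sim @ (w * x)
    theta_loo_sim = (sxy_sim[:, None] - w * x * y_sim) / (sxx - w * x * x)
    sim_terms = w * (y_sim - theta_loo_sim * x) ** 2
    rss_sim = sim_terms.sum(axis=1)

    global_p = float(np.mean(rss_sim >= rss_obs))
    p_variant = np.mean(sim_terms >= obs_terms[None, :], axis=0)
    flags = p_variant * j < outlier_alpha
    if flags.all():
        raise EstimationError("no_instruments_remain: every variant flagged")
    sub = HarmonizedSet.from_arrays(
        x[~flags], h.se_exposure[~flags, 0], y[~flags], sy[~flags],
        exposure_names=[name],
        variant_ids=[v for v, f in zip(h.variant_ids, flags) if not f],
        outcome_scale=h.outcome_scale)
    corrected = ivw(sub)
    corrected.method = "presso_corrected"
    corrected.extra.update(global_p=global_p, n_outliers=int(flags.sum()))
    return global_p, flags, corrected


# ---------------------------------------------------------------------------
# Multivariable IVW
# ---------------------------------------------------------------------------

def mvmr_ivw(h: HarmonizedSet) -> list[MREstimate]:
    """Multivariable IVW: WLS of beta_Y on the variant x exposure matrix with
    no intercept and weights 1/se_Y^2; one conditional estimate per exposure,
    with multiplicative overdispersion max(1, sqrt(Q/(J-k)))."""
    bx = h.beta_exposure
    y, sy = h.beta_outcome, h.se_outcome
    j, k = bx.shape
    if j <= k:
        raise EstimationError("mvmr_ivw requires more instruments than exposures")
    w = 1.0 / sy ** 2
    gram = bx.T @ (bx * w[:, None])
    if np.linalg.cond(gram) > 1e12:
        raise EstimationError("collinear_exposures")
    coef = np.linalg.solve(gram, bx.T @ (w * y))
    resid = y - bx @ coef
    q = float(np.sum(w * resid ** 2))
    scale = max(1.0, np.sqrt(q / (j - k)))
    cov = np.linalg.inv(gram) * scale ** 2
    return [
        _finalize("mvmr_ivw", coef[m], np.sqrt(cov[m, m]), j, q, scale, h,
                  h.exposure_names[m])
        for m in range(k)
    ]
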