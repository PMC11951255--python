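"""Two-step cis-MR mediation: decompose a cis-instrumented exposure-outcome
effect into a path through a mediator (indirect) and a residual direct path.

Two routes to the direct effect are provided and should agree on well-behaved
data: (i) the coefficient route — indirect = theta_XM * theta_MY by the
product method, direct = total - indirect by the difference method; and
(ii) the variant-level route — subtract theta_MY * beta_Mj from each variant's
outcome association and re-run IVW on the adjusted associations ("adjusting
for" the mediator).  Uncertainty for the decomposition comes from a seeded
parametric bootstrap over the three component estimates, treated as
independent (two-sample framing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .estimators import EstimationError, MREstimate, ivw, ivw_ld
from .summary_stats import HarmonizedSet


class MediationError(ValueError):
    """Fatal mediation-analysis failure."""


@dataclass
class MediationInputs:
    """The three component estimates plus the per-variant cis set.

    ``cis_set`` must carry both the exposure and the mediator associations for
    every cis instrument (two exposure columns), alongside the outcome.
    ``theta_xm`` and ``theta_total`` must come from the same cis instruments;
    ``theta_my`` is the genome-wide mediator-outcome estimate.
    """

    theta_total: MREstimate
    theta_xm: MREstimate
    theta_my: MREstimate
    cis_set: HarmonizedSet | None = None


@dataclass
class MediationResult:
    """Total/direct/indirect decomposition with bootstrap uncertainty."""

    total: float
    indirect_product: float
    direct_difference: float
    proportion_mediated: float
    direct_variant_level: MREstimate | None = None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    se: dict[str, float] = field(default_factory=dict)
    n_boot: int = 0
    seed: int | None = None
    guard_rejections: int = 0
    flags: list[str] = field(default_factory=list)


def indirect_product(theta_xm: MREstimate, theta_my: MREstimate) -> float:
    """Product-of-coefficients indirect effect: theta_XM * theta_MY."""
    return theta_xm.theta * theta_my.theta


def direct_difference(theta_total: MREstimate, indirect: float) -> float:
    """Difference-method direct effect: total - indirect."""
    return theta_total.theta - indirect


def proportion_mediated(total: float, indirect: float) -> float:
    """indirect / total on the log-odds scale; values outside [0, 1] are
    returned as-is (sampling variation can push the CI past those bounds)."""
    if total == 0:
        raise MediationError("undefined_proportion: total effect is zero")
    return indirect / total


def adjusted_outcome_mr(cis_set: HarmonizedSet, theta_my: MREstimate,
                        exposure: int | str = 0,
                        mediator: int | str = 1) -> MREstimate:
    """Variant-level direct effect: IVW after removing the mediated component
    from each variant's outcome association.

    beta'_Yj = beta_Yj - theta_MY * beta_Mj with
    se'_j = sqrt(se_Yj^2 + beta_Mj^2 * se(theta_MY)^2).
    """
    names = cis_set.exposure_names
    e = names.index(exposure) if isinstance(exposure, str) else exposure
    m = names.index(mediator) if isinstance(mediator, str) else mediator
    if cis_set.n_exposures < 2:
        raise MediationError(
            "adjusted_outcome_mr: cis_set must carry exposure and mediator columns")
    beta_m = cis_set.beta_exposure[:, m]
    if np.any(~np.isfinite(beta_m)):
        bad = [v for v, b in zip(cis_set.variant_ids, beta_m)
               if not np.isfinite(b)]
        raise MediationError(f"missing mediator associations for: {bad}")
    adj_y = cis_set.beta_outcome - theta_my.theta * beta_m
    adj_se = np.sqrt(cis_set.se_outcome ** 2 + beta_m ** 2 * theta_my.se ** 2)
    sub = HarmonizedSet.from_arrays(
        cis_set.beta_exposure[:, e], cis_set.se_exposure[:, e], adj_y, adj_se,
        ld=cis_set.ld, exposure_names=[names[e]],
        variant_ids=cis_set.variant_ids, outcome_scale=cis_set.outcome_scale)
    # GLS when residual LD information is available, matching the estimator
    # used for the unadjusted cis estimates
    est = ivw_ld(sub) if sub.ld is not None else ivw(sub)
    est.method = "ivw_adjusted"
    est.extra.update(adjusted_for=names[m], theta_my=theta_my.theta)
    return est


def bootstrap_mediation(inputs: MediationInputs, n_boot: int = 1_000_000,
                        seed: int | None = None,
                        proportion_guard: float = 1e-6) -> MediationResult:
    """Parametric bootstrap over the three component estimates.

    Draws (total*, theta_XM*, theta_MY*) independently from normals centred at
    the point estimates with their standard errors, recomputes indirect,
    direct and proportion per draw, and reports percentile (2.5/97.5) CIs and
    draw-SD standard errors.  Proportion draws with |total*| below the guard
    are rejected and counted; a rejection fraction above 1% triggers an
    ``unstable_proportion_ci`` warning.
    """
    t, xm, my = inputs.theta_total, inputs.theta_xm, inputs.theta_my
    ind = indirect_product(xm, my)
    dire = direct_difference(t, ind)
    prop = proportion_mediated(t.theta, ind)

    rng = np.random.default_rng(seed)
    t_star = rng.normal(t.theta, t.se, n_boot)
    xm_star = rng.normal(xm.theta, xm.se, n_boot)
    my_star = rng.normal(my.theta, my.se, n_boot)
    ind_star = xm_star * my_star
    dir_star = t_star - ind_star
    ok = np.abs(t_star) > proportion_guard
    guard_rejections = int(n_boot - ok.sum())
    prop_star = ind_star[ok] / t_star[ok]

    flags = []
    if n_boot > 0 and guard_rejections > 0.01 * n_boot:
        flags.append("unstable_proportion_ci")
        warnings.warn("unstable_proportion_ci: >1% of bootstrap draws had a "
                      "near-zero total effect")
    if prop < 0:
        flags.append("inconsistent_mediation")

    def pct(a: np.ndarray, point: float) -> tuple[tuple[float, float], float]:
        if a.size == 0 or np.allclose(np.std(a), 0.0):
            return (point, point), 0.0
        lo, hi = np.percentile(a, [2.5, 97.5])
        return (float(lo), float(hi)), float(np.std(a, ddof=1))

    ci: dict[str, tuple[float, float]] = {}
    se: dict[str, float] = {}
    for name, draws, point in (("total", t_star, t.theta),
                               ("indirect", ind_star, ind),
                               ("direct", dir_star, dire),
                               ("proportion", prop_star, prop)):
        if n_boot == 0 or (draws.size and np.std(draws) == 0.0):
            ci[name], se[name] = (point, point), 0.0
        else:
            ci[name], se[name] = pct(draws, point)

    result = MediationResult(
        total=t.theta, indirect_product=ind, direct_difference=dire,
        proportion_mediated=prop, ci=ci, se=se, n_boot=n_boot, seed=seed,
        guard_rejections=guard_rejections, flags=flags)
    if inputs.cis_set is not None:
        result.direct_variant_level = adjusted_outcome_mr(inputs.cis_set, my)
    return result
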