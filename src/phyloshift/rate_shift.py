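"""ML branch-scaling fits and the rate-shift likelihood-ratio test.

Null model: every branch of the neutral tree is scaled by a single
factor rho0.  Alternative: background branches are scaled by rho1 and
foreground branches by rho1 * lam.  The LRT statistic 2*(logL_alt -
logL_null) is referred to a chi-square with one degree of freedom
(nominal; the downstream permutation calibration absorbs boundary
effects), and the signed score is -log10(p) with positive sign for
deceleration (lam < 1) and negative for acceleration (lam > 1).

Optimization is bounded quasi-Newton in log-parameter space with
rho in [1e-4, 20] and lam in [1e-4, 100], tolerance 1e-6 in logL, and
one restart from a perturbed point on non-convergence.  The alternative
fit is initialized at (rho0, 1), whose likelihood equals the null fit's,
so logL_alt >= logL_null holds on every input.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .likelihood import Alignment, ForegroundSpec, LikelihoodEngine
from .substitution import NeutralModel

__all__ = [
    "NullFit", "AltFit", "LrtResult",
    "fit_null", "fit_alt", "lrt", "signed_score",
    "RHO_BOUNDS", "LAM_BOUNDS",
]

RHO_BOUNDS = (1e-4, 20.0)
LAM_BOUNDS = (1e-4, 100.0)
_LOGL_TOL = 1e-6


@dataclass
class NullFit:
    rho0: float
    logL: float
    converged: bool


@dataclass
class AltFit:
    rho1: float
    lam: float
    logL: float
    converged: bool


@dataclass
class LrtResult:
    stat: float
    pvalue: float
    signed_score: float


def fit_null(
    source: Alignment | LikelihoodEngine, model: NeutralModel | None = None
) -> NullFit:
    """Maximize logL over a single uniform scale rho0."""
    engine = _as_engine(source, model)
    lo, hi = np.log(RHO_BOUNDS)

    def neg(x: float) -> float:
        return -engine.loglik(math.exp(x))

    res = optimize.minimize_scalar(
        neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-7}
    )
    rho0 = float(math.exp(res.x))
    logL = -float(res.fun)
    # a bounded scalar search can stall on flat likelihoods; check endpoints
    for edge in RHO_BOUNDS:
        l_edge = engine.loglik(edge)
        if l_edge > logL + _LOGL_TOL:
            rho0, logL = edge, l_edge
    return NullFit(rho0, logL, bool(res.success))


def fit_alt(
    source: Alignment | LikelihoodEngine,
    model: NeutralModel | None,
    fg: ForegroundSpec,
    null: NullFit | None = None,
) -> AltFit:
    """Joint bounded maximization of logL over (rho1, lam).

    Initialized at (rho0, 1) so the alternative log-likelihood can never
    fall below the null's.
    """
    engine = _as_engine(source, model)
    if null is None:
        null = fit_null(engine)
    log_bounds = [tuple(np.log(RHO_BOUNDS)), tuple(np.log(LAM_BOUNDS))]

    def neg(x: np.ndarray) -> float:
        return -engine.loglik(math.exp(x[0]), math.exp(x[1]), fg)

    x0 = np.array([math.log(null.rho0), 0.0])
    best_x, best_f, converged = x0, -null.logL, False
    rng = np.random.default_rng(0)
    for attempt in range(2):
        start = x0 if attempt == 0 else x0 + rng.normal(0, 0.3, size=2)
        start = np.clip(start, [b[0] for b in log_bounds], [b[1] for b in log_bounds])
        res = optimize.minimize(
            neg, start, method="L-BFGS-B", bounds=log_bounds,
            options={"ftol": 1e-12, "gtol": 1e-8},
        )
        if res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)
        if res.success:
            converged = True
            break
    logL = -best_f
    if logL < null.logL:  # numerical guard; init point makes this exact
        best_x, logL = x0, null.logL
    return AltFit(float(math.exp(best_x[0])), float(math.exp(best_x[1])), logL, converged)


def signed_score(pvalue: float, lam: float) -> float:
    """-log10(p), positive for deceleration (lam<1), negative for
    acceleration (lam>1), zero when lam == 1."""
    if lam == 1.0:
        return 0.0
    p = max(pvalue, np.finfo(float).tiny)
    return float(-math.log10(p) * (1.0 if lam < 1.0 else -1.0)) + 0.0


def lrt(nullfit: NullFit, altfit: AltFit) -> LrtResult:
    """Likelihood-ratio test of lam = 1, chi-square df=1 upper tail."""
    stat = 2.0 * (altfit.logL - nullfit.logL)
    if stat < -1e-8:
        raise RuntimeError(
            f"nesting violated: LRT statistic {stat} < 0 beyond tolerance"
        )
    stat = max(stat, 0.0)
    pvalue = float(stats.chi2.sf(stat, df=1))
    return LrtResult(stat, pvalue, signed_score(pvalue, altfit.lam))


def _as_engine(
    source: Alignment | LikelihoodEngine, model: NeutralModel | None
) -> LikelihoodEngine:
    if isinstance(source, LikelihoodEngine):
        return source
    if model is None:
        raise ValueError("model is required when passing a raw alignment")
    return LikelihoodEngine(source, model)
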