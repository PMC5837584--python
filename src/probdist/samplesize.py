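"""Pilot-run sample-size planning for the Monte Carlo distance estimators.

The unbiased per-draw Hellinger term

    R_1 = 1 - (1/2) [ sqrt(q/p)(s_p) + sqrt(p/q)(s_q) ]

has mean mu_0 = d_H^2 and variance sigma_0^2.  A pilot run of size m_0
estimates both, and the sample size needed for the Hellinger *distance*
(the square root) to land within an absolute tolerance tau of the truth
with probability 1 - beta is

    m >= z_{beta/2}^2 sigma_0^2 / (tau^2 (2 sqrt(mu_0) - tau)^2),

where z_beta is the upper-beta normal quantile.  A relative tolerance
alpha is the special case tau = alpha sqrt(mu_0).  The
(2 sqrt(mu_0) - tau)^2 factor converts the tolerance from the distance
scale to the squared scale on which R_m is normal.

The same machinery extends to the other estimators: JS shares the
square-root structure and uses the identical bound on its squared scale;
KL and TV are estimated on their own scale, so the plain normal bound
m >= z^2 sigma^2 / tau^2 applies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .distances import (
    DistanceEstimate,
    _LOG2,
    _as_rng,
    _check_taxa,
    _guard_finite,
    _two_sample_logprobs,
    mc_distance,
)

__all__ = ["SampleSizePlan", "pilot", "required_m", "auto_distance"]

DEFAULT_PILOT_SIZE = 1000

#: distances whose point estimate is the square root of the estimated raw
_SQRT_SCALE = {"hellinger", "js"}


@dataclass
class SampleSizePlan:
    """Record of a pilot run and the resulting sample-size decision."""

    m0: int
    mu0_hat: float
    sigma0sq_hat: float
    criterion: str  # "absolute" | "relative"
    tau: float
    alpha: float | None
    beta: float
    z: float
    m_required: int

    def as_record(self) -> dict:
        return {
            "m0": self.m0,
            "mu0_hat": self.mu0_hat,
            "sigma0sq_hat": self.sigma0sq_hat,
            "criterion": self.criterion,
            "tau": self.tau,
            "alpha": self.alpha,
            "beta": self.beta,
            "z": self.z,
            "m_required": self.m_required,
        }


def _pilot_terms(pair1, pair2, name: str, m0: int, rng) -> np.ndarray:
    """Per-draw estimator terms whose mean is the raw distance quantity."""
    lpp, lqp, lpq, lqq = _two_sample_logprobs(pair1, pair2, m0, rng)
    if name == "hellinger":
        _guard_finite(lqp - lpp, "p-sample")
        _guard_finite(lpq - lqq, "q-sample")
        return 1.0 - 0.5 * (np.exp(0.5 * (lqp - lpp)) + np.exp(0.5 * (lpq - lqq)))
    if name == "js":
        t1 = lpp - (np.logaddexp(lpp, lqp) - _LOG2)
        t2 = lqq - (np.logaddexp(lpq, lqq) - _LOG2)
        return 0.5 * (t1 + t2)
    if name == "kl":
        terms = lpp - lqp
        _guard_finite(terms, "p-sample")
        return terms
    if name == "tv":
        _guard_finite(lqp - lpp, "p-sample")
        _guard_finite(lpq - lqq, "q-sample")
        return 0.5 * (np.abs(1.0 - np.exp(lqp - lpp)) + np.abs(1.0 - np.exp(lpq - lqq)))
    raise ValueError(f"unknown distance {name!r}")


def pilot(
    pair1, pair2, m0: int, rng, name: str = "hellinger"
) -> tuple[float, float]:
    """Pilot estimates (mu0_hat, sigma0sq_hat) from m0 per-draw R_1 values.

    Each of the m0 realizations is one R_1; their sample mean and sample
    variance (denominator m0 - 1) are unbiased for mu_0 and sigma_0^2.
    """
    if m0 < 2:
        raise ValueError("pilot size m0 must be >= 2")
    _check_taxa(pair1, pair2)
    terms = _pilot_terms(pair1, pair2, name, m0, rng)
    return float(terms.mean()), float(terms.var(ddof=1))


def required_m(mu0: float, sigma0sq: float, tau: float, beta: float) -> int:
    """Smallest m meeting the absolute-tolerance bound on the distance scale.

    ``m >= z_{beta/2}^2 sigma0^2 / (tau^2 (2 sqrt(mu0) - tau)^2)``,
    rounded up, minimum 1.
    """
    if mu0 <= 0:
        raise ValueError("mu0 must be positive; run a larger pilot")
    if sigma0sq < 0:
        raise ValueError("sigma0sq must be >= 0")
    if not (0.0 < beta < 1.0):
        raise ValueError("beta must be in (0, 1)")
    if not (0.0 < tau < 2.0 * math.sqrt(mu0)):
        raise ValueError(
            f"tau must be in (0, 2*sqrt(mu0)) = (0, {2*math.sqrt(mu0):.6g}); "
            "the tolerance is unachievable in this normal approximation"
        )
    z = float(norm.ppf(1.0 - beta / 2.0))
    bound = z * z * sigma0sq / (tau * tau * (2.0 * math.sqrt(mu0) - tau) ** 2)
    return max(1, math.ceil(bound))


def _required_m_linear(sigma0sq: float, tau: float, beta: float) -> int:
    """Plain normal bound for estimators reported on their own scale (KL, TV)."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    if not (0.0 < beta < 1.0):
        raise ValueError("beta must be in (0, 1)")
    z = float(norm.ppf(1.0 - beta / 2.0))
    return max(1, math.ceil(z * z * sigma0sq / (tau * tau)))


DEGENERATE_PILOT_TOL = 1e-12


def auto_distance(
    pair1,
    pair2,
    name: str = "hellinger",
    alpha: float | None = None,
    tau: float | None = None,
    beta: float = 0.2,
    m0: int = DEFAULT_PILOT_SIZE,
    rng=None,
    use_cv: bool = False,
    seed: int | None = None,
) -> DistanceEstimate:
    """Pilot run, Eq.-style sample-size choice, then a fresh full-size run.

    Exactly one of ``alpha`` (relative tolerance on the distance) or
    ``tau`` (absolute tolerance) must be given.  If the pilot estimate of
    the distance is numerically 0 the trees are indistinguishable at pilot
    precision and a zero estimate with m = m0 is returned with a warning.
    """
    if (alpha is None) == (tau is None):
        raise ValueError("give exactly one of alpha (relative) or tau (absolute)")
    rng = _as_rng(rng)
    mu0, sig0 = pilot(pair1, pair2, m0, rng, name=name)
    z = float(norm.ppf(1.0 - beta / 2.0))
    if mu0 < DEGENERATE_PILOT_TOL:
        warnings.warn(
            "pilot distance estimate is 0; the two tree-model pairs are "
            "indistinguishable at pilot precision",
            stacklevel=2,
        )
        plan = SampleSizePlan(
            m0=m0, mu0_hat=mu0, sigma0sq_hat=sig0,
            criterion="relative" if alpha is not None else "absolute",
            tau=0.0 if tau is None else tau, alpha=alpha, beta=beta, z=z, m_required=m0,
        )
        return DistanceEstimate(
            name=name, estimate=0.0, raw=mu0, stderr=math.sqrt(max(sig0, 0.0) / m0),
            m=m0, method="mc", seed=seed, plan=plan,
        )
    if name in _SQRT_SCALE:
        tol = alpha * math.sqrt(mu0) if alpha is not None else tau
        m_req = required_m(mu0, sig0, tol, beta)
    else:
        tol = alpha * abs(mu0) if alpha is not None else tau
        m_req = _required_m_linear(sig0, tol, beta)
    plan = SampleSizePlan(
        m0=m0, mu0_hat=mu0, sigma0sq_hat=sig0,
        criterion="relative" if alpha is not None else "absolute",
        tau=tol, alpha=alpha, beta=beta, z=z, m_required=m_req,
    )
    est = mc_distance(pair1, pair2, name, m_req, rng, use_cv=use_cv, seed=seed)
    est.plan = plan
    return est
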