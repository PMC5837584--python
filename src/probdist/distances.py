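"""Probabilistic distances between character distributions of tree pairs.

Four measures between the distributions p, q induced by two
(tree, model) pairs on a common taxon set:

* Hellinger:  d_H^2 = (1/2) sum_s (sqrt(p) - sqrt(q))^2, a metric in [0, 1];
* Kullback-Leibler: d_KL = sum_s p log(p/q), non-negative, asymmetric;
* Jensen-Shannon: d_JS^2 = (1/2) d_KL(p; (p+q)/2) + (1/2) d_KL(q; (p+q)/2),
  a metric bounded by sqrt(log 2);
* total variation: d_TV = sum_s |p - q|, in [0, 2].

Each has an exact mode (full enumeration of Omega^n, feasible for small n)
and a Monte Carlo estimator driven by simulated characters and exact
per-character probabilities.  The Hellinger estimator is the unbiased

    R_m = 1 - (1/2m) sum_i [ sqrt(q/p)(s_p,i) + sqrt(p/q)(s_q,i) ]

for d_H^2, with samples s_p,i ~ p and s_q,i ~ q.  All probability ratios
are exponentials of log-probability differences; probabilities are never
divided directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .characters import CharacterSample, enumerate_characters

__all__ = [
    "DistanceEstimate",
    "DISTANCE_NAMES",
    "ZeroProbabilityError",
    "exact_distance",
    "hellinger_mc",
    "kl_mc",
    "js_mc",
    "tv_mc",
    "mc_distance",
]

DISTANCE_NAMES = ("hellinger", "kl", "js", "tv")

JS_UPPER_BOUND = math.sqrt(math.log(2.0))

_LOG2 = math.log(2.0)


class ZeroProbabilityError(ValueError):
    """A simulated character received probability 0 under the other model."""


@dataclass
class DistanceEstimate:
    """Point estimate of a distance plus its Monte Carlo bookkeeping.

    ``raw`` is the quantity the estimator is unbiased for (d_H^2 for
    Hellinger, d_JS^2 for JS, the divergence itself for KL/TV); it may be
    negative by chance and is preserved so unbiasedness stays testable.
    ``estimate`` is the reported distance: sqrt(max(raw, 0)) for
    Hellinger/JS, max(raw, 0) for KL/TV.  ``stderr`` is the standard error
    of ``raw``.
    """

    name: str
    estimate: float
    raw: float
    stderr: float
    m: int
    method: str  # "mc" | "mc_cv" | "exact"
    seed: int | None = None
    plan: object | None = None  # SampleSizePlan when produced by auto mode

    def as_record(self) -> dict:
        return {
            "distance": self.name,
            "estimate": self.estimate,
            "raw": self.raw,
            "stderr": self.stderr,
            "m": self.m,
            "method": self.method,
            "seed": self.seed,
        }


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _check_taxa(d1, d2) -> None:
    if tuple(d1.taxa) != tuple(d2.taxa):
        raise ValueError(
            "taxon sets differ; use the missing-taxa methods "
            f"({sorted(set(d1.taxa) ^ set(d2.taxa))} not shared)"
        )
    if tuple(d1.alphabet) != tuple(d2.alphabet):
        raise ValueError("the two models use different alphabets")


# ---------------------------------------------------------------------------
# Exact computation by enumeration
# ---------------------------------------------------------------------------

DEFAULT_ENUMERATION_CAP = 65_536


def _enumerate(dist) -> tuple[np.ndarray, np.ndarray]:
    """States and log-probs for any object with the distribution protocol."""
    if hasattr(dist, "enumerate"):
        return dist.enumerate()
    return enumerate_characters(dist)


def exact_distance(
    pair1, pair2, name: str, cap: int = DEFAULT_ENUMERATION_CAP
) -> DistanceEstimate:
    """Distance by full enumeration of Omega^n; the oracle for the MC modes."""
    if name not in DISTANCE_NAMES:
        raise ValueError(f"unknown distance {name!r}")
    _check_taxa(pair1, pair2)
    n = len(pair1.taxa)
    k = len(pair1.alphabet)
    n_outcomes = k**n
    if n_outcomes > cap:
        raise ValueError(
            f"|Omega|^n = {n_outcomes} exceeds the enumeration cap {cap}; "
            "use the Monte Carlo estimators"
        )
    # accumulated rounding in the enumeration sums below this is treated as 0,
    # so identical distributions report an exactly zero distance
    snap = 1e-12
    states, logp = _enumerate(pair1)
    logq = pair2.log_probs(
        CharacterSample(taxa=tuple(pair1.taxa), states=states, alphabet=tuple(pair1.alphabet))
    )
    p = np.exp(logp)
    q = np.exp(logq)
    if name == "hellinger":
        raw = 1.0 - float(np.exp(0.5 * (logp + logq)).sum())
        est = math.sqrt(max(raw, 0.0))
    elif name == "kl":
        with np.errstate(invalid="ignore"):
            terms = np.where(p > 0, p * (logp - logq), 0.0)
        raw = float(terms.sum())
        est = max(raw, 0.0)
    elif name == "js":
        logmix = np.logaddexp(logp, logq) - _LOG2
        t1 = np.where(p > 0, p * (logp - logmix), 0.0).sum()
        t2 = np.where(q > 0, q * (logq - logmix), 0.0).sum()
        raw = float(0.5 * (t1 + t2))
        est = math.sqrt(max(raw, 0.0))
    else:  # tv
        raw = float(np.abs(p - q).sum())
        est = raw
    if abs(raw) < snap:
        raw, est = 0.0, 0.0
    return DistanceEstimate(name=name, estimate=est, raw=raw, stderr=0.0, m=n_outcomes, method="exact")


# ---------------------------------------------------------------------------
# Monte Carlo estimators
# ---------------------------------------------------------------------------


def _two_sample_logprobs(pair1, pair2, m: int, rng):
    """Simulate m characters from each distribution; return the four
    log-prob arrays (log p and log q evaluated on both samples)."""
    rng = _as_rng(rng)
    r1, r2 = rng.spawn(2)
    sp = pair1.simulate(m, r1)
    sq = pair2.simulate(m, r2)
    lpp = pair1.log_probs(sp)  # log p(s_p)
    lqp = pair2.log_probs(sp)  # log q(s_p)
    lpq = pair1.log_probs(sq)  # log p(s_q)
    lqq = pair2.log_probs(sq)  # log q(s_q)
    return lpp, lqp, lpq, lqq


def _guard_finite(log_ratio: np.ndarray, what: str) -> None:
    bad = np.flatnonzero(~np.isfinite(log_ratio))
    if bad.size:
        raise ZeroProbabilityError(
            f"{what}: character {int(bad[0])} has probability 0 under the "
            "other model; ensure strictly positive edge lengths"
        )


def _cv_adjust(terms: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Regression-adjusted control variate with known control mean 1.

    The regression coefficient is cross-fitted on two half-samples (each
    half is adjusted with the coefficient estimated from the other), so the
    coefficient is independent of the adjustment it multiplies and the
    estimator stays exactly unbiased; likelihood ratios are heavy-tailed
    enough for a same-sample coefficient to bias the mean noticeably.
    """
    n = terms.size
    if n < 4:
        return terms
    h = n // 2
    halves = (slice(0, h), slice(h, None))
    out = terms.astype(float).copy()
    for fit, apply_ in (halves, halves[::-1]):
        vc = control[fit].var(ddof=1)
        if vc < 1e-30:
            continue
        beta = np.cov(terms[fit], control[fit], ddof=1)[0, 1] / vc
        out[apply_] = terms[apply_] - beta * (control[apply_] - 1.0)
    return out


def hellinger_mc(
    pair1, pair2, m: int, rng, use_cv: bool = False, seed: int | None = None
) -> DistanceEstimate:
    """Monte Carlo Hellinger distance via the unbiased R_m estimator.

    With ``use_cv``, the likelihood ratios q/p (p-sample) and p/q
    (q-sample), whose means are exactly 1, serve as regression-adjusted
    control variates.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    _check_taxa(pair1, pair2)
    lpp, lqp, lpq, lqq = _two_sample_logprobs(pair1, pair2, m, rng)
    _guard_finite(lqp - lpp, "p-sample")
    _guard_finite(lpq - lqq, "q-sample")
    a = np.exp(0.5 * (lqp - lpp))  # sqrt(q/p) at s_p
    b = np.exp(0.5 * (lpq - lqq))  # sqrt(p/q) at s_q
    if use_cv:
        a = _cv_adjust(a, np.exp(lqp - lpp))
        b = _cv_adjust(b, np.exp(lpq - lqq))
    raw = 1.0 - 0.5 * (a.mean() + b.mean())
    var = (a.var(ddof=1) + b.var(ddof=1)) / (4.0 * m) if m > 1 else np.inf
    return DistanceEstimate(
        name="hellinger",
        estimate=math.sqrt(max(raw, 0.0)),
        raw=float(raw),
        stderr=float(math.sqrt(var)),
        m=m,
        method="mc_cv" if use_cv else "mc",
        seed=seed,
    )


def kl_mc(pair_p, pair_q, m: int, rng, seed: int | None = None) -> DistanceEstimate:
    """Monte Carlo KL divergence: mean of log(p/q) over m draws from p."""
    if m < 1:
        raise ValueError("m must be >= 1")
    _check_taxa(pair_p, pair_q)
    rng = _as_rng(rng)
    sp = pair_p.simulate(m, rng)
    lpp = pair_p.log_probs(sp)
    lqp = pair_q.log_probs(sp)
    terms = lpp - lqp
    _guard_finite(terms, "p-sample")
    raw = float(terms.mean())
    stderr = float(terms.std(ddof=1) / math.sqrt(m)) if m > 1 else math.inf
    return DistanceEstimate(
        name="kl", estimate=max(raw, 0.0), raw=raw, stderr=stderr, m=m, method="mc", seed=seed
    )


def js_mc(pair1, pair2, m: int, rng, seed: int | None = None) -> DistanceEstimate:
    """Monte Carlo Jensen-Shannon distance via the two KL-to-mixture terms.

    The mixture probability (p(s)+q(s))/2 is evaluated from both models by
    log-sum-exp, so the logs are always finite and the per-draw terms are
    bounded by log 2; the estimate therefore respects the sqrt(log 2)
    upper bound by construction.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    _check_taxa(pair1, pair2)
    lpp, lqp, lpq, lqq = _two_sample_logprobs(pair1, pair2, m, rng)
    t1 = lpp - (np.logaddexp(lpp, lqp) - _LOG2)  # log p/mix at s_p
    t2 = lqq - (np.logaddexp(lpq, lqq) - _LOG2)  # log q/mix at s_q
    raw = 0.5 * (t1.mean() + t2.mean())
    var = (t1.var(ddof=1) + t2.var(ddof=1)) / (4.0 * m) if m > 1 else np.inf
    return DistanceEstimate(
        name="js",
        estimate=math.sqrt(max(raw, 0.0)),
        raw=float(raw),
        stderr=float(math.sqrt(var)),
        m=m,
        method="mc",
        seed=seed,
    )


def tv_mc(pair1, pair2, m: int, rng, seed: int | None = None) -> DistanceEstimate:
    """Monte Carlo total variation: each half E_p|1 - q/p| = E_q|1 - p/q|
    is unbiased for sum_s |p - q|; the two halves are averaged."""
    if m < 1:
        raise ValueError("m must be >= 1")
    _check_taxa(pair1, pair2)
    lpp, lqp, lpq, lqq = _two_sample_logprobs(pair1, pair2, m, rng)
    _guard_finite(lqp - lpp, "p-sample")
    _guard_finite(lpq - lqq, "q-sample")
    h1 = np.abs(1.0 - np.exp(lqp - lpp))
    h2 = np.abs(1.0 - np.exp(lpq - lqq))
    raw = 0.5 * (h1.mean() + h2.mean())
    var = (h1.var(ddof=1) + h2.var(ddof=1)) / (4.0 * m) if m > 1 else np.inf
    return DistanceEstimate(
        name="tv",
        estimate=max(float(raw), 0.0),
        raw=float(raw),
        stderr=float(math.sqrt(var)),
        m=m,
        method="mc",
        seed=seed,
    )


_MC = {"hellinger": hellinger_mc, "kl": kl_mc, "js": js_mc, "tv": tv_mc}


def mc_distance(
    pair1, pair2, name: str, m: int, rng, use_cv: bool = False, seed: int | None = None
) -> DistanceEstimate:
    """Dispatch to the named Monte Carlo estimator."""
    if name not in _MC:
        raise ValueError(f"unknown distance {name!r}")
    if name == "hellinger":
        return hellinger_mc(pair1, pair2, m, rng, use_cv=use_cv, seed=seed)
    return _MC[name](pair1, pair2, m, rng, seed=seed)
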