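"""Reversible substitution models and transition probabilities.

Two model families are shipped: the symmetric two-state (CFN) process,
which has no free parameters, and the general time-reversible (GTR)
nucleotide model with optional discrete-Gamma across-site rate
heterogeneity and an invariant-sites class.  The machinery is
alphabet-agnostic: nothing below hard-codes the alphabet size.

Conventions
-----------
* Rate matrices are normalized so that the expected number of
  substitutions per unit edge length is 1 at the mixture's mean relative
  rate, i.e. ``-sum_i pi_i Q_ii = 1`` and ``sum_k w_k r_k = 1``.  Edge
  lengths are therefore expected substitutions per site and are comparable
  across models.
* GTR exchangeabilities are ordered AC, AG, AT, CG, CT, GT; stationary
  frequencies are ordered A, C, G, T.
* Transition matrices ``P = exp(Q t r)`` are computed through the
  symmetric similarity transform ``B = diag(sqrt(pi)) Q diag(1/sqrt(pi))``,
  eigendecomposed once per model and cached per (t, rate).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

__all__ = [
    "RateMixture",
    "SubstitutionModel",
    "cfn_model",
    "gtr_model",
    "jc_model",
    "discrete_gamma_rates",
    "transition_matrix",
    "model_from_config",
    "model_to_config",
]

_DNA = ("A", "C", "G", "T")
_BINARY = ("0", "1")


@dataclass(frozen=True)
class RateMixture:
    """Discrete relative-rate mixture with mean 1.

    ``rates[k] >= 0`` and ``weights[k] > 0`` with ``sum w = 1`` and
    ``sum w r = 1``; an invariant-sites class appears as rate 0.
    """

    rates: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self):
        r = np.asarray(self.rates)
        w = np.asarray(self.weights)
        if r.shape != w.shape or r.ndim != 1 or r.size < 1:
            raise ValueError("rates and weights must be 1-d of equal length >= 1")
        if np.any(r < 0) or np.any(w <= 0):
            raise ValueError("rates must be >= 0 and weights > 0")
        if not np.isclose(w.sum(), 1.0, atol=1e-12):
            raise ValueError("weights must sum to 1")
        if not np.isclose(w @ r, 1.0, atol=1e-10):
            raise ValueError("mixture mean rate must be 1")

    @property
    def n_classes(self) -> int:
        return len(self.rates)


_SINGLE_RATE = RateMixture(rates=(1.0,), weights=(1.0,))


class SubstitutionModel:
    """A reversible Markov substitution process plus an across-site rate mixture."""

    def __init__(
        self,
        alphabet: tuple[str, ...],
        Q: np.ndarray,
        pi: np.ndarray,
        mixture: RateMixture = _SINGLE_RATE,
        name: str = "custom",
    ):
        self.alphabet = tuple(alphabet)
        self.Q = np.asarray(Q, dtype=float)
        self.pi = np.asarray(pi, dtype=float)
        self.mixture = mixture
        self.name = name
        self._validate()
        # symmetric similarity transform, decomposed once
        sqrt_pi = np.sqrt(self.pi)
        B = sqrt_pi[:, None] * self.Q / sqrt_pi[None, :]
        evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
        self._evals = evals
        self._left = evecs / sqrt_pi[:, None]   # diag(1/sqrt(pi)) U
        self._right = evecs.T * sqrt_pi[None, :]  # U^T diag(sqrt(pi))
        self._pcache: dict[tuple[float, float], np.ndarray] = {}

    def _validate(self) -> None:
        k = len(self.alphabet)
        if self.Q.shape != (k, k) or self.pi.shape != (k,):
            raise ValueError("inconsistent alphabet/Q/pi dimensions")
        if np.any(self.pi <= 0) or not np.isclose(self.pi.sum(), 1.0, atol=1e-10):
            raise ValueError("pi must be strictly positive and sum to 1")
        off = self.Q[~np.eye(k, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if not np.allclose(self.Q.sum(axis=1), 0.0, atol=1e-10):
            raise ValueError("rows of Q must sum to 0")
        flux = self.pi[:, None] * self.Q
        if not np.allclose(flux, flux.T, atol=1e-10):
            raise ValueError("detailed balance pi_i Q_ij = pi_j Q_ji violated")
        rate = -float(self.pi @ np.diag(self.Q))
        if not np.isclose(rate, 1.0, atol=1e-10):
            raise ValueError(f"Q must be normalized to unit rate, got {rate}")

    @property
    def n_states(self) -> int:
        return len(self.alphabet)

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """``P = exp(Q * t * rate)``; rows sum to 1, entries in [0, 1]."""
        if t < 0 or rate < 0:
            raise ValueError("t and rate must be non-negative")
        key = (float(t), float(rate))
        P = self._pcache.get(key)
        if P is None:
            tt = key[0] * key[1]
            if tt == 0.0:
                P = np.eye(self.n_states)
            else:
                P = (self._left * np.exp(self._evals * tt)) @ self._right
                np.clip(P, 0.0, 1.0, out=P)
            P.setflags(write=False)
            self._pcache[key] = P
        return P

    def state_index(self, state: str) -> int:
        return self.alphabet.index(state)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<SubstitutionModel {self.name} |Omega|={self.n_states}>"


def transition_matrix(model: SubstitutionModel, t: float, rate: float = 1.0) -> np.ndarray:
    """Functional alias for :meth:`SubstitutionModel.transition_matrix`."""
    return model.transition_matrix(t, rate)


# ---------------------------------------------------------------------------
# Constructors
# ---------------------------------------------------------------------------


def cfn_model() -> SubstitutionModel:
    """The symmetric two-state (Cavender–Farris–Neyman) process.

    No free parameters: Q = [[-1, 1], [1, -1]], uniform stationary
    distribution, no rate heterogeneity.
    """
    Q = np.array([[-1.0, 1.0], [1.0, -1.0]])
    pi = np.array([0.5, 0.5])
    return SubstitutionModel(_BINARY, Q, pi, name="CFN")


def discrete_gamma_rates(shape: float, K: int) -> RateMixture:
    """K equal-weight discrete-Gamma rate categories with mean rate 1.

    The Gamma(shape, scale=1/shape) distribution is cut at its K-quantiles
    and each category rate is the conditional mean over its bin (not the
    median), renormalized so the mixture mean is exactly 1.
    """
    if shape <= 0:
        raise ValueError("shape must be positive")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K == 1:
        return _SINGLE_RATE
    a = float(shape)
    cuts = gamma_dist.ppf(np.arange(1, K) / K, a, scale=1.0 / a)
    edges = np.concatenate([[0.0], cuts, [np.inf]])
    # E[X; X in bin] for X ~ Gamma(a, rate=a): mean * (F_{a+1}(b*x_hi) - F_{a+1}(b*x_lo))
    upper = gammainc(a + 1.0, a * edges[1:])
    upper[-1] = 1.0
    lower = gammainc(a + 1.0, a * edges[:-1])
    rates = K * (upper - lower)  # each bin has probability 1/K
    rates = rates / np.mean(rates)
    weights = np.full(K, 1.0 / K)
    return RateMixture(tuple(rates), tuple(weights))


def _with_invariant(mix: RateMixture, p_invariant: float) -> RateMixture:
    if not (0.0 <= p_invariant < 1.0):
        raise ValueError("p_invariant must be in [0, 1)")
    if p_invariant == 0.0:
        return mix
    # rate-0 class with weight p; remaining classes rescaled to keep mean 1
    scale = 1.0 / (1.0 - p_invariant)
    rates = (0.0,) + tuple(r * scale for r in mix.rates)
    weights = (p_invariant,) + tuple(w * (1.0 - p_invariant) for w in mix.weights)
    return RateMixture(rates, weights)


def gtr_model(
    exchangeabilities,
    pi,
    gamma_shape: float | None = None,
    n_categories: int = 4,
    p_invariant: float = 0.0,
) -> SubstitutionModel:
    """General time-reversible DNA model, optionally +Gamma and +I.

    ``exchangeabilities`` are the six symmetric rate multipliers in the
    order AC, AG, AT, CG, CT, GT; ``pi`` the stationary frequencies in the
    order A, C, G, T.  ``q_ij = s_ij pi_j`` off-diagonal, diagonals fix the
    zero row sums, and the matrix is rescaled to unit expected rate; the
    rate mixture keeps mean 1 so edge lengths remain expected
    substitutions per site.
    """
    s = np.asarray(exchangeabilities, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if s.shape != (6,) or np.any(s <= 0):
        raise ValueError("need 6 positive exchangeabilities (AC,AG,AT,CG,CT,GT)")
    if pi.shape != (4,) or np.any(pi <= 0) or not np.isclose(pi.sum(), 1.0, atol=1e-8):
        raise ValueError("pi must be 4 positive frequencies summing to 1")
    pi = pi / pi.sum()
    S = np.zeros((4, 4))
    S[np.triu_indices(4, 1)] = s
    S = S + S.T
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -float(pi @ np.diag(Q))
    Q = Q / rate
    if gamma_shape is None:
        mix = _SINGLE_RATE
    else:
        mix = discrete_gamma_rates(gamma_shape, n_categories)
    mix = _with_invariant(mix, p_invariant)
    return SubstitutionModel(_DNA, Q, pi, mixture=mix, name="GTR")


def jc_model(
    gamma_shape: float | None = None, n_categories: int = 4, p_invariant: float = 0.0
) -> SubstitutionModel:
    """Jukes–Cantor: GTR with equal exchangeabilities and uniform frequencies."""
    m = gtr_model(np.ones(6), np.full(4, 0.25), gamma_shape, n_categories, p_invariant)
    m.name = "JC"
    return m


# ---------------------------------------------------------------------------
# JSON config
# ---------------------------------------------------------------------------


def model_from_config(config) -> SubstitutionModel:
    """Build a model from a JSON config dict, JSON string, or file path.

    ``{"model": "CFN"}`` or
    ``{"model": "GTR", "exchangeabilities": [...6, order AC,AG,AT,CG,CT,GT],
    "pi": [...4, order A,C,G,T], "gamma_shape": float|null,
    "n_categories": int, "p_invariant": float}``.
    """
    if isinstance(config, str):
        if config.lstrip().startswith("{"):
            config = json.loads(config)
        else:
            with open(config) as fh:
                config = json.load(fh)
    kind = config.get("model", "").upper()
    if kind == "CFN":
        return cfn_model()
    if kind == "JC":
        return jc_model(
            config.get("gamma_shape"),
            config.get("n_categories", 4),
            config.get("p_invariant", 0.0),
        )
    if kind == "GTR":
        return gtr_model(
            config["exchangeabilities"],
            config["pi"],
            config.get("gamma_shape"),
            config.get("n_categories", 4),
            config.get("p_invariant", 0.0),
        )
    raise ValueError(f"unknown model kind {config.get('model')!r}")


def model_to_config(model: SubstitutionModel) -> dict:
    """Inverse of :func:`model_from_config` for the shipped families."""
    if model.name == "CFN":
        return {"model": "CFN"}
    pi = model.pi
    S = model.Q / pi[None, :]
    iu = np.triu_indices(4, 1)
    exch = S[iu]
    exch = exch / exch[-1]
    rates = np.array(model.mixture.rates)
    weights = np.array(model.mixture.weights)
    p_inv = float(weights[rates == 0.0].sum())
    n_var = int((rates > 0).sum())
    gamma_shape = None if n_var <= 1 else _infer_gamma_shape(model.mixture)
    return {
        "model": "GTR",
        "exchangeabilities": [float(x) for x in exch],
        "pi": [float(x) for x in pi],
        "gamma_shape": gamma_shape,
        "n_categories": n_var,
        "p_invariant": p_inv,
    }


def _infer_gamma_shape(mix: RateMixture) -> float | None:  # pragma: no cover
    # round-trip helper only; the shape is not recoverable in general
    return None
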