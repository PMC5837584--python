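"""Distances between trees whose taxon sets differ.

Two strategies for trees T_A, T_B with taxon sets A != B, A ∩ B != ∅:

* **common taxa** — both trees are cropped down to A ∩ B (path lengths
  among the kept taxa preserved) and the ordinary distance is computed;
* **augmentation** — each character distribution is extended from its own
  taxon set to A ∪ B by making the missing taxa uniform on the alphabet:

      p_{A∪B}(s) = p(s_A) / |Omega|^{|B \\ A|},

  the maximal-uncertainty assignment for the position of the missing
  taxa.  The augmented distributions live on a common outcome space, so
  every estimator (and exact enumeration) applies unchanged.

Model parameters are carried over unchanged by both methods; nothing is
re-estimated after cropping.
"""

from __future__ import annotations

import itertools
import math
import warnings
from typing import Iterable

import numpy as np

from .characters import CharacterSample, TreeModelPair, enumerate_characters
from .distances import DistanceEstimate, _as_rng, exact_distance, mc_distance
from .samplesize import auto_distance
from .treeio import restrict_to_taxa

__all__ = ["AugmentedPair", "augmented_char_log_prob", "augmented_simulate", "distance_missing"]


class AugmentedPair:
    """A tree-model pair extended to a taxon superset with uniform margins.

    Implements the same distribution protocol as :class:`TreeModelPair`
    (``taxa``, ``alphabet``, ``log_probs``, ``simulate``), so the distance
    estimators work on it transparently.  With no extra taxa it is the
    identity wrapper and delegates draw-for-draw to the base pair.
    """

    def __init__(self, base: TreeModelPair, union_taxa: Iterable[str]):
        union = tuple(sorted(set(union_taxa)))
        missing = set(base.taxa) - set(union)
        if missing:
            raise ValueError(f"union_taxa must contain the base taxa; missing {sorted(missing)}")
        self.base = base
        self.taxa = union
        self.extra = tuple(sorted(set(union) - set(base.taxa)))
        self._base_cols = [i for i, t in enumerate(union) if t not in self.extra]
        self._extra_cols = [i for i, t in enumerate(union) if t in self.extra]

    @property
    def alphabet(self) -> tuple[str, ...]:
        return self.base.alphabet

    @property
    def n_extra(self) -> int:
        return len(self.extra)

    def log_probs(self, sample: CharacterSample) -> np.ndarray:
        """log p_{A∪B}(s) = log p(s_A) - |extra| log |Omega| per row."""
        if set(sample.taxa) != set(self.taxa):
            raise ValueError("character taxa must cover exactly the union taxon set")
        col = {t: i for i, t in enumerate(sample.taxa)}
        base_idx = [col[t] for t in self.base.taxa]
        base_states = sample.states[:, base_idx]
        base_lp = self.base.log_probs(
            CharacterSample(taxa=self.base.taxa, states=base_states, alphabet=self.alphabet)
        )
        return base_lp - self.n_extra * math.log(len(self.alphabet))

    def simulate(self, m: int, rng: np.random.Generator) -> CharacterSample:
        """m draws from the augmented distribution: base simulation plus
        independent uniform states on the extra taxa."""
        if m < 1:
            raise ValueError("m must be >= 1")
        rng = _as_rng(rng)
        base_sample = self.base.simulate(m, rng)
        if not self.extra:
            return base_sample
        k = len(self.alphabet)
        states = np.empty((m, len(self.taxa)), dtype=np.int64)
        states[:, self._base_cols] = base_sample.states
        states[:, self._extra_cols] = rng.integers(0, k, size=(m, self.n_extra))
        return CharacterSample(taxa=self.taxa, states=states, alphabet=self.alphabet)

    def enumerate(self) -> tuple[np.ndarray, np.ndarray]:
        """All |Omega|^|union| characters with augmented log-probs."""
        k = len(self.alphabet)
        n = len(self.taxa)
        states = np.array(list(itertools.product(range(k), repeat=n)), dtype=np.int64)
        sample = CharacterSample(taxa=self.taxa, states=states, alphabet=self.alphabet)
        return states, self.log_probs(sample)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<AugmentedPair n={len(self.taxa)} extra={self.n_extra}>"


def augmented_char_log_prob(aug: AugmentedPair, char: dict) -> float:
    """Augmented log-probability of one character given as ``{taxon: state}``."""
    if set(char) != set(aug.taxa):
        raise ValueError("character must cover exactly the union taxon set")
    idx = np.array([aug.base.model.state_index(char[t]) for t in aug.taxa])
    sample = CharacterSample(taxa=aug.taxa, states=idx[None, :], alphabet=aug.alphabet)
    return float(aug.log_probs(sample)[0])


def augmented_simulate(aug: AugmentedPair, m: int, rng) -> CharacterSample:
    """Functional alias for :meth:`AugmentedPair.simulate`."""
    return aug.simulate(m, _as_rng(rng))


def distance_missing(
    pairA: TreeModelPair,
    pairB: TreeModelPair,
    method: str,
    name: str = "hellinger",
    m: int | None = None,
    exact: bool = False,
    auto: dict | None = None,
    rng=None,
    use_cv: bool = False,
    seed: int | None = None,
) -> DistanceEstimate:
    """Distance between pairs with different taxon sets.

    ``method`` is ``"common"`` (crop to A ∩ B) or ``"augment"`` (extend
    both to A ∪ B).  Estimation mode: ``exact=True`` for enumeration,
    ``m`` for a fixed-size Monte Carlo run, or ``auto`` as a dict of
    keyword arguments for :func:`probdist.samplesize.auto_distance`
    (e.g. ``{"alpha": 0.05, "beta": 0.2}``).
    """
    A, B = set(pairA.taxa), set(pairB.taxa)
    if not (A & B):
        raise ValueError("taxon sets are disjoint; no distance is defined")
    if method == "common":
        shared = A & B
        if len(shared) == 1:
            warnings.warn(
                "only one shared taxon: the cropped distributions depend "
                "only on the stationary distribution",
                stacklevel=2,
            )
        d1 = TreeModelPair(restrict_to_taxa(pairA.tree, shared), pairA.model)
        d2 = TreeModelPair(restrict_to_taxa(pairB.tree, shared), pairB.model)
    elif method == "augment":
        union = A | B
        d1 = AugmentedPair(pairA, union)
        d2 = AugmentedPair(pairB, union)
    else:
        raise ValueError(f"method must be 'common' or 'augment', got {method!r}")
    if exact:
        return exact_distance(d1, d2, name)
    if auto is not None:
        return auto_distance(d1, d2, name=name, rng=rng, use_cv=use_cv, seed=seed, **auto)
    if m is None:
        raise ValueError("give m, auto=..., or exact=True")
    return mc_distance(d1, d2, name, m, rng, use_cv=use_cv, seed=seed)
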