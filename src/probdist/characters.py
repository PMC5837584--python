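"""Character distributions induced by a (tree, model) pair.

A character is one alignment column: an assignment of a state to every
taxon.  A :class:`TreeModelPair` induces a probability distribution on
characters; this module evaluates that probability exactly (Felsenstein's
pruning algorithm, summed over the rate mixture) and draws iid samples
from it.

Pruning runs vectorized over characters with per-node rescaling of the
partial-likelihood arrays, so 100-taxon trees evaluate without underflow.
Characters are stored column-ordered by the canonical sorted taxon
ordering; cross-tree evaluations re-index by label, never by position.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .submodels import SubstitutionModel
from .treeio import PhyloTree

__all__ = [
    "TreeModelPair",
    "CharacterSample",
    "char_log_prob",
    "char_log_probs",
    "simulate_characters",
    "enumerate_characters",
]


@dataclass
class CharacterSample:
    """m simulated characters over a fixed taxon ordering.

    ``states`` is an (m, n) integer array of alphabet indices whose columns
    follow ``taxa``.
    """

    taxa: tuple[str, ...]
    states: np.ndarray
    alphabet: tuple[str, ...]
    seed: int | None = None
    source: str | None = None

    def __post_init__(self):
        self.states = np.asarray(self.states)
        if self.states.ndim != 2 or self.states.shape[1] != len(self.taxa):
            raise ValueError("states must be (m, n_taxa)")
        if self.states.shape[0] < 1:
            raise ValueError("need at least one character")

    @property
    def m(self) -> int:
        return self.states.shape[0]

    def to_fasta(self) -> str:
        """Relaxed sequential FASTA, one sequence per taxon, sites as columns."""
        lines = []
        for j, taxon in enumerate(self.taxa):
            lines.append(f">{taxon}")
            lines.append("".join(self.alphabet[s] for s in self.states[:, j]))
        return "\n".join(lines) + "\n"


class TreeModelPair:
    """A tree together with its substitution model: the object distances
    are defined between.  Induces a character distribution on Omega^n."""

    def __init__(self, tree: PhyloTree, model: SubstitutionModel):
        if tree.n_leaves < 1:
            raise ValueError("tree must have at least one leaf")
        self.tree = tree
        self.model = model
        self.taxa: tuple[str, ...] = tuple(sorted(tree.taxa))
        self._col = {t: i for i, t in enumerate(self.taxa)}

    @property
    def alphabet(self) -> tuple[str, ...]:
        return self.model.alphabet

    # -- protocol used by the distance estimators ----------------------

    def log_probs(self, sample: CharacterSample) -> np.ndarray:
        return char_log_probs(self, sample.states, sample.taxa)

    def simulate(self, m: int, rng: np.random.Generator) -> CharacterSample:
        return simulate_characters(self, m, rng)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<TreeModelPair n={len(self.taxa)} model={self.model.name}>"


# ---------------------------------------------------------------------------
# Exact character probabilities (pruning)
# ---------------------------------------------------------------------------


def _prune_class(
    pair: TreeModelPair, rate: float, states: np.ndarray, col: Mapping[str, int]
) -> np.ndarray:
    """Log-likelihood per character for one rate class; (m,) array."""
    model = pair.model
    k = model.n_states
    m = states.shape[0]
    eye = np.eye(k)

    def rec(node) -> tuple[np.ndarray, np.ndarray]:
        if node.is_leaf:
            return eye[:, states[:, col[node.label]]], np.zeros(m)
        L = None
        logscale = np.zeros(m)
        for child in node.children:
            Lc, lsc = rec(child)
            P = model.transition_matrix(child.edge_length, rate)
            msg = P @ Lc
            L = msg if L is None else L * msg
            logscale += lsc
        mx = L.max(axis=0)
        ok = mx > 0
        safe = np.where(ok, mx, 1.0)
        logscale += np.where(ok, np.log(safe), -np.inf)
        L = L / safe[None, :]
        return L, logscale

    L, logscale = rec(pair.tree.root)
    site = model.pi @ L
    with np.errstate(divide="ignore"):
        return np.log(site) + logscale


def char_log_probs(
    pair: TreeModelPair, states: np.ndarray, taxa: Sequence[str]
) -> np.ndarray:
    """Vectorized log p(s) for each row of ``states`` (columns follow ``taxa``).

    Felsenstein pruning per rate class, combined across the mixture by
    log-sum-exp with the class weights.
    """
    taxa = tuple(taxa)
    if set(taxa) != set(pair.taxa):
        raise ValueError(
            f"character taxa {sorted(set(taxa))} do not match tree taxa {list(pair.taxa)}"
        )
    states = np.asarray(states)
    if states.ndim == 1:
        states = states[None, :]
    col = {t: i for i, t in enumerate(taxa)}
    mix = pair.model.mixture
    per_class = np.stack(
        [
            _prune_class(pair, r, states, col) + np.log(w)
            for r, w in zip(mix.rates, mix.weights)
        ]
    )
    return logsumexp(per_class, axis=0)


def char_log_prob(pair: TreeModelPair, char: Mapping[str, str]) -> float:
    """Log-probability of a single character given as ``{taxon: state}``."""
    if set(char) != set(pair.taxa):
        raise ValueError("character taxa do not match tree taxa")
    idx = np.array([pair.model.state_index(char[t]) for t in pair.taxa])
    return float(char_log_probs(pair, idx[None, :], pair.taxa)[0])


def enumerate_characters(pair: TreeModelPair) -> tuple[np.ndarray, np.ndarray]:
    """All |Omega|^n characters (canonical taxon order) and their log-probs."""
    k = pair.model.n_states
    n = len(pair.taxa)
    states = np.array(list(itertools.product(range(k), repeat=n)), dtype=np.int64)
    return states, char_log_probs(pair, states, pair.taxa)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate_characters(
    pair: TreeModelPair, m: int, rng: np.random.Generator
) -> CharacterSample:
    """Draw ``m`` iid characters from the pair's distribution.

    Per character: one rate class from the mixture weights (across-site
    semantics: the class applies to the whole tree), a root state from pi,
    then states propagate down each edge via its transition matrix.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    model = pair.model
    mix = model.mixture
    k = model.n_states
    rates = np.asarray(mix.rates)
    classes = rng.choice(mix.n_classes, size=m, p=np.asarray(mix.weights))
    state_of: dict[int, np.ndarray] = {}
    root = pair.tree.root
    state_of[id(root)] = rng.choice(k, size=m, p=model.pi)
    for node in pair.tree.preorder():
        if node.parent is None:
            continue
        parent_states = state_of[id(node.parent)]
        out = np.empty(m, dtype=np.int64)
        for kc in np.unique(classes):
            idx = np.flatnonzero(classes == kc)
            P = model.transition_matrix(node.edge_length, float(rates[kc]))
            cum = np.cumsum(P, axis=1)
            u = rng.random(idx.size)
            out[idx] = np.minimum(
                (u[:, None] > cum[parent_states[idx]]).sum(axis=1), k - 1
            )
        state_of[id(node)] = out
    cols = np.empty((m, len(pair.taxa)), dtype=np.int64)
    for leaf in pair.tree.leaves():
        cols[:, pair._col[leaf.label]] = state_of[id(leaf)]
    return CharacterSample(taxa=pair.taxa, states=cols, alphabet=model.alphabet)
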