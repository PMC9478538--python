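"""Finite probability primitives for data–hypothesis inference.

Everything in this package works with distributions over a *finite ordered
label set*: data labels ``d1..dN`` and hypothesis labels ``h1..hN``.  Three
small immutable containers carry the probabilistic state:

``ProbVector``
    a distribution over one label set (prior, posterior or data marginal);
``LikelihoodMatrix``
    conditional distributions ``P(d|h)``, one column per hypothesis;
``JointMatrix``
    the joint ``P(d, h)`` with a state flag distinguishing globally
    normalized joints from block-renormalized ones (the excess phase
    deliberately leaves the global sum unconstrained).

The operations here are the textbook pieces the simulations are built from:
the Kullback–Leibler divergence and the variational free-energy objective
(KLD between prior and posterior minus the log evidence), the Bayes
posterior, and constructors for the near-one-to-one likelihood and joints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import rel_entr

__all__ = [
    "ATOL",
    "ProbVector",
    "LikelihoodMatrix",
    "JointMatrix",
    "DivergenceError",
    "data_labels",
    "hyp_labels",
    "kld",
    "variational_objective",
    "bayes_posterior",
    "ideal_likelihood",
    "joint_from_likelihood",
    "joint_from_marginals",
    "empirical_data_prob",
]

#: absolute tolerance for normalization invariants
ATOL = 1e-9


class DivergenceError(ValueError):
    """KLD is undefined: p puts mass where q has none."""


def data_labels(n: int) -> tuple[str, ...]:
    """Ordered data labels ``d1..dn`` (1-based, matching the field's indexing)."""
    return tuple(f"d{i}" for i in range(1, n + 1))


def hyp_labels(n: int) -> tuple[str, ...]:
    """Ordered hypothesis labels ``h1..hn``."""
    return tuple(f"h{i}" for i in range(1, n + 1))


@dataclass(frozen=True)
class ProbVector:
    """A distribution over a finite ordered label set.

    Values are nonnegative and sum to one within :data:`ATOL` unless the
    vector is explicitly flagged ``unnormalized`` (used for raw counts or
    diagnostic weights).
    """

    labels: tuple[str, ...]
    values: np.ndarray
    unnormalized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", tuple(self.labels))
        if values.ndim != 1 or len(self.labels) != values.size:
            raise ValueError("labels and values must have matching length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("probabilities must be finite and nonnegative")
        if not self.unnormalized and abs(values.sum() - 1.0) > ATOL:
            raise ValueError(f"probabilities sum to {values.sum()!r}, not 1")

    @classmethod
    def uniform(cls, labels: tuple[str, ...] | list[str]) -> "ProbVector":
        n = len(labels)
        return cls(tuple(labels), np.full(n, 1.0 / n))

    @classmethod
    def point_mass(cls, labels, label: str) -> "ProbVector":
        values = np.zeros(len(labels))
        values[list(labels).index(label)] = 1.0
        return cls(tuple(labels), values)

    def __getitem__(self, label: str) -> float:
        return float(self.values[self.labels.index(label)])

    def entropy(self) -> float:
        """Shannon entropy in nats (0·ln 0 = 0)."""
        p = self.values[self.values > 0]
        return float(-(p * np.log(p)).sum())


@dataclass(frozen=True)
class LikelihoodMatrix:
    """Conditional distributions ``P(d_i | h_j)``.

    ``entries[i, j]`` is the probability of datum ``data_labels[i]`` under
    hypothesis ``hyp_labels[j]``; every column is a distribution over data.
    """

    data_labels: tuple[str, ...]
    hyp_labels: tuple[str, ...]
    entries: np.ndarray

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "data_labels", tuple(self.data_labels))
        object.__setattr__(self, "hyp_labels", tuple(self.hyp_labels))
        if entries.shape != (len(self.data_labels), len(self.hyp_labels)):
            raise ValueError("entry shape does not match labels")
        if np.any(entries < 0) or not np.all(np.isfinite(entries)):
            raise ValueError("likelihoods must be finite and nonnegative")
        colsums = entries.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > ATOL):
            raise ValueError("each hypothesis' conditional must sum to 1")


@dataclass(frozen=True)
class JointMatrix:
    """Joint weights ``P(d_i, h_j)`` over data × hypotheses.

    ``state`` is ``"normalized"`` (global sum 1, the Bayesian phase) or
    ``"renormalized"`` (block-wise renormalized, the excess phase; the global
    sum is intentionally unconstrained there).
    """

    data_labels: tuple[str, ...]
    hyp_labels: tuple[str, ...]
    entries: np.ndarray
    state: str = "normalized"

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "data_labels", tuple(self.data_labels))
        object.__setattr__(self, "hyp_labels", tuple(self.hyp_labels))
        if self.state not in ("normalized", "renormalized"):
            raise ValueError(f"unknown state {self.state!r}")
        if entries.shape != (len(self.data_labels), len(self.hyp_labels)):
            raise ValueError("entry shape does not match labels")
        if np.any(entries < 0) or not np.all(np.isfinite(entries)):
            raise ValueError("joint entries must be finite and nonnegative")
        if self.state == "normalized" and abs(entries.sum() - 1.0) > ATOL:
            raise ValueError(f"joint sums to {entries.sum()!r}, not 1")

    @property
    def n_data(self) -> int:
        return len(self.data_labels)

    @property
    def n_hyp(self) -> int:
        return len(self.hyp_labels)


def _check_same_labels(p: ProbVector, q: ProbVector) -> None:
    if p.labels != q.labels:
        raise ValueError("label sets differ")


def kld(p: ProbVector, q: ProbVector) -> float:
    """Kullback–Leibler divergence ``sum_i p_i ln(p_i / q_i)`` in nats.

    Terms with ``p_i = 0`` contribute zero.  Raises :class:`DivergenceError`
    when absolute continuity fails (``p_i > 0`` where ``q_i = 0``).
    """
    _check_same_labels(p, q)
    bad = (p.values > 0) & (q.values == 0)
    if np.any(bad):
        label = p.labels[int(np.argmax(bad))]
        raise DivergenceError(f"p has mass at {label!r} where q is zero")
    return float(rel_entr(p.values, q.values).sum())


def variational_objective(prior: ProbVector, posterior: ProbVector, evidence: float) -> float:
    """The free-energy objective ``KLD(prior ‖ posterior) − ln(evidence)``.

    The bound is minimized — equal to the surprise ``−ln(evidence)`` —
    exactly when prior and posterior coincide.
    """
    if not 0 < evidence <= 1:
        raise ValueError(f"evidence must lie in (0, 1], got {evidence}")
    return kld(prior, posterior) - math.log(evidence)


def bayes_posterior(lik: LikelihoodMatrix, prior: ProbVector, d: str) -> ProbVector:
    """Posterior over hypotheses after observing datum ``d``.

    ``P(h_j | d) = P(d | h_j) P(h_j) / sum_k P(d | h_k) P(h_k)``.
    """
    if prior.labels != lik.hyp_labels:
        raise ValueError("prior labels do not match likelihood hypotheses")
    if d not in lik.data_labels:
        raise ValueError(f"unknown datum {d!r}")
    i = lik.data_labels.index(d)
    weights = lik.entries[i, :] * prior.values
    z = weights.sum()
    if z <= 0:
        raise ZeroDivisionError(f"datum {d!r} is impossible under every hypothesis")
    return ProbVector(lik.hyp_labels, weights / z)


def ideal_likelihood(n: int, alpha: float) -> LikelihoodMatrix:
    """Near-one-to-one likelihood: ``alpha`` on the diagonal, the remaining
    mass ``(1 − alpha)/(n − 1)`` spread over the off-diagonal data.

    ``alpha = 1`` gives the exact one-to-one (identity) correspondence.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if n == 1:
        if alpha != 1.0:
            raise ValueError("n=1 admits only alpha=1")
        off = 0.0
    else:
        if not (1.0 / n < alpha <= 1.0):
            raise ValueError(f"alpha must lie in (1/{n}, 1], got {alpha}")
        off = (1.0 - alpha) / (n - 1)
    entries = np.full((n, n), off)
    np.fill_diagonal(entries, alpha)
    return LikelihoodMatrix(data_labels(n), hyp_labels(n), entries)


def joint_from_likelihood(lik: LikelihoodMatrix, prior: ProbVector) -> JointMatrix:
    """Joint ``P(d_i, h_j) = P(d_i | h_j) P(h_j)`` (globally normalized)."""
    if prior.labels != lik.hyp_labels:
        raise ValueError("prior labels do not match likelihood hypotheses")
    return JointMatrix(lik.data_labels, lik.hyp_labels, lik.entries * prior.values)


def joint_from_marginals(pd: ProbVector, ph: ProbVector) -> JointMatrix:
    """Independent joint ``P(d_i) P(h_j)`` — the product of the marginals.

    This is the joint the iterated-Bayesian snapshots display: the cumulative
    data marginal times the current belief over hypotheses.
    """
    return JointMatrix(pd.labels, ph.labels, np.outer(pd.values, ph.values))


def empirical_data_prob(counts, labels=None, smoothing: str = "none") -> ProbVector:
    """Cumulative empirical data distribution from observation counts.

    ``smoothing="none"`` gives plain relative frequencies (never-observed data
    get exactly zero); ``"laplace"`` adds one pseudo-count per label.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0) or np.any(counts != np.floor(counts)):
        raise ValueError("counts must be nonnegative integers")
    n = counts.size
    if labels is None:
        labels = data_labels(n)
    if smoothing == "none":
        total = counts.sum()
        if total < 1:
            raise ValueError("all counts are zero; nothing to normalize")
        values = counts / total
    elif smoothing == "laplace":
        values = (counts + 1.0) / (counts.sum() + n)
    else:
        raise ValueError(f"unknown smoothing {smoothing!r}")
    return ProbVector(tuple(labels), values)
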