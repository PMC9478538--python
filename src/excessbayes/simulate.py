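"""Iterated Bayesian belief dynamics.

The simulated agent holds a belief ``P^t(h)`` over hypotheses and a fixed
near-one-to-one likelihood ``P(d|h)``.  At each step a datum is drawn
uniformly at random from the *experienced* subset of the data universe, the
posterior is computed by Bayes' rule and adopted as the next prior
(posterior → prior updating), the cumulative empirical data distribution is
updated, and the displayed joint is recomputed as the product of the two
marginals ``P^{t+1}(d) P^{t+1}(h)``.

Because only experienced data are ever presented, the empirical probability
of every other datum is exactly zero (with ``smoothing="none"``) and the
empirical probability of each experienced datum converges to
``1/|experienced|``: iterated Bayesian updating restricts the effective
universe to what has been experienced.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .probability import (
    DivergenceError,
    JointMatrix,
    LikelihoodMatrix,
    ProbVector,
    bayes_posterior,
    data_labels,
    empirical_data_prob,
    ideal_likelihood,
    joint_from_marginals,
    kld,
)

__all__ = [
    "SimulationConfig",
    "ExperimentState",
    "HeatmapGrid",
    "Snapshot",
    "bayes_step",
    "run_bayesian_phase",
    "heatmap_bins",
    "BIN_NAMES",
]

logger = logging.getLogger("excessbayes.simulate")

#: heatmap bin names, high to low
BIN_NAMES = ("black", "pink", "orange", "pale_yellow", "white")


class SimulationConfig(BaseModel):
    """Complete description of a run; a single JSON document round-trips.

    Parameters
    ----------
    n : dimension of the data/hypothesis universe.
    alpha : diagonal likelihood mass (0.8 in the reference simulations;
        1.0 is the exact one-to-one correspondence).
    experienced : 1-based indices of the data that can actually be drawn.
    theta : strict threshold for turning an ideal joint into a relation.
    relation_threshold : binarization level for simulation-derived joints.
    bayes_steps : length of the Bayesian phase (30 in the excess protocol;
        a couple of thousand for pure convergence runs).
    excess_steps : length of the excess phase (0 = pure Bayesian run).
    seed : RNG seed; runs with equal config and seed are bit-identical.
    heatmap_edges : descending bin edges for the five-color heatmap.
    smoothing : "none" keeps never-drawn data at exactly zero probability;
        "laplace" adds one pseudo-count per datum.
    articulation_mode : which blocks become diagonal squares in the final
        articulated relation of the excess phase.
    alternation_start : whether the first excess step renormalizes each
        datum over hypotheses ("data") or each hypothesis over data
        ("hypothesis").
    snapshot_every : snapshot cadence during the Bayesian phase (0 = none).
    sum_upper_inclusive : include the next block's first index in the
        renormalization sums (the printed-equation reading) instead of
        stopping at the block boundary (the worked-example reading).
    zero_block_sum : "skip" leaves a row/column with zero in-block mass
        untouched (and logs a warning); "error" raises instead.
    """

    n: int = Field(ge=1)
    alpha: float = 0.8
    experienced: list[int]
    theta: float = 0.1
    relation_threshold: float = 0.0006
    bayes_steps: int = Field(default=30, ge=0)
    excess_steps: int = Field(default=0, ge=0)
    seed: int = 0
    heatmap_edges: list[float] = [0.01, 0.008, 0.002, 0.0006]
    smoothing: Literal["none", "laplace"] = "none"
    articulation_mode: Literal["all_blocks", "experienced_only"] = "all_blocks"
    alternation_start: Literal["data", "hypothesis"] = "data"
    snapshot_every: int = Field(default=10, ge=0)
    sum_upper_inclusive: bool = False
    zero_block_sum: Literal["skip", "error"] = "skip"

    @field_validator("experienced")
    @classmethod
    def _nonempty(cls, v: list[int]) -> list[int]:
        if not v:
            raise ValueError("experienced must be nonempty")
        return sorted(set(v))

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if not set(self.experienced) <= set(range(1, self.n + 1)):
            raise ValueError("experienced must be a subset of 1..n")
        edges = self.heatmap_edges
        if len(edges) != 4 or any(not 0 < e < 1 for e in edges) or any(
            nxt >= prev for nxt, prev in zip(edges[1:], edges[:-1])
        ):
            raise ValueError("heatmap_edges must be 4 strictly decreasing values in (0,1)")
        return self


@dataclass(frozen=True)
class Snapshot:
    t: int
    joint: JointMatrix
    prior: ProbVector
    phase: str  # "bayes" or "excess"


@dataclass
class ExperimentState:
    """Mutable-through-replacement record of a run in progress."""

    t: int
    prior: ProbVector
    likelihood: LikelihoodMatrix
    counts: np.ndarray
    joint: JointMatrix
    history: list = field(default_factory=list)
    excess_steps_done: int = 0
    last_partition: object = None

    def data_marginal(self, smoothing: str = "none") -> ProbVector:
        return empirical_data_prob(self.counts, self.joint.data_labels, smoothing)


@dataclass(frozen=True)
class HeatmapGrid:
    """Five-bin discretization of a joint matrix for display/export."""

    data_labels: tuple[str, ...]
    hyp_labels: tuple[str, ...]
    bins: np.ndarray  # array of bin-name strings, shape (n_data, n_hyp)


def initial_state(config: SimulationConfig) -> ExperimentState:
    """State at t=0: uniform prior, zero counts, and — since there are no
    observations yet — a uniform stand-in data marginal so the initial joint
    is well formed."""
    lik = ideal_likelihood(config.n, config.alpha)
    prior = ProbVector.uniform(lik.hyp_labels)
    pd0 = ProbVector.uniform(lik.data_labels)
    return ExperimentState(
        t=0,
        prior=prior,
        likelihood=lik,
        counts=np.zeros(config.n, dtype=np.int64),
        joint=joint_from_marginals(pd0, prior),
    )


def bayes_step(state: ExperimentState, d: str, smoothing: str = "none") -> ExperimentState:
    """One posterior→prior update after observing datum ``d``.

    The new displayed joint is the product of the updated cumulative data
    marginal and the new belief over hypotheses.
    """
    posterior = bayes_posterior(state.likelihood, state.prior, d)
    counts = state.counts.copy()
    counts[state.likelihood.data_labels.index(d)] += 1
    pd = empirical_data_prob(counts, state.likelihood.data_labels, smoothing)
    joint = joint_from_marginals(pd, posterior)
    if logger.isEnabledFor(logging.DEBUG):
        try:
            step_kld = kld(state.prior, posterior)
        except DivergenceError:
            step_kld = math.inf
        surprise = -math.log(pd[d]) if pd[d] > 0 else math.inf
        logger.debug(
            "t=%d d=%s entropy=%.6f surprise=%.6f kld=%.6f",
            state.t + 1, d, posterior.entropy(), surprise, step_kld,
        )
    return replace(
        state, t=state.t + 1, prior=posterior, counts=counts, joint=joint,
        history=state.history,
    )


def run_bayesian_phase(config: SimulationConfig) -> ExperimentState:
    """Draw ``bayes_steps`` data uniformly at random (seeded) from the
    experienced subset, applying :func:`bayes_step` after each draw."""
    rng = np.random.default_rng(config.seed)
    state = initial_state(config)
    dl = data_labels(config.n)
    experienced = [dl[i - 1] for i in config.experienced]
    for step in range(config.bayes_steps):
        d = experienced[rng.integers(len(experienced))]
        state = bayes_step(state, d, config.smoothing)
        if config.snapshot_every and state.t % config.snapshot_every == 0:
            state.history.append(Snapshot(state.t, state.joint, state.prior, "bayes"))
    return state


def heatmap_bins(joint: JointMatrix, edges) -> HeatmapGrid:
    """Discretize a joint into the five display bins.

    An entry ≥ the highest edge is ``black``; the comparison at every edge is
    inclusive from above, so an entry exactly at an edge takes the darker bin;
    below all edges is ``white``.
    """
    edges = list(edges)
    if len(edges) != 4 or any(nxt >= prev for nxt, prev in zip(edges[1:], edges[:-1])):
        raise ValueError("edges must be 4 strictly decreasing values")
    e = joint.entries
    bins = np.full(e.shape, "white", dtype=object)
    for name, edge in zip(BIN_NAMES[:4], edges):
        bins[(bins == "white") & (e >= edge)] = name
    return HeatmapGrid(joint.data_labels, joint.hyp_labels, bins)
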