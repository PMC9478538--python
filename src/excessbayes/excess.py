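"""Excess Bayesian inference: block detection and joint renormalization.

The excess phase treats the experienced part of the data universe as the
whole universe.  At each step the current joint is binarized into a relation,
the diagonal of that relation is scanned for membership flips (the boundary
set), maximal runs of constant diagonal membership become *blocks*, and the
joint is renormalized block-wise — for every datum over the hypotheses of
its block, or (alternating) for every hypothesis over the data of its block.
Dividing whole rows/columns by an *in-block* sum amplifies the joint mass
outside the experienced diagonal: excess Bayesian inference brings the
ignored background back above threshold instead of suppressing it.

The final articulated relation assembles one diagonal square per block with
a fully related background outside all squares.  (Thresholding the
renormalized joint itself cannot produce that pattern: the renormalizations
compose to a row/column scaling ``D1·J·D2`` of the warm-up joint, and for
any such matrix the off-diagonal cells inside and across blocks cannot be
separated by one threshold.  The articulation is therefore the operative
construction, with the thresholded relation kept as a diagnostic.)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .probability import JointMatrix
from .relation import BinaryRelation
from .simulate import ExperimentState, SimulationConfig, Snapshot, run_bayesian_phase

__all__ = [
    "BlockPartition",
    "threshold_relation",
    "boundary_set",
    "block_partition",
    "articulated_relation",
    "renorm_over_hypotheses",
    "renorm_over_data",
    "excess_step",
    "run_excess_phase",
]

logger = logging.getLogger("excessbayes.excess")


def threshold_relation(joint: JointMatrix, theta: float, inclusive: bool = False) -> BinaryRelation:
    """Binarize a joint: ``(h_j, d_i)`` is related iff the entry exceeds
    ``theta`` (strictly by default; ``inclusive=True`` uses ≥, the final
    display convention)."""
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    mask = joint.entries >= theta if inclusive else joint.entries > theta
    pairs = {
        (joint.hyp_labels[j], joint.data_labels[i])
        for i, j in zip(*np.nonzero(mask))
    }
    return BinaryRelation(joint.hyp_labels, joint.data_labels, frozenset(pairs))


@dataclass(frozen=True)
class BlockPartition:
    """Maximal runs of constant diagonal membership on a square relation.

    ``blocks`` are 1-based inclusive intervals covering ``1..n``;
    ``experienced_flags[k]`` records whether block k's diagonal cells are in
    the relation; ``boundary_elements`` are the block start indices.
    """

    n: int
    boundary_elements: tuple[int, ...]
    blocks: tuple[tuple[int, int], ...]
    experienced_flags: tuple[bool, ...]

    def __post_init__(self) -> None:
        cover = [i for p, q in self.blocks for i in range(p, q + 1)]
        if cover != list(range(1, self.n + 1)):
            raise ValueError("blocks must be disjoint, consecutive, and cover 1..n")
        if len(self.experienced_flags) != len(self.blocks):
            raise ValueError("one flag per block required")

    def block_of(self, i: int) -> int:
        """Index of the block containing diagonal position ``i`` (1-based)."""
        for k, (p, q) in enumerate(self.blocks):
            if p <= i <= q:
                return k
        raise ValueError(f"index {i} outside 1..{self.n}")

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(q - p + 1 for p, q in self.blocks)


def _require_square(rel: BinaryRelation) -> int:
    if not rel.is_square:
        raise ValueError("a square relation (|H| = |D|) is required")
    return len(rel.data_labels)


def boundary_set(rel: BinaryRelation) -> list[int]:
    """Diagonal indices where membership flips between ``i`` and ``i+1``,
    plus the sentinel index ``n``, in increasing order."""
    n = _require_square(rel)
    diag = rel.diagonal_membership()
    flips = [i for i in range(1, n) if diag[i - 1] != diag[i]]
    return flips + [n]


def block_partition(rel: BinaryRelation) -> BlockPartition:
    """Partition ``1..n`` into the maximal runs of constant diagonal
    membership; equivalently, blocks start just after each flip index."""
    n = _require_square(rel)
    diag = rel.diagonal_membership()
    ends = boundary_set(rel)
    starts = [1] + [e + 1 for e in ends[:-1]]
    blocks = tuple((p, q) for p, q in zip(starts, ends))
    flags = tuple(bool(diag[p - 1]) for p, _ in blocks)
    return BlockPartition(n, tuple(starts), blocks, flags)


def partition_from_indicator(indicator) -> BlockPartition:
    """Partition ``1..n`` into maximal runs of a boolean per-index indicator
    (used in ``experienced_only`` mode, where articulation follows the
    realized experience — which data have actually been presented — rather
    than the thresholded relation's diagonal)."""
    indicator = np.asarray(indicator, dtype=bool)
    n = indicator.size
    flips = [i for i in range(1, n) if indicator[i - 1] != indicator[i]]
    ends = flips + [n]
    starts = [1] + [e + 1 for e in ends[:-1]]
    blocks = tuple((p, q) for p, q in zip(starts, ends))
    flags = tuple(bool(indicator[p - 1]) for p, _ in blocks)
    return BlockPartition(n, tuple(starts), blocks, flags)


def articulated_relation(
    part: BlockPartition,
    hyp_labels: tuple[str, ...],
    data_labels: tuple[str, ...],
    mode: str = "all_blocks",
) -> BinaryRelation:
    """Assemble the relation the articulation describes.

    Every block square becomes a diagonal relation and every cell outside
    all block squares is related (the fused background).  In
    ``experienced_only`` mode, only experienced blocks are articulated as
    diagonal squares; the squares of never-experienced blocks are absorbed
    into the fully related background.
    """
    if mode not in ("all_blocks", "experienced_only"):
        raise ValueError(f"unknown articulation mode {mode!r}")
    n = part.n
    pairs = set()
    block_of = np.empty(n, dtype=int)
    for k, (p, q) in enumerate(part.blocks):
        block_of[p - 1:q] = k
    for i in range(n):
        for j in range(n):
            bi, bj = block_of[i], block_of[j]
            if bi != bj:
                pairs.add((hyp_labels[j], data_labels[i]))
            else:
                articulate = mode == "all_blocks" or part.experienced_flags[bi]
                if articulate:
                    if i == j:
                        pairs.add((hyp_labels[j], data_labels[i]))
                else:
                    pairs.add((hyp_labels[j], data_labels[i]))
    return BinaryRelation(hyp_labels, data_labels, frozenset(pairs))


def _domain(part: BlockPartition, i: int, sum_upper_inclusive: bool) -> tuple[int, int]:
    """In-block summation domain for diagonal index ``i`` as 0-based
    half-open ``[lo, hi)``."""
    p, q = part.blocks[part.block_of(i)]
    if sum_upper_inclusive:
        q = min(q + 1, part.n)
    return p - 1, q


def _renorm(
    entries: np.ndarray,
    part: BlockPartition,
    mode: str,
    axis: int,
    sum_upper_inclusive: bool,
    zero_block_sum: str,
) -> np.ndarray:
    out = entries.copy()
    skipped = []
    for i in range(1, part.n + 1):
        k = part.block_of(i)
        if mode == "experienced_only" and not part.experienced_flags[k]:
            continue
        lo, hi = _domain(part, i, sum_upper_inclusive)
        if axis == 0:  # per datum, sum over in-block hypotheses
            s = entries[i - 1, lo:hi].sum()
        else:  # per hypothesis, sum over in-block data
            s = entries[lo:hi, i - 1].sum()
        if s <= 0:
            if zero_block_sum == "error":
                raise ZeroDivisionError(f"zero in-block sum at index {i}")
            skipped.append(i)
            continue
        if axis == 0:
            out[i - 1, :] = entries[i - 1, :] / s
        else:
            out[:, i - 1] = entries[:, i - 1] / s
    if skipped:
        # expected whenever never-experienced lines are exactly zero
        logger.debug(
            "zero in-block sums left unrenormalized at indices %s", skipped
        )
    return out


def renorm_over_hypotheses(
    joint: JointMatrix,
    part: BlockPartition,
    mode: str = "all_blocks",
    sum_upper_inclusive: bool = False,
    zero_block_sum: str = "skip",
) -> JointMatrix:
    """For every datum ``d_i``, divide the *entire* row by the in-block sum
    ``S(d_i) = Σ_{j ∈ B(i)} P(d_i, h_j)``.

    After the operation every renormalized datum has in-block hypothesis
    mass exactly 1; entries outside the block grow whenever ``S < 1``.
    In ``experienced_only`` mode, data whose block is not experienced pass
    through unchanged.
    """
    if len(joint.data_labels) != part.n or len(joint.hyp_labels) != part.n:
        raise ValueError("partition size does not match the joint")
    out = _renorm(joint.entries, part, mode, 0, sum_upper_inclusive, zero_block_sum)
    return JointMatrix(joint.data_labels, joint.hyp_labels, out, state="renormalized")


def renorm_over_data(
    joint: JointMatrix,
    part: BlockPartition,
    mode: str = "all_blocks",
    sum_upper_inclusive: bool = False,
    zero_block_sum: str = "skip",
) -> JointMatrix:
    """Mirror of :func:`renorm_over_hypotheses`: for every hypothesis
    ``h_j``, divide the entire column by ``Σ_{i ∈ B(j)} P(d_i, h_j)``."""
    if len(joint.data_labels) != part.n or len(joint.hyp_labels) != part.n:
        raise ValueError("partition size does not match the joint")
    out = _renorm(joint.entries, part, mode, 1, sum_upper_inclusive, zero_block_sum)
    return JointMatrix(joint.data_labels, joint.hyp_labels, out, state="renormalized")


def excess_step(state: ExperimentState, config: SimulationConfig) -> ExperimentState:
    """One excess step: binarize, partition, and apply exactly one of the
    two renormalizations, alternating across steps.

    In ``all_blocks`` mode the partition follows the diagonal of the
    thresholded relation; in ``experienced_only`` mode it follows the
    realized experience (which data have been observed at least once).
    """
    if config.articulation_mode == "experienced_only":
        part = partition_from_indicator(state.counts > 0)
    else:
        rel = threshold_relation(state.joint, config.relation_threshold)
        part = block_partition(rel)
    data_first = config.alternation_start == "data"
    do_hyp_renorm = (state.excess_steps_done % 2 == 0) == data_first
    op = renorm_over_hypotheses if do_hyp_renorm else renorm_over_data
    joint = op(
        state.joint,
        part,
        mode=config.articulation_mode,
        sum_upper_inclusive=config.sum_upper_inclusive,
        zero_block_sum=config.zero_block_sum,
    )
    return replace(
        state,
        t=state.t + 1,
        joint=joint,
        history=state.history,
        excess_steps_done=state.excess_steps_done + 1,
        last_partition=part,
    )


def run_excess_phase(config: SimulationConfig) -> tuple[ExperimentState, BinaryRelation]:
    """Bayesian warm-up followed by ``excess_steps`` excess steps.

    Returns the final state and the final articulated relation, built from
    the block partition of the ≥-binarized final joint (the display
    convention).  With ``excess_steps=0`` the state is exactly the output of
    :func:`run_bayesian_phase`.
    """
    state = run_bayesian_phase(config)
    for _ in range(config.excess_steps):
        state = excess_step(state, config)
        state.history.append(Snapshot(state.t, state.joint, state.prior, "excess"))
    if config.articulation_mode == "experienced_only":
        part = partition_from_indicator(state.counts > 0)
    else:
        final_rel = threshold_relation(
            state.joint, config.relation_threshold, inclusive=True
        )
        part = block_partition(final_rel)
    state.last_partition = part
    articulated = articulated_relation(
        part, state.joint.hyp_labels, state.joint.data_labels, config.articulation_mode
    )
    return state, articulated
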