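"""Binary relations between hypotheses and data, fixtures, and CSV I/O.

A :class:`BinaryRelation` is the bridge between the probabilistic phase and
the order-theoretic phase: joint distributions are binarized into relations,
and rough-set lattices are built from relations.

Orientation convention: a pair is stored hypothesis-major as ``(h, d)``; in
the infix notation used by the approximation operators, ``s R T`` with a
datum ``s`` and hypothesis ``T`` means ``(T, s)`` is in the pair set.

Three fixture families mirror the canonical shapes studied here:

``diagonal``
    the exact one-to-one correspondence ``{(h_i, d_i)}``;
``subdiagonal``
    the identity restricted to an experienced subset of data, empty
    elsewhere (what iterated Bayesian updating leaves behind);
``blocks_with_background``
    consecutive diagonal blocks whose squares contain only the identity
    pairs, with *every* cell outside the block squares related — the shape
    excess Bayesian inference produces and the source of orthomodular,
    non-Boolean logic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Literal, Optional

import numpy as np
from pydantic import BaseModel, model_validator

from .probability import data_labels, hyp_labels

__all__ = [
    "BinaryRelation",
    "FixtureSpec",
    "make_fixture",
    "subdiagonal_relation",
    "read_relation_csv",
    "write_relation_csv",
    "RelationParseError",
]


class RelationParseError(ValueError):
    """Relation CSV does not conform to the documented dialect."""


@dataclass(frozen=True)
class BinaryRelation:
    """A finite relation R ⊆ H × D with ordered labels."""

    hyp_labels: tuple[str, ...]
    data_labels: tuple[str, ...]
    pairs: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "hyp_labels", tuple(self.hyp_labels))
        object.__setattr__(self, "data_labels", tuple(self.data_labels))
        object.__setattr__(self, "pairs", frozenset(self.pairs))
        hset, dset = set(self.hyp_labels), set(self.data_labels)
        if len(hset) != len(self.hyp_labels) or len(dset) != len(self.data_labels):
            raise ValueError("duplicate labels")
        for h, d in self.pairs:
            if h not in hset or d not in dset:
                raise ValueError(f"pair ({h!r}, {d!r}) outside the label universe")

    @property
    def is_square(self) -> bool:
        return len(self.hyp_labels) == len(self.data_labels)

    def matrix(self) -> np.ndarray:
        """Boolean incidence matrix, shape (n_data, n_hyp): ``m[i, j]`` iff
        ``(hyp_labels[j], data_labels[i])`` is related."""
        hidx = {h: j for j, h in enumerate(self.hyp_labels)}
        didx = {d: i for i, d in enumerate(self.data_labels)}
        m = np.zeros((len(self.data_labels), len(self.hyp_labels)), dtype=bool)
        for h, d in self.pairs:
            m[didx[d], hidx[h]] = True
        return m

    def diagonal_membership(self) -> np.ndarray:
        """Boolean vector: position k is True iff the k-th diagonal cell
        ``(h_k, d_k)`` is related.  Requires a square relation."""
        if not self.is_square:
            raise ValueError("diagonal membership requires a square relation")
        return np.array(
            [(h, d) in self.pairs for h, d in zip(self.hyp_labels, self.data_labels)]
        )

    def __contains__(self, pair) -> bool:
        return pair in self.pairs


class FixtureSpec(BaseModel):
    """Declarative description of a fixture relation (pure function of its
    fields; no randomness)."""

    kind: Literal["diagonal", "subdiagonal", "blocks_with_background"]
    n: Optional[int] = None
    experienced: Optional[list[int]] = None
    block_sizes: Optional[list[int]] = None

    @model_validator(mode="after")
    def _check(self) -> "FixtureSpec":
        if self.kind == "blocks_with_background":
            if not self.block_sizes or any(b < 1 for b in self.block_sizes):
                raise ValueError("block_sizes must be positive integers")
            total = sum(self.block_sizes)
            if self.n is None:
                self.n = total
            elif self.n != total:
                raise ValueError("block_sizes must sum to n")
        else:
            if self.n is None or self.n < 1:
                raise ValueError("n must be a positive integer")
        if self.kind == "subdiagonal":
            if not self.experienced:
                raise ValueError("subdiagonal requires a nonempty experienced set")
            if not set(self.experienced) <= set(range(1, self.n + 1)):
                raise ValueError("experienced must be a subset of 1..n")
        return self


def make_fixture(spec: FixtureSpec) -> BinaryRelation:
    """Construct the relation a :class:`FixtureSpec` describes."""
    n = spec.n
    hl, dl = hyp_labels(n), data_labels(n)
    if spec.kind == "diagonal":
        pairs = {(hl[i], dl[i]) for i in range(n)}
    elif spec.kind == "subdiagonal":
        pairs = {(hl[i - 1], dl[i - 1]) for i in spec.experienced}
    else:
        pairs = set()
        starts = np.cumsum([0] + list(spec.block_sizes))
        block_of = np.empty(n, dtype=int)
        for b, (lo, hi) in enumerate(zip(starts[:-1], starts[1:])):
            block_of[lo:hi] = b
            for i in range(lo, hi):
                pairs.add((hl[i], dl[i]))
        for i in range(n):
            for j in range(n):
                if block_of[i] != block_of[j]:
                    pairs.add((hl[j], dl[i]))
    return BinaryRelation(hl, dl, frozenset(pairs))


def subdiagonal_relation(n: int, experienced: Iterable[int]) -> BinaryRelation:
    """The analytic sub-diagonal relation ``{(h_i, d_i) : i ∈ experienced}``
    on an ``n × n`` universe — the limiting relation iterated Bayesian
    updating leaves when only the experienced data are ever presented."""
    return make_fixture(
        FixtureSpec(kind="subdiagonal", n=n, experienced=sorted(set(experienced)))
    )


def write_relation_csv(rel: BinaryRelation, path) -> None:
    """Write the documented dialect: header ``R,h1,...``; one row per datum
    with 0/1 cells (1 iff ``(h_j, d_i)`` related)."""
    m = rel.matrix()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["R", *rel.hyp_labels])
        for i, d in enumerate(rel.data_labels):
            w.writerow([d, *(int(x) for x in m[i])])


def read_relation_csv(path) -> BinaryRelation:
    """Parse a relation CSV; raises :class:`RelationParseError` with the
    offending line number on any deviation from the dialect."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    rows = [r for r in rows if r]  # tolerate trailing blank lines
    if not rows:
        raise RelationParseError("line 1: empty file is not a relation")
    header = rows[0]
    if header[0] != "R" or len(header) < 2:
        raise RelationParseError("line 1: header must be 'R,h1,...'")
    hl = tuple(header[1:])
    if len(set(hl)) != len(hl):
        raise RelationParseError("line 1: duplicate hypothesis labels")
    dl: list[str] = []
    pairs = set()
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise RelationParseError(f"line {lineno}: ragged row")
        d = row[0]
        if d in dl:
            raise RelationParseError(f"line {lineno}: duplicate data label {d!r}")
        dl.append(d)
        for h, cell in zip(hl, row[1:]):
            if cell not in ("0", "1"):
                raise RelationParseError(f"line {lineno}: non-binary cell {cell!r}")
            if cell == "1":
                pairs.add((h, d))
    if not dl:
        raise RelationParseError("line 2: relation has no data rows")
    return BinaryRelation(hl, tuple(dl), frozenset(pairs))
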