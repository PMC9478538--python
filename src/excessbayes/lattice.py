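"""Rough-set lattices from binary relations.

Given a relation R ⊆ H × D, the upper approximation of a data subset X is
the set of hypotheses related to at least one datum of X; the lower
approximation of a hypothesis subset Y is the set of data all of whose
related hypotheses lie in Y.  Their composite is a closure operator on
subsets of D (extensive, monotone, idempotent — the two maps form an
adjunction), and the rough-set lattice is the family of its fixed points
ordered by inclusion.  Meet is plain intersection (closed sets are closed
under intersection); join is the closure of the union.

For a full diagonal relation the lattice is the power set of D — classical
Boolean logic.  For consecutive diagonal blocks over a fully related
background it is a disjoint union of Boolean blocks sharing only bottom and
top — the orthomodular shape of quantum logic.

Sets are represented internally as bitmasks over the data universe, which
keeps closure evaluation and the fixed-point enumeration cheap; public
operations speak frozensets of labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable

import numpy as np

from .relation import BinaryRelation

__all__ = [
    "RoughLattice",
    "LatticeSizeError",
    "upper_approx",
    "lower_approx",
    "closure",
    "enumerate_lattice",
    "brute_force_lattice_elements",
    "meet",
    "join",
    "reduce_relation",
    "hasse_covers",
]

#: default cap on the number of enumerated elements
DEFAULT_GUARD = 1 << 16


class LatticeSizeError(RuntimeError):
    """Enumeration exceeded the element guard limit."""


@lru_cache(maxsize=128)
def _bits(rel: BinaryRelation):
    """Per-datum hypothesis masks and label/bit translation tables."""
    hidx = {h: j for j, h in enumerate(rel.hyp_labels)}
    didx = {d: i for i, d in enumerate(rel.data_labels)}
    hyps_of = [0] * len(rel.data_labels)
    for h, d in rel.pairs:
        hyps_of[didx[d]] |= 1 << hidx[h]
    return hidx, didx, hyps_of


def _data_mask(rel: BinaryRelation, X: Iterable[str]) -> int:
    _, didx, _ = _bits(rel)
    m = 0
    for d in X:
        if d not in didx:
            raise ValueError(f"datum {d!r} outside the universe")
        m |= 1 << didx[d]
    return m


def _hyp_mask(rel: BinaryRelation, Y: Iterable[str]) -> int:
    hidx, _, _ = _bits(rel)
    m = 0
    for h in Y:
        if h not in hidx:
            raise ValueError(f"hypothesis {h!r} outside the universe")
        m |= 1 << hidx[h]
    return m


def _upper_mask(rel: BinaryRelation, xmask: int) -> int:
    _, _, hyps_of = _bits(rel)
    y = 0
    i = 0
    m = xmask
    while m:
        if m & 1:
            y |= hyps_of[i]
        m >>= 1
        i += 1
    return y


def _lower_mask(rel: BinaryRelation, ymask: int) -> int:
    _, _, hyps_of = _bits(rel)
    x = 0
    for i, hm in enumerate(hyps_of):
        if hm & ~ymask == 0:
            x |= 1 << i
    return x


def _closure_mask(rel: BinaryRelation, xmask: int) -> int:
    return _lower_mask(rel, _upper_mask(rel, xmask))


def _unmask_data(rel: BinaryRelation, m: int) -> frozenset:
    return frozenset(d for i, d in enumerate(rel.data_labels) if m >> i & 1)


def _unmask_hyps(rel: BinaryRelation, m: int) -> frozenset:
    return frozenset(h for j, h in enumerate(rel.hyp_labels) if m >> j & 1)


def upper_approx(rel: BinaryRelation, X: Iterable[str]) -> frozenset:
    """Hypotheses related to at least one datum of X (existential reading)."""
    return _unmask_hyps(rel, _upper_mask(rel, _data_mask(rel, X)))


def lower_approx(rel: BinaryRelation, Y: Iterable[str]) -> frozenset:
    """Data whose related hypotheses all lie in Y.

    Data related to no hypothesis belong vacuously; relations without empty
    data rows therefore have ``lower_approx(∅) = ∅``.
    """
    return _unmask_data(rel, _lower_mask(rel, _hyp_mask(rel, Y)))


def closure(rel: BinaryRelation, X: Iterable[str]) -> frozenset:
    """The composite lower∘upper approximation of X — a closure operator
    (extensive, monotone, idempotent)."""
    return _unmask_data(rel, _closure_mask(rel, _data_mask(rel, X)))


@dataclass
class RoughLattice:
    """The fixed points of the closure operator, ordered by inclusion.

    ``elements`` are sorted by (size, data-label positions) so indices are
    deterministic; ``bottom`` is the closure of the empty set (the empty set
    itself whenever every datum is related to something) and ``top`` is the
    full universe.
    """

    universe: tuple[str, ...]
    elements: list
    generator_relation: BinaryRelation
    masks: list = field(repr=False, default_factory=list)
    _index: dict = field(repr=False, default_factory=dict)

    @property
    def bottom(self) -> frozenset:
        # closure(∅) is contained in every closed set, so the size sort
        # places it first
        return self.elements[0]

    @property
    def top(self) -> frozenset:
        return frozenset(self.universe)

    def __len__(self) -> int:
        return len(self.elements)

    def __contains__(self, X) -> bool:
        return frozenset(X) in self._index

    def index(self, X) -> int:
        return self._index[frozenset(X)]


def enumerate_lattice(rel: BinaryRelation, guard: int = DEFAULT_GUARD) -> RoughLattice:
    """Enumerate all closure-fixed subsets of D by join-generation.

    Seeds with the closure of the empty set and of every singleton, then
    closes under join (closure of pairwise unions) to a fixed point.  This
    is complete because every closed set is the join of the singleton
    closures it contains.  Raises :class:`LatticeSizeError` beyond ``guard``
    elements.
    """
    n = len(rel.data_labels)
    full = (1 << n) - 1
    seen = {_closure_mask(rel, 0), full}
    frontier = list(seen)
    for i in range(n):
        c = _closure_mask(rel, 1 << i)
        if c not in seen:
            seen.add(c)
            frontier.append(c)
    while frontier:
        new = []
        snapshot = list(seen)
        for a in frontier:
            for b in snapshot:
                u = a | b
                if u in seen:
                    continue
                c = _closure_mask(rel, u)
                if c not in seen:
                    seen.add(c)
                    new.append(c)
                    if len(seen) > guard:
                        raise LatticeSizeError(
                            f"lattice exceeds guard limit {guard} elements"
                        )
        frontier = new
    order = sorted(seen, key=lambda m: (bin(m).count("1"), _mask_sort_key(m, n)))
    lat = RoughLattice(
        universe=rel.data_labels,
        elements=[_unmask_data(rel, m) for m in order],
        generator_relation=rel,
        masks=order,
    )
    lat._index = {e: i for i, e in enumerate(lat.elements)}
    return lat


def _mask_sort_key(m: int, n: int) -> tuple:
    return tuple(i for i in range(n) if m >> i & 1)


def brute_force_lattice_elements(rel: BinaryRelation) -> set:
    """Oracle enumeration: filter the whole power set of D by the fixed-point
    condition.  Exponential; intended for small universes in tests."""
    n = len(rel.data_labels)
    if n > 20:
        raise ValueError("brute force is limited to small universes")
    out = set()
    for m in range(1 << n):
        if _closure_mask(rel, m) == m:
            out.add(_unmask_data(rel, m))
    return out


def _require_element(lat: RoughLattice, X) -> frozenset:
    X = frozenset(X)
    if X not in lat._index:
        raise ValueError(f"{sorted(X)} is not a lattice element")
    return X


def meet(lat: RoughLattice, X, Y) -> frozenset:
    """Greatest lower bound: plain intersection (closed under this closure)."""
    X, Y = _require_element(lat, X), _require_element(lat, Y)
    return X & Y


def join(lat: RoughLattice, X, Y) -> frozenset:
    """Least upper bound: the closure of the union."""
    X, Y = _require_element(lat, X), _require_element(lat, Y)
    return closure(lat.generator_relation, X | Y)


def reduce_relation(rel: BinaryRelation) -> tuple[BinaryRelation, list]:
    """Iteratively remove every datum related to all remaining hypotheses and
    every hypothesis related to all remaining data, until stable.

    Such rows/columns only feed the top element of the rough-set lattice;
    removing them leaves the proper part of the lattice unchanged.  Returns
    the reduced relation and a removal log of ``("data"|"hyp", label)``.
    """
    hl, dl = list(rel.hyp_labels), list(rel.data_labels)
    pairs = set(rel.pairs)
    log: list = []
    changed = True
    while changed and hl and dl:
        changed = False
        for d in list(dl):
            if all((h, d) in pairs for h in hl):
                dl.remove(d)
                pairs -= {(h, d) for h in hl}
                log.append(("data", d))
                changed = True
        for h in list(hl):
            if dl and all((h, d) in pairs for d in dl):
                hl.remove(h)
                pairs -= {(h, d) for d in dl}
                log.append(("hyp", h))
                changed = True
    return BinaryRelation(tuple(hl), tuple(dl), frozenset(pairs)), log


def hasse_covers(lat: RoughLattice) -> set:
    """All covering pairs (X, Y): X ⊂ Y with no element strictly between."""
    nelem = len(lat.masks)
    # leq[i, j] iff element i ⊆ element j
    if len(lat.universe) <= 63:
        masks = np.array(lat.masks, dtype=np.uint64)
        leq = (masks[:, None] & ~masks[None, :]) == 0
    else:  # arbitrary-width fallback
        leq = np.array(
            [[a & ~b == 0 for b in lat.masks] for a in lat.masks], dtype=bool
        )
    strict = leq & ~np.eye(nelem, dtype=bool)
    two_step = (strict.astype(np.uint8) @ strict.astype(np.uint8)) > 0
    cover = strict & ~two_step
    return {
        (lat.elements[i], lat.elements[j]) for i, j in zip(*np.nonzero(cover))
    }
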