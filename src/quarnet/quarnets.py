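"""tf-quarnet values, dense weighted quarnet sets, consistency scores and file I/O.

A *tf-quarnet* is a four-leaf triangle-free level-1 semi-directed network.  Up to
leaf relabeling there are exactly two shapes: the quartet tree (one nontrivial
split) and the 4-cycle (a cyclic leaf ordering plus the leaf below the
reticulation).  A *dense* quarnet set contains exactly one tf-quarnet for every
4-subset of the taxon set.

Internally a dense set is stored as a flat integer code array over the 4-subsets
in lexicographic :func:`itertools.combinations` order, which makes the
consistency scores cheap vectorized comparisons.

Code scheme for a 4-subset with sorted leaves ``(l0, l1, l2, l3)``:

* quartet tree: ``p`` in ``{0,1,2}`` where ``l0``'s split-partner is ``l[p+1]``;
* 4-cycle: ``3 + 4*p + r`` where ``p`` identifies ``l0``'s *opposite* leaf in
  the cycle and ``r`` in ``{0..3}`` is the index of the reticulation leaf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Split",
    "TFQuarnet",
    "DenseQuarnetSet",
    "consistency_C",
    "consistency_S",
    "weighted_consistency",
    "read_quarnets",
    "write_quarnets",
    "canonical_cycle_order",
]

N_CODES = 15  # 3 quartet codes + 12 cycle codes


class DegenerateWeightsError(ValueError):
    """All input weights are zero; the weighted consistency score is undefined."""


def make_split(side_a: Iterable[str], side_b: Iterable[str]) -> frozenset:
    """An unordered bipartition ``A|B``, represented as a frozenset of frozensets."""
    a, b = frozenset(side_a), frozenset(side_b)
    if not a or not b:
        raise ValueError("both sides of a split must be nonempty")
    if a & b:
        raise ValueError(f"split sides overlap: {sorted(a & b)}")
    return frozenset({a, b})


Split = frozenset  # alias: frozenset({frozenset(A), frozenset(B)})


def split_sides(split: Split) -> tuple[frozenset, frozenset]:
    sides = sorted(split, key=lambda s: sorted(s))
    if len(sides) == 1:  # both sides identical cannot happen; guard anyway
        raise ValueError("degenerate split")
    return sides[0], sides[1]


def canonical_cycle_order(order: Sequence[str]) -> tuple[str, ...]:
    """Lexicographically minimal rotation/reflection of a cyclic sequence."""
    order = tuple(order)
    n = len(order)
    best = None
    for seq in (order, order[::-1]):
        for i in range(n):
            rot = seq[i:] + seq[:i]
            if best is None or rot < best:
                best = rot
    return best


@dataclass(frozen=True)
class TFQuarnet:
    """A single weighted tf-quarnet: quartet tree or 4-cycle on four taxa."""

    leaves: tuple[str, ...]
    shape: str  # "quartet" | "cycle4"
    split: Split | None = None
    cycle_order: tuple[str, ...] | None = None
    reticulation_leaf: str | None = None
    weight: float = 1.0

    def __post_init__(self):
        leaves = tuple(sorted(self.leaves))
        object.__setattr__(self, "leaves", leaves)
        if len(set(leaves)) != 4:
            raise ValueError("a tf-quarnet has exactly four distinct leaves")
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError(f"weight {self.weight} outside [0, 1]")
        if self.shape == "quartet":
            if self.split is None or self.cycle_order is not None:
                raise ValueError("quartet tree requires a split and no cycle order")
            a, b = split_sides(self.split)
            if a | b != frozenset(leaves) or len(a) != 2:
                raise ValueError("split must be a 2|2 bipartition of the leaves")
        elif self.shape == "cycle4":
            if self.cycle_order is None or self.reticulation_leaf is None:
                raise ValueError("4-cycle requires a cycle order and reticulation leaf")
            if set(self.cycle_order) != set(leaves):
                raise ValueError("cycle order must use exactly the four leaves")
            if self.reticulation_leaf not in leaves:
                raise ValueError("reticulation leaf must be one of the leaves")
            object.__setattr__(
                self, "cycle_order", canonical_cycle_order(self.cycle_order)
            )
        else:
            raise ValueError(f"unknown tf-quarnet shape {self.shape!r}")

    # -- canonical integer code -------------------------------------------------

    @property
    def code(self) -> int:
        l0 = self.leaves[0]
        if self.shape == "quartet":
            a, b = split_sides(self.split)
            side = a if l0 in a else b
            partner = next(x for x in side if x != l0)
            return self.leaves.index(partner) - 1
        # cycle4: l0's opposite leaf is the one two steps away in the order
        i = self.cycle_order.index(l0)
        opposite = self.cycle_order[(i + 2) % 4]
        p = self.leaves.index(opposite) - 1
        r = self.leaves.index(self.reticulation_leaf)
        return 3 + 4 * p + r

    @property
    def skeleton_code(self) -> int:
        """Code of the undirected topology: 0-2 quartet pairings, 3-5 cycle pairings."""
        c = self.code
        return c if c < 3 else 3 + (c - 3) // 4

    @staticmethod
    def from_code(code: int, leaves: Sequence[str], weight: float = 1.0) -> "TFQuarnet":
        leaves = tuple(sorted(leaves))
        if not 0 <= code < N_CODES:
            raise ValueError(f"bad quarnet code {code}")
        if code < 3:
            partner = leaves[code + 1]
            rest = [x for x in leaves[1:] if x != partner]
            return TFQuarnet(
                leaves=leaves,
                shape="quartet",
                split=make_split({leaves[0], partner}, rest),
                weight=weight,
            )
        p, r = divmod(code - 3, 4)
        opposite = leaves[p + 1]
        x, y = [t for t in leaves[1:] if t != opposite]
        order = (leaves[0], x, opposite, y)
        return TFQuarnet(
            leaves=leaves,
            shape="cycle4",
            cycle_order=order,
            reticulation_leaf=leaves[r],
            weight=weight,
        )

    def same_topology(self, other: "TFQuarnet") -> bool:
        return self.leaves == other.leaves and self.code == other.code


class DenseQuarnetSet:
    """Exactly one weighted tf-quarnet per 4-subset of the taxon set."""

    def __init__(self, taxa: Iterable[str], quarnets: Iterable[TFQuarnet] | None = None,
                 codes: np.ndarray | None = None, weights: np.ndarray | None = None):
        self.taxa: tuple[str, ...] = tuple(sorted(set(taxa)))
        n = len(self.taxa)
        if n < 4:
            raise ValueError("a dense quarnet set needs at least 4 taxa")
        self._index = {
            frozenset(c): i for i, c in enumerate(combinations(self.taxa, 4))
        }
        m = len(self._index)
        if codes is not None:
            codes = np.asarray(codes, dtype=np.int8)
            weights = (np.ones(m) if weights is None
                       else np.asarray(weights, dtype=float))
            if codes.shape != (m,) or weights.shape != (m,):
                raise ValueError("codes/weights length must equal C(n, 4)")
            self.codes, self.weights = codes, weights
        else:
            self.codes = np.full(m, -1, dtype=np.int8)
            self.weights = np.ones(m, dtype=float)
            for q in quarnets or ():
                key = frozenset(q.leaves)
                if key not in self._index:
                    unknown = set(q.leaves) - set(self.taxa)
                    raise ValueError(f"quarnet on unknown taxa {sorted(unknown)}")
                i = self._index[key]
                if self.codes[i] != -1:
                    raise ValueError(f"duplicate quarnet for {sorted(key)}")
                self.codes[i] = q.code
                self.weights[i] = q.weight
            if (self.codes == -1).any():
                missing = m - int((self.codes != -1).sum())
                raise ValueError(f"quarnet set not dense: {missing} 4-subsets missing")
        if (self.weights < 0).any() or (self.weights > 1).any():
            raise ValueError("weights must lie in [0, 1]")

    # -- container protocol -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.codes)

    def __iter__(self) -> Iterator[TFQuarnet]:
        for four, i in self._index.items():
            yield TFQuarnet.from_code(
                int(self.codes[i]), sorted(four), float(self.weights[i])
            )

    def subsets(self) -> Iterator[tuple[str, ...]]:
        return combinations(self.taxa, 4)

    def index_of(self, four_taxa: Iterable[str]) -> int:
        return self._index[frozenset(four_taxa)]

    def quarnet(self, four_taxa: Iterable[str]) -> TFQuarnet:
        i = self.index_of(four_taxa)
        return TFQuarnet.from_code(
            int(self.codes[i]), sorted(frozenset(four_taxa)), float(self.weights[i])
        )

    def with_unit_weights(self) -> "DenseQuarnetSet":
        return DenseQuarnetSet(self.taxa, codes=self.codes.copy())

    def copy(self) -> "DenseQuarnetSet":
        return DenseQuarnetSet(
            self.taxa, codes=self.codes.copy(), weights=self.weights.copy()
        )

    def __eq__(self, other) -> bool:
        return (isinstance(other, DenseQuarnetSet)
                and self.taxa == other.taxa
                and np.array_equal(self.codes, other.codes)
                and np.allclose(self.weights, other.weights))


def _check_same_taxa(a: DenseQuarnetSet, b: DenseQuarnetSet) -> None:
    if a.taxa != b.taxa:
        raise ValueError("quarnet sets are on different taxon sets")


def consistency_C(reference: DenseQuarnetSet, candidate: DenseQuarnetSet) -> float:
    """|Q(N) ∩ Q(M)| / |Q(N)|, comparing canonical topologies (weights ignored)."""
    _check_same_taxa(reference, candidate)
    return float(np.mean(reference.codes == candidate.codes))


def consistency_S(reference: DenseQuarnetSet, candidate: DenseQuarnetSet) -> float:
    """|Q(N) ∩ Q(M)| / |Q(N) ∪ Q(M)| for dense sets on the same taxa.

    Each disagreeing 4-subset contributes two distinct quarnets to the union,
    so with ``k`` disagreements out of ``m`` subsets the score is (m-k)/(m+k).
    """
    _check_same_taxa(reference, candidate)
    m = len(reference)
    k = int(np.sum(reference.codes != candidate.codes))
    return (m - k) / (m + k)


def weighted_consistency(inputQ: DenseQuarnetSet, network) -> float:
    """w(Q ∩ Q(N)) / w(Q): weight fraction of input quarnets induced by ``network``."""
    induced = network.induced_quarnet_set()
    _check_same_taxa(inputQ, induced)
    total = float(inputQ.weights.sum())
    if total == 0.0:
        raise DegenerateWeightsError("total quarnet weight is zero")
    hit = float(inputQ.weights[inputQ.codes == induced.codes].sum())
    return hit / total


# -- text format --------------------------------------------------------------
#
#   # optional comments
#   taxa: a b c d e
#   T a b c d a,b|c,d 1.0
#   C a b c d a,b,c,d a 0.571
#
# One record per 4-subset; the weight column defaults to 1.0.


def write_quarnets(qset: DenseQuarnetSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("taxa: " + " ".join(qset.taxa) + "\n")
        for q in qset:
            if q.shape == "quartet":
                a, b = split_sides(q.split)
                srepr = ",".join(sorted(a)) + "|" + ",".join(sorted(b))
                fh.write(f"T {' '.join(q.leaves)} {srepr} {q.weight:g}\n")
            else:
                orepr = ",".join(q.cycle_order)
                fh.write(
                    f"C {' '.join(q.leaves)} {orepr} {q.reticulation_leaf} "
                    f"{q.weight:g}\n"
                )


def read_quarnets(path) -> DenseQuarnetSet:
    taxa: list[str] | None = None
    quarnets: list[TFQuarnet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("taxa:"):
                taxa = line[len("taxa:"):].split()
                continue
            parts = line.split()
            try:
                kind, leaves = parts[0], parts[1:5]
                if kind == "T":
                    sa, sb = parts[5].split("|")
                    weight = float(parts[6]) if len(parts) > 6 else 1.0
                    q = TFQuarnet(
                        leaves=tuple(leaves),
                        shape="quartet",
                        split=make_split(sa.split(","), sb.split(",")),
                        weight=weight,
                    )
                elif kind == "C":
                    order = tuple(parts[5].split(","))
                    ret = parts[6]
                    weight = float(parts[7]) if len(parts) > 7 else 1.0
                    q = TFQuarnet(
                        leaves=tuple(leaves),
                        shape="cycle4",
                        cycle_order=order,
                        reticulation_leaf=ret,
                        weight=weight,
                    )
                else:
                    raise ValueError(f"unknown record type {kind!r}")
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed quarnet record: {exc}")
            quarnets.append(q)
    if taxa is None:
        raise ValueError(f"{path}: missing 'taxa:' header")
    return DenseQuarnetSet(taxa, quarnets)
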