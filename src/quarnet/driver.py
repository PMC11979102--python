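"""Main reconstruction driver: candidate blobtrees -> expanded networks -> argmax.

Builds the n-3 candidate blobtrees, expands each into a triangle-free
semi-directed level-1 network, scores every candidate by weighted quarnet
consistency against the input set, and returns the best-scoring network
(first in candidate order on ties).
"""

from __future__ import annotations

import logging

import numpy as np

from .blobtree import candidate_blobtrees
from .cycles import HELD_KARP_MAX, expand_tree
from .networks import SemiDirectedNetwork
from .quarnets import DenseQuarnetSet, weighted_consistency

__all__ = ["squirrel", "SquirrelResult"]

log = logging.getLogger(__name__)


class SquirrelResult:
    """Best network plus all scored candidates, in construction order."""

    def __init__(self, best, candidates):
        self.best: SemiDirectedNetwork = best
        self.candidates: list[tuple[SemiDirectedNetwork, float]] = candidates

    @property
    def best_score(self) -> float:
        return max(score for _, score in self.candidates)

    def __iter__(self):
        return iter((self.best, self.candidates))


def squirrel(
    Q: DenseQuarnetSet,
    outgroup: str | None = None,
    tsp_mode: str = "auto",
    seed: int | np.random.Generator | None = 0,
    hk_threshold: int = HELD_KARP_MAX,
) -> SquirrelResult:
    """Reconstruct a triangle-free semi-directed level-1 network from ``Q``.

    Returns the highest weighted-consistency candidate among the n-3 networks
    obtained by expanding each candidate blobtree.  All randomness (tie-breaks,
    annealing) flows from ``seed``.
    """
    if outgroup is not None and outgroup not in Q.taxa:
        raise KeyError(f"outgroup {outgroup!r} is not among the taxa")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    trees = candidate_blobtrees(Q, rng)
    candidates = []
    for i, tree in enumerate(trees, 1):
        net = expand_tree(
            tree,
            Q,
            outgroup=outgroup,
            tsp_mode=tsp_mode,
            rng=rng,
            hk_threshold=hk_threshold,
        )
        score = weighted_consistency(Q, net)
        log.debug("candidate %d/%d: score %.4f", i, len(trees), score)
        candidates.append((net, score))
    best = max(candidates, key=lambda item: item[1])[0]
    # ties: keep the first (most resolved) candidate
    for net, score in candidates:
        if score == max(s for _, s in candidates):
            best = net
            break
    return SquirrelResult(best, candidates)
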