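"""Expanding multifurcations of a candidate blobtree into cycles.

For each internal vertex of degree s >= 4: build a dense set of representative
tf-quarnets on s symbolic leaves (one per neighbor component), derive pairwise
distances from the quarnet topologies, order the cycle by solving a traveling
salesman instance on those distances, and place the reticulation following a
ranking, falling back down the ranking until the partial network stays rootable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .blobtree import CandidateBlobtree, _subtree_taxa
from .networks import SemiDirectedNetwork, valid_root_edges
from .quarnets import DenseQuarnetSet, TFQuarnet

__all__ = [
    "RepresentativeQuarnetSet",
    "representative_quarnets",
    "tau",
    "quarnet_distances",
    "solve_tsp",
    "reticulation_ranking",
    "expand_tree",
    "HELD_KARP_MAX",
]

HELD_KARP_MAX = 13  # paper default: exact TSP up to this many cycle leaves


@dataclass
class RepresentativeQuarnetSet:
    """Dense quarnets on symbolic leaves y_i, one per component around a vertex."""

    vertex: object
    labels: tuple[str, ...]  # y-labels, sorted
    component_of: dict  # taxon -> y-label
    components: dict  # y-label -> frozenset of taxa
    qset: DenseQuarnetSet


def _component_labels(s: int) -> list[str]:
    width = len(str(s - 1))
    return [f"y{i:0{width}d}" for i in range(s)]


# lookup: given a pairing that joins column 0 with column p+1 (and the other
# two columns with each other), the partner column of any column k
_PARTNER = np.zeros((3, 4), dtype=np.int64)
for _p in range(3):
    a, b = 0, _p + 1
    c, d = [k for k in range(1, 4) if k != _p + 1]
    _PARTNER[_p, a], _PARTNER[_p, b] = b, a
    _PARTNER[_p, c], _PARTNER[_p, d] = d, c


def representative_quarnets(
    v,
    tree: CandidateBlobtree | nx.Graph,
    Q: DenseQuarnetSet,
    rng: np.random.Generator,
) -> RepresentativeQuarnetSet:
    """Vote a dense representative quarnet set for a degree->=4 vertex.

    For every 4-subset of components, all input quarnets with one leaf in each
    component vote (by weight) for one of the six undirected skeletons; the
    winner is kept with weight w(winner)/w(all votes), and for a winning
    4-cycle the reticulation leaf is the weighted-modal reticulation component.
    """
    g = tree.graph if isinstance(tree, CandidateBlobtree) else tree
    nbrs = sorted(g.neighbors(v), key=str)
    comp_taxa = [_subtree_taxa(g, u, v) for u in nbrs]
    # deterministic component order: by smallest contained taxon
    order = sorted(range(len(nbrs)), key=lambda i: min(comp_taxa[i]))
    comp_taxa = [comp_taxa[i] for i in order]
    s = len(comp_taxa)
    labels = _component_labels(s)
    taxa = Q.taxa
    n = len(taxa)
    tidx = {t: i for i, t in enumerate(taxa)}
    comp_arr = np.full(n, -1, dtype=np.int64)
    for ci, leaves in enumerate(comp_taxa):
        for t in leaves:
            comp_arr[tidx[t]] = ci

    subsets = np.array(list(itertools.combinations(range(n), 4)), dtype=np.int64)
    comps = comp_arr[subsets]
    srt = np.sort(comps, axis=1)
    ok = np.all(np.diff(srt, axis=1) > 0, axis=1) & np.all(comps >= 0, axis=1)
    rows = np.nonzero(ok)[0]
    comps = comps[rows]
    codes = Q.codes[rows].astype(np.int64)
    weights = Q.weights[rows]
    ranks = np.argsort(np.argsort(comps, axis=1), axis=1)

    is_cycle = codes >= 3
    p_in = np.where(is_cycle, (codes - 3) // 4, codes)
    r_in = np.where(is_cycle, (codes - 3) % 4, 0)
    k0 = np.argmax(ranks == 0, axis=1)
    partner_col = _PARTNER[p_in, k0]
    rep_p = np.take_along_axis(ranks, partner_col[:, None], axis=1)[:, 0] - 1
    rep_r = np.take_along_axis(ranks, r_in[:, None], axis=1)[:, 0]

    key = (
        srt[rows][:, 0] * s**3
        + srt[rows][:, 1] * s**2
        + srt[rows][:, 2] * s
        + srt[rows][:, 3]
    )
    ukeys, kinv = np.unique(key, return_inverse=True)
    nk = len(ukeys)
    skel = np.where(is_cycle, 3 + rep_p, rep_p)
    skel_w = np.zeros((nk, 6))
    np.add.at(skel_w, (kinv, skel), weights)
    ret_w = np.zeros((nk, 3, 4))
    ci = np.nonzero(is_cycle)[0]
    np.add.at(ret_w, (kinv[ci], rep_p[ci], rep_r[ci]), weights[ci])

    quarnets = []
    for kpos, packed in enumerate(ukeys):
        c3, rem = divmod(int(packed), s**3)
        c2, rem = divmod(rem, s**2)
        c1, c0 = divmod(rem, s)
        four = [labels[c] for c in (c3, c2, c1, c0)][::-1]
        four = sorted(four)
        w_row = skel_w[kpos]
        total = float(w_row.sum())
        win = _argmax_tiebreak(w_row, rng)
        new_w = min(1.0, float(w_row[win]) / total) if total > 0 else 1.0
        if win < 3:
            quarnets.append(TFQuarnet.from_code(win, four, new_w))
        else:
            p = win - 3
            r = _argmax_tiebreak(ret_w[kpos, p], rng)
            quarnets.append(TFQuarnet.from_code(3 + 4 * p + r, four, new_w))
    qset = DenseQuarnetSet(labels, quarnets)
    return RepresentativeQuarnetSet(
        vertex=v,
        labels=tuple(labels),
        component_of={t: labels[ci] for ci, ts in enumerate(comp_taxa) for t in ts},
        components={labels[ci]: comp_taxa[ci] for ci in range(s)},
        qset=qset,
    )


def _argmax_tiebreak(values: np.ndarray, rng: np.random.Generator) -> int:
    best = values.max()
    cands = np.nonzero(values == best)[0]
    if len(cands) == 1:
        return int(cands[0])
    return int(rng.choice(cands))


# -- distances -----------------------------------------------------------------


def tau(q: TFQuarnet, a: str, b: str) -> float:
    """Distance contribution of quarnet q to the leaf pair {a, b}.

    (3 - w)/2 for same-side quartet pairs and neighboring cycle leaves;
    (3 + w)/2 for cross pairs and opposite cycle leaves.
    """
    if a == b:
        raise ValueError("tau requires two distinct leaves")
    if a not in q.leaves or b not in q.leaves:
        raise ValueError("both leaves must belong to the quarnet")
    ia, ib = q.leaves.index(a), q.leaves.index(b)
    if q.shape == "quartet":
        p = q.code
        close = _PARTNER[p, ia] == ib
    else:
        p = (q.code - 3) // 4
        close = _PARTNER[p, ia] != ib  # cycle neighbors = not opposite
    return (3.0 - q.weight) / 2.0 if close else (3.0 + q.weight) / 2.0


def quarnet_distances(rep: RepresentativeQuarnetSet) -> np.ndarray:
    """Symmetric matrix over rep.labels: sums of tau over shared quarnets."""
    labels = rep.labels
    li = {y: i for i, y in enumerate(labels)}
    s = len(labels)
    D = np.zeros((s, s))
    for q in rep.qset:
        idx = [li[t] for t in q.leaves]
        if q.shape == "quartet":
            p = q.code
        else:
            p = (q.code - 3) // 4
        for a, b in itertools.combinations(range(4), 2):
            if q.shape == "quartet":
                close = _PARTNER[p, a] == b
            else:
                close = _PARTNER[p, a] != b
            t = (3.0 - q.weight) / 2.0 if close else (3.0 + q.weight) / 2.0
            D[idx[a], idx[b]] += t
            D[idx[b], idx[a]] += t
    return D


# -- TSP -----------------------------------------------------------------------


def _held_karp(D: np.ndarray) -> list[int]:
    """Exact minimum Hamiltonian cycle by dynamic programming over subsets."""
    s = len(D)
    if s <= 3:
        return list(range(s))
    m = s - 1  # cities 1..s-1; city 0 fixed as tour start
    full = 1 << m
    INF = math.inf
    dp = [[INF] * m for _ in range(full)]
    par = [[-1] * m for _ in range(full)]
    for j in range(m):
        dp[1 << j][j] = D[0][j + 1]
    for mask in range(1, full):
        row = dp[mask]
        for j in range(m):
            cj = row[j]
            if cj == INF or not (mask >> j) & 1:
                continue
            dj = D[j + 1]
            for k in range(m):
                if (mask >> k) & 1:
                    continue
                nmask = mask | (1 << k)
                cand = cj + dj[k + 1]
                if cand < dp[nmask][k]:
                    dp[nmask][k] = cand
                    par[nmask][k] = j
    best, bj = INF, -1
    last = full - 1
    for j in range(m):
        cand = dp[last][j] + D[j + 1][0]
        if cand < best:
            best, bj = cand, j
    tour = [0]
    mask, j = last, bj
    rev = []
    while j >= 0:
        rev.append(j + 1)
        mask, j = mask ^ (1 << j), par[mask][j]
    return tour + rev[::-1]


try:  # optional numba acceleration for larger exact instances
    import numba as _numba
except Exception:  # pragma: no cover - numba is optional
    _numba = None


if _numba is not None:

    @_numba.njit(cache=False)
    def _hk_core(D):  # pragma: no cover - exercised via solve_tsp
        s = D.shape[0]
        m = s - 1
        full = 1 << m
        INF = 1e18
        dp = np.full((full, m), INF)
        par = np.full((full, m), -1, dtype=np.int64)
        for j in range(m):
            dp[1 << j, j] = D[0, j + 1]
        for mask in range(1, full):
            for j in range(m):
                cj = dp[mask, j]
                if cj >= INF or not (mask >> j) & 1:
                    continue
                for k in range(m):
                    if (mask >> k) & 1:
                        continue
                    nmask = mask | (1 << k)
                    cand = cj + D[j + 1, k + 1]
                    if cand < dp[nmask, k]:
                        dp[nmask, k] = cand
                        par[nmask, k] = j
        best = INF
        bj = -1
        for j in range(m):
            cand = dp[full - 1, j] + D[j + 1, 0]
            if cand < best:
                best = cand
                bj = j
        tour = np.empty(s, dtype=np.int64)
        tour[0] = 0
        mask = full - 1
        j = bj
        pos = s - 1
        while j >= 0:
            tour[pos] = j + 1
            pos -= 1
            nj = par[mask, j]
            mask ^= 1 << j
            j = nj
        return tour


def _tour_length(D: np.ndarray, tour: list[int]) -> float:
    return float(
        sum(D[tour[i], tour[(i + 1) % len(tour)]] for i in range(len(tour)))
    )


def _anneal(D: np.ndarray, rng: np.random.Generator) -> list[int]:
    """Seeded 2-opt simulated annealing, geometric cooling, best of 3 restarts."""
    s = len(D)
    iters = 20 * s * s
    best_tour, best_len = None, math.inf
    for _ in range(3):
        tour = list(rng.permutation(s))
        cur = _tour_length(D, tour)
        temp = float(np.mean(D)) * s / 4.0 + 1e-9
        for _ in range(iters):
            i, j = sorted(rng.integers(0, s, size=2))
            if i == j or (i == 0 and j == s - 1):
                temp *= 0.995
                continue
            a, b = tour[i - 1], tour[i]
            c, d = tour[j], tour[(j + 1) % s]
            delta = (D[a, c] + D[b, d]) - (D[a, b] + D[c, d])
            if delta < 0 or rng.random() < math.exp(-delta / temp):
                tour[i : j + 1] = tour[i : j + 1][::-1]
                cur += delta
            temp *= 0.995
        cur = _tour_length(D, tour)
        if cur < best_len:
            best_tour, best_len = tour, cur
    return best_tour


def solve_tsp(
    D: np.ndarray,
    mode: str = "auto",
    rng: np.random.Generator | None = None,
    hk_threshold: int = HELD_KARP_MAX,
) -> list[int]:
    """Cyclic order of the indices of D: exact Held-Karp or 2-opt annealing.

    mode: "auto" (exact up to ``hk_threshold`` leaves), "exact", "anneal".
    """
    s = len(D)
    if s < 4:
        return list(range(s))
    if mode not in ("auto", "exact", "anneal"):
        raise ValueError(f"unknown TSP mode {mode!r}")
    exact = mode == "exact" or (mode == "auto" and s <= hk_threshold)
    if exact:
        if _numba is not None and s > 10:
            return [int(x) for x in _hk_core(np.asarray(D, dtype=float))]
        return _held_karp(np.asarray(D, dtype=float))
    if rng is None:
        rng = np.random.default_rng(0)
    return _anneal(np.asarray(D, dtype=float), rng)


# -- reticulation ranking ------------------------------------------------------


def reticulation_ranking(
    rep: RepresentativeQuarnetSet,
    rng: np.random.Generator,
    count_mode: str = "reticulation",
) -> list[str]:
    """Total order on rep.labels: most plausible reticulation component first.

    With five or more components, leaves are ordered by descending weighted
    count of representative 4-cycles in which they sit below the reticulation
    (``count_mode="membership"`` counts any 4-cycle membership instead).  With
    exactly four, the single quarnet dictates the front of the ranking; the
    rest is seeded-random.
    """
    labels = list(rep.labels)
    if len(labels) == 4:
        (q,) = list(rep.qset)
        if q.shape == "cycle4":
            others = [y for y in labels if y != q.reticulation_leaf]
            tail = [others[i] for i in rng.permutation(3)]
            return [q.reticulation_leaf] + tail
        return [labels[i] for i in rng.permutation(4)]
    counts = {y: 0.0 for y in labels}
    for q in rep.qset:
        if q.shape != "cycle4":
            continue
        if count_mode == "reticulation":
            counts[q.reticulation_leaf] += q.weight
        else:
            for y in q.leaves:
                counts[y] += q.weight
    jitter = {y: i for i, y in zip(rng.permutation(len(labels)), labels)}
    return sorted(labels, key=lambda y: (-counts[y], jitter[y]))


# -- expansion -----------------------------------------------------------------


def expand_tree(
    tree: CandidateBlobtree,
    Q: DenseQuarnetSet,
    outgroup: str | None = None,
    tsp_mode: str = "auto",
    rng: np.random.Generator | int | None = 0,
    hk_threshold: int = HELD_KARP_MAX,
    count_mode: str = "reticulation",
) -> SemiDirectedNetwork:
    """Replace every degree->=4 vertex of ``tree`` by a cycle with a reticulation.

    Vertices are processed in decreasing degree order; after placing each
    reticulation the partial network must remain rootable (at the outgroup if
    one is given), else the next leaf in the reticulation ranking is tried.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    g = nx.Graph()
    for v, d in tree.graph.nodes(data=True):
        g.add_node(v, **({"taxon": d["taxon"]} if d.get("taxon") else {}))
    for u, v in tree.graph.edges:
        g.add_edge(u, v, head=None)
    todo = [v for v in g.nodes if g.degree(v) >= 4]
    todo.sort(
        key=lambda v: (
            -g.degree(v),
            tuple(sorted(min(_subtree_taxa(g, u, v)) for u in g.neighbors(v))),
        )
    )
    fresh = itertools.count()
    for v in todo:
        rep = representative_quarnets(v, CandidateBlobtree(g), Q, rng)
        D = quarnet_distances(rep)
        tour = solve_tsp(D, mode=tsp_mode, rng=rng, hk_threshold=hk_threshold)
        theta = [rep.labels[i] for i in tour]
        ranking = reticulation_ranking(rep, rng, count_mode=count_mode)
        # neighbor vertex corresponding to each component label
        nbr_of = {}
        for u in g.neighbors(v):
            taxa_u = _subtree_taxa(g, u, v)
            nbr_of[rep.component_of[min(taxa_u)]] = u
        cyc_vertex = {}
        for y in theta:
            c = ("cyc", next(fresh))
            cyc_vertex[y] = c
            g.add_node(c)
        g.remove_node(v)
        s = len(theta)
        for i, y in enumerate(theta):
            g.add_edge(cyc_vertex[y], cyc_vertex[theta[(i + 1) % s]], head=None)
            g.add_edge(cyc_vertex[y], nbr_of[y], head=None)
        placed = False
        for y in ranking:
            c = cyc_vertex[y]
            ring = [w for w in g.neighbors(c) if w in set(cyc_vertex.values())]
            for w in ring:
                g.edges[c, w]["head"] = c
            if _is_rootable(g, outgroup):
                placed = True
                break
            for w in ring:
                g.edges[c, w]["head"] = None
        if not placed:
            raise AssertionError(
                "no reticulation placement keeps the network rootable"
            )
    net = SemiDirectedNetwork(g)
    return net


def _is_rootable(g: nx.Graph, outgroup: str | None) -> bool:
    from .networks import is_rootable

    return is_rootable(g, outgroup)
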