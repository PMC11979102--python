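"""Candidate blobtree sequence construction from a dense tf-quarnet set.

Three stages: (A1) the most-refined tree every one of whose induced quartets is
explicitly confirmed by the input quartet trees; (A2) full resolution of the
remaining multifurcations by an adapted QuartetJoining agglomeration; (A3) the
contraction sequence ordered by edge split-support.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .quarnets import DenseQuarnetSet, Split, TFQuarnet, make_split, split_sides

__all__ = [
    "CandidateBlobtree",
    "SplitWeightFunction",
    "build_qstar_tree",
    "omega_from_quarnets",
    "refine_quartetjoining",
    "split_support",
    "candidate_blobtrees",
    "tree_from_splits",
]


class CandidateBlobtree:
    """An unrooted leaf-labeled tree; internal vertices may have degree >= 3."""

    def __init__(self, graph: nx.Graph, split_support: dict | None = None):
        self.graph = graph
        self.split_support = split_support or {}
        self._taxon_node = {
            d["taxon"]: v
            for v, d in graph.nodes(data=True)
            if d.get("taxon") is not None
        }

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(sorted(self._taxon_node))

    def validate(self) -> None:
        g = self.graph
        if not nx.is_tree(g):
            raise ValueError("candidate blobtree must be a tree")
        for v in g.nodes:
            deg = g.degree(v)
            if deg == 1 and g.nodes[v].get("taxon") is None:
                raise ValueError(f"unlabeled leaf {v!r}")
            if deg == 2:
                raise ValueError(f"degree-2 vertex {v!r}")

    def copy(self) -> "CandidateBlobtree":
        return CandidateBlobtree(self.graph.copy(), dict(self.split_support))

    def is_binary(self) -> bool:
        return all(
            self.graph.degree(v) in (1, 3) for v in self.graph.nodes
        )

    def internal_edges(self) -> list[tuple]:
        return [
            (u, v)
            for u, v in self.graph.edges
            if self.graph.degree(u) > 1 and self.graph.degree(v) > 1
        ]

    def split_of_edge(self, edge: tuple) -> Split:
        u, v = edge
        g = self.graph.copy()
        g.remove_edge(u, v)
        comp = nx.node_connected_component(g, u)
        side_a = {t for t, node in self._taxon_node.items() if node in comp}
        return make_split(side_a, set(self.taxa) - side_a)

    def splits(self, nontrivial_only: bool = True) -> set:
        out = set()
        for e in self.graph.edges:
            s = self.split_of_edge(e)
            if nontrivial_only and min(len(x) for x in s) < 2:
                continue
            out.add(s)
        return out

    def contract_edge(self, edge: tuple) -> "CandidateBlobtree":
        u, v = edge
        g = self.graph.copy()
        for w in list(g.neighbors(v)):
            if w != u:
                g.add_edge(u, w)
        g.remove_node(v)
        return CandidateBlobtree(g)

    def newick(self) -> str:
        g = self.graph
        start = self._taxon_node[self.taxa[0]]
        anchor = next(iter(g.neighbors(start)))

        def render(v, parent) -> str:
            taxon = g.nodes[v].get("taxon")
            kids = [w for w in g.neighbors(v) if w != parent]
            if not kids:
                return taxon or ""
            return "(" + ",".join(render(w, v) for w in sorted(kids, key=str)) + ")"

        inner = ",".join(
            [g.nodes[start].get("taxon", "")]
            + [render(w, anchor) for w in sorted(g.neighbors(anchor), key=str)
               if w != start]
        )
        return f"({inner});"


class SplitWeightFunction(dict):
    """Nonnegative weights on nontrivial 4-leaf splits; 0 for unseen splits."""

    def __missing__(self, key):
        return 0.0


# -- Step A1: the Q*-tree ------------------------------------------------------


_CONFLICT = object()  # marks 4-subsets carrying two different quartet trees


def _quartet_map(quartets: Iterable[TFQuarnet]) -> dict:
    """frozenset(4 leaves) -> split side containing the minimum leaf."""
    qmap: dict = {}
    for q in quartets:
        if q.shape != "quartet":
            continue
        key = frozenset(q.leaves)
        a, b = split_sides(q.split)
        side = a if min(q.leaves) in a else b
        if key in qmap and qmap[key] != side:
            qmap[key] = _CONFLICT  # contradictory evidence voids the subset
        else:
            qmap[key] = side
    return qmap


def _has_quartet(qmap: dict, a: str, a2: str, b: str, b2: str) -> bool:
    """Is aa2|bb2 the unique quartet tree recorded on this 4-subset?"""
    four = (a, a2, b, b2)
    side = qmap.get(frozenset(four))
    if side is None or side is _CONFLICT:
        return False
    lo = min(four)
    want = frozenset((a, a2)) if lo in (a, a2) else frozenset((b, b2))
    return side == want


def _cluster_supported(qmap: dict, cluster: frozenset, rest: Sequence[str],
                       new_leaf: str | None = None) -> bool:
    """Is the split cluster|rest fully supported by quartets in qmap?

    When ``new_leaf`` is given, only cross 4-subsets containing it are checked
    (the remainder was verified on the smaller taxon set).
    """
    cl = sorted(cluster)
    rs = sorted(rest)
    if new_leaf is None:
        pairs_a = list(itertools.combinations(cl, 2))
        pairs_b = list(itertools.combinations(rs, 2))
        for a, a2 in pairs_a:
            for b, b2 in pairs_b:
                if not _has_quartet(qmap, a, a2, b, b2):
                    return False
        return True
    if new_leaf in cluster:
        others = [x for x in cl if x != new_leaf]
        for a in others:
            for b, b2 in itertools.combinations(rs, 2):
                if not _has_quartet(qmap, new_leaf, a, b, b2):
                    return False
    else:
        others = [x for x in rs if x != new_leaf]
        for b in others:
            for a, a2 in itertools.combinations(cl, 2):
                if not _has_quartet(qmap, a, a2, new_leaf, b):
                    return False
    return True


def build_qstar_tree(
    quartets: Iterable[TFQuarnet], taxa: Iterable[str]
) -> CandidateBlobtree:
    """Most refined tree all of whose induced nontrivial quartets are in the input.

    A split A|B is retained iff for every a,a' in A and b,b' in B the quartet
    tree aa'|bb' is explicitly present.  Such splits are pairwise compatible
    when the input holds at most one quartet per 4-subset, so the tree is
    unique; conflicts push the result toward the star tree.

    Built incrementally: leaves are inserted one at a time, and every supported
    split of the enlarged set restricts to a supported split (or a trivial one)
    of the smaller set, so only extensions of current splits and the new
    cherry splits need checking.
    """
    taxa = sorted(set(taxa))
    if len(taxa) < 4:
        raise ValueError("need at least 4 taxa")
    qmap = _quartet_map(quartets)
    current = list(taxa[:4])
    splits: list[frozenset] = []  # store one side (cluster) per split
    a, b, c, d = current
    for cl in (frozenset((a, b)), frozenset((a, c)), frozenset((a, d))):
        rest = [x for x in current if x not in cl]
        if _cluster_supported(qmap, cl, rest):
            splits.append(cl)
    for z in taxa[4:]:
        prev = list(current)
        current.append(z)
        new_splits: list[frozenset] = []
        for cl in splits:
            rest = [x for x in current if x not in cl]
            grown = cl | {z}
            # z on the cluster side
            if _cluster_supported(qmap, grown, [x for x in rest if x != z],
                                  new_leaf=z):
                new_splits.append(grown)
            # z on the other side
            if _cluster_supported(qmap, cl, rest, new_leaf=z):
                new_splits.append(cl)
        for b1 in prev:  # new cherry {b1, z}
            cl = frozenset((b1, z))
            rest = [x for x in current if x not in cl]
            if len(rest) >= 2 and _cluster_supported(qmap, cl, rest, new_leaf=z):
                new_splits.append(cl)
        splits = _dedupe_clusters(new_splits, current)
    full_splits = {
        make_split(cl, set(current) - cl) for cl in splits
    }
    return tree_from_splits(taxa, full_splits)


def _dedupe_clusters(clusters: list[frozenset], taxa: list[str]) -> list[frozenset]:
    seen = set()
    out = []
    allset = frozenset(taxa)
    for cl in clusters:
        key = min(cl, allset - cl, key=lambda s: (len(s), sorted(s)))
        if key not in seen:
            seen.add(key)
            out.append(cl)
    return out


def tree_from_splits(taxa: Iterable[str], splits: Iterable[Split]) -> CandidateBlobtree:
    """Build the (unique) unrooted tree displaying a compatible split set."""
    taxa = sorted(set(taxa))
    anchor = taxa[0]
    clusters = {frozenset(taxa) - {anchor}}
    clusters |= {frozenset((t,)) for t in taxa[1:]}
    for s in splits:
        a, b = split_sides(s)
        cl = b if anchor in a else a
        if min(len(a), len(b)) < 2:
            continue
        clusters.add(frozenset(cl))
    ordered = sorted(clusters, key=len, reverse=True)
    for c1, c2 in itertools.combinations(ordered, 2):
        if c1 & c2 and not (c1 <= c2 or c2 <= c1):
            raise ValueError("splits are not compatible")
    g = nx.Graph()
    node_of: dict = {}
    for cl in ordered:
        if len(cl) == 1:
            (t,) = cl
            node_of[cl] = ("leaf", t)
            g.add_node(node_of[cl], taxon=t)
        else:
            node_of[cl] = ("clade", tuple(sorted(cl)))
            g.add_node(node_of[cl])
    for i, cl in enumerate(ordered):
        if i == 0:
            continue
        parent = min(
            (p for p in ordered[:i] if cl < p), key=len, default=None
        )
        if parent is None:
            parent = ordered[0]
        g.add_edge(node_of[cl], node_of[parent])
    root_node = node_of[ordered[0]]
    leaf0 = ("leaf", anchor)
    g.add_node(leaf0, taxon=anchor)
    g.add_edge(leaf0, root_node)
    # contract any degree-2 vertices introduced by redundant clusters
    for v in list(g.nodes):
        if g.degree(v) == 2 and g.nodes[v].get("taxon") is None:
            u, w = g.neighbors(v)
            g.remove_node(v)
            g.add_edge(u, w)
    tree = CandidateBlobtree(g)
    tree.validate()
    return tree


# -- Step A2: omega and the adapted QuartetJoining -----------------------------


def omega_from_quarnets(Q: DenseQuarnetSet) -> SplitWeightFunction:
    """omega(split of quartet q) = w(q); every other 4-leaf split has weight 0."""
    omega = SplitWeightFunction()
    taxa = Q.taxa
    for four, i in Q._index.items():
        code = int(Q.codes[i])
        if code >= 3:
            continue
        leaves = sorted(four)
        partner = leaves[code + 1]
        rest = [x for x in leaves[1:] if x != partner]
        omega[make_split({leaves[0], partner}, rest)] = float(Q.weights[i])
    return omega


def _omega_entries(omega: SplitWeightFunction) -> list[tuple]:
    entries = []
    for split, w in omega.items():
        if w == 0.0:
            continue
        a, b = split_sides(split)
        (x, x2), (y, y2) = sorted(a), sorted(b)
        entries.append((x, x2, y, y2, w))
    return entries


def refine_quartetjoining(
    tstar: CandidateBlobtree,
    omega: SplitWeightFunction,
    rng: np.random.Generator | int | None = None,
) -> CandidateBlobtree:
    """Resolve the multifurcations of ``tstar`` as far as the data supports.

    At each vertex of degree >= 4 with neighbor components X1..Xs, every pair
    {Xi, Xj} is scored by the mean omega over splits x x'|y y' with x in Xi,
    x' in Xj and y, y' in two distinct other components; the best pair is
    joined under a fresh vertex.  Ties break on lexicographic component labels.

    Joins require strictly positive support: a vertex whose remaining pairs
    all score zero stays multifurcating.  In particular the components around
    a cycle of the generating network stop resolving at four (every 4-subset
    hitting four distinct components there induces a 4-cycle, which carries no
    omega weight), which keeps the blobtree reachable within the contraction
    sequence even when it is the star tree.
    """
    entries = _omega_entries(omega)
    g = tstar.graph.copy()
    fresh = itertools.count()
    multis = sorted(
        (v for v in g.nodes if g.degree(v) >= 4), key=str
    )
    for v in multis:
        while g.degree(v) > 3:
            nbrs = sorted(g.neighbors(v), key=str)
            comp_leaves = []
            for u in nbrs:
                comp = _subtree_taxa(g, u, v)
                comp_leaves.append(comp)
            comp_of = {}
            for i, leaves in enumerate(comp_leaves):
                for t in leaves:
                    comp_of[t] = i
            s = len(nbrs)
            sizes = np.array([len(c) for c in comp_leaves], dtype=float)
            numer = np.zeros((s, s))
            for x, x2, y, y2, w in entries:
                ci = comp_of.get(x)
                if ci is None:
                    continue
                cj, ck, cl = comp_of[x2], comp_of[y], comp_of[y2]
                if len({ci, cj, ck, cl}) != 4:
                    continue
                numer[ci, cj] += w
                numer[cj, ci] += w
                numer[ck, cl] += w
                numer[cl, ck] += w
            total = sizes.sum()
            sq = (sizes**2).sum()
            best = None
            for i in range(s):
                for j in range(i + 1, s):
                    u = total - sizes[i] - sizes[j]
                    usq = sq - sizes[i] ** 2 - sizes[j] ** 2
                    pairs_others = (u * u - usq) / 2.0
                    denom = sizes[i] * sizes[j] * pairs_others
                    score = numer[i, j] / denom if denom > 0 else 0.0
                    label = (
                        tuple(sorted(comp_leaves[i])),
                        tuple(sorted(comp_leaves[j])),
                    )
                    cand = (-score, min(label), max(label), i, j)
                    if best is None or cand < best[0]:
                        best = (cand, i, j)
            if best[0][0] >= 0.0:  # no pair has positive support
                break
            _, i, j = best
            w_new = ("qj", next(fresh))
            g.add_node(w_new)
            g.remove_edge(v, nbrs[i])
            g.remove_edge(v, nbrs[j])
            g.add_edge(w_new, nbrs[i])
            g.add_edge(w_new, nbrs[j])
            g.add_edge(v, w_new)
    out = CandidateBlobtree(g)
    out.validate()
    return out


def _subtree_taxa(g: nx.Graph, start, blocked) -> frozenset:
    seen = {blocked, start}
    stack = [start]
    taxa = set()
    while stack:
        x = stack.pop()
        t = g.nodes[x].get("taxon")
        if t is not None:
            taxa.add(t)
        for wv in g.neighbors(x):
            if wv not in seen:
                seen.add(wv)
                stack.append(wv)
    return frozenset(taxa)


# -- Step A3: split support and the contraction sequence -----------------------


def split_support(Q: DenseQuarnetSet, split: Split) -> float:
    """Weighted fraction of straddling quarnets whose quartet split agrees."""
    a, b = split_sides(split)
    if min(len(a), len(b)) < 2:
        raise ValueError("split support is defined for nontrivial splits")
    taxa = Q.taxa
    member = np.array([t in a for t in taxa], dtype=bool)
    subsets = np.array(
        list(itertools.combinations(range(len(taxa)), 4)), dtype=np.int32
    )
    m = member[subsets]  # (n4, 4)
    relevant = m.sum(axis=1) == 2
    if not relevant.any():
        raise AssertionError("no straddling 4-subsets for a nontrivial split")
    codes = Q.codes[relevant]
    weights = Q.weights[relevant]
    mr = m[relevant]
    quartet = codes < 3
    partner_col = np.clip(codes, 0, 2).astype(np.int64) + 1
    partner_same = (
        np.take_along_axis(mr, partner_col[:, None], axis=1)[:, 0] == mr[:, 0]
    )
    supporting = quartet & partner_same
    denom = float(weights.sum())
    assert denom > 0, "zero total weight on straddling quarnets"
    return float(weights[supporting].sum()) / denom


def candidate_blobtrees(
    Q: DenseQuarnetSet, seed: int | np.random.Generator | None = 0
) -> list[CandidateBlobtree]:
    """The length-(n-3) candidate sequence, from T1 toward the star tree.

    Ti is T1 with its i-1 least split-supported internal edges contracted;
    supports are computed once, on T1.  When T1 is binary it has n-3 internal
    edges and the last candidate keeps one of them; when QuartetJoining
    stalled (zero-support multifurcations), the chain runs down to the fully
    contracted tree and the last candidate is repeated to keep the count at
    n-3.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    tstar = build_qstar_tree(
        (q for q in Q if q.shape == "quartet"), Q.taxa
    )
    omega = omega_from_quarnets(Q)
    t1 = refine_quartetjoining(tstar, omega, rng)
    edges = t1.internal_edges()
    n = len(Q.taxa)
    assert len(edges) <= n - 3
    scored = []
    support_map = {}
    for e in edges:
        s = t1.split_of_edge(e)
        supp = split_support(Q, s)
        support_map[frozenset(e)] = supp
        small_side = min(split_sides(s), key=lambda x: (len(x), sorted(x)))
        scored.append((supp, tuple(sorted(small_side)), e))
    scored.sort(key=lambda item: (item[0], item[1]))
    t1.split_support = support_map
    out = [t1]
    contracted: list[tuple] = []
    for supp, _, e in scored[: n - 4]:
        contracted.append(e)
        out.append(_contract_edges(t1, contracted))
    while len(out) < n - 3:
        out.append(out[-1])
    return out


def _contract_edges(tree: CandidateBlobtree, edges: list[tuple]) -> CandidateBlobtree:
    """T1 with the given internal edges contracted (union-find quotient)."""
    parent = {v: v for v in tree.graph.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[rv] = ru
    g = nx.Graph()
    for v, d in tree.graph.nodes(data=True):
        r = find(v)
        g.add_node(r)
        if d.get("taxon") is not None:
            g.nodes[r]["taxon"] = d["taxon"]
    for u, v in tree.graph.edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            g.add_edge(ru, rv)
    return CandidateBlobtree(g)
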