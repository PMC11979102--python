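"""Simulation machinery: random networks, quarnet perturbation, K2P alignments.

Random triangle-free level-1 networks are grown as rooted binary trees plus
rejection-sampled reticulation attachments; quarnet noise rewrites the
undirected skeleton of a chosen fraction of a dense set; sequence simulation
runs a Kimura 2-parameter model independently along every displayed tree of the
(randomly rooted) network and concatenates the alignments.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .delta import Alignment
from .networks import RootedNetwork, SemiDirectedNetwork
from .quarnets import DenseQuarnetSet

__all__ = [
    "PerturbationSpec",
    "random_network",
    "perturb_quarnets",
    "displayed_trees",
    "branch_lengths",
    "simulate_alignment",
    "run_noise_experiment",
]


@dataclass(frozen=True)
class PerturbationSpec:
    epsilon: float
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("perturbation ratio must lie in [0, 1]")


# -- random networks -----------------------------------------------------------


def _random_rooted_tree(taxa: list[str], rng: np.random.Generator) -> nx.DiGraph:
    g = nx.DiGraph()
    root = ("v", 0)
    counter = itertools.count(1)
    l0, l1 = ("leaf", taxa[0]), ("leaf", taxa[1])
    g.add_node(root)
    g.add_node(l0, taxon=taxa[0])
    g.add_node(l1, taxon=taxa[1])
    g.add_edge(root, l0)
    g.add_edge(root, l1)
    for t in taxa[2:]:
        edges = list(g.edges)
        u, v = edges[rng.integers(len(edges))]
        mid = ("v", next(counter))
        leaf = ("leaf", t)
        g.remove_edge(u, v)
        g.add_edge(u, mid)
        g.add_edge(mid, v)
        g.add_node(leaf, taxon=t)
        g.add_edge(mid, leaf)
    return g


def _add_reticulation(
    g: nx.DiGraph, blocked: set, rng: np.random.Generator, counter
) -> bool:
    """Join two random edges by a new reticulation edge, in place.

    ``blocked`` holds vertices already on cycles; the new cycle must avoid
    them (level-1), have length >= 4 (triangle-free) and keep the digraph
    acyclic.  Returns False (graph untouched) if the sampled pair fails.
    """
    candidates = [
        (x, y) for x, y in g.edges if x not in blocked and y not in blocked
    ]
    if len(candidates) < 2:
        return False
    i, j = rng.choice(len(candidates), size=2, replace=False)
    (a, b), (c, d) = candidates[i], candidates[j]
    u, w = ("v", next(counter)), ("v", next(counter))
    g.remove_edge(a, b)
    g.remove_edge(c, d)
    g.add_edge(a, u)
    g.add_edge(u, b)
    g.add_edge(c, w)
    g.add_edge(w, d)

    def undo() -> bool:
        g.remove_node(u)
        g.remove_node(w)
        g.add_edge(a, b)
        g.add_edge(c, d)
        return False

    # BFS from u to w in the underlying graph, avoiding existing cycles
    und = g.to_undirected(as_view=True)
    parentmap = {u: None}
    frontier = [u]
    while frontier and w not in parentmap:
        nxt = []
        for x in frontier:
            for y in und.neighbors(x):
                if y in parentmap or y in blocked:
                    continue
                parentmap[y] = x
                nxt.append(y)
        frontier = nxt
    if w not in parentmap:
        return undo()
    path = [w]
    while parentmap[path[-1]] is not None:
        path.append(parentmap[path[-1]])
    if len(path) < 4:  # cycle length = path edges + 1 must be >= 4
        return undo()
    g.add_edge(u, w)  # w becomes the reticulation
    if not nx.is_directed_acyclic_graph(g):
        g.remove_edge(u, w)
        return undo()
    blocked.update(path)
    return True


def random_network(
    n: int, seed: int | np.random.Generator | None = 0
) -> SemiDirectedNetwork:
    """Random binary triangle-free semi-directed level-1 network on n leaves.

    The reticulation number is drawn uniformly from {0, ..., floor(n/3)}; the
    network is grown from a random rooted binary tree by repeatedly joining
    two random edges with a new reticulation edge, rejecting additions that
    break the level-1/triangle-free/validity invariants.
    """
    if n < 4:
        raise ValueError("need at least 4 leaves")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    width = len(str(n))
    taxa = [f"t{i:0{width}d}" for i in range(1, n + 1)]
    r = int(rng.integers(0, n // 3 + 1))
    for _ in range(500):  # rebuild attempts
        g = _random_rooted_tree(taxa, rng)
        counter = itertools.count(10 * len(g))
        blocked: set = set()
        added = 0
        tries = 0
        while added < r and tries < 300:
            tries += 1
            if _add_reticulation(g, blocked, rng, counter):
                added += 1
        if added != r:
            continue
        try:
            rooted = RootedNetwork(g)
            rooted.validate()
            out = rooted.semidirect()
            out.validate(triangle_free=True)
        except ValueError:
            continue
        return out
    raise RuntimeError(f"could not generate a network with n={n}, r={r}")


# -- quarnet perturbation ------------------------------------------------------


def perturb_quarnets(
    Q: DenseQuarnetSet, spec: PerturbationSpec
) -> DenseQuarnetSet:
    """Rewrite the undirected skeleton of round(eps * C(n,4)) quarnets.

    Each chosen quarnet receives a skeleton drawn uniformly from the five
    other skeletons (three quartet splits, three undirected 4-cycle
    pairings); a quarnet that becomes a 4-cycle gets a uniform-random
    reticulation leaf.  Weights are untouched.
    """
    rng = np.random.default_rng(spec.seed)
    m = len(Q)
    k = int(round(spec.epsilon * m))
    chosen = rng.choice(m, size=k, replace=False)
    codes = Q.codes.copy()
    for i in chosen:
        old_skel = codes[i] if codes[i] < 3 else 3 + (codes[i] - 3) // 4
        options = [sk for sk in range(6) if sk != old_skel]
        new_skel = options[rng.integers(5)]
        if new_skel < 3:
            codes[i] = new_skel
        else:
            ret = rng.integers(4)
            codes[i] = 3 + 4 * (new_skel - 3) + ret
    return DenseQuarnetSet(Q.taxa, codes=codes, weights=Q.weights.copy())


# -- displayed trees and branch lengths ---------------------------------------


def displayed_trees(rooted: RootedNetwork) -> list[nx.DiGraph]:
    """The 2^r rooted trees obtained by deleting one incoming edge per
    reticulation and suppressing elementary vertices; duplicates retained.

    Edge ``length`` attributes, if present, are summed along suppressed paths.
    """
    g = rooted.digraph
    retics = sorted(rooted.reticulations(), key=str)
    choices_per_retic = [sorted(g.predecessors(v), key=str) for v in retics]
    out = []
    for combo in itertools.product(*choices_per_retic) if retics else [()]:
        t = g.copy()
        for v, keep in zip(retics, combo):
            for p in list(t.predecessors(v)):
                if p != keep:
                    t.remove_edge(p, v)
        _suppress_elementary(t)
        out.append(t)
    return out


def _suppress_elementary(t: nx.DiGraph) -> None:
    changed = True
    while changed:
        changed = False
        for v in list(t.nodes):
            din, dout = t.in_degree(v), t.out_degree(v)
            taxon = t.nodes[v].get("taxon")
            if din == 1 and dout == 1:
                (p,) = t.predecessors(v)
                (c,) = t.successors(v)
                length = t.edges[p, v].get("length", 0) + t.edges[v, c].get(
                    "length", 0
                )
                t.remove_node(v)
                t.add_edge(p, c, length=length)
                changed = True
            elif din == 0 and dout == 1 and taxon is None:
                (c,) = t.successors(v)
                t.remove_node(v)
                changed = True
            elif dout == 0 and taxon is None:
                t.remove_node(v)
                changed = True


def branch_lengths(rooted: RootedNetwork, target: float = 0.3) -> None:
    """Assign each edge (u, v) the length target / p(u, v), in place.

    p(u, v) is the mean edge-count of all root-to-leaf paths through (u, v),
    which makes every root-to-leaf path roughly ``target`` long.
    """
    g = rooted.digraph
    leaves = [v for v in g.nodes if g.out_degree(v) == 0]
    path_sum = {e: 0 for e in g.edges}
    path_cnt = {e: 0 for e in g.edges}
    for leaf in leaves:
        for path in nx.all_simple_paths(g, rooted.root, leaf):
            k = len(path) - 1
            for a, b in zip(path, path[1:]):
                path_sum[(a, b)] += k
                path_cnt[(a, b)] += 1
    for e in g.edges:
        assert path_cnt[e] > 0, "edge on no root-to-leaf path"
        p = path_sum[e] / path_cnt[e]
        g.edges[e]["length"] = target / p


# -- K2P sequence simulation ---------------------------------------------------

# rate convention: transition rate alpha, each transversion rate beta,
# alpha + 2*beta = 1 (branch length = expected substitutions per site),
# transition/transversion bias R = alpha / (2*beta)


def _k2p_matrix(d: float, bias: float = 4.0) -> np.ndarray:
    beta = 1.0 / (2.0 * bias + 2.0)
    alpha = 2.0 * bias * beta
    e1 = math.exp(-4.0 * beta * d)
    e2 = math.exp(-2.0 * (alpha + beta) * d)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # each of the two transversion targets
    p_same = 1.0 - p_ts - 2.0 * p_tv
    # base order A, G, C, T: transitions are A<->G and C<->T
    M = np.array(
        [
            [p_same, p_ts, p_tv, p_tv],
            [p_ts, p_same, p_tv, p_tv],
            [p_tv, p_tv, p_same, p_ts],
            [p_tv, p_tv, p_ts, p_same],
        ]
    )
    return M


_BASES = np.array(list("AGCT"))


def _simulate_tree(
    tree: nx.DiGraph, sites: int, rng: np.random.Generator, bias: float = 4.0
) -> dict[str, np.ndarray]:
    roots = [v for v in tree.nodes if tree.in_degree(v) == 0]
    (root,) = roots
    seqs = {root: rng.integers(0, 4, size=sites)}
    out: dict[str, np.ndarray] = {}
    for u, v in nx.bfs_edges(tree, root):
        d = tree.edges[u, v].get("length", 0.0)
        M = _k2p_matrix(d, bias)
        cum = np.cumsum(M, axis=1)
        draws = rng.random(sites)
        parent = seqs[u]
        child = (draws[:, None] > cum[parent]).sum(axis=1)
        seqs[v] = child
        taxon = tree.nodes[v].get("taxon")
        if taxon is not None:
            out[taxon] = child
    if tree.nodes[root].get("taxon") is not None:  # degenerate single-leaf
        out[tree.nodes[root]["taxon"]] = seqs[root]
    return out


def simulate_alignment(
    net: SemiDirectedNetwork,
    k: int,
    seed: int | np.random.Generator | None = 0,
    bias: float = 4.0,
    target_depth: float = 0.3,
) -> Alignment:
    """Simulate a k-site alignment along all displayed trees of ``net``.

    The network is rooted uniformly at random among its valid root edges,
    branch lengths follow the mean-path-depth rule, each displayed tree
    contributes an equal share of sites (balanced rounding), and the
    per-tree alignments are concatenated.
    """
    if k < 1:
        raise ValueError("need at least one site")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    edges = sorted(
        net.valid_root_edges(), key=lambda e: sorted(map(str, e))
    )
    assert edges, "network has no valid root location"
    edge = edges[rng.integers(len(edges))]
    from .networks import _orient

    dg = _orient(net.graph, tuple(sorted(edge, key=str)))
    rooted = RootedNetwork(dg)
    branch_lengths(rooted, target=target_depth)
    trees = displayed_trees(rooted)
    T = len(trees)
    base, extra = divmod(k, T)
    taxa = net.taxa
    chunks: dict[str, list[np.ndarray]] = {t: [] for t in taxa}
    for i, tree in enumerate(trees):
        sites = base + (1 if i < extra else 0)
        if sites == 0:
            continue
        seqs = _simulate_tree(tree, sites, rng, bias)
        for t in taxa:
            chunks[t].append(seqs[t])
    seq_strings = [
        "".join(_BASES[np.concatenate(chunks[t])]) for t in taxa
    ]
    return Alignment(list(taxa), seq_strings)


# -- the perturbation experiment ----------------------------------------------


def run_noise_experiment(
    ns: list[int],
    eps_list: list[float],
    reps: int,
    seed: int = 0,
    tsp_mode: str = "auto",
):
    """Reconstruct from perturbed induced quarnet sets; returns a DataFrame
    with one row per (n, eps, rep): C, S and the reticulation difference."""
    import pandas as pd

    from .driver import squirrel
    from .quarnets import consistency_C, consistency_S

    root_rng = np.random.default_rng(seed)
    rows = []
    for n in ns:
        for rep in range(reps):
            net_seed, pert_seed, alg_seed = root_rng.integers(2**31, size=3)
            N = random_network(n, int(net_seed))
            Q = N.induced_quarnet_set()
            QN = Q  # unit weights already
            for eps in eps_list:
                Qe = perturb_quarnets(
                    QN, PerturbationSpec(eps, int(pert_seed))
                )
                result = squirrel(Qe, tsp_mode=tsp_mode, seed=int(alg_seed))
                M = result.best
                QM = M.induced_quarnet_set()
                rows.append(
                    {
                        "n": n,
                        "eps": eps,
                        "rep": rep,
                        "C": consistency_C(QN, QM),
                        "S": consistency_S(QN, QM),
                        "r_true": N.reticulation_number(),
                        "r_est": M.reticulation_number(),
                        "dr": N.reticulation_number() - M.reticulation_number(),
                    }
                )
    return pd.DataFrame(rows)
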