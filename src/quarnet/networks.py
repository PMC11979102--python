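"""Binary level-1 semi-directed phylogenetic networks.

A semi-directed network is stored as a single mixed graph: an undirected
:class:`networkx.Graph` in which every edge carries a ``head`` attribute that is
``None`` for undirected edges and equal to one endpoint for reticulation edges
(the edge is directed toward that endpoint).  Reticulation vertices are derived
(vertices with two incoming directed edges), not stored.

Leaves are degree-1 vertices carrying a ``taxon`` node attribute.
"""

from __future__ import annotations

import itertools
from typing import Hashable, Iterable, Iterator, Optional, Sequence

import networkx as nx
import numpy as np

from .quarnets import DenseQuarnetSet, TFQuarnet, make_split

__all__ = [
    "SemiDirectedNetwork",
    "RootedNetwork",
    "splits",
    "blobtree",
    "induced_tf_quarnet",
    "induced_quarnet_set",
    "valid_root_edges",
    "root_network",
    "write_enewick",
    "read_enewick",
]


class InvalidNetworkError(ValueError):
    pass


class NoValidRootError(ValueError):
    pass


def _edge_key(u, v) -> frozenset:
    return frozenset((u, v))


class SemiDirectedNetwork:
    """A binary, level-1, (optionally triangle-free) semi-directed network."""

    def __init__(self, graph: nx.Graph):
        self.graph = graph
        self._taxon_node = {
            data["taxon"]: v
            for v, data in graph.nodes(data=True)
            if data.get("taxon") is not None
        }

    # -- construction ----------------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        undirected: Iterable[tuple[Hashable, Hashable]],
        directed: Iterable[tuple[Hashable, Hashable]] = (),
        leaf_labels: dict[Hashable, str] | None = None,
    ) -> "SemiDirectedNetwork":
        """Build from edge lists; ``directed`` pairs point toward reticulations.

        If ``leaf_labels`` is omitted, every degree-1 vertex is labeled by its
        own vertex name.
        """
        g = nx.Graph()
        for u, v in undirected:
            g.add_edge(u, v, head=None)
        for u, v in directed:
            g.add_edge(u, v, head=v)
        labels = leaf_labels or {
            v: str(v) for v in g.nodes if g.degree(v) == 1
        }
        for v, taxon in labels.items():
            g.nodes[v]["taxon"] = taxon
        return cls(g)

    def copy(self) -> "SemiDirectedNetwork":
        return SemiDirectedNetwork(self.graph.copy())

    # -- basic queries ---------------------------------------------------------

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(sorted(self._taxon_node))

    def leaf_of(self, taxon: str):
        return self._taxon_node[taxon]

    def leaves(self) -> list:
        return list(self._taxon_node.values())

    def reticulations(self) -> list:
        """Vertices with exactly two incoming directed edges."""
        indeg: dict = {}
        for u, v, head in self.graph.edges(data="head"):
            if head is not None:
                indeg[head] = indeg.get(head, 0) + 1
        return [v for v, d in indeg.items() if d == 2]

    def reticulation_number(self) -> int:
        return len(self.reticulations())

    def undirected_edges(self) -> list[tuple]:
        return [(u, v) for u, v, h in self.graph.edges(data="head") if h is None]

    def reticulation_edges(self) -> list[tuple]:
        """Directed edges as (tail, head) pairs."""
        out = []
        for u, v, h in self.graph.edges(data="head"):
            if h is not None:
                out.append((v, u) if h == u else (u, v))
        return out

    # -- validation ------------------------------------------------------------

    def validate(self, triangle_free: bool = True) -> None:
        g = self.graph
        if not nx.is_connected(g):
            raise InvalidNetworkError("network is not connected")
        if len(self._taxon_node) < 4:
            raise InvalidNetworkError("a network needs at least four labeled leaves")
        if len(set(self._taxon_node)) != len(self._taxon_node):
            raise InvalidNetworkError("taxon labels are not unique")
        indeg: dict = {}
        for u, v, head in g.edges(data="head"):
            if head is not None:
                if head not in (u, v):
                    raise InvalidNetworkError("edge head must be an endpoint")
                indeg[head] = indeg.get(head, 0) + 1
        retics = {v for v, d in indeg.items() if d == 2}
        if any(d not in (0, 2) for d in indeg.values()):
            raise InvalidNetworkError("reticulations need exactly two incoming edges")
        for v in g.nodes:
            deg = g.degree(v)
            taxon = g.nodes[v].get("taxon")
            if deg == 1:
                if taxon is None:
                    raise InvalidNetworkError(f"unlabeled leaf {v!r}")
            elif deg == 3:
                if taxon is not None:
                    raise InvalidNetworkError(f"internal vertex {v!r} has a taxon")
            else:
                raise InvalidNetworkError(
                    f"vertex {v!r} has degree {deg}; network must be binary"
                )
            if v in retics:
                n_undir = sum(
                    1 for _, _, h in g.edges(v, data="head") if h is None
                )
                if g.degree(v) != 3 or n_undir != 1:
                    raise InvalidNetworkError(
                        f"reticulation {v!r} must have two incoming edges and "
                        "one undirected edge"
                    )
        # level-1: every nontrivial biconnected component is a cycle containing
        # exactly one reticulation whose two directed edges lie on the cycle.
        seen_retics = set()
        for comp in nx.biconnected_components(g):
            if len(comp) <= 2:
                continue
            sub = g.subgraph(comp)
            if any(sub.degree(v) != 2 for v in comp):
                raise InvalidNetworkError("blob is not a simple cycle (level > 1)")
            comp_retics = retics & comp
            if len(comp_retics) != 1:
                raise InvalidNetworkError(
                    f"cycle must contain exactly one reticulation, got "
                    f"{len(comp_retics)}"
                )
            (r,) = comp_retics
            for _, w, h in g.edges(r, data="head"):
                if h == r and w not in comp:
                    raise InvalidNetworkError(
                        "reticulation edges must lie on the reticulation's cycle"
                    )
            seen_retics |= comp_retics
            if triangle_free and len(comp) == 3:
                raise InvalidNetworkError("network contains a triangle")
        if seen_retics != retics:
            raise InvalidNetworkError("reticulation not on any cycle")

    # -- cycles and blobtree ---------------------------------------------------

    def cycles(self) -> list[dict]:
        """All cycles, each as ``{"order": [v0, v1, ...], "retic": r}``.

        ``order`` walks the cycle; the reticulation is included in the walk.
        """
        g = self.graph
        out = []
        for comp in nx.biconnected_components(g):
            if len(comp) <= 2:
                continue
            sub = g.subgraph(comp)
            start = min(comp, key=str)
            order = [start]
            prev = None
            while True:
                nbrs = [w for w in sub.neighbors(order[-1]) if w != prev]
                nxt = nbrs[0]
                if nxt == start:
                    break
                prev = order[-1]
                order.append(nxt)
            retic = None
            for v in comp:
                heads = [h for _, _, h in g.edges(v, data="head") if h == v]
                if len(heads) == 2:
                    retic = v
            out.append({"order": order, "retic": retic})
        return out

    def blobtree(self):
        """Collapse every cycle into a single vertex; returns a CandidateBlobtree."""
        from .blobtree import CandidateBlobtree

        tree, _ = self._blob_graph()
        return CandidateBlobtree(tree)

    def _blob_graph(self) -> tuple[nx.Graph, dict]:
        """The blobtree as a plain graph plus a vertex -> blob mapping."""
        blob_of = {v: v for v in self.graph.nodes}
        for i, cyc in enumerate(self.cycles()):
            bid = ("blob", i)
            for v in cyc["order"]:
                blob_of[v] = bid
        tree = nx.Graph()
        for v, data in self.graph.nodes(data=True):
            b = blob_of[v]
            tree.add_node(b)
            if data.get("taxon") is not None:
                tree.nodes[b]["taxon"] = data["taxon"]
        for u, v in self.graph.edges:
            if blob_of[u] != blob_of[v]:
                tree.add_edge(blob_of[u], blob_of[v])
        return tree, blob_of

    # -- splits ----------------------------------------------------------------

    def splits(self, nontrivial_only: bool = False) -> set:
        """All splits realized by removing a single edge (directions ignored)."""
        g = self.graph
        out = set()
        taxa = set(self._taxon_node)
        for u, v in g.edges:
            h = g.copy()
            h.remove_edge(u, v)
            if nx.is_connected(h):
                continue
            comp = nx.node_connected_component(h, u)
            side_a = {t for t, node in self._taxon_node.items() if node in comp}
            side_b = taxa - side_a
            if not side_a or not side_b:
                continue
            if nontrivial_only and min(len(side_a), len(side_b)) < 2:
                continue
            out.add(make_split(side_a, side_b))
        return out

    # -- induced quarnets ------------------------------------------------------

    def induced_tf_quarnet(self, four_taxa: Iterable[str]) -> TFQuarnet:
        """Restriction of the network to four leaves, via fixpoint reduction.

        Deletes leaves outside ``four_taxa`` and exhaustively applies: deleting
        unlabeled leaves, deleting degree-2 reticulations, suppressing
        nonreticulate degree-2 vertices, suppressing parallel edges, and
        suppressing triangles.
        """
        four = frozenset(four_taxa)
        if len(four) != 4 or not four <= set(self._taxon_node):
            raise ValueError(f"{sorted(four_taxa)} is not a 4-subset of the taxa")
        g = nx.MultiGraph()
        for u, v, h in self.graph.edges(data="head"):
            g.add_edge(u, v, head=h)
        for v, data in self.graph.nodes(data=True):
            if data.get("taxon") is not None:
                g.nodes[v]["taxon"] = data["taxon"]
        _reduce_to_quarnet(g, four)
        return _read_off_quarnet(g, four)

    def induced_quarnet_set(self) -> DenseQuarnetSet:
        """Dense unit-weight set of all induced tf-quarnets (vectorized)."""
        taxa = self.taxa
        n = len(taxa)
        idx = {t: i for i, t in enumerate(taxa)}
        tree, blob_of = self._blob_graph()
        # unit-length leaf-to-leaf distances on the blobtree
        nodes = list(tree.nodes)
        node_i = {v: i for i, v in enumerate(nodes)}
        leaf_nodes = [blob_of[self._taxon_node[t]] for t in taxa]
        D = np.zeros((n, n), dtype=np.int32)
        for a, t in enumerate(taxa):
            dist = nx.single_source_shortest_path_length(tree, leaf_nodes[a])
            for b in range(n):
                D[a, b] = dist[leaf_nodes[b]]
        subsets = np.array(
            list(itertools.combinations(range(n), 4)), dtype=np.int32
        )
        # quartet codes from the tree metric: the split pairing with the
        # smallest sum of within-pair distances wins (four-point condition).
        l0, l1, l2, l3 = (subsets[:, k] for k in range(4))
        sums = np.stack(
            [
                D[l0, l1] + D[l2, l3],
                D[l0, l2] + D[l1, l3],
                D[l0, l3] + D[l1, l2],
            ],
            axis=1,
        )
        codes = np.argmin(sums, axis=1).astype(np.int8)
        # overwrite subsets whose four leaves attach to one cycle at four
        # distinct positions: 4-cycle if the reticulation position is hit,
        # otherwise the quartet obtained by opening the cycle at the retic.
        for cyc in self.cycles():
            order = cyc["order"]
            length = len(order)
            pos_of_taxon = np.full(n, -1, dtype=np.int32)
            rpos = order.index(cyc["retic"])
            cycset = set(order)
            for p, c in enumerate(order):
                ext = [w for w in self.graph.neighbors(c) if w not in cycset]
                if not ext:
                    continue
                comp = _component_without(self.graph, ext[0], cycset)
                for v in comp:
                    t = self.graph.nodes[v].get("taxon")
                    if t is not None:
                        pos_of_taxon[idx[t]] = p
            pos = pos_of_taxon[subsets]  # (m, 4)
            srt = np.sort(pos, axis=1)
            distinct = np.all(np.diff(srt, axis=1) > 0, axis=1)
            if not distinct.any():
                continue
            rows = np.nonzero(distinct)[0]
            p_rows = pos[rows]
            has_ret = np.any(p_rows == rpos, axis=1)
            # ranks of the four attachment positions around the cycle,
            # starting just after the reticulation position
            rel = (p_rows - rpos - 1) % length
            ranks = np.argsort(np.argsort(rel, axis=1), axis=1)
            rank0 = ranks[:, 0]
            cyc_rows = rows[has_ret]
            if cyc_rows.size:
                rk, pr = ranks[has_ret], p_rows[has_ret]
                opp_rank = (rk[:, [0]] + 2) % 4
                partner_col = np.argmax(rk == opp_rank, axis=1)
                ret_col = np.argmax(pr == rpos, axis=1)
                codes[cyc_rows] = (3 + 4 * (partner_col - 1) + ret_col).astype(
                    np.int8
                )
            open_rows = rows[~has_ret]
            if open_rows.size:
                rk = ranks[~has_ret]
                same_side = (rk // 2) == (rk[:, [0]] // 2)
                same_side[:, 0] = False
                partner_col = np.argmax(same_side, axis=1)
                codes[open_rows] = (partner_col - 1).astype(np.int8)
        return DenseQuarnetSet(taxa, codes=codes)

    # -- rooting ---------------------------------------------------------------

    def valid_root_edges(self, outgroup: str | None = None) -> set[frozenset]:
        return valid_root_edges(self.graph, outgroup)

    def root_network(self, outgroup: str) -> "RootedNetwork":
        leaf = self._taxon_node.get(outgroup)
        if leaf is None:
            raise KeyError(f"unknown outgroup taxon {outgroup!r}")
        (nbr,) = self.graph.neighbors(leaf)
        edge = _edge_key(leaf, nbr)
        if edge not in self.valid_root_edges(outgroup):
            raise NoValidRootError(f"no valid root at outgroup {outgroup!r}")
        dg = _orient(self.graph, (leaf, nbr))
        return RootedNetwork(dg)

    def root_anywhere(self) -> "RootedNetwork":
        """Root at an arbitrary valid edge (deterministic choice)."""
        edges = self.valid_root_edges()
        if not edges:
            raise NoValidRootError("network has no valid root location")
        edge = min(edges, key=lambda e: sorted(map(str, e)))
        dg = _orient(self.graph, tuple(sorted(edge, key=str)))
        return RootedNetwork(dg)

    # -- comparison ------------------------------------------------------------

    def _iso_digraph(self) -> nx.MultiDiGraph:
        d = nx.MultiDiGraph()
        for v, data in self.graph.nodes(data=True):
            d.add_node(v, taxon=data.get("taxon"))
        for u, v, h in self.graph.edges(data="head"):
            if h is None:
                d.add_edge(u, v, kind="u")
                d.add_edge(v, u, kind="u")
            else:
                tail = v if h == u else u
                d.add_edge(tail, h, kind="d")
        return d

    def is_isomorphic(self, other: "SemiDirectedNetwork") -> bool:
        """Leaf-label-respecting isomorphism honoring edge directions."""
        if self.taxa != other.taxa:
            return False
        from networkx.algorithms import isomorphism as iso

        gm = iso.MultiDiGraphMatcher(
            self._iso_digraph(),
            other._iso_digraph(),
            node_match=iso.categorical_node_match("taxon", None),
            edge_match=iso.categorical_multiedge_match("kind", None),
        )
        return gm.is_isomorphic()


def _component_without(g: nx.Graph, start, excluded: set) -> set:
    """Vertices reachable from ``start`` without entering ``excluded``."""
    seen = {start}
    stack = [start]
    while stack:
        v = stack.pop()
        for w in g.neighbors(v):
            if w not in excluded and w not in seen:
                seen.add(w)
                stack.append(w)
    return seen


# -- fixpoint reduction to a tf-quarnet ---------------------------------------


def _retic_nodes(g: nx.MultiGraph) -> set:
    indeg: dict = {}
    for u, v, h in g.edges(data="head"):
        if h is not None:
            indeg[h] = indeg.get(h, 0) + 1
    return {v for v, d in indeg.items() if d == 2}


def _reduce_to_quarnet(g: nx.MultiGraph, keep: frozenset) -> None:
    """Apply the five reduction operations until none applies (in place)."""
    changed = True
    while changed:
        changed = False
        retics = _retic_nodes(g)
        # delete unlabeled leaves (and leaves outside the kept taxa)
        for v in list(g.nodes):
            if g.degree(v) <= 1 and g.nodes[v].get("taxon") not in keep:
                g.remove_node(v)
                changed = True
        if changed:
            continue
        # delete degree-2 reticulations
        for v in retics:
            if v in g and g.degree(v) == 2:
                heads = [h for _, _, h in g.edges(v, data="head")]
                if all(h == v for h in heads):
                    g.remove_node(v)
                    changed = True
        if changed:
            continue
        # suppress parallel edges: replace the pair by one undirected edge
        for u, v in list(g.edges()):
            if u != v and g.number_of_edges(u, v) >= 2:
                while g.number_of_edges(u, v):
                    g.remove_edge(u, v)
                g.add_edge(u, v, head=None)
                changed = True
                break
        if changed:
            continue
        # suppress triangles: contract a 3-cycle into a single vertex
        tri = _find_triangle(g)
        if tri is not None:
            a, b, c = tri
            for x, y in ((a, b), (b, c), (a, c)):
                while g.number_of_edges(x, y):
                    g.remove_edge(x, y)
            for v in (b, c):
                for _, w, h in list(g.edges(v, data="head")):
                    g.add_edge(a, w, head=h if h != v else None)
                g.remove_node(v)
            changed = True
            continue
        # suppress nonreticulate degree-2 vertices
        retics = _retic_nodes(g)
        for v in list(g.nodes):
            if v in g and g.degree(v) == 2 and v not in retics:
                edges = list(g.edges(v, data="head"))
                if len(edges) != 2:
                    continue  # parallel pair; handled above
                (_, u, h1), (_, w, h2) = edges
                if u == w:
                    continue
                assert h1 != v and h2 != v, "degree-2 vertex with incoming edge"
                head = h1 if h1 == u else (h2 if h2 == w else None)
                g.remove_node(v)
                g.add_edge(u, w, head=head)
                changed = True
                break


def _find_triangle(g: nx.MultiGraph):
    for v in g.nodes:
        nbrs = [w for w in g.neighbors(v) if w != v]
        for a, b in itertools.combinations(nbrs, 2):
            if g.has_edge(a, b):
                return (v, a, b)
    return None


def _read_off_quarnet(g: nx.MultiGraph, four: frozenset) -> TFQuarnet:
    leaf_node = {}
    for v in g.nodes:
        t = g.nodes[v].get("taxon")
        if t in four:
            leaf_node[t] = v
    assert set(leaf_node) == set(four), "reduction lost a labeled leaf"
    internal = [v for v in g.nodes if g.nodes[v].get("taxon") not in four]
    if len(internal) == 2:  # quartet tree
        u, w = internal
        side = [t for t in four if g.has_edge(leaf_node[t], u)]
        assert len(side) == 2, "malformed quartet tree after reduction"
        return TFQuarnet(
            leaves=tuple(sorted(four)),
            shape="quartet",
            split=make_split(side, set(four) - set(side)),
        )
    assert len(internal) == 4, (
        f"reduction did not reach a tf-quarnet shape ({len(internal)} internal)"
    )
    sub = g.subgraph(internal)
    assert all(sub.degree(v) == 2 for v in internal), "internal part is not a cycle"
    start = internal[0]
    order_nodes = [start]
    prev = None
    while len(order_nodes) < 4:
        nbrs = [w for w in sub.neighbors(order_nodes[-1]) if w != prev]
        prev = order_nodes[-1]
        order_nodes.append(nbrs[0])
    retics = _retic_nodes(g)
    assert len(retics & set(internal)) == 1, "4-cycle must have one reticulation"
    (r,) = retics & set(internal)
    taxon_of = {}
    for t, ln in leaf_node.items():
        (nbr,) = g.neighbors(ln)
        taxon_of[nbr] = t
    return TFQuarnet(
        leaves=tuple(sorted(four)),
        shape="cycle4",
        cycle_order=tuple(taxon_of[v] for v in order_nodes),
        reticulation_leaf=taxon_of[r],
    )


# -- root validity and orientation --------------------------------------------


def valid_root_edges(graph: nx.Graph, outgroup: str | None = None) -> set[frozenset]:
    """Undirected edges on which the mixed graph can be rooted.

    Works for partially expanded networks: internal vertices may have any
    degree; reticulations keep their given directions.  If ``outgroup`` is
    given, only its pendant edge is considered.
    """
    candidates = []
    if outgroup is not None:
        leaf = next(
            (
                v
                for v, d in graph.nodes(data=True)
                if d.get("taxon") == outgroup
            ),
            None,
        )
        if leaf is None:
            raise KeyError(f"unknown outgroup taxon {outgroup!r}")
        (nbr,) = graph.neighbors(leaf)
        if graph.edges[leaf, nbr]["head"] is None:
            candidates.append((leaf, nbr))
    else:
        candidates = [
            (u, v) for u, v, h in graph.edges(data="head") if h is None
        ]
    out = set()
    for u, v in candidates:
        if _orient(graph, (u, v)) is not None:
            out.add(_edge_key(u, v))
    return out


def is_rootable(graph: nx.Graph, outgroup: str | None = None) -> bool:
    """True iff some undirected edge (the outgroup's pendant edge, if given)
    admits a valid rooting; stops at the first hit."""
    if outgroup is not None:
        return bool(valid_root_edges(graph, outgroup))
    for u, v, h in graph.edges(data="head"):
        if h is None and _orient(graph, (u, v)) is not None:
            return True
    return False


_ROOT = ("root",)


def _orient(graph: nx.Graph, root_edge: tuple) -> Optional[nx.DiGraph]:
    """Orient all edges away from a root subdividing ``root_edge``.

    Returns the resulting DAG, or None if no valid orientation exists.  The
    orientation is forced: reticulations keep their directed edges and take all
    other incident edges outgoing; every other non-root vertex has exactly one
    incoming edge.
    """
    u0, v0 = root_edge
    if graph.edges[u0, v0]["head"] is not None:
        return None  # cannot root on a reticulation edge
    edges = {}  # key -> (u, v) endpoints
    orient = {}  # key -> (tail, head) once decided
    adj: dict = {v: [] for v in graph.nodes}
    adj[_ROOT] = []

    def add(u, v, head):
        k = (u, v) if str(u) <= str(v) else (v, u)
        edges[k] = (u, v)
        adj[u].append(k)
        adj[v].append(k)
        if head is not None:
            orient[k] = ((v, u) if head == u else (u, v))

    for a, b, h in graph.edges(data="head"):
        if _edge_key(a, b) == _edge_key(u0, v0):
            continue
        add(a, b, h)
    add(_ROOT, u0, None)
    add(_ROOT, v0, None)

    retics = set()
    indeg_directed: dict = {}
    for k, (t, h) in orient.items():
        indeg_directed[h] = indeg_directed.get(h, 0) + 1
    retics = {v for v, d in indeg_directed.items() if d == 2}
    if any(d not in (0, 2) for d in indeg_directed.values()):
        return None

    incoming: dict = {v: 0 for v in adj}
    for t, h in orient.values():
        incoming[h] += 1

    def orient_away(x) -> bool:
        """Orient all unoriented edges at x away from x; False on conflict."""
        for k in adj[x]:
            if k in orient:
                continue
            a, b = edges[k]
            other = b if a == x else a
            orient[k] = (x, other)
            incoming[other] += 1
            limit = 2 if other in retics else 1
            if other in retics:
                return False  # a reticulation's third edge must be outgoing
            if incoming[other] > limit:
                return False
            queue.append(other)
        return True

    queue = [_ROOT] + list(retics)
    processed = set()
    while queue:
        x = queue.pop()
        if x in processed:
            continue
        if x is not _ROOT and x not in retics and incoming[x] == 0:
            continue  # not yet reached; leave queued via future increments
        processed.add(x)
        if not orient_away(x):
            return None
    if len(orient) != len(edges):
        return None  # orientation not forced to completion: invalid
    for v, c in incoming.items():
        need = 0 if v is _ROOT else (2 if v in retics else 1)
        if c != need:
            return None
    dg = nx.DiGraph()
    for v in adj:
        dg.add_node(v)
        if v is not _ROOT and graph.nodes[v].get("taxon") is not None:
            dg.nodes[v]["taxon"] = graph.nodes[v]["taxon"]
    for t, h in orient.values():
        dg.add_edge(t, h)
    if not nx.is_directed_acyclic_graph(dg):
        return None
    return dg


# -- rooted networks ----------------------------------------------------------


class RootedNetwork:
    """A rooted binary phylogenetic network (DAG with a single out-degree-2 root)."""

    def __init__(self, digraph: nx.DiGraph):
        self.digraph = digraph
        roots = [v for v in digraph.nodes if digraph.in_degree(v) == 0]
        if len(roots) != 1:
            raise InvalidNetworkError(f"expected one root, found {len(roots)}")
        self.root = roots[0]
        self._taxon_node = {
            d["taxon"]: v
            for v, d in digraph.nodes(data=True)
            if d.get("taxon") is not None
        }

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(sorted(self._taxon_node))

    def reticulations(self) -> list:
        return [v for v in self.digraph.nodes if self.digraph.in_degree(v) == 2]

    def validate(self) -> None:
        g = self.digraph
        if not nx.is_directed_acyclic_graph(g):
            raise InvalidNetworkError("rooted network must be acyclic")
        if g.out_degree(self.root) != 2:
            raise InvalidNetworkError("root must have out-degree 2")
        for v in g.nodes:
            din, dout = g.in_degree(v), g.out_degree(v)
            if v == self.root:
                continue
            if dout == 0:
                if din != 1 or g.nodes[v].get("taxon") is None:
                    raise InvalidNetworkError(f"bad leaf {v!r}")
            elif (din, dout) not in ((1, 2), (2, 1)):
                raise InvalidNetworkError(
                    f"vertex {v!r} has in/out degree ({din}, {dout})"
                )

    def semidirect(self) -> SemiDirectedNetwork:
        """Suppress the root and undirect all non-reticulation edges."""
        g = self.digraph
        retics = set(self.reticulations())
        out = nx.Graph()
        for v, d in g.nodes(data=True):
            if v == self.root:
                continue
            out.add_node(v)
            if d.get("taxon") is not None:
                out.nodes[v]["taxon"] = d["taxon"]
        for u, v in g.edges:
            if u == self.root:
                continue
            out.add_edge(u, v, head=v if v in retics else None)
        c1, c2 = list(g.successors(self.root))
        if c1 in retics and c2 in retics:
            raise InvalidNetworkError(
                "cannot suppress a root whose children are both reticulations"
            )
        head = c1 if c1 in retics else (c2 if c2 in retics else None)
        if out.has_edge(c1, c2):
            raise InvalidNetworkError("suppressing the root creates parallel edges")
        out.add_edge(c1, c2, head=head)
        return SemiDirectedNetwork(out)

    def is_isomorphic(self, other: "RootedNetwork") -> bool:
        from networkx.algorithms import isomorphism as iso

        gm = iso.DiGraphMatcher(
            self.digraph,
            other.digraph,
            node_match=iso.categorical_node_match("taxon", None),
        )
        return gm.is_isomorphic()


def root_network(network: SemiDirectedNetwork, outgroup: str) -> RootedNetwork:
    return network.root_network(outgroup)


# -- module-level op aliases ---------------------------------------------------


def splits(network: SemiDirectedNetwork, nontrivial_only: bool = False) -> set:
    return network.splits(nontrivial_only=nontrivial_only)


def blobtree(network: SemiDirectedNetwork):
    return network.blobtree()


def induced_tf_quarnet(network: SemiDirectedNetwork, four_taxa) -> TFQuarnet:
    return network.induced_tf_quarnet(four_taxa)


def induced_quarnet_set(network: SemiDirectedNetwork) -> DenseQuarnetSet:
    return network.induced_quarnet_set()


# -- eNewick ------------------------------------------------------------------


def write_enewick(rooted: RootedNetwork) -> str:
    """Serialize a rooted network; reticulations appear twice via #H labels."""
    g = rooted.digraph
    hybrid_id: dict = {}
    for i, v in enumerate(
        sorted(rooted.reticulations(), key=str), start=1
    ):
        hybrid_id[v] = i
    written = set()

    def render(v) -> str:
        taxon = g.nodes[v].get("taxon") or ""
        tag = f"#H{hybrid_id[v]}" if v in hybrid_id else ""
        if v in written:
            return f"{taxon}{tag}"
        written.add(v)
        kids = sorted(g.successors(v), key=str)
        if not kids:
            return f"{taxon}{tag}"
        inner = ",".join(render(c) for c in kids)
        return f"({inner}){taxon}{tag}"

    return render(rooted.root) + ";"


class ENewickError(ValueError):
    def __init__(self, msg: str, line: int, col: int):
        super().__init__(f"eNewick parse error at {line}:{col}: {msg}")
        self.line, self.col = line, col


def read_enewick(text: str) -> RootedNetwork:
    """Parse an eNewick string into a rooted network."""
    pos = 0
    line, col = 1, 1
    n_text = text.strip()

    def err(msg):
        raise ENewickError(msg, line, col)

    def advance(k=1):
        nonlocal pos, line, col
        for _ in range(k):
            if pos < len(n_text) and n_text[pos] == "\n":
                line += 1
                col = 1
            else:
                col += 1
            pos += 1

    def peek():
        return n_text[pos] if pos < len(n_text) else ""

    g = nx.DiGraph()
    counter = itertools.count()
    hybrids: dict[str, Hashable] = {}

    def read_label() -> tuple[str, str]:
        nonlocal pos
        start = pos
        while pos < len(n_text) and n_text[pos] not in "(),;:":
            advance()
        raw = n_text[start:pos]
        if "#" in raw:
            name, _, tag = raw.partition("#")
            return name, tag
        return raw, ""

    def skip_length():
        if peek() == ":":
            advance()
            while pos < len(n_text) and (peek().isdigit() or peek() in ".eE+-"):
                advance()

    def parse_node():
        children = []
        if peek() == "(":
            advance()
            children.append(parse_node())
            while peek() == ",":
                advance()
                children.append(parse_node())
            if peek() != ")":
                err(f"expected ')', got {peek()!r}")
            advance()
        name, tag = read_label()
        skip_length()
        if tag:
            if tag in hybrids:
                node = hybrids[tag]
            else:
                node = ("h", tag)
                hybrids[tag] = node
                g.add_node(node)
        else:
            node = next(counter)
            g.add_node(node)
        if name and not children and not tag:
            g.nodes[node]["taxon"] = name
        for c in children:
            g.add_edge(node, c)
        return node

    root = parse_node()
    if peek() != ";":
        err(f"expected ';', got {peek()!r}")
    return RootedNetwork(g)
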