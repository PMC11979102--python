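import itertools

import numpy as np
import pytest

from conftest import make_caterpillar, make_cycle_network
from quarnet.blobtree import tree_from_splits
from quarnet.cycles import (
    expand_tree,
    quarnet_distances,
    representative_quarnets,
    reticulation_ranking,
    solve_tsp,
    tau,
)
from quarnet.quarnets import DenseQuarnetSet, TFQuarnet, make_split


def quartet(leaves, side, weight=1.0):
    return TFQuarnet(
        leaves=tuple(leaves),
        shape="quartet",
        split=make_split(side, set(leaves) - set(side)),
        weight=weight,
    )


def cycle(order, ret, weight=1.0):
    return TFQuarnet(
        leaves=tuple(order), shape="cycle4", cycle_order=tuple(order),
        reticulation_leaf=ret, weight=weight,
    )


def seven_voter_instance():
    """A degree-4 vertex whose cross multiset holds exactly 7 unit quarnets:
    four share the 4-cycle skeleton (a,b,c,d) (modal reticulation: the A
    component), two are quartet trees, one is a different 4-cycle skeleton."""
    a_taxa = [f"a{i}" for i in range(1, 8)]
    taxa = a_taxa + ["b", "c", "d"]
    tree = tree_from_splits(
        taxa, {make_split(a_taxa, {"b", "c", "d"})}
    )
    voters = []
    for i, ai in enumerate(a_taxa):
        if i < 4:  # skeleton (ai, b, c, d); retic: ai thrice, b once
            voters.append(cycle((ai, "b", "c", "d"), ai if i < 3 else "b"))
        elif i < 6:
            voters.append(quartet((ai, "b", "c", "d"), {ai, "b"}))
        else:  # a different skeleton: opposite pairs {ai,b},{c,d}
            voters.append(cycle((ai, "c", "b", "d"), ai))
    filler = [
        quartet(s, set(sorted(s)[:2]))
        for s in itertools.combinations(sorted(taxa), 4)
        if len({t[0] for t in s}) < 4
    ]
    Q = DenseQuarnetSet(taxa, voters + filler)
    hub = next(v for v in tree.graph.nodes if tree.graph.degree(v) == 4)
    return tree, Q, hub


class TestRepresentativeVoting:
    def test_four_of_seven_vote(self):
        tree, Q, hub = seven_voter_instance()
        rep = representative_quarnets(hub, tree, Q, np.random.default_rng(0))
        q = rep.qset.quarnet(rep.qset.taxa)
        assert q.shape == "cycle4"
        assert q.weight == pytest.approx(4 / 7)
        assert rep.components[q.reticulation_leaf] == frozenset(
            f"a{i}" for i in range(1, 8)
        )

    def test_single_voter_renormalizes(self):
        taxa = list("abcd")
        star = tree_from_splits(taxa, set())
        Q = DenseQuarnetSet(taxa, [quartet("abcd", {"a", "b"}, weight=0.4)])
        hub = next(v for v in star.graph.nodes if star.graph.degree(v) == 4)
        rep = representative_quarnets(hub, star, Q, np.random.default_rng(0))
        q = rep.qset.quarnet(rep.qset.taxa)
        assert q.shape == "quartet"
        assert q.weight == 1.0  # 0.4 / 0.4

    def test_unanimous_vote(self, cycle4):
        Q = cycle4.induced_quarnet_set()
        star = tree_from_splits(list("abcd"), set())
        hub = next(v for v in star.graph.nodes if star.graph.degree(v) == 4)
        rep = representative_quarnets(hub, star, Q, np.random.default_rng(0))
        q = rep.qset.quarnet(rep.qset.taxa)
        assert q.shape == "cycle4"
        assert q.weight == 1.0


class TestTau:
    def test_unit_quartet(self):
        q = quartet("abcd", {"a", "b"})
        assert tau(q, "a", "b") == 1.0
        assert tau(q, "c", "d") == 1.0
        assert tau(q, "a", "c") == 2.0
        assert tau(q, "b", "d") == 2.0

    def test_unit_cycle(self):
        q = cycle(("a", "b", "c", "d"), "a")
        assert tau(q, "a", "b") == 1.0  # neighbors
        assert tau(q, "b", "c") == 1.0
        assert tau(q, "a", "c") == 2.0  # opposite
        assert tau(q, "b", "d") == 2.0

    @pytest.mark.parametrize("w", [0.0, 0.5, 1.0])
    def test_weighted_formula(self, w):
        q = quartet("abcd", {"a", "b"}, weight=w)
        assert tau(q, "a", "b") == pytest.approx((3 - w) / 2)
        assert tau(q, "a", "c") == pytest.approx((3 + w) / 2)
        c = cycle(("a", "b", "c", "d"), "b", weight=w)
        assert tau(c, "a", "b") == pytest.approx((3 - w) / 2)
        assert tau(c, "a", "c") == pytest.approx((3 + w) / 2)

    def test_same_leaf_rejected(self):
        with pytest.raises(ValueError):
            tau(quartet("abcd", {"a", "b"}), "a", "a")


class TestDistances:
    def test_s4_single_cycle(self, cycle4):
        Q = cycle4.induced_quarnet_set()
        star = tree_from_splits(list("abcd"), set())
        hub = next(v for v in star.graph.nodes if star.graph.degree(v) == 4)
        rep = representative_quarnets(hub, star, Q, np.random.default_rng(0))
        D = quarnet_distances(rep)
        labels = rep.labels
        li = {rep.components[y] and min(rep.components[y]): i
              for i, y in enumerate(labels)}
        a, b, c, d = (li[t] for t in "abcd")
        assert D[a, b] == 1.0 and D[b, c] == 1.0
        assert D[a, c] == 2.0 and D[b, d] == 2.0
        assert np.allclose(D, D.T)
        assert np.all(np.diag(D) == 0)

    def test_brute_force_sum(self, cat5):
        Q = cat5.induced_quarnet_set()
        star = tree_from_splits(cat5.taxa, set())
        hub = next(v for v in star.graph.nodes if star.graph.degree(v) == 5)
        rng = np.random.default_rng(0)
        rep = representative_quarnets(hub, star, Q, rng)
        D = quarnet_distances(rep)
        # independent direct summation over the dense representative set
        labels = rep.labels
        for i, j in itertools.combinations(range(len(labels)), 2):
            expect = 0.0
            for q in rep.qset:
                if labels[i] in q.leaves and labels[j] in q.leaves:
                    expect += tau(q, labels[i], labels[j])
            assert D[i, j] == pytest.approx(expect)


class TestTSP:
    def _brute_force(self, D):
        s = len(D)
        best, best_len = None, np.inf
        for perm in itertools.permutations(range(1, s)):
            tour = (0,) + perm
            ln = sum(D[tour[i], tour[(i + 1) % s]] for i in range(s))
            if ln < best_len:
                best, best_len = tour, ln
        return best, best_len

    def _tour_len(self, D, tour):
        s = len(tour)
        return sum(D[tour[i], tour[(i + 1) % s]] for i in range(s))

    @pytest.mark.parametrize("s", [4, 6, 7])
    def test_exact_matches_brute_force(self, s):
        rng = np.random.default_rng(s)
        M = rng.random((s, s))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0)
        _, best_len = self._brute_force(D)
        tour = solve_tsp(D, mode="exact")
        assert self._tour_len(D, tour) == pytest.approx(best_len)

    def test_numba_path_matches_brute_force(self):
        s = 11  # above the pure-python cutoff inside solve_tsp
        rng = np.random.default_rng(11)
        M = rng.random((s, s))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0)
        tour = solve_tsp(D, mode="exact")
        greedy = solve_tsp(D, mode="anneal", rng=np.random.default_rng(0))
        assert self._tour_len(D, tour) <= self._tour_len(D, greedy) + 1e-9

    @pytest.mark.parametrize("s", [5, 6, 7, 8])
    def test_cycle_network_order_recovered(self, s):
        taxa = [chr(ord("a") + i) for i in range(s)]
        net = make_cycle_network(taxa)
        Q = net.induced_quarnet_set()
        star = tree_from_splits(taxa, set())
        hub = next(v for v in star.graph.nodes if star.graph.degree(v) == s)
        rep = representative_quarnets(hub, star, Q, np.random.default_rng(0))
        D = quarnet_distances(rep)
        tour = solve_tsp(D, mode="exact")
        # the optimal tour must be the cycle order (up to rotation/reflection)
        order = [min(rep.components[rep.labels[i]]) for i in tour]
        idx = order.index("a")
        rot = order[idx:] + order[:idx]
        assert rot == taxa or rot == [taxa[0]] + taxa[1:][::-1]

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        M = rng.random((6, 6))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0)
        tour = solve_tsp(D, mode="exact")
        perm = np.array([2, 0, 1, 5, 3, 4])
        Dp = D[np.ix_(perm, perm)]
        tour_p = solve_tsp(Dp, mode="exact")
        assert self._tour_len(Dp, tour_p) == pytest.approx(
            self._tour_len(D, tour)
        )

    def test_anneal_deterministic_under_seed(self):
        rng1 = np.random.default_rng(9)
        rng2 = np.random.default_rng(9)
        M = np.random.default_rng(1).random((15, 15))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0)
        assert solve_tsp(D, "anneal", rng1) == solve_tsp(D, "anneal", rng2)


class TestRanking:
    def _rep(self, net, rng=None):
        taxa = net.taxa
        star = tree_from_splits(taxa, set())
        hub = next(
            v for v in star.graph.nodes if star.graph.degree(v) == len(taxa)
        )
        return representative_quarnets(
            hub, star, net.induced_quarnet_set(),
            rng or np.random.default_rng(0),
        )

    def test_y4_cycle_leads_with_retic(self, cycle4):
        rep = self._rep(cycle4)
        rho = reticulation_ranking(rep, np.random.default_rng(0))
        assert rep.components[rho[0]] == frozenset("a")
        assert sorted(rho) == list(rep.labels)

    def test_y4_quartet_random_permutation(self):
        net = make_caterpillar(list("abcd"))
        rep = self._rep(net)
        rho = reticulation_ranking(rep, np.random.default_rng(0))
        assert sorted(rho) == list(rep.labels)

    def test_y5_counts_reticulation_appearances(self, cycle5):
        rep = self._rep(cycle5)
        rho = reticulation_ranking(rep, np.random.default_rng(0))
        # 'a' is below the reticulation in every induced 4-cycle
        assert rep.components[rho[0]] == frozenset("a")


class TestExpandTree:
    def test_binary_tree_unchanged(self, cat6):
        Q = cat6.induced_quarnet_set()
        bt = cat6.blobtree()
        net = expand_tree(bt, Q, rng=np.random.default_rng(0))
        assert net.is_isomorphic(cat6)
        assert net.reticulation_number() == 0

    def test_star4_expands_to_cycle(self, cycle4):
        Q = cycle4.induced_quarnet_set()
        star = tree_from_splits(list("abcd"), set())
        net = expand_tree(star, Q, rng=np.random.default_rng(0))
        assert net.is_isomorphic(cycle4)

    def test_blobtree_expansion_recovers_network(self, random_networks):
        for src in random_networks[:8]:
            Q = src.induced_quarnet_set()
            bt = src.blobtree()
            net = expand_tree(
                bt, Q, tsp_mode="exact", rng=np.random.default_rng(0)
            )
            assert net.is_isomorphic(src)

    def test_reticulation_count_equals_expanded_vertices(self, random_networks):
        for src in random_networks[:5]:
            Q = src.induced_quarnet_set()
            bt = src.blobtree()
            multis = sum(
                1 for v in bt.graph.nodes if bt.graph.degree(v) >= 4
            )
            net = expand_tree(
                bt, Q, tsp_mode="exact", rng=np.random.default_rng(0)
            )
            assert net.reticulation_number() == multis

    def test_output_always_rootable(self, random_networks):
        from quarnet.networks import is_rootable

        for src in random_networks[:5]:
            Q = src.induced_quarnet_set()
            net = expand_tree(
                src.blobtree(), Q, rng=np.random.default_rng(0)
            )
            assert is_rootable(net.graph, None)

    def test_outgroup_respected(self, cycle4):
        Q = cycle4.induced_quarnet_set()
        star = tree_from_splits(list("abcd"), set())
        net = expand_tree(
            star, Q, outgroup="c", rng=np.random.default_rng(0)
        )
        assert net.valid_root_edges("c")

    def test_outgroup_below_modal_retic_moves_it(self):
        # with outgroup 'a' the modal placement (retic below a) is invalid,
        # so the ranking iteration must pick another leaf
        net = make_cycle_network(list("abcd"))
        Q = net.induced_quarnet_set()
        star = tree_from_splits(list("abcd"), set())
        out = expand_tree(star, Q, outgroup="a", rng=np.random.default_rng(0))
        out.validate()
        assert out.valid_root_edges("a")
        assert out.reticulation_number() == 1
        assert not out.is_isomorphic(net)
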