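"""The four predictors against hand computations and brute-force oracles."""

import numpy as np
import pytest

from ppiloc.core import AnnotationSet, LocalizationVocabulary
from ppiloc.predictors import (
    chi2_predict,
    funflow_predict,
    gmc_predict,
    majority_common,
    majority_merged,
    majority_predict,
)

from conftest import make_network
from oracles import (
    adjacency,
    chi2_oracle,
    common_oracle,
    funflow_oracle,
    gmc_best_objective,
    gmc_objective_oracle,
    merged_oracle,
)

V6 = LocalizationVocabulary(
    ("Nucleus", "Cytoplasm", "ER", "Bud", "Mito", "Golgi")
)


def ann6(d):
    return AnnotationSet.from_names(V6, d)


def row(sm, pid):
    return sm.proteins.index(pid)


class TestMajority:
    def test_unanimous_neighbors(self):
        net = make_network([("u", "n1"), ("u", "n2"), ("u", "n3")])
        ann = ann6({"u": [], "n1": ["Nucleus"], "n2": ["Nucleus"], "n3": ["Nucleus"]})
        sm = majority_predict(net, ann)
        i = row(sm, "u")
        assert sm.scores[i, 0] == 3.0
        assert sm.called_labels("u") == ("Nucleus",)

    def test_top3_cut_with_tie_break(self):
        # neighbor label counts: Nucleus 3, Cytoplasm 2, ER 2, Bud 1
        edges, named = [], {"u": []}
        neighbor_counts = [("Nucleus", 3), ("Cytoplasm", 2), ("ER", 2), ("Bud", 1)]
        i = 0
        for lab, cnt in neighbor_counts:
            for _ in range(cnt):
                named[f"n{i}"] = [lab]
                edges.append(("u", f"n{i}"))
                i += 1
        sm = majority_predict(make_network(edges), ann6(named))
        assert set(sm.called_labels("u")) == {"Nucleus", "Cytoplasm", "ER"}

    def test_weighted_votes_rank_by_edge_weight(self):
        net = make_network(
            [("u", "a"), ("u", "b"), ("u", "c")],
            weights={("u", "a"): 0.9, ("u", "b"): 0.4, ("u", "c"): 0.4},
        )
        ann = ann6({"u": [], "a": ["Nucleus"], "b": ["Cytoplasm"], "c": ["Cytoplasm"]})
        sm = majority_predict(net, ann, weighted=True)
        i = row(sm, "u")
        assert sm.scores[i, 0] == pytest.approx(0.9)
        assert sm.scores[i, 1] == pytest.approx(0.8)
        # 0.9 > 0.8: the single strong neighbor outranks the two weak ones
        order = np.argsort(-sm.scores[i])
        assert order[0] == 0

    def test_isolated_node_gets_no_calls(self):
        net = make_network([("u", "v"), ("x", "y")])
        ann = ann6({"u": [], "v": [], "x": ["ER"], "y": ["ER"]})
        sm = majority_predict(net, ann)
        assert sm.called_labels("u") == ()


class TestMergedCommon:
    def test_merged_union_and_common_intersection(self):
        net = make_network([("u", "a"), ("u", "b")])
        ann = ann6({"u": [], "a": ["Nucleus", "Cytoplasm"], "b": ["Cytoplasm", "ER"]})
        assert set(majority_merged(net, ann).called_labels("u")) == {
            "Nucleus", "Cytoplasm", "ER"
        }
        assert majority_common(net, ann).called_labels("u") == ("Cytoplasm",)

    def test_common_empty_on_total_disagreement(self):
        net = make_network([("u", "a"), ("u", "b")])
        ann = ann6({"u": [], "a": ["Nucleus"], "b": ["ER"]})
        assert majority_common(net, ann).called_labels("u") == ()

    def test_single_labeled_neighbor_inherited_by_all_variants(self):
        net = make_network([("u", "a")])
        ann = ann6({"u": [], "a": ["Golgi", "Mito"]})
        for predict in (majority_predict, majority_merged, majority_common):
            assert set(predict(net, ann).called_labels("u")) == {"Golgi", "Mito"}

    def test_six_node_fixture_matches_set_oracles(self):
        net = make_network(
            [("u", "a"), ("u", "b"), ("v", "b"), ("v", "c"), ("u", "v"), ("a", "c")]
        )
        ann = ann6({"u": [], "v": [],
                    "a": ["Nucleus", "ER"], "b": ["ER", "Mito"], "c": ["Mito"]})
        adj = adjacency(net)
        labels = {p: ann.labels_of(p) for p in adj}
        merged = majority_merged(net, ann)
        common = majority_common(net, ann)
        mo = merged_oracle(adj, labels)
        co = common_oracle(adj, labels)
        for u in ("u", "v"):
            i = row(merged, u)
            assert {k for k in range(V6.size) if merged.calls[i, k]} == mo[u]
            assert {k for k in range(V6.size) if common.calls[i, k]} == co[u]


class TestChi2:
    def test_closed_form_scores(self):
        # 5 labeled neighbors: 4 Nucleus + 1 Cytoplasm; global frequencies
        # tuned so e_Nucleus = 1 over the 5-member neighborhood
        edges, named = [], {"u": []}
        for i in range(4):
            named[f"n{i}"] = ["Nucleus"]
            edges.append(("u", f"n{i}"))
        named["n4"] = ["Cytoplasm"]
        edges.append(("u", "n4"))
        # 15 distant labeled proteins set the global frequency of Nucleus to
        # 4/20 = 0.2 -> e_Nucleus = 5 * 0.2 = 1, n_Nucleus = 4 -> score 9
        for i in range(15):
            named[f"far{i}"] = ["ER"]
            edges.append((f"far{i}", f"far{(i + 1) % 15}"))
        sm = chi2_predict(make_network(edges), ann6(named), sigma=1)
        i = row(sm, "u")
        assert sm.scores[i, V6.index("Nucleus")] == pytest.approx(9.0)

    def test_under_representation_scores_zero(self):
        # u's neighborhood lacks ER entirely although ER is globally common
        edges = [("u", "n0"), ("u", "n1")]
        named = {"u": [], "n0": ["Nucleus"], "n1": ["Nucleus"]}
        for i in range(8):
            named[f"far{i}"] = ["ER"]
            edges.append((f"far{i}", f"far{(i + 1) % 8}"))
        sm = chi2_predict(make_network(edges), ann6(named), sigma=1)
        i = row(sm, "u")
        assert sm.scores[i, V6.index("ER")] == 0.0

    def test_exact_expectation_scores_zero(self):
        # n_k == e_k: 1 Nucleus of 2 neighbors, global frequency 1/2
        edges = [("u", "n0"), ("u", "n1"), ("n2", "n3")]
        named = {"u": [], "n0": ["Nucleus"], "n1": ["Cytoplasm"],
                 "n2": ["Nucleus"], "n3": ["Cytoplasm"]}
        sm = chi2_predict(make_network(edges), ann6(named), sigma=1)
        i = row(sm, "u")
        assert sm.scores[i, V6.index("Nucleus")] == 0.0

    @pytest.mark.parametrize("sigma", [1, 2, 3])
    def test_matches_direct_oracle_on_random_graphs(self, sigma):
        rng = np.random.default_rng(17 + sigma)
        for _ in range(10):
            n = int(rng.integers(6, 12))
            edges = [
                (f"p{i}", f"p{j}") for i in range(n) for j in range(i + 1, n)
                if rng.random() < 0.35
            ]
            if not edges:
                continue
            net = make_network(edges)
            named = {}
            for u in net.nodes:
                if rng.random() < 0.4:
                    named[u] = []
                else:
                    ks = rng.choice(3, size=int(rng.integers(1, 3)), replace=False)
                    named[u] = [V6.labels[k] for k in ks]
            ann = ann6(named)
            sm = chi2_predict(net, ann, sigma=sigma)
            oracle = chi2_oracle(adjacency(net),
                                 {p: ann.labels_of(p) for p in net.nodes},
                                 V6.size, sigma)
            for u in sm.proteins:
                assert sm.scores[row(sm, u)].tolist() == pytest.approx(oracle[u])


class TestGMC:
    def test_dominant_positive_neighborhood(self):
        net = make_network([("u", "a"), ("u", "b")])
        ann = ann6({"u": [], "a": ["Nucleus"], "b": ["Nucleus"]})
        sm = gmc_predict(net, ann, solver="ilp")
        assert sm.calls[row(sm, "u"), 0] == 1

    def test_ilp_objective_equals_enumeration_on_toy(self):
        # 2 labeled carriers, 1 labeled non-carrier, 3 unlabeled in a path
        net = make_network(
            [("u1", "u2"), ("u2", "u3"), ("u1", "a"), ("u1", "b"),
             ("u3", "c"), ("u2", "b")],
            weights={("u1", "u2"): 0.7, ("u2", "u3"): 0.5},
        )
        ann = ann6({"u1": [], "u2": [], "u3": [],
                    "a": ["Nucleus"], "b": ["Nucleus"], "c": ["ER"]})
        sm = gmc_predict(net, ann, solver="ilp")
        adj = adjacency(net)
        labels = {p: ann.labels_of(p) for p in adj}
        targets = sm.proteins
        for k in range(V6.size):
            x = {u: int(sm.calls[row(sm, u), k]) for u in targets}
            achieved = gmc_objective_oracle(adj, labels, k, targets, x)
            best = gmc_best_objective(adj, labels, k, targets)
            assert achieved == pytest.approx(best)

    def test_unanchored_component_defaults_to_all_zero(self):
        net = make_network([("u1", "u2"), ("u2", "u3")])
        ann = ann6({"u1": [], "u2": [], "u3": []})
        sm = gmc_predict(net, ann, solver="ilp")
        assert not sm.calls.any()

    def test_local_search_never_beats_ilp(self):
        rng = np.random.default_rng(5)
        for trial in range(5):
            n = int(rng.integers(5, 9))
            edges = [
                (f"p{i}", f"p{j}") for i in range(n) for j in range(i + 1, n)
                if rng.random() < 0.5
            ]
            if not edges:
                continue
            net = make_network(edges)
            named = {
                u: ([V6.labels[int(rng.integers(0, 3))]] if rng.random() < 0.5 else [])
                for u in net.nodes
            }
            ann = ann6(named)
            ilp = gmc_predict(net, ann, solver="ilp")
            ls = gmc_predict(net, ann, solver="local_search", seed=trial)
            adj = adjacency(net)
            labels = {p: ann.labels_of(p) for p in adj}
            for k in range(3):
                xi = {u: int(ilp.calls[row(ilp, u), k]) for u in ilp.proteins}
                xl = {u: int(ls.calls[row(ls, u), k]) for u in ls.proteins}
                oi = gmc_objective_oracle(adj, labels, k, ilp.proteins, xi)
                ol = gmc_objective_oracle(adj, labels, k, ls.proteins, xl)
                assert oi >= ol - 1e-9

    def test_deterministic_given_seed(self):
        net = make_network([("u1", "u2"), ("u1", "a"), ("u2", "b")])
        ann = ann6({"u1": [], "u2": [], "a": ["Nucleus"], "b": ["ER"]})
        a = gmc_predict(net, ann, solver="local_search", seed=42)
        b = gmc_predict(net, ann, solver="local_search", seed=42)
        assert np.array_equal(a.calls, b.calls)
        assert np.array_equal(a.scores, b.scores)


class TestFunFlow:
    def test_single_downhill_step(self):
        net = make_network([("a", "b")])
        ann = ann6({"a": ["Nucleus"], "b": []})
        sm = funflow_predict(net, ann, d=1)
        assert sm.scores[row(sm, "b"), 0] == pytest.approx(1.0)

    def test_two_step_path_hand_simulation(self):
        # a(k) - b - c with unit weights, d = 2:
        # t1: a->b carries 1;  t2: a->b carries 1, b->c carries min(1, 1/2*1)
        net = make_network([("a", "b"), ("b", "c")])
        ann = ann6({"a": ["Nucleus"], "b": [], "c": []})
        sm = funflow_predict(net, ann, d=2)
        assert sm.scores[row(sm, "b"), 0] == pytest.approx(2.0)
        assert sm.scores[row(sm, "c"), 0] == pytest.approx(0.5)

    def test_no_carrier_no_flow(self):
        net = make_network([("a", "b"), ("b", "c")])
        ann = ann6({"a": ["Nucleus"], "b": [], "c": []})
        sm = funflow_predict(net, ann, d=3)
        assert np.all(sm.scores[:, 1:] == 0.0)

    def test_matches_step_simulator_on_random_graphs(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            n = int(rng.integers(4, 9))
            edges = [
                (f"p{i}", f"p{j}") for i in range(n) for j in range(i + 1, n)
                if rng.random() < 0.5
            ]
            if not edges:
                continue
            weights = {e: float(rng.uniform(0.2, 1.0)) for e in edges}
            net = make_network(edges, weights=weights)
            named = {
                u: ([V6.labels[int(rng.integers(0, 3))]] if rng.random() < 0.5 else [])
                for u in net.nodes
            }
            ann = ann6(named)
            d = int(rng.integers(1, 5))
            sm = funflow_predict(net, ann, d=d)
            oracle = funflow_oracle(adjacency(net),
                                    {p: ann.labels_of(p) for p in net.nodes},
                                    V6.size, d)
            for u in sm.proteins:
                assert sm.scores[row(sm, u)].tolist() == pytest.approx(oracle[u])

    def test_cumulative_inflow_nondecreasing_in_d(self):
        rng = np.random.default_rng(31)
        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("b", "d")]
        net = make_network(edges, weights={e: float(rng.uniform(0.3, 1)) for e in edges})
        ann = ann6({"a": ["Nucleus"], "b": [], "c": [], "d": ["Cytoplasm"]})
        prev = None
        for d in range(1, 7):
            sm = funflow_predict(net, ann, d=d)
            if prev is not None:
                assert np.all(sm.scores >= prev - 1e-12)
            prev = sm.scores
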