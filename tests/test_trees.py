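import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeRegressor

from adaptmap import (
    OccurrenceTable,
    TermKey,
    TreeNode,
    bootstrap_term_occurrences,
    enumerate_terms,
    fit_pruned_tree,
    threshold_terms,
)
from adaptmap.trees import _encode_matrix, _weakest_link_alphas

from oracles import brute_force_terms, random_tree


def leaf(v=0.0):
    return TreeNode(value=v)


class TestFitPrunedTree:
    def test_constant_response_gives_root_only_tree(self, rng):
        X = rng.standard_normal((100, 3))
        tree = fit_pruned_tree(X, np.full(100, 5.0), seed=0)
        assert tree.n_internal == 0
        assert np.allclose(tree.predict(pd.DataFrame(X, columns=tree.feature_names)), 5.0)

    def test_dominant_split_found_in_nearly_all_seeds(self):
        rng = np.random.default_rng(0)
        hits = 0
        for s in range(60):
            X = rng.standard_normal((500, 5))
            y = (X[:, 1] > 0).astype(float) + 0.01 * rng.standard_normal(500)
            tree = fit_pruned_tree(X, y, seed=s)
            root = tree.to_nodes()
            hits += (not root.is_leaf) and root.feature == "f1"
        assert hits >= 57  # >= 95%

    def test_pure_noise_usually_prunes_to_root(self):
        rng = np.random.default_rng(1)
        root_only = 0
        for s in range(60):
            X = rng.standard_normal((500, 5))
            y = rng.standard_normal(500)
            root_only += fit_pruned_tree(X, y, seed=s).n_internal == 0
        assert root_only >= 48  # >= 80%

    def test_weakest_link_matches_sklearn_pruning_path(self, rng):
        for _ in range(10):
            X = rng.standard_normal((300, 4))
            y = X[:, 0] + 0.5 * rng.standard_normal(300)
            est = DecisionTreeRegressor(min_samples_leaf=20, max_depth=6,
                                        random_state=0).fit(X, y)
            mine = _weakest_link_alphas(est.tree_)
            mine = np.unique(np.r_[0.0, mine[np.isfinite(mine)]])
            theirs = np.unique(est.cost_complexity_pruning_path(X, y).ccp_alphas)
            assert np.allclose(np.sort(mine), np.sort(theirs), atol=1e-12)

    def test_categorical_features_split_and_keep_whole_feature_name(self, rng):
        n = 400
        cat = rng.choice(["a", "b", "c"], n)
        y = np.where(cat == "a", 3.0, 0.0) + 0.1 * rng.standard_normal(n)
        X = pd.DataFrame({"grp": cat, "noise": rng.standard_normal(n)})
        tree = fit_pruned_tree(X, y, seed=0)
        terms = enumerate_terms(tree)
        assert TermKey(("grp",)) in terms

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_pruned_tree(rng.standard_normal((10, 2)), np.zeros(10))


class TestEnumerateTerms:
    def test_root_only_tree_has_no_terms(self):
        assert enumerate_terms(leaf()) == set()

    def test_branching_tree_pairs_no_triples(self):
        # root A; children split B and C; grandchildren are leaves
        tree = TreeNode("A",
                        TreeNode("B", leaf(), leaf()),
                        TreeNode("C", leaf(), leaf()))
        got = enumerate_terms(tree)
        assert got == {TermKey(("A",)), TermKey(("B",)), TermKey(("C",)),
                       TermKey(("A", "B")), TermKey(("A", "C"))}

    def test_chain_tree_yields_triple(self):
        tree = TreeNode("A", TreeNode("B", TreeNode("D", leaf(), leaf()),
                                      leaf()), leaf())
        got = enumerate_terms(tree)
        assert got == {TermKey(("A",)), TermKey(("B",)), TermKey(("D",)),
                       TermKey(("A", "B")), TermKey(("B", "D")),
                       TermKey(("A", "B", "D"))}

    def test_repeated_feature_yields_no_self_interaction(self):
        tree = TreeNode("A", TreeNode("A", leaf(), leaf()), leaf())
        got = enumerate_terms(tree)
        assert got == {TermKey(("A",))}

    def test_matches_brute_force_walker_on_random_trees(self):
        rng = np.random.default_rng(99)
        feats = [f"f{i}" for i in range(6)]
        for _ in range(300):
            tree = random_tree(rng, feats)
            assert enumerate_terms(tree) == brute_force_terms(tree)


class TestBootstrap:
    def test_strong_signal_main_term_in_every_resample(self, rng):
        X = rng.standard_normal((300, 3))
        y = 10.0 * (X[:, 0] > 0) + 0.01 * rng.standard_normal(300)
        occ = bootstrap_term_occurrences(X, y, B=20, seed=3)
        assert occ.count(TermKey(("f0",))) == 20
        assert (occ.counts <= occ.B).all()

    def test_deterministic_under_seed(self, rng):
        X = rng.standard_normal((200, 3))
        y = X[:, 0] + rng.standard_normal(200)
        a = bootstrap_term_occurrences(X, y, B=10, seed=5)
        b = bootstrap_term_occurrences(X, y, B=10, seed=5)
        assert a.terms == b.terms
        assert np.array_equal(a.incidence, b.incidence)

    def test_planted_interaction_pair_beats_noise_pairs(self):
        hits = 0
        for s in range(5):
            rng = np.random.default_rng(1000 + s)
            X = rng.standard_normal((400, 5))
            y = (2.0 * X[:, 0] + 1.5 * X[:, 1] + 2.0 * X[:, 0] * X[:, 1]
                 + rng.standard_normal(400))
            occ = bootstrap_term_occurrences(X, y, B=40, seed=s)
            planted = occ.count(TermKey(("f0", "f1")))
            noise = max(
                (occ.count(t) for t in occ.terms
                 if t.order == 2 and t != TermKey(("f0", "f1"))),
                default=0,
            )
            hits += planted > noise
        assert hits == 5


class TestThreshold:
    def test_strict_inequality_at_cutoff(self):
        a, b = TermKey(("a",)), TermKey(("b",))
        inc = np.zeros((300, 2), dtype=bool)
        inc[:3, 0] = True   # count 3 == 0.01*300: excluded (strict)
        inc[:4, 1] = True   # count 4 > 3: included
        occ = OccurrenceTable([a, b], inc)
        kept = threshold_terms(occ, 0.01)
        assert "a" not in kept.mains
        assert "b" in kept.mains

    def test_marginality_closure_after_threshold(self):
        a, b, ab = TermKey(("a",)), TermKey(("b",)), TermKey(("a", "b"))
        inc = np.zeros((100, 3), dtype=bool)
        inc[:80, 0] = True   # a frequent
        inc[:2, 1] = True    # b rare
        inc[:50, 2] = True   # a:b frequent
        occ = OccurrenceTable([a, b, ab], inc)
        kept = threshold_terms(occ, 0.10)
        assert kept.mains == {"a", "b"}  # b pulled in by closure
        assert ab in kept.interactions

    def test_empty_table_gives_empty_set(self):
        occ = OccurrenceTable.from_term_sets([set(), set()])
        assert len(threshold_terms(occ, 0.05)) == 0

    def test_raising_cutoff_never_enlarges_selection(self, rng):
        terms = [TermKey((f"f{i}",)) for i in range(8)]
        occ = OccurrenceTable(terms, rng.random((50, 8)) < rng.random(8))
        prev = None
        for cut in (0.05, 0.1, 0.2, 0.4):
            mains = threshold_terms(occ, cut).mains
            if prev is not None:
                assert mains <= prev
            prev = mains


class TestEncoding:
    def test_target_mean_encoding_reused_for_prediction(self, rng):
        n = 300
        cat = rng.choice(["lo", "hi"], n)
        y = np.where(cat == "hi", 5.0, 0.0) + 0.1 * rng.standard_normal(n)
        X = pd.DataFrame({"c": cat})
        tree = fit_pruned_tree(X, y, min_leaf=10, seed=0)
        pred = tree.predict(pd.DataFrame({"c": ["hi", "lo"]}))
        assert pred[0] > pred[1]

    def test_numeric_passthrough(self, rng):
        X = pd.DataFrame({"a": [1.0, 2.0], "b": [3, 4]})
        enc, names, _ = _encode_matrix(X)
        assert names == ["a", "b"]
        assert np.array_equal(enc, [[1, 3], [2, 4]])
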