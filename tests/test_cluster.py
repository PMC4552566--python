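import numpy as np
import pandas as pd
import pytest

import metakin as mk
from metakin.cluster import dendrogram_segments, tree_to_dict
from metakin.kinetics import KineticSignature
from metakin.preprocess import Grid

GRID = Grid()
POS = GRID.positions


def sig(name, relative, fitted=None):
    relative = np.asarray(relative, dtype=float)
    if fitted is None:
        fitted = 10.0 * (1.0 + relative / 100.0)
    return KineticSignature(
        metabolite=name,
        degree=9,
        coefficients=np.zeros(10),
        positions=POS,
        fitted=np.asarray(fitted, dtype=float),
        relative=relative,
        rss=0.0,
    )


def random_signatures(n, seed=0):
    rng = np.random.default_rng(seed)
    return [sig(f"m{i}", np.cumsum(rng.standard_normal(len(POS)))) for i in range(n)]


class TestDistanceMatrix:
    def test_identical_curves_have_zero_distance(self):
        s = [sig("a", np.ones(len(POS))), sig("b", np.ones(len(POS)))]
        d = mk.signature_distance_matrix(s)
        assert d.loc["a", "b"] == 0.0

    def test_constant_offset_closed_form(self):
        s = [sig("a", np.zeros(len(POS))), sig("b", np.full(len(POS), 10.0))]
        d = mk.signature_distance_matrix(s)
        assert d.loc["a", "b"] == pytest.approx(10.0 * np.sqrt(118.0))

    def test_symmetry_and_zero_diagonal(self):
        d = mk.signature_distance_matrix(random_signatures(6)).to_numpy()
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0.0)

    def test_mismatched_grids_rejected(self):
        a = sig("a", np.zeros(len(POS)))
        short = Grid(step=2.0)
        b = KineticSignature("b", 9, np.zeros(10), short.positions,
                             np.ones(len(short)), np.zeros(len(short)), 0.0)
        with pytest.raises(ValueError, match="grid"):
            mk.signature_distance_matrix([a, b])


class TestHierarchicalCluster:
    def _tree_from(self, dmat, labels):
        d = pd.DataFrame(dmat, index=labels, columns=labels)
        return mk.hierarchical_cluster(d)

    def test_close_pair_merges_first(self):
        tree = self._tree_from(
            [[0, 1, 10], [1, 0, 10], [10, 10, 0]], ["a", "b", "c"]
        )
        assert tree.merges[0, 2] == pytest.approx(1.0)
        assert {int(tree.merges[0, 0]), int(tree.merges[0, 1])} == {0, 1}

    def test_complete_linkage_final_height(self):
        d_ac, d_bc = 7.0, 9.0
        tree = self._tree_from(
            [[0, 1, d_ac], [1, 0, d_bc], [d_ac, d_bc, 0]], ["a", "b", "c"]
        )
        assert tree.merges[-1, 2] == pytest.approx(max(d_ac, d_bc))

    def test_n_minus_one_merges(self):
        s = random_signatures(30)
        tree = mk.hierarchical_cluster(mk.signature_distance_matrix(s))
        assert tree.merges.shape[0] == 29

    def test_single_metabolite_trivial_tree(self):
        tree = mk.hierarchical_cluster(mk.signature_distance_matrix([sig("a", np.zeros(len(POS)))]))
        assert tree.merges.shape[0] == 0
        assert mk.cut_tree(tree, 35.0).tolist() == [1]


@pytest.fixture(scope="module")
def tree():
    return mk.hierarchical_cluster(mk.signature_distance_matrix(random_signatures(12)))


@pytest.fixture(scope="module")
def sigs():
    return random_signatures(8, seed=5)


class TestCutTree:

    def test_zero_height_gives_singletons(self, tree):
        assert mk.cut_tree(tree, 0.0).nunique() == 12

    def test_huge_height_gives_one_cluster(self, tree):
        assert mk.cut_tree(tree, tree.merges[-1, 2] + 1).nunique() == 1

    def test_cluster_count_monotone_in_height(self, tree):
        heights = np.linspace(0, tree.merges[-1, 2] + 1, 25)
        counts = [mk.cut_tree(tree, h).nunique() for h in heights]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_ids_contiguous_from_one(self, tree):
        assign = mk.cut_tree(tree, np.median(tree.merges[:, 2]))
        assert sorted(assign.unique()) == list(range(1, assign.nunique() + 1))

    def test_assignment_invariant_to_input_order(self):
        sigs = random_signatures(15, seed=42)
        d = mk.signature_distance_matrix(sigs)
        a = mk.cut_tree(mk.hierarchical_cluster(d), 20.0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(sigs))
        d2 = mk.signature_distance_matrix([sigs[i] for i in perm])
        b = mk.cut_tree(mk.hierarchical_cluster(d2), 20.0)
        # same partition up to cluster-id renaming
        for x in d.index:
            for y in d.index:
                assert (a[x] == a[y]) == (b[x] == b[y])


class TestDeriveTemplates:
    def test_singleton_template_equals_signature(self):
        sigs = [sig("a", np.linspace(0, 30, len(POS))), sig("b", np.zeros(len(POS)))]
        assign = pd.Series([1, 2], index=["a", "b"], name="cluster")
        (ta, tb) = mk.derive_templates(assign, sigs)
        np.testing.assert_allclose(ta.curve, sigs[0].relative)

    def test_mirror_curves_average_to_sustained(self):
        x = np.linspace(0, 30, len(POS))
        assign = pd.Series([1, 1], index=["a", "b"], name="cluster")
        (t,) = mk.derive_templates(assign, [sig("a", x), sig("b", -x)])
        np.testing.assert_allclose(t.curve, 0.0)
        assert t.pattern == "sustained"

    def test_uncovered_signature_raises(self):
        assign = pd.Series([1], index=["a"], name="cluster")
        with pytest.raises(ValueError, match="b"):
            mk.derive_templates(assign, [sig("a", np.zeros(len(POS))), sig("b", np.zeros(len(POS)))])

    def test_pipeline_recovers_generating_kinds(self):
        # three metabolites per shape kind; noiseless cohort
        panel = {}
        for i, (name, t) in enumerate(mk.demo_panel().items()):
            for j in range(3):
                panel[f"{name}_{j}"] = t
        cohort, truth = mk.simulate_cohort(
            mk.SimulationConfig(n_subjects=12, panel=panel, noise_cv=0.0,
                                p_missing_max=0.0, seed=13)
        )
        res = mk.KineticProfileModel(cohort).fit()
        truth = truth.set_index("metabolite")["pattern"]
        for t in res.templates:
            for member in t.members:
                assert t.pattern == truth[member]


class TestHeatmapExport:
    def test_rows_are_standardised(self, sigs):
        tree = mk.hierarchical_cluster(mk.signature_distance_matrix(sigs))
        hm = mk.heatmap_export(sigs, tree)
        np.testing.assert_allclose(hm.to_numpy().mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(hm.to_numpy().std(axis=1), 1.0, atol=1e-9)

    def test_constant_row_stays_zero(self):
        sigs = [sig("a", np.zeros(len(POS))), sig("b", np.linspace(0, 30, len(POS)))]
        tree = mk.hierarchical_cluster(mk.signature_distance_matrix(sigs))
        hm = mk.heatmap_export(sigs, tree)
        np.testing.assert_allclose(hm.loc["a"], 0.0)

    def test_row_scaling_never_feeds_back_into_clustering(self, sigs):
        d = mk.signature_distance_matrix(sigs)
        tree = mk.hierarchical_cluster(d)
        before = mk.cut_tree(tree, 20.0)
        mk.heatmap_export(sigs, tree)
        after = mk.cut_tree(mk.hierarchical_cluster(mk.signature_distance_matrix(sigs)), 20.0)
        pd.testing.assert_series_equal(before, after)

    def test_rows_follow_leaf_order(self, sigs):
        tree = mk.hierarchical_cluster(mk.signature_distance_matrix(sigs))
        hm = mk.heatmap_export(sigs, tree)
        assert list(hm.index) == tree.leaf_order


class TestTreeExport:
    def test_json_round_trip_fields(self):
        tree = mk.hierarchical_cluster(mk.signature_distance_matrix(random_signatures(5)))
        d = tree_to_dict(tree)
        assert len(d["merges"]) == 4
        assert set(d["leaf_order"]) == {f"m{i}" for i in range(5)}
        assert dendrogram_segments(tree)["ivl"]
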