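import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import metakin as mk
from metakin.preprocess import Grid, InterpolatedCurve, MedianCurve
from metakin.stats import ExtremaResult


def median_curve(values):
    values = np.asarray(values, dtype=float)
    grid = Grid(step=117.0 / max(len(values) - 1, 1))
    # use a bare MedianCurve on arbitrary-length vectors for unit tests
    return MedianCurve("m", grid, values)


def extrema_of(values):
    v = np.asarray(values, dtype=float)
    m = MedianCurve("m", Grid(), v) if len(v) == 118 else None
    # locate directly without a grid-length constraint
    idx_min, idx_max = int(np.argmin(v)), int(np.argmax(v))
    return ExtremaResult("m", idx_min, idx_max, float(v[idx_min]), float(v[idx_max]))


def brute_force_mfc(values):
    """Independent oracle: explicit scan with earliest-tie extrema."""
    v = list(values)
    cmin, cmax = min(v), max(v)
    imin, imax = v.index(cmin), v.index(cmax)
    if imin == imax:
        return 1.0
    return cmax / cmin if imin < imax else cmin / cmax


class TestLocateExtrema:
    def test_scan(self):
        ext = mk.locate_extrema(median_curve([2, 1, 4, 3]))
        assert (ext.idx_min, ext.idx_max) == (1, 2)

    def test_ties_take_earliest_index(self):
        ext = mk.locate_extrema(median_curve([1, 4, 1, 4]))
        assert (ext.idx_min, ext.idx_max) == (0, 1)

    def test_constant_curve_degenerates(self):
        ext = mk.locate_extrema(median_curve([5, 5, 5]))
        assert ext.idx_min == ext.idx_max == 0


class TestComputeMfc:
    def test_min_first(self):
        assert mk.compute_mfc(mk.locate_extrema(median_curve([2, 1, 4]))) == pytest.approx(4.0)

    def test_max_first(self):
        assert mk.compute_mfc(mk.locate_extrema(median_curve([4, 2, 1]))) == pytest.approx(0.25)

    def test_constant_gives_one(self):
        assert mk.compute_mfc(mk.locate_extrema(median_curve([3, 3, 3]))) == 1.0

    def test_zero_minimum_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            mk.compute_mfc(ExtremaResult("m", 0, 2, 0.0, 5.0))

    @given(
        st.lists(st.floats(0.1, 100.0), min_size=2, max_size=30),
        st.floats(0.01, 50.0),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_scale_invariance(self, values, c):
        assert mk.compute_mfc(extrema_of(values)) == pytest.approx(
            mk.compute_mfc(extrema_of([c * v for v in values]))
        )

    def test_reversal_inverts_mfc_for_unique_extrema(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            v = rng.uniform(1, 10, rng.integers(3, 20))
            if len(np.unique(v)) != len(v):
                continue
            m = mk.compute_mfc(extrema_of(v))
            m_rev = mk.compute_mfc(extrema_of(v[::-1]))
            assert m_rev == pytest.approx(1.0 / m)

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(12345)
        for _ in range(2000):
            n = int(rng.integers(2, 25))
            v = rng.uniform(0.5, 5.0, n)
            if rng.random() < 0.3:  # force ties
                v = np.round(v, 1)
            v = np.maximum(v, 0.1)
            assert mk.compute_mfc(extrema_of(v)) == pytest.approx(
                brute_force_mfc(list(v)), rel=1e-12
            )


def wilcoxon_enumeration_oracle(diffs):
    """Exact two-sided P by enumerating all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.asarray(ws)
    p_le = (ws <= w_obs).mean()
    p_ge = (ws >= w_obs).mean()
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_five_positive_distinct_pairs(self):
        x = np.zeros(5)
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        p, branch = mk.wilcoxon_signed_rank(x, y)
        assert branch == "exact"
        assert p == pytest.approx(0.0625)

    def test_matches_enumeration_for_small_n(self):
        rng = np.random.default_rng(7)
        for n in range(4, 11):
            for _ in range(5):
                d = rng.standard_normal(n)
                p, branch = mk.wilcoxon_signed_rank(np.zeros(n), d)
                assert branch == "exact"
                assert p == pytest.approx(wilcoxon_enumeration_oracle(d), abs=1e-12)

    def test_antisymmetric_pairs_are_null(self):
        d = np.concatenate([np.arange(1, 11), -np.arange(1, 11)]).astype(float)
        p, _ = mk.wilcoxon_signed_rank(np.zeros(20), d)
        assert p > 0.95

    def test_all_zero_differences(self):
        p, branch = mk.wilcoxon_signed_rank(np.ones(8), np.ones(8))
        assert p == 1.0 and branch == "degenerate"

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(8)
        d = rng.standard_normal(47) + 0.5
        p, branch = mk.wilcoxon_signed_rank(np.zeros(47), d)
        assert branch == "approx"
        assert 0.0 < p < 1.0


def bh_oracle(p):
    """Independent step-up re-implementation."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestFdrAdjust:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(mk.fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(mk.fdr_adjust([0.2]), [0.2])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(mk.fdr_adjust([0.4] * 5), [0.4] * 5)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_matches_independent_oracle_and_invariants(self, p):
        adj = mk.fdr_adjust(p)
        np.testing.assert_allclose(adj, bh_oracle(p), atol=1e-12)
        assert np.all(adj >= np.asarray(p) - 1e-12)  # never decreases
        assert np.all(adj <= 1.0 + 1e-12)
        # order preservation
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestClassifyPredictor:
    @pytest.mark.parametrize(
        "mfc,p_adj,expected",
        [
            (1.97, 2.84e-13, "strong"),
            (1.32, 2.38e-8, "moderate"),
            (1.16, 9.81e-3, "none"),  # fails both the cut and the alpha
            (1.45, 0.01, "none"),  # big effect, not significant
            (0.70, 1e-6, "strong"),  # symmetric treatment of decreases
        ],
    )
    def test_threshold_rules(self, mfc, p_adj, expected):
        assert mk.classify_predictor(mfc, p_adj) == expected

    def test_monotone_in_magnitude_and_significance(self):
        rank = {"none": 0, "moderate": 1, "strong": 2}
        rng = np.random.default_rng(9)
        for _ in range(200):
            mfc, p = rng.uniform(1.0, 2.0), 10 ** rng.uniform(-6, 0)
            base = rank[mk.classify_predictor(mfc, p)]
            assert rank[mk.classify_predictor(mfc * 1.1, p)] >= base
            assert rank[mk.classify_predictor(mfc, p / 10)] >= base


class TestNormalityScreen:
    def test_normal_samples_mostly_pass(self):
        rng = np.random.default_rng(10)
        passes = sum(
            mk.normality_screen(rng.standard_normal(50))[0] == "pass" for _ in range(200)
        )
        assert passes >= 190  # alpha = 0.01

    def test_heavy_tailed_samples_mostly_fail(self):
        rng = np.random.default_rng(11)
        fails = sum(
            mk.normality_screen(rng.lognormal(0.0, 1.0, 50))[0] == "fail"
            for _ in range(200)
        )
        assert fails >= 190

    def test_degenerate_samples_not_assessed(self):
        assert mk.normality_screen(np.ones(10))[0] == "not assessed"
        assert mk.normality_screen(np.array([1.0, 2.0]))[0] == "not assessed"


class TestPairedSamples:
    def test_identical_subjects_give_identical_pairs(self, noiseless_results):
        r = noiseless_results.pipeline_result
        name = "late_linear_like"
        ext = mk.locate_extrema(r.medians[name])
        x, y, dropped = mk.paired_samples_at_extrema(r.curves[name], ext)
        assert len(x) == 47 and dropped == 0
        assert np.allclose(y / x, y[0] / x[0])

    def test_subject_not_covering_extrema_is_dropped(self):
        grid = Grid()
        full = np.linspace(1, 2, len(grid))
        partial = full.copy()
        partial[grid.positions < 5] = np.nan  # misses index 0
        curves = [
            InterpolatedCurve("1", "m", grid, full),
            InterpolatedCurve("2", "m", grid, partial),
        ]
        ext = ExtremaResult("m", 0, len(grid) - 1, 1.0, 2.0)
        x, y, dropped = mk.paired_samples_at_extrema(curves, ext)
        assert len(x) == 1 and dropped == 1


class TestVolcano:
    def test_transforms_to_machine_precision(self, noiseless_results):
        table = noiseless_results.biomarkers
        np.testing.assert_allclose(table["log2_mfc"], np.log2(table["mfc"]), rtol=1e-12)
        finite = table["p_adj"].notna()
        np.testing.assert_allclose(
            table.loc[finite, "neglog10_p"],
            -np.log10(table.loc[finite, "p_adj"]),
            rtol=1e-9,
        )
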