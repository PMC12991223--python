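import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from vgckit import (
    BinormalFitError,
    VGCCurve,
    average_auc,
    effect_size,
    empirical_auc,
    fit_binormal,
    per_observer_auc,
    vgc_curve,
)
from vgckit.vgc import auc_from_counts

from conftest import build_panel


def brute_force_auc(test, ref):
    """Independent pairwise oracle: full weight for wins, half for ties."""
    wins = sum(1.0 for t in test for r in ref if t > r)
    ties = sum(1.0 for t in test for r in ref if t == r)
    return (wins + 0.5 * ties) / (len(test) * len(ref))


ratings_lists = st.lists(st.integers(1, 5), min_size=1, max_size=12)


class TestEmpiricalAUC:
    @pytest.mark.parametrize(
        "test,ref,expected",
        [
            ([1, 2, 3], [1, 2, 3], 0.5),
            ([5, 5], [1, 1], 1.0),
            ([3, 4], [2, 4], 0.625),  # enumerated by hand: 2 wins, 1 tie of 4 pairs
            ([1, 1], [5, 5], 0.0),
        ],
    )
    def test_known_values(self, test, ref, expected):
        assert empirical_auc(test, ref) == pytest.approx(expected)

    def test_empty_multiset_rejected(self):
        with pytest.raises(ValueError):
            empirical_auc([], [1, 2])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(test=ratings_lists, ref=ratings_lists)
    def test_matches_pairwise_oracle_and_mannwhitney(self, test, ref):
        auc = empirical_auc(test, ref, 5)
        assert auc == pytest.approx(brute_force_auc(test, ref), abs=1e-12)
        u = stats.mannwhitneyu(test, ref, alternative="two-sided").statistic
        assert auc == pytest.approx(u / (len(test) * len(ref)), abs=1e-9)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(test=ratings_lists, ref=ratings_lists)
    def test_antisymmetry(self, test, ref):
        assert empirical_auc(test, ref, 5) + empirical_auc(ref, test, 5) == pytest.approx(1.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(test=ratings_lists, ref=ratings_lists)
    def test_rank_invariance(self, test, ref):
        """A strictly increasing relabeling of categories leaves the AUC unchanged."""
        relabel = {1: 1, 2: 4, 3: 5, 4: 8, 5: 9}
        a = empirical_auc(test, ref, 5)
        b = empirical_auc([relabel[t] for t in test], [relabel[r] for r in ref], 9)
        assert a == pytest.approx(b, abs=1e-12)


class TestVGCCurve:
    def test_identical_uniform_ratings_lie_on_diagonal(self):
        r = [1, 2, 3, 4, 5] * 3
        curve = vgc_curve(r, r, 5)
        assert np.allclose(curve.x, curve.y)
        assert curve.area() == pytest.approx(0.5)

    def test_complete_separation_passes_through_corner(self):
        curve = vgc_curve([5] * 4, [1] * 4, 5)
        assert (0.0, 1.0) in curve.points
        assert curve.area() == pytest.approx(1.0)

    def test_trapezoid_area_equals_u_statistic(self):
        curve = vgc_curve([3, 4], [2, 4], 5)
        assert len(curve.points) == 6
        assert curve.area() == pytest.approx(0.625)

    def test_point_count_and_endpoints(self):
        curve = vgc_curve([2, 3, 3], [1, 2, 4], 4)
        assert len(curve.points) == 5
        assert curve.points[0] == (0.0, 0.0)
        assert curve.points[-1] == (1.0, 1.0)
        assert (np.diff(curve.x) >= 0).all() and (np.diff(curve.y) >= 0).all()

    def test_rating_outside_scale_rejected(self):
        with pytest.raises(ValueError):
            vgc_curve([6], [1], 5)

    def test_invalid_curve_rejected(self):
        with pytest.raises(ValueError):
            VGCCurve(x=[0.0, 0.5, 1.0], y=[0.0, 0.2, 0.9])


class TestObserverLevel:
    def test_identical_ratings_give_half_everywhere(self, identical_panel):
        aucs = per_observer_auc(identical_panel, "test", "ref")
        assert set(aucs) == {"o1", "o2"}
        assert all(a == pytest.approx(0.5) for a in aucs.values())

    def test_separation_is_per_observer(self):
        # o1 rates the test protocol strictly higher everywhere; o2 is mixed
        def fn(o, c, p, q):
            if o == "o1":
                return 5 if p == "test" else 1
            return 3
        panel = build_panel(fn, ["o1", "o2"], ["c1", "c2"], ["ref", "test"], ["Q1"])
        aucs = per_observer_auc(panel, "test", "ref")
        assert aucs["o1"] == pytest.approx(1.0)
        assert aucs["o2"] == pytest.approx(0.5)

    def test_unknown_labels_rejected(self, identical_panel):
        with pytest.raises(KeyError):
            per_observer_auc(identical_panel, "nope", "ref")
        with pytest.raises(KeyError):
            per_observer_auc(identical_panel, "test", "ref", criteria=["QX"])

    def test_criterion_subset_pools_only_those_criteria(self):
        def fn(o, c, p, q):
            if q == "Q1":
                return 5 if p == "test" else 1
            return 3
        panel = build_panel(fn, ["o1"], ["c1", "c2"], ["ref", "test"], ["Q1", "Q2"])
        assert per_observer_auc(panel, "test", "ref", ["Q1"])["o1"] == pytest.approx(1.0)
        assert per_observer_auc(panel, "test", "ref", ["Q2"])["o1"] == pytest.approx(0.5)


class TestAveragingAndEffectSize:
    def test_average(self):
        assert average_auc({"o1": 0.4, "o2": 0.6}) == pytest.approx(0.5)
        vals = {"o1": 0.52, "o2": 0.47, "o3": 0.55, "o4": 0.49}
        assert average_auc(vals) == pytest.approx(sum(vals.values()) / 4)

    def test_average_empty_rejected(self):
        with pytest.raises(ValueError):
            average_auc({})

    @pytest.mark.parametrize(
        "auc,expected", [(0.51, 0.01), (0.5, 0.0), (0.46, 0.04), (0.47, 0.03)]
    )
    def test_effect_size_is_distance_from_null(self, auc, expected):
        assert effect_size(auc) == pytest.approx(expected)

    def test_effect_size_domain(self):
        with pytest.raises(ValueError):
            effect_size(1.2)


class TestBinormal:
    @staticmethod
    def _discretize(x, thr):
        return (np.asarray(x)[:, None] >= np.asarray(thr)).sum(axis=1) + 1

    def test_identical_large_samples_give_half(self):
        rng = np.random.default_rng(0)
        x = self._discretize(rng.normal(0, 1, 4000), [-1.5, -0.5, 0.5, 1.5])
        fit = fit_binormal(x, x, 5)
        assert fit.auc_binormal == pytest.approx(0.5, abs=1e-6)
        assert fit.a == pytest.approx(0.0, abs=1e-4)

    def test_recovers_latent_parameters(self):
        rng = np.random.default_rng(11)
        thr = [-1.5, -0.5, 0.5, 1.5]
        ref = self._discretize(rng.normal(0, 1, 5000), thr)
        test = self._discretize(rng.normal(1, 1, 5000), thr)
        fit = fit_binormal(test, ref, 5)
        assert abs(fit.a - 1.0) < 0.1
        assert fit.auc_binormal == pytest.approx(stats.norm.cdf(1 / np.sqrt(2)), abs=0.02)
        assert np.all(np.diff(fit.thresholds) > 0)

    def test_auc_consistent_with_parameters(self):
        rng = np.random.default_rng(5)
        thr = [-1.0, 0.0, 1.0]
        ref = self._discretize(rng.normal(0, 1, 800), thr)
        test = self._discretize(rng.normal(0.4, 1.3, 800), thr)
        fit = fit_binormal(test, ref, 4)
        assert fit.auc_binormal == pytest.approx(
            stats.norm.cdf(fit.a / np.sqrt(1 + fit.b**2)), abs=1e-12
        )

    def test_degenerate_single_category_rejected(self):
        with pytest.raises(BinormalFitError):
            fit_binormal([3] * 10, [1, 2, 3, 4] * 3, 5)


def test_auc_from_counts_matches_multiset_form():
    t, r = [1, 3, 3, 5], [2, 3, 4, 4]
    counts = lambda x: np.bincount(x, minlength=6)[1:]
    assert auc_from_counts(counts(t), counts(r)) == pytest.approx(brute_force_auc(t, r))
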