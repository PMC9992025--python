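"""Correlation tests, group comparisons, effect grading and the screens."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lesionqol import (
    chi_square_2x2,
    classify_d,
    classify_mcid,
    classify_r,
    cohens_d,
    kendall_tau_b,
    laterality_comparison,
    lesion_hrqol_screen,
    mann_whitney_u,
    pearson_r,
    rsfc_hrqol_screen,
    volume_hrqol_correlations,
)

from conftest import kendall_tau_b_brute


class TestKendall:
    def test_perfect_concordance(self):
        tau, p = kendall_tau_b([1, 2, 3], [1, 2, 3])
        assert tau == pytest.approx(1.0)

    def test_perfect_discordance(self):
        tau, _ = kendall_tau_b([1, 2, 3, 4], [4, 3, 2, 1])
        assert tau == pytest.approx(-1.0)

    def test_tied_instance_matches_brute_force(self):
        x = [1, 1, 2, 3, 3, 3, 4, 5]
        y = [2, 1, 1, 3, 4, 4, 4, 5]
        tau, _ = kendall_tau_b(x, y)
        assert tau == pytest.approx(kendall_tau_b_brute(x, y), abs=1e-12)

    def test_constant_input_flagged_not_propagated(self):
        tau, p = kendall_tau_b([2, 2, 2, 2], [1, 2, 3, 4])
        assert np.isnan(tau) and np.isnan(p)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            kendall_tau_b([1, 2], [2, 1])

    def test_pairwise_complete_missing_handling(self):
        x = [1.0, np.nan, 2.0, 3.0, 4.0]
        y = [1.0, 5.0, 2.0, np.nan, 4.0]
        tau, _ = kendall_tau_b(x, y)
        assert tau == pytest.approx(1.0)

    @given(
        st.lists(st.integers(0, 5), min_size=3, max_size=30).flatmap(
            lambda xs: st.tuples(
                st.just(xs), st.lists(st.integers(0, 5), min_size=len(xs), max_size=len(xs))
            )
        )
    )
    def test_matches_brute_force_enumeration(self, xy):
        x, y = xy
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        tau, _ = kendall_tau_b(x, y)
        assert tau == pytest.approx(kendall_tau_b_brute(x, y), abs=1e-12)

    @given(st.lists(st.integers(-50, 50), min_size=5, max_size=20, unique=True))
    def test_invariant_under_monotone_transform(self, x):
        rng = np.random.default_rng(0)
        y = rng.permutation(len(x)).astype(float)
        tau1, p1 = kendall_tau_b(np.asarray(x, dtype=float), y)
        tau2, p2 = kendall_tau_b(np.exp(np.asarray(x) / 50.0), y)
        assert tau1 == pytest.approx(tau2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestMannWhitney:
    def test_identical_groups(self):
        a = np.arange(30.0)
        _, p = mann_whitney_u(a, a.copy())
        assert p > 0.95

    def test_fully_separated_3v3_exact(self):
        # only 1 of C(6,3)=20 arrangements is as extreme, two-sided doubles it
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert p == pytest.approx(0.1)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            mann_whitney_u([], [1.0])


class TestChiSquare:
    def test_independence(self):
        stat, p = chi_square_2x2([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2([[0, 0], [5, 5]])

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            chi_square_2x2([[1.5, 2], [3, 4]])


class TestEffectSizes:
    def test_equal_means_negligible(self):
        a = np.array([1.0, 2.0, 3.0])
        d = cohens_d(a, a + 0.0)
        assert d == 0.0 and classify_d(d) == "negligible"

    def test_boundary_inclusive_medium(self):
        # means 10 apart, pooled SD 20 -> d = 0.5 exactly
        a = np.array([0.0, 20.0, 40.0])  # sample SD = 20
        d = cohens_d(a, a - 10.0)
        assert d == pytest.approx(0.5)
        assert classify_d(d) == "medium"

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(2, 3, 17), rng.normal(1, 2, 23)
        s2 = (16 * a.var(ddof=1) + 22 * b.var(ddof=1)) / 38
        assert cohens_d(a, b) == pytest.approx(
            (a.mean() - b.mean()) / np.sqrt(s2), abs=1e-12
        )

    @pytest.mark.parametrize(
        "delta,expected",
        [(3, "trivial"), (5, "minimal"), (9.9, "minimal"), (10, "moderate"),
         (15, "moderate"), (20, "moderate"), (20.1, "very_much"), (-25, "very_much")],
    )
    def test_mcid_bands(self, delta, expected):
        assert classify_mcid(delta) == expected

    @pytest.mark.parametrize(
        "r,expected",
        [(0.05, "negligible"), (0.1, "small"), (-0.3, "medium"), (0.51, "large")],
    )
    def test_correlation_classes(self, r, expected):
        assert classify_r(r) == expected


def _toy_overlaps(n=20, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    subjects = [f"s{i}" for i in range(n)]
    for s in subjects:
        for region, val in (("RH_tract_a", rng.uniform()), ("LH_tract_b", 0.0)):
            rows.append(
                {"subject": s, "lesion_type": "flair", "atlas": "tracts",
                 "region": 1, "region_name": region, "hemisphere": "right",
                 "class_": "t", "overlap_ml": val, "overlap_fraction": val}
            )
    return pd.DataFrame(rows), subjects


class TestScreens:
    def test_constant_predictor_excluded(self):
        overlaps, subjects = _toy_overlaps()
        rng = np.random.default_rng(1)
        scores = pd.DataFrame({"scale_x": rng.normal(50, 10, len(subjects))},
                              index=subjects)
        res = lesion_hrqol_screen(overlaps, scores, alpha=0.5)
        assert np.isnan(res.p_values.loc["flair:tracts:LH_tract_b", "scale_x"])
        assert all(h.predictor != "flair:tracts:LH_tract_b" for h in res.significant)

    def test_planted_monotone_association_found(self):
        overlaps, subjects = _toy_overlaps(n=40, seed=2)
        x = overlaps[overlaps["region_name"] == "RH_tract_a"].set_index("subject")[
            "overlap_ml"
        ]
        scores = pd.DataFrame({"scale_x": 90 - 50 * x.loc[subjects]}, index=subjects)
        res = lesion_hrqol_screen(overlaps, scores, alpha=0.001)
        hit = res.p_values.loc["flair:tracts:RH_tract_a", "scale_x"]
        assert hit < 1e-6
        assert res.estimates.loc["flair:tracts:RH_tract_a", "scale_x"] < 0

    def test_too_few_subjects_rejected(self):
        overlaps, subjects = _toy_overlaps(n=5)
        scores = pd.DataFrame({"scale_x": np.arange(5.0)}, index=subjects)
        with pytest.raises(ValueError, match=">= 10"):
            lesion_hrqol_screen(overlaps, scores)

    def test_rsfc_screen_constant_column_undefined(self):
        rng = np.random.default_rng(3)
        subjects = [f"s{i}" for i in range(15)]
        wnc = pd.DataFrame(
            {"node_1": rng.normal(size=15), "node_2": np.full(15, 0.4)}, index=subjects
        )
        scores = pd.DataFrame({"scale_x": rng.normal(50, 10, 15)}, index=subjects)
        res = rsfc_hrqol_screen(wnc, scores)
        assert np.isnan(res.p_values.loc["node_2", "scale_x"])

    def test_volume_correlations_constant_undefined_and_small_n_refused(self):
        subjects = [f"s{i}" for i in range(12)]
        totals = pd.DataFrame(
            {"subject": subjects, "lesion_type": "flair", "total_ml": 5.0}
        )
        rng = np.random.default_rng(4)
        scores = pd.DataFrame({"global_health": rng.normal(60, 10, 12)}, index=subjects)
        res = volume_hrqol_correlations(totals, scores)
        assert res[0].undefined
        with pytest.raises(ValueError):
            volume_hrqol_correlations(totals.iloc[:3], scores.iloc[:3])


class TestLateralityComparison:
    def _cohort(self, seed=0, shift=0.0):
        rng = np.random.default_rng(seed)
        subjects = [f"s{i}" for i in range(40)]
        side = pd.Series(["left"] * 20 + ["right"] * 20, index=subjects)
        vals = rng.normal(70, 15, 40)
        vals[20:] -= shift
        scores = pd.DataFrame({"physical_functioning": vals}, index=subjects)
        return scores, side

    def test_identical_groups_null(self):
        scores, side = self._cohort()
        scores.iloc[20:, 0] = scores.iloc[:20, 0].to_numpy()
        tab = laterality_comparison(scores, side)
        assert tab["p_value"].iloc[0] > 0.9
        assert tab["cohens_d"].iloc[0] == pytest.approx(0.0)

    def test_label_swap_antisymmetry(self):
        scores, side = self._cohort(seed=5, shift=12.0)
        tab = laterality_comparison(scores, side)
        flipped = side.map({"left": "right", "right": "left"})
        tab2 = laterality_comparison(scores, flipped)
        assert tab2["cohens_d"].iloc[0] == pytest.approx(-tab["cohens_d"].iloc[0])
        assert tab2["mean_difference"].iloc[0] == pytest.approx(
            -tab["mean_difference"].iloc[0]
        )
        assert tab2["p_value"].iloc[0] == pytest.approx(tab["p_value"].iloc[0])

    def test_single_sided_cohort_rejected(self):
        scores, side = self._cohort()
        with pytest.raises(ValueError, match="both sides"):
            laterality_comparison(scores, pd.Series("left", index=scores.index))


class TestPearson:
    def test_matches_numpy(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=25), rng.normal(size=25)
        r, _ = pearson_r(x, y)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_constant_undefined(self):
        r, p = pearson_r(np.full(10, 2.0), np.arange(10.0))
        assert np.isnan(r) and np.isnan(p)
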