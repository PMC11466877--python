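import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soyshade.datatypes import PhenotypeTable
from soyshade.evaluation import (
    ShadeToleranceEvaluation,
    compute_asfv,
    compute_d,
    compute_sfv,
    compute_stc,
    compute_weights,
    grade,
    select_tolerant,
)


def _pheno_from_means(means):
    """means: {(accession, condition, trait): mean} -> 2-replicate table."""
    rows = []
    for (acc, cond, trait), m in means.items():
        for rep in (1, 2):
            rows.append((acc, "E1", cond, rep, trait, m))
    return PhenotypeTable(
        pd.DataFrame(
            rows,
            columns=["accession", "year", "condition", "replicate", "trait", "value"],
        )
    )


class TestComputeSTC:
    def test_ratio_of_condition_means(self):
        pheno = _pheno_from_means(
            {
                ("a1", "shade", "plant_height"): 30.0,
                ("a1", "CK", "plant_height"): 20.0,
                ("a2", "shade", "plant_height"): 10.0,
                ("a2", "CK", "plant_height"): 10.0,
            }
        )
        stc = compute_stc(pheno, "E1")
        assert stc.values.loc["a1", "plant_height"] == pytest.approx(1.5)
        assert stc.values.loc["a2", "plant_height"] == pytest.approx(1.0)

    def test_zero_shade_count_gives_stc_zero(self):
        pheno = _pheno_from_means(
            {
                ("a1", "shade", "branch_number"): 0.0,
                ("a1", "CK", "branch_number"): 2.0,
            }
        )
        stc = compute_stc(pheno, "E1")
        assert stc.values.loc["a1", "branch_number"] == 0.0

    def test_zero_ck_mean_and_missing_condition_flagged(self):
        pheno = _pheno_from_means(
            {
                ("a1", "shade", "branch_number"): 1.0,
                ("a1", "CK", "branch_number"): 0.0,
                ("a2", "shade", "plant_height"): 5.0,
            }
        )
        stc = compute_stc(pheno, "E1")
        assert np.isnan(stc.values.loc["a1", "branch_number"])
        assert stc.flags[("a1", "branch_number")] == "CK mean is zero"
        assert stc.flags[("a2", "plant_height")] == "missing condition"


class TestComputeSFV:
    def test_minmax_endpoints_and_midpoint(self):
        stc = pd.DataFrame({"plant_height": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        stc["pod_number"] = [0.5, 0.7, 0.9]
        sfv, dropped = compute_sfv(stc)
        assert dropped == []
        assert sfv.loc["a", "plant_height"] == 0.0
        assert sfv.loc["c", "plant_height"] == 1.0
        assert sfv.loc["b", "plant_height"] == pytest.approx(0.5)

    def test_constant_trait_dropped_with_warning(self):
        stc = pd.DataFrame(
            {"plant_height": [1.0, 1.0, 1.0], "pod_number": [0.1, 0.5, 0.9]}
        )
        with pytest.warns(UserWarning, match="dropped"):
            sfv, dropped = compute_sfv(stc)
        assert dropped == ["plant_height"]
        assert list(sfv.columns) == ["pod_number"]

    def test_sfv_spans_exactly_zero_to_one_per_trait(self):
        rng = np.random.default_rng(3)
        stc = pd.DataFrame(rng.lognormal(0, 0.4, size=(30, 6)))
        sfv, _ = compute_sfv(stc)
        np.testing.assert_allclose(sfv.min(axis=0), 0.0, atol=1e-15)
        np.testing.assert_allclose(sfv.max(axis=0), 1.0, atol=1e-15)


class TestComputeWeights:
    def test_uncorrelated_traits_share_weight_equally(self):
        sfv = pd.DataFrame({"t1": [1.0, 1.0, 0.0, 0.0], "t2": [1.0, 0.0, 1.0, 0.0]})
        _, w, _ = compute_weights(sfv)
        np.testing.assert_allclose(w, [0.5, 0.5], atol=1e-12)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            sfv = pd.DataFrame(rng.random((12, 4)))
            _, w, _ = compute_weights(sfv)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_eigendecomposition_oracle(self):
        sfv = pd.DataFrame(
            [[0.1, 0.9, 0.4], [0.8, 0.2, 0.9], [0.3, 0.7, 0.1], [0.9, 0.1, 0.6]]
        )
        p, w, _ = compute_weights(sfv)
        eig = np.sort(np.real(np.linalg.eigvals(np.corrcoef(sfv.T))))[::-1]
        np.testing.assert_allclose(p, eig / eig.sum(), atol=1e-8)
        np.testing.assert_allclose(w, eig / eig.sum(), atol=1e-8)

    def test_degenerate_rank_errors(self):
        sfv = pd.DataFrame({"t1": [0.5, 0.5, 0.5], "t2": [0.5, 0.5, 0.5]})
        with pytest.raises(ValueError, match="degenerate"):
            compute_weights(sfv)


class TestComputeD:
    def test_weighted_sum_of_membership_scores(self):
        u = np.array([[0.3, 0.9]])
        assert compute_d(u, np.array([1.0, 0.0]), standardize=False)[0] == 0.3
        assert compute_d(np.ones((4, 3)), np.array([0.2, 0.3, 0.5]),
                         standardize=False) == pytest.approx(1.0)

    def test_equals_manual_dot_product(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(5, 3))
        w = np.array([0.2, 0.5, 0.3])
        d = compute_d(X, w)
        U = (X - X.min(axis=0)) / (X.max(axis=0) - X.min(axis=0))
        np.testing.assert_allclose(d, U @ w, atol=1e-12)

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValueError, match="weights"):
            compute_d(np.ones((3, 2)), np.array([1.0]))


class TestASFVAndGrading:
    def test_asfv_is_mean_and_permutation_invariant(self):
        sfv = pd.DataFrame({"t1": [0.0, 0.4], "t2": [1.0, 0.6]})
        asfv = compute_asfv(sfv)
        np.testing.assert_allclose(asfv, [0.5, 0.5])
        shuffled = compute_asfv(sfv[["t2", "t1"]])
        pd.testing.assert_series_equal(asfv, shuffled)

    def test_single_trait_asfv_equals_sfv(self):
        sfv = pd.DataFrame({"t1": [0.2, 0.8]})
        np.testing.assert_allclose(compute_asfv(sfv), sfv["t1"])

    def test_quantile_grading_splits_evenly(self):
        asfv = pd.Series(np.linspace(0, 1, 10))
        grades, _ = grade(asfv, "quantile")
        assert grades.value_counts().eq(2).all()

    def test_equal_width_thresholds(self):
        asfv = pd.Series(np.linspace(0.0, 1.0, 11))
        _, cuts = grade(asfv, "equal_width")
        np.testing.assert_allclose(cuts, [0.2, 0.4, 0.6, 0.8], atol=1e-12)

    def test_unknown_strategy_errors(self):
        with pytest.raises(ValueError, match="strategy"):
            grade(pd.Series(np.linspace(0, 1, 8)), "tertile")

    @settings(derandomize=True, max_examples=40)
    @given(
        values=st.lists(
            st.floats(min_value=0, max_value=1, allow_nan=False), min_size=6, max_size=40
        ),
        strategy=st.sampled_from(["quantile", "equal_width", "mean_sd"]),
    )
    def test_grading_is_monotone_in_asfv(self, values, strategy):
        asfv = pd.Series(values)
        if asfv.nunique() < 2:
            return
        grades, _ = grade(asfv, strategy)
        order = asfv.sort_values().index
        codes = grades.loc[order].cat.codes.to_numpy()
        assert (np.diff(codes) >= 0).all()


class TestSelectTolerant:
    @pytest.mark.parametrize("n_hst,expected", [(2, 0.76), (4, 1.52), (0, 0.0)])
    def test_panel_percentage(self, n_hst, expected):
        n = 264
        asfv = pd.Series(np.linspace(0.1, 0.6, n), index=[f"a{i}" for i in range(n)])
        labels = ["MST"] * (n - n_hst) + ["HST"] * n_hst
        grades = pd.Series(
            pd.Categorical(labels, categories=["HSS", "SS", "MST", "ST", "HST"],
                           ordered=True),
            index=asfv.index,
        )
        hst, pct = select_tolerant(grades, asfv)
        assert len(hst) == n_hst
        assert pct == expected
        assert list(hst["asfv"]) == sorted(hst["asfv"], reverse=True)


class TestEvaluationModel:
    def test_end_to_end_invariants(self, small_phenotypes):
        results = ShadeToleranceEvaluation(small_phenotypes).fit()
        for year in results.years:
            sfv = results.sfv[year]
            np.testing.assert_allclose(sfv.min(axis=0), 0.0, atol=1e-14)
            np.testing.assert_allclose(sfv.max(axis=0), 1.0, atol=1e-14)
            assert results.weights[year].sum() == pytest.approx(1.0, abs=1e-9)
            assert ((results.d_value[year] >= -1e-12) & (results.d_value[year] <= 1 + 1e-12)).all()
            assert ((results.asfv[year] >= 0) & (results.asfv[year] <= 1)).all()
            assert (np.diff(results.thresholds[year]) > 0).all()

    def test_asfv_invariant_under_affine_rescaling_of_one_trait(self, small_phenotypes):
        base = ShadeToleranceEvaluation(small_phenotypes, years=["E1"]).fit()
        stc = base.stc["E1"].values.copy()
        rescaled = stc.copy()
        rescaled["plant_height"] = 3.0 * rescaled["plant_height"] + 7.0
        sfv_a, _ = compute_sfv(stc)
        sfv_b, _ = compute_sfv(rescaled)
        pd.testing.assert_frame_equal(sfv_a, sfv_b, atol=1e-9, rtol=0)
        pd.testing.assert_series_equal(
            compute_asfv(sfv_a), compute_asfv(sfv_b), atol=1e-9, rtol=0
        )

    def test_cross_year_union_reports_repeat_selections_once(self):
        rng = np.random.default_rng(21)
        rows = []
        n = 30
        for year in ("E1", "E2"):
            for i in range(n):
                acc = f"a{i:02d}"
                # accession a00 is strongly tolerant in both years
                ratio = 3.0 if i == 0 else 0.8 + 0.01 * i
                for trait in ("plant_height", "pod_number", "grain_weight"):
                    for rep in (1, 2):
                        ck = 10 + rng.random()
                        rows.append((acc, year, "CK", rep, trait, ck))
                        rows.append((acc, year, "shade", rep, trait, ck * ratio))
        pheno = PhenotypeTable(
            pd.DataFrame(
                rows,
                columns=["accession", "year", "condition", "replicate", "trait", "value"],
            )
        )
        results = ShadeToleranceEvaluation(pheno).fit()
        union = results.tolerant_union()
        assert (union["accession"] == "a00").sum() == 1
        row = union[union["accession"] == "a00"].iloc[0]
        assert row["years"] == "E1,E2"
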