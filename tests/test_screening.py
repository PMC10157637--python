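import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.weightstats import ttest_ind as sm_ttest

from seroscreen import (
    ScreenCriteria,
    classify_marker,
    fold_change,
    optimal_cutoff,
    positive_ratio,
    screen_all,
    t_test_pvalue,
    volcano_table,
)
from seroscreen.io import SampleManifest, SNRMatrix, ValidationError
from seroscreen.screening import (
    DegenerateMarkerError,
    MarkerScreener,
    sens_spec_at,
    summarize_counts,
)


def brute_force_best_j(case, control, min_spec=0.90):
    """Oracle: max Youden's J over every threshold that changes the decision."""
    best = -np.inf
    for t in np.concatenate([np.unique(np.concatenate([case, control])),
                             [max(np.max(case), np.max(control)) + 1]]):
        sens = np.mean(case > t)
        spec = np.mean(control <= t)
        if spec >= min_spec:
            best = max(best, sens + spec - 1.0)
    return best


class TestOptimalCutoff:
    def test_perfect_separation(self):
        cut = optimal_cutoff([5, 6, 7], [1, 2, 3])
        assert 3 < cut < 5
        assert sens_spec_at([5, 6, 7], [1, 2, 3], cut) == (1.0, 1.0)

    def test_ninety_percent_specificity_instance(self):
        rc = [10.0] * 10
        hc = [1, 2, 3, 4, 5, 6, 7, 8, 9, 20.0]
        cut = optimal_cutoff(rc, hc)
        assert 9 < cut <= 10
        sens, spec = sens_spec_at(rc, hc, cut)
        assert (sens, spec) == (1.0, 0.9)
        assert sens + spec - 1 == pytest.approx(brute_force_best_j(np.array(rc), np.array(hc)))

    def test_no_signal_keeps_specificity(self, rng):
        vals = rng.normal(size=12)
        cut = optimal_cutoff(vals, vals)
        sens, spec = sens_spec_at(vals, vals, cut)
        assert spec >= 0.9
        assert sens + spec - 1 == pytest.approx(0.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            optimal_cutoff([], [1.0])

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=60)
    def test_agrees_with_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(1, 21, size=2)
        case = np.round(rng.normal(rng.uniform(0, 2), 1, n1), 1)
        control = np.round(rng.normal(0, 1, n2), 1)
        cut = optimal_cutoff(case, control)
        sens, spec = sens_spec_at(case, control, cut)
        assert spec >= 0.9
        assert sens + spec - 1 == pytest.approx(brute_force_best_j(case, control))


class TestRatioFcPvalue:
    @pytest.mark.parametrize(
        "n_pos,expected", [(9, 0.5625), (5, 0.3125), (0, 0.0)]
    )
    def test_positive_ratio_of_sixteen(self, n_pos, expected):
        values = [2.0] * n_pos + [0.5] * (16 - n_pos)
        assert positive_ratio(values, 1.0) == pytest.approx(expected)

    def test_fold_change_arithmetic(self):
        assert fold_change([3.0, 3.0], [2.0, 2.0]) == pytest.approx(1.5)
        assert fold_change([1.0, 2.0], [1.0, 2.0]) == pytest.approx(1.0)

    @given(
        a=st.lists(st.floats(0.1, 50), min_size=1, max_size=10),
        b=st.lists(st.floats(0.1, 50), min_size=1, max_size=10),
    )
    @settings(deadline=None, max_examples=50)
    def test_fold_change_reciprocal_symmetry(self, a, b):
        assert fold_change(a, b) * fold_change(b, a) == pytest.approx(1.0)

    def test_zero_control_mean_degenerate(self):
        with pytest.raises(DegenerateMarkerError):
            fold_change([1.0], [0.0, 0.0])

    def test_identical_groups_p_one(self):
        assert t_test_pvalue([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == 1.0

    def test_swap_symmetry(self, rng):
        a, b = rng.normal(size=8), rng.normal(1, 2, size=6)
        assert t_test_pvalue(a, b) == pytest.approx(t_test_pvalue(b, a))

    def test_welch_matches_independent_reference(self):
        rc = [5.1, 5.2, 4.9, 5.0]
        hc = [1.0, 1.1, 0.9, 1.2]
        _, p_ref, _ = sm_ttest(rc, hc, usevar="unequal")
        assert t_test_pvalue(rc, hc) == pytest.approx(p_ref, rel=1e-6)


class TestClassifyMarker:
    @pytest.mark.parametrize(
        "rc_pos,hc_pos,fc,p,label,subflag",
        [
            (0.5625, 0.00, 2.5, 0.001, "Up", "n/a"),
            (0.05, 0.40, 0.50, 0.01, "Down", "n/a"),
            (0.35, 0.05, 1.2, 0.001, "Unchanged", "ratio_consistent_fc_or_p_fail"),
            (0.05, 0.05, 1.0, 0.9, "Unchanged", "other"),
        ],
    )
    def test_labels(self, rc_pos, hc_pos, fc, p, label, subflag):
        assert classify_marker(rc_pos, hc_pos, fc, p) == (label, subflag)

    def test_boundary_semantics(self):
        # ratio bounds strict, FC >= 1.5 inclusive, p < 0.05 strict
        assert classify_marker(0.30, 0.0, 2.0, 0.01)[0] == "Unchanged"
        assert classify_marker(0.31, 0.10, 2.0, 0.01)[0] == "Unchanged"
        assert classify_marker(0.31, 0.09, 1.5, 0.01)[0] == "Up"
        assert classify_marker(0.31, 0.09, 2.0, 0.05)[0] == "Unchanged"
        assert classify_marker(0.0, 0.31, 2.0 / 3.0, 0.01)[0] == "Unchanged"
        assert classify_marker(0.0, 0.31, 0.66, 0.01)[0] == "Down"

    def test_undefined_fc_is_unchanged(self):
        assert classify_marker(0.5, 0.0, None, 0.001) == ("Unchanged", "other")

    def test_group_exchange_maps_up_to_down(self):
        # swapping the groups (ratios swap, FC inverts) flips Up to Down
        label_up, _ = classify_marker(0.5, 0.05, 2.0, 0.01)
        label_dn, _ = classify_marker(0.05, 0.5, 0.5, 0.01)
        assert (label_up, label_dn) == ("Up", "Down")


def tiny_screen(rc_rows, hc_rows, protein="P1"):
    values = pd.DataFrame(
        {f"RC_{i}": [v] for i, v in enumerate(rc_rows)}
        | {f"HC_{i}": [v] for i, v in enumerate(hc_rows)},
        index=[protein],
    )
    igg = SNRMatrix("IgG", values, normalized=True)
    igm = SNRMatrix("IgM", values, normalized=True)
    manifest = SampleManifest(
        pd.DataFrame(
            {
                "array_id": list(values.columns),
                "group": ["RC"] * len(rc_rows) + ["HC"] * len(hc_rows),
            }
        ).set_index("array_id")
    )
    return igg, igm, manifest


class TestScreenAll:
    def test_single_perfectly_separated_protein_is_up(self):
        igg, igm, manifest = tiny_screen([6.0, 6.1, 6.2, 5.9], [2.0, 2.1, 1.9, 2.0])
        results = screen_all(igg, igm, manifest)
        row = results[(results.isotype == "IgG")].iloc[0]
        assert row.label == "Up"
        assert row.fc == pytest.approx(3.0, rel=0.05)

    def test_down_marker_detected_with_rc_reference_cutoff(self):
        igg, igm, manifest = tiny_screen([2.0, 2.1, 1.9, 2.0], [6.0, 6.1, 6.2, 5.9])
        results = screen_all(igg, igm, manifest)
        row = results[(results.isotype == "IgG")].iloc[0]
        assert row.label == "Down"
        assert row.hc_pos > 0.30 and row.rc_pos < 0.10

    def test_labels_partition_universe(self, small_cohort):
        from seroscreen.preprocess import preprocess_cohort

        tables, manifest, _ = small_cohort
        normalized, excluded = preprocess_cohort(tables)
        results = screen_all(
            normalized["IgG"], normalized["IgM"], manifest, excluded=excluded
        )
        counts = summarize_counts(results)
        n_proteins = normalized["IgG"].values.shape[0]
        for iso in ("IgG", "IgM"):
            assert sum(counts[iso].values()) == n_proteins
        # each row has exactly one label
        assert results["label"].isin(["Up", "Down", "Unchanged", "Negative"]).all()

    def test_reported_specificity_meets_constraint(self, small_cohort):
        from seroscreen.preprocess import preprocess_cohort

        tables, manifest, _ = small_cohort
        normalized, excluded = preprocess_cohort(tables)
        results = screen_all(
            normalized["IgG"], normalized["IgM"], manifest, excluded=excluded
        )
        up = results[results.label == "Up"]
        assert (up.hc_pos <= 0.10 + 1e-12).all()
        down = results[results.label == "Down"]
        assert (down.rc_pos <= 0.10 + 1e-12).all()

    def test_planted_up_markers_recovered(self, small_cohort):
        from seroscreen import recovery_report
        from seroscreen.preprocess import preprocess_cohort

        tables, manifest, truth = small_cohort
        normalized, excluded = preprocess_cohort(tables)
        results = screen_all(
            normalized["IgG"], normalized["IgM"], manifest, excluded=excluded
        )
        report = recovery_report(truth, results)
        assert report["recovery_sensitivity"] >= 0.9
        assert report["recovery_fdr"] <= 0.1


class TestMarkerScreenerEstimator:
    def test_sklearn_contract(self):
        from sklearn.utils.validation import check_is_fitted

        X = pd.DataFrame(
            np.vstack([np.full((4, 1), 6.0) + np.arange(4)[:, None] * 0.1,
                       np.full((4, 1), 2.0)]),
            columns=["P1"],
        )
        y = np.array(["RC"] * 4 + ["HC"] * 4)
        screener = MarkerScreener().fit(X, y)
        check_is_fitted(screener)
        assert screener.get_support().sum() == 1
        assert screener.transform(X).shape == (8, 1)
        params = screener.get_params()
        assert "criteria" in params and "excluded" in params

    def test_rejects_bad_labels(self):
        X = pd.DataFrame({"P1": np.arange(4.0)})
        with pytest.raises(ValidationError, match="RC/HC"):
            MarkerScreener().fit(X, np.array(["case"] * 2 + ["ctrl"] * 2))


class TestVolcano:
    def test_exact_transforms(self):
        results = pd.DataFrame(
            {
                "protein_id": ["P1", "P2", "P3"],
                "isotype": ["IgG"] * 3,
                "fc": [2.0, 1.0, 2.0 / 3.0],
                "p": [0.01, 1.0, 0.5],
                "label": ["Up", "Unchanged", "Unchanged"],
            }
        )
        out = volcano_table(results)
        np.testing.assert_allclose(out.log2_fc, [1.0, 0.0, -0.585], atol=5e-4)
        np.testing.assert_allclose(out.neg_log10_p, [2.0, 0.0, 0.30103], atol=1e-5)
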