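import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from seroscreen import (
    ELISAPlate,
    PanelModel,
    choose_cutoff,
    evaluate_marker,
    evaluate_panel,
    plate_snr,
    roc_auc,
    sample_relative_od,
    sens_spec_at,
)
from seroscreen.elisa import PlateQCError, read_plates, score_cohort, write_plates
from seroscreen.io import ValidationError


def make_plate(sample_ods, pos=2.0, neg=0.5, plate_id="P1"):
    rows = [(f"W{i}", "sample", f"S{i}", od) for i, od in enumerate(sample_ods)]
    rows += [("WP1", "positive_control", None, pos), ("WP2", "positive_control", None, pos)]
    rows += [("WN1", "negative_control", None, neg), ("WN2", "negative_control", None, neg)]
    return ELISAPlate(
        plate_id, pd.DataFrame(rows, columns=["well_id", "role", "sample_id", "od450"])
    )


class TestPlateSNR:
    def test_formula(self):
        assert plate_snr(make_plate([1.0], pos=2.0, neg=0.5)) == pytest.approx(3.0)

    def test_equal_controls_zero(self):
        assert plate_snr(make_plate([1.0], pos=0.5, neg=0.5)) == pytest.approx(0.0)

    def test_zero_negative_mean_fails_qc(self):
        with pytest.raises(PlateQCError):
            plate_snr(make_plate([1.0], neg=0.0))


class TestSampleScores:
    def test_relative_od(self):
        s = sample_relative_od(make_plate([1.0, 0.5], neg=0.5))
        assert s["S0"] == pytest.approx(1.0)
        assert s["S1"] == pytest.approx(0.0)

    def test_scale_invariance_across_plates(self):
        a = sample_relative_od(make_plate([1.0, 0.8], neg=0.5, pos=2.0))
        b = sample_relative_od(make_plate([2.0, 1.6], neg=1.0, pos=4.0, plate_id="P2"))
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())

    def test_low_snr_plate_rejected_with_missing_samples(self):
        good = make_plate([1.0], pos=2.0, neg=0.5, plate_id="G")
        bad = make_plate([1.0], pos=0.6, neg=0.5, plate_id="B")
        scores = score_cohort([good, bad], min_plate_snr=1.0)
        assert len(scores) == 1

    def test_plate_csv_round_trip(self, tmp_path):
        plates = [make_plate([1.0, 0.7], plate_id="P1"), make_plate([0.9], plate_id="P2")]
        path = tmp_path / "plates.csv"
        write_plates(plates, path)
        back = read_plates(path)
        assert [p.plate_id for p in back] == ["P1", "P2"]
        pd.testing.assert_frame_equal(
            back[0].wells, plates[0].wells, check_dtype=False
        )


def brute_force_auc(case, control):
    wins = sum((c > h) + 0.5 * (c == h) for c in case for h in control)
    return wins / (len(case) * len(control))


class TestRocAuc:
    def test_derived_four_pair_instance(self):
        assert roc_auc([3, 2], [1, 2.5]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_auc([5, 6], [1, 2]) == 1.0

    def test_all_ties(self):
        assert roc_auc([1, 1, 1], [1, 1]) == 0.5

    @given(st.integers(0, 100_000))
    @settings(deadline=None, max_examples=80)
    def test_matches_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(1, 51, size=2)
        case = np.round(rng.normal(0.3, 1, n1), 1)  # rounding induces ties
        control = np.round(rng.normal(0, 1, n2), 1)
        assert roc_auc(case, control) == pytest.approx(brute_force_auc(case, control))

    def test_complement_symmetry_and_sklearn_agreement(self, rng):
        case, control = rng.normal(1, 1, 20), rng.normal(0, 1, 25)
        auc = roc_auc(case, control)
        assert auc + roc_auc(control, case) == pytest.approx(1.0)
        y = np.r_[np.ones(20), np.zeros(25)]
        assert auc == pytest.approx(roc_auc_score(y, np.r_[case, control]))

    def test_invariant_under_monotone_transform(self, rng):
        case, control = rng.lognormal(0.5, 1, 15), rng.lognormal(0, 1, 15)
        auc = roc_auc(case, control)
        assert roc_auc(np.log(case), np.log(control)) == pytest.approx(auc)
        assert roc_auc(case**3, control**3) == pytest.approx(auc)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([], [1.0])


class TestSensSpec:
    def test_extreme_cutoffs(self):
        rc, hc = [1.0, 2.0], [1.5, 2.5]
        assert sens_spec_at(rc, hc, 0.0) == (1.0, 0.0)
        assert sens_spec_at(rc, hc, 10.0) == (0.0, 1.0)

    def test_direct_count(self):
        assert sens_spec_at([5, 6, 7, 1], [1, 2, 3, 9], 4) == (0.75, 0.75)

    def test_monotone_in_cutoff(self, rng):
        rc, hc = rng.normal(1, 1, 30), rng.normal(0, 1, 30)
        cuts = np.linspace(-3, 4, 50)
        sens = [sens_spec_at(rc, hc, c)[0] for c in cuts]
        spec = [sens_spec_at(rc, hc, c)[1] for c in cuts]
        assert all(a >= b for a, b in zip(sens, sens[1:]))
        assert all(a <= b for a, b in zip(spec, spec[1:]))

    def test_choose_cutoff_delegates_to_screen_rule(self, rng):
        rc, hc = [5, 6, 7], [1, 2, 3]
        cut = choose_cutoff(rc, hc)
        assert sens_spec_at(rc, hc, cut) == (1.0, 1.0)
        res = evaluate_marker(rng.normal(1, 1, 20), rng.normal(0, 1, 20))
        assert res.specificity >= 0.9
        assert 0.0 <= res.auc <= 1.0


class TestPanel:
    def labels(self, n_rc=72, n_hc=66):
        return np.array(["RC"] * n_rc + ["HC"] * n_hc)

    def scores(self, rng, effect, n_rc=72, n_hc=66):
        return np.r_[rng.normal(effect, 1, n_rc), rng.normal(0, 1, n_hc)]

    def test_single_marker_panel_reproduces_marker(self, rng):
        x = self.scores(rng, 1.0)
        y = self.labels()
        table = pd.DataFrame({"M1": x})
        res = evaluate_panel(table, y)
        assert res.auc == pytest.approx(roc_auc(x[y == "RC"], x[y == "HC"]))

    def test_noise_marker_does_not_hurt_logistic_panel(self):
        worse = 0
        for seed in range(20):
            rng = np.random.default_rng(2000 + seed)
            y = self.labels()
            info = self.scores(rng, 1.2)
            noise = rng.standard_normal(len(y))
            marker_auc = roc_auc(info[y == "RC"], info[y == "HC"])
            panel_auc = evaluate_panel(
                pd.DataFrame({"A": info, "B": noise}), y
            ).auc
            worse += panel_auc < marker_auc - 0.02
        assert worse == 0

    def test_or_rule_positive_iff_any_marker_positive(self, rng):
        y = self.labels(10, 10)
        a = self.scores(rng, 3.0, 10, 10)
        b = self.scores(rng, 3.0, 10, 10)
        model = PanelModel(method="or_rule").fit(pd.DataFrame({"A": a, "B": b}), y)
        scores = model.decision_function(pd.DataFrame({"A": a, "B": b}))
        expected = (a > model.cutoffs_["A"]) | (b > model.cutoffs_["B"])
        np.testing.assert_array_equal(scores.astype(bool), expected)

    def test_separation_falls_back_to_or_rule(self):
        y = self.labels(8, 8)
        x = np.r_[np.full(8, 5.0), np.zeros(8)]
        with pytest.warns(UserWarning, match="or_rule"):
            model = PanelModel(method="logistic").fit(
                pd.DataFrame({"A": x, "B": x[::-1]}), y
            )
        assert model.method_used_ == "or_rule"
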