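import math

import numpy as np
import pytest

from cirtdose import ConstraintSet, DoseConstraint, evaluate_compliance, cohort_summary
from cirtdose.curve import CurveMonotonicityError
from cirtdose.dvh import dose_at_relative_volume, read_dvh_csv
from cirtdose.synthetic import (
    CohortSpec,
    DVHShapeParams,
    fit_ratio_params,
    generate_cohort,
    generate_conversion_curve,
    generate_dvh,
    generate_dvh_with_metrics,
    write_cohort,
)


def lem_16fx_set():
    return ConstraintSet(
        "center-lem-16fx",
        [DoseConstraint.from_label(lbl, lim, "LEM", 16)
         for lbl, lim in [("D20%", 43.14), ("D10%", 58.48),
                          ("D5%", 65.11), ("D0%", 68.33)]],
    )


class TestGenerateDvh:
    def test_logistic_half_volume_at_d50(self):
        params = DVHShapeParams(d50=35.0, steepness=4.0, tail_dmax=70.0)
        dvh = generate_dvh(params)
        i = int(np.argmin(np.abs(dvh.dose_grid - 35.0)))
        assert dvh.rel_volume[i] == pytest.approx(0.5, abs=0.02)

    def test_deterministic_for_seed(self):
        params = DVHShapeParams(d50=35.0, steepness=4.0, tail_dmax=70.0,
                                noise_sd=0.01, seed=11)
        a, b = generate_dvh(params), generate_dvh(params)
        np.testing.assert_array_equal(a.rel_volume, b.rel_volume)

    def test_different_seed_differs(self):
        base = dict(d50=35.0, steepness=4.0, tail_dmax=70.0, noise_sd=0.01)
        a = generate_dvh(DVHShapeParams(seed=1, **base))
        b = generate_dvh(DVHShapeParams(seed=2, **base))
        assert not np.array_equal(a.rel_volume, b.rel_volume)

    def test_d20_matches_logistic_inversion(self):
        # noiseless logistic: rel(d) = v  <=>  d = d50 + s * ln((1-v)/v)
        params = DVHShapeParams(d50=35.0, steepness=4.0, tail_dmax=80.0)
        dvh = generate_dvh(params)
        expected = 35.0 + 4.0 * math.log(0.8 / 0.2)
        assert dose_at_relative_volume(dvh, 0.20) == pytest.approx(expected, abs=0.1)

    def test_invariants_hold_with_noise(self):
        params = DVHShapeParams(d50=30.0, steepness=3.0, tail_dmax=60.0,
                                noise_sd=0.05, seed=3)
        dvh = generate_dvh(params)  # DVH validation runs in the constructor
        assert dvh.rel_volume[0] == 1.0
        assert np.all(np.diff(dvh.rel_volume) <= 0)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            DVHShapeParams(d50=0.0, steepness=4.0, tail_dmax=70.0)
        with pytest.raises(ValueError):
            DVHShapeParams(d50=35.0, steepness=4.0, tail_dmax=30.0)


class TestGenerateDvhWithMetrics:
    def test_two_targets_recovered(self):
        dvh = generate_dvh_with_metrics([("D20%", 37.91), ("D10%", 53.53)])
        assert dose_at_relative_volume(dvh, 0.20) == pytest.approx(37.91, abs=0.05)
        assert dose_at_relative_volume(dvh, 0.10) == pytest.approx(53.53, abs=0.05)

    def test_max_dose_target(self):
        dvh = generate_dvh_with_metrics([("D0%", 60.0)])
        assert dose_at_relative_volume(dvh, 0.0) == pytest.approx(60.0, abs=0.05)

    def test_absolute_target(self):
        dvh = generate_dvh_with_metrics([("D10cc", 50.0)], total_volume=50.0)
        assert dose_at_relative_volume(dvh, 0.20) == pytest.approx(50.0, abs=0.05)

    def test_contradictory_targets_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            generate_dvh_with_metrics([("D20%", 55.0), ("D10%", 50.0)])

    def test_duplicate_volume_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            generate_dvh_with_metrics([("D20%", 40.0), ("D10cc", 45.0)],
                                      total_volume=50.0)

    def test_mixed_targets_round_trip(self):
        dvh = generate_dvh_with_metrics(
            [("D20%", 40.0), ("D10cc", 52.0), ("D0%", 61.0)], total_volume=60.0
        )
        assert dose_at_relative_volume(dvh, 10.0 / 60.0) == pytest.approx(52.0, abs=0.05)
        assert dose_at_relative_volume(dvh, 0.0) == pytest.approx(61.0, abs=0.05)


class TestGenerateCohort:
    def test_exceedance_counts_recovered(self):
        cset = lem_16fx_set()
        spec = CohortSpec(38, 16, {"D20%": 8, "D10%": 4}, seed=5)
        cohort = generate_cohort(spec, cset)
        reports = [evaluate_compliance(p.dvh, cset, p.patient_id)
                   for p in cohort.patients]
        summary = cohort_summary(reports)
        assert summary.exceedance_count["D20%"] == 8
        assert summary.exceedance_count["D10%"] == 4
        assert summary.exceedance_count["D5%"] == 0

    def test_nested_exceedance(self):
        cset = lem_16fx_set()
        spec = CohortSpec(38, 16, {"D20%": 8, "D10%": 4}, seed=5)
        cohort = generate_cohort(spec, cset)
        reports = [evaluate_compliance(p.dvh, cset, p.patient_id)
                   for p in cohort.patients]
        over_d10 = {r.patient_id for r in reports if "D10%" in r.exceeded_labels()}
        over_d20 = {r.patient_id for r in reports if "D20%" in r.exceeded_labels()}
        assert over_d10 <= over_d20

    def test_zero_exceedances_all_pass(self):
        cset = lem_16fx_set()
        cohort = generate_cohort(CohortSpec(5, 16, {}, seed=1), cset)
        for p in cohort.patients:
            rep = evaluate_compliance(p.dvh, cset, p.patient_id)
            assert rep.exceeded_labels() == []

    def test_same_seed_identical(self):
        cset = lem_16fx_set()
        spec = CohortSpec(6, 16, {"D20%": 2}, seed=9)
        a, b = generate_cohort(spec, cset), generate_cohort(spec, cset)
        for pa, pb in zip(a.patients, b.patients):
            np.testing.assert_array_equal(pa.dvh.rel_volume, pb.dvh.rel_volume)
            assert pa.truth == pb.truth

    def test_cohort_size_change_keeps_patients(self):
        # per-patient substreams: enlarging the cohort must not reshuffle
        cset = lem_16fx_set()
        small = generate_cohort(CohortSpec(3, 16, {"D20%": 2}, seed=13), cset)
        large = generate_cohort(CohortSpec(10, 16, {"D20%": 2}, seed=13), cset)
        for pa, pb in zip(small.patients, large.patients):
            np.testing.assert_array_equal(pa.dvh.rel_volume, pb.dvh.rel_volume)

    def test_truth_table_matches_pipeline(self):
        cset = lem_16fx_set()
        cohort = generate_cohort(CohortSpec(12, 16, {"D20%": 5}, seed=2), cset)
        assert cohort.truth_exceedance_counts()["D20%"] == 5
        for p in cohort.patients:
            rep = evaluate_compliance(p.dvh, cset, p.patient_id)
            for (label, value, exceeds), rec in zip(p.truth, rep.records):
                assert rec.constraint_label == label
                assert rec.measured == pytest.approx(value, abs=0.05)
                assert (rec.passed is False) == exceeds

    def test_unknown_label_rejected(self):
        with pytest.raises(KeyError):
            generate_cohort(CohortSpec(5, 16, {"D42%": 1}, seed=0), lem_16fx_set())

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(5, 16, {"D20%": 9}, seed=0)


class TestGenerateConversionCurve:
    def test_identity_when_a_zero(self):
        curve = generate_conversion_curve((20.0, 60.0), a=0.0, b=30.0)
        assert curve.mkm_to_lem(37.5) == pytest.approx(37.5, abs=1e-9)

    def test_fit_reproduces_extreme_anchor_ratios(self):
        a, b = fit_ratio_params((28.80, 43.14), (60.80, 68.33))
        r_lo = 1.0 + a * math.exp(-28.80 / b)
        r_hi = 1.0 + a * math.exp(-60.80 / b)
        assert r_lo == pytest.approx(43.14 / 28.80, abs=1e-6)
        assert r_hi == pytest.approx(68.33 / 60.80, abs=1e-6)

    def test_generated_curve_is_valid_and_ratio_decreasing(self):
        a, b = fit_ratio_params((28.80, 43.14), (60.80, 68.33))
        curve = generate_conversion_curve((25.0, 65.0), a, b)
        ratios = [anchor.lem_dose / anchor.mkm_dose for anchor in curve.anchors]
        assert all(x > y for x, y in zip(ratios, ratios[1:]))

    def test_noise_is_repaired_or_rejected(self):
        a, b = fit_ratio_params((28.80, 43.14), (60.80, 68.33))
        curve = generate_conversion_curve((25.0, 65.0), a, b, noise_sd=0.05, seed=4)
        lems = [anchor.lem_dose for anchor in curve.anchors]
        assert all(x < y for x, y in zip(lems, lems[1:]))

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            generate_conversion_curve((25.0, 65.0), a=-1.0, b=10.0)
        with pytest.raises(ValueError):
            fit_ratio_params((10.0, 11.0), (20.0, 23.0))  # increasing ratio


class TestWriteCohort:
    def test_artifacts_round_trip(self, tmp_path):
        cset = lem_16fx_set()
        cohort = generate_cohort(CohortSpec(4, 16, {"D20%": 1}, seed=3), cset)
        manifest = write_cohort(cohort, tmp_path)
        lines = manifest.read_text().splitlines()
        assert lines[0] == "patient_id,dvh_path,n_fractions"
        assert len(lines) == 5
        dvh = read_dvh_csv(tmp_path / lines[1].split(",")[1])
        assert dvh.rel_volume[0] == 1.0
        truth = (tmp_path / "truth_table.csv").read_text().splitlines()
        assert truth[0] == "patient_id,metric,true_value,exceeds"
        assert len(truth) == 1 + 4 * len(cset)
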