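"""CNR/SNR formulas, diagnostic classification and the synthetic ROI generator."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from contrastflow import (
    IqThresholds,
    PKParameters,
    Patient,
    RoiMeasurement,
    RoiNoiseConfig,
    ScanMode,
    ScanProtocol,
    SegmentIQ,
    Sex,
    ValidationError,
    classify,
    cnr,
    cohort_iq_summary,
    default_calibration,
    generate_protocol,
    nadler_blood_volume,
    simulate_roi_set,
    snr,
)
from contrastflow.iq import VESSEL_BY_SEGMENT, read_segments_csv


def make_roi(vessel=350.0, vessel_sd=40.0, fat=-80.0, fat_sd=30.0):
    return RoiMeasurement(vessel_mean=vessel, vessel_sd=vessel_sd, fat_mean=fat, fat_sd=fat_sd)


def make_segment(roi, seg_id=1):
    return SegmentIQ(
        segment_id=seg_id,
        vessel=VESSEL_BY_SEGMENT[seg_id],
        roi=roi,
        cnr=cnr(roi),
        snr=snr(roi),
        assessable=True,
    )


class TestFormulas:
    def test_cnr_known_value(self):
        assert cnr(make_roi(vessel=360.0, fat=-80.0, fat_sd=30.0)) == pytest.approx(14.67, abs=0.01)

    def test_cnr_zero_when_vessel_equals_fat(self):
        assert cnr(make_roi(vessel=-80.0, fat=-80.0)) == 0.0

    def test_snr_known_values(self):
        assert snr(make_roi(vessel=350.0, vessel_sd=35.0)) == pytest.approx(10.0)
        # typical high-pitch cohort means: 367 HU vessel, 43 HU noise
        assert snr(make_roi(vessel=367.0, vessel_sd=43.0)) == pytest.approx(8.53, abs=0.01)

    def test_zero_sd_guards(self):
        with pytest.raises(ValidationError, match="fat_sd"):
            RoiMeasurement(vessel_mean=350.0, vessel_sd=40.0, fat_mean=-80.0, fat_sd=0.0)
        with pytest.raises(ValidationError, match="vessel_sd"):
            RoiMeasurement(vessel_mean=350.0, vessel_sd=0.0, fat_mean=-80.0, fat_sd=30.0)

    @given(
        vessel=st.floats(-100.0, 900.0),
        vessel_sd=st.floats(1.0, 100.0),
        fat=st.floats(-150.0, 0.0),
        fat_sd=st.floats(1.0, 60.0),
    )
    def test_formulas_match_brute_force(self, vessel, vessel_sd, fat, fat_sd):
        roi = make_roi(vessel, vessel_sd, fat, fat_sd)
        assert cnr(roi) == pytest.approx((vessel - fat) / fat_sd, rel=1e-12)
        assert snr(roi) == pytest.approx(vessel / vessel_sd, rel=1e-12)


class TestClassify:
    def test_attenuation_boundary_inclusive(self):
        seg = classify(make_segment(make_roi(vessel=300.0)))
        assert seg.diagnostic_attenuation is True

    def test_cnr_boundary_strict(self):
        roi = make_roi(vessel=220.0, fat=-80.0, fat_sd=30.0)  # CNR exactly 10
        assert cnr(roi) == pytest.approx(10.0)
        assert classify(make_segment(roi)).diagnostic_cnr is False

    def test_low_attenuation_not_diagnostic(self):
        seg = classify(make_segment(make_roi(vessel=263.0)))
        assert seg.diagnostic_attenuation is False

    def test_non_assessable_flags_cleared(self):
        seg = SegmentIQ(segment_id=9, vessel="LAD")
        out = classify(seg)
        assert out.diagnostic_attenuation is False and out.diagnostic_cnr is False

    def test_idempotent_and_pure(self):
        seg = make_segment(make_roi(vessel=350.0))
        once = classify(seg)
        assert classify(once) == once
        assert seg.diagnostic_attenuation is False  # input untouched


def test_segment_invariants():
    with pytest.raises(ValidationError):
        SegmentIQ(segment_id=18, vessel="RCA")
    with pytest.raises(ValidationError, match="cnr"):
        SegmentIQ(segment_id=1, vessel="RCA", roi=make_roi(), assessable=True)


@pytest.fixture(scope="module")
def simulated_scan():
    k, cal = default_calibration()
    patient = Patient(Sex.FEMALE, 1.65, 60.0)
    bv = nadler_blood_volume(patient)
    from contrastflow import IOPROMIDE_300

    proto = generate_protocol(patient, ScanProtocol(ScanMode.HIGH_PITCH, 70.0), IOPROMIDE_300, cal)
    pk = PKParameters(flow=proto.flow, iodine_concentration=300.0, attenuation_constant=k)
    return proto, bv, pk


class TestSimulateRoiSet:
    def test_seventeen_segments_in_order(self, simulated_scan):
        proto, bv, pk = simulated_scan
        segs = simulate_roi_set(proto, 70.0, bv, pk, seed=1)
        assert [s.segment_id for s in segs] == list(range(1, 18))

    def test_seed_determinism(self, simulated_scan):
        proto, bv, pk = simulated_scan
        assert simulate_roi_set(proto, 70.0, bv, pk, seed=5) == simulate_roi_set(
            proto, 70.0, bv, pk, seed=5
        )

    def test_zero_dropout_all_assessable(self, simulated_scan):
        proto, bv, pk = simulated_scan
        noise = RoiNoiseConfig(dropout={}, baseline_dropout=0.0)
        segs = simulate_roi_set(proto, 70.0, bv, pk, noise=noise, seed=2)
        assert sum(s.assessable for s in segs) == 17

    def test_degenerate_noise_returns_predicted_attenuation(self, simulated_scan):
        proto, bv, pk = simulated_scan
        from contrastflow import predicted_attenuation

        predicted = predicted_attenuation(proto.flow, 70.0, bv, pk)
        noise = RoiNoiseConfig(attenuation_sd=0.0, noise_sd=0.0, fat_spread=0.0,
                               fat_noise_sd=0.0, dropout={}, baseline_dropout=0.0)
        segs = simulate_roi_set(proto, 70.0, bv, pk, noise=noise, seed=3)
        assert all(s.roi.vessel_mean == pytest.approx(predicted) for s in segs)

    def test_default_dropout_gives_about_95pct_assessable(self, simulated_scan):
        proto, bv, pk = simulated_scan
        rng = np.random.default_rng(8)
        total = assessable = 0
        for _ in range(114):
            segs = simulate_roi_set(proto, 70.0, bv, pk, seed=rng)
            total += len(segs)
            assessable += sum(s.assessable for s in segs)
        assert assessable / total == pytest.approx(0.96, abs=0.02)


class TestCohortSummary:
    def test_single_patient_all_diagnostic(self):
        segs = [make_segment(make_roi(vessel=350.0), seg_id=i) for i in range(1, 18)]
        segs = [classify(s) for s in segs]
        out = cohort_iq_summary({"P1": segs})
        assert out["per_patient"]["P1"]["overall_attenuation_hu"] == pytest.approx(350.0)
        assert out["patient_diagnostic_fraction"] == 1.0
        assert out["segment_assessable_fraction"] == 1.0

    def test_patient_diagnostic_fraction_half(self):
        lo = [classify(make_segment(make_roi(vessel=290.0), seg_id=i)) for i in (1, 2)]
        hi = [classify(make_segment(make_roi(vessel=310.0), seg_id=i)) for i in (1, 2)]
        out = cohort_iq_summary({"A": lo, "B": hi})
        assert out["patient_diagnostic_fraction"] == 0.5

    def test_zero_assessable_patient_excluded_with_warning(self):
        good = [classify(make_segment(make_roi(), seg_id=1))]
        bad = [SegmentIQ(segment_id=1, vessel="RCA")]
        with pytest.warns(UserWarning, match="no assessable"):
            out = cohort_iq_summary({"A": good, "B": bad})
        assert out["n_patients"] == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            cohort_iq_summary({})


def test_read_segments_csv(tmp_path):
    path = tmp_path / "segments.csv"
    path.write_text(
        "patient_id,segment_id,vessel,vessel_mean_hu,vessel_sd_hu,fat_mean_hu,fat_sd_hu,likert\n"
        "P1,1,RCA,360,40,-80,30,4\n"
        "P1,9,LAD,,,,,1\n"
        "P2,5,LM,250,45,-70,25,\n",
        encoding="utf-8",
    )
    out = read_segments_csv(path)
    assert set(out) == {"P1", "P2"}
    seg1, seg9 = out["P1"]
    assert seg1.assessable and seg1.diagnostic_attenuation and seg1.likert == 4
    assert not seg9.assessable and seg9.likert == 1
    (seg5,) = out["P2"]
    assert seg5.assessable and not seg5.diagnostic_attenuation and seg5.likert is None
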