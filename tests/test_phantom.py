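"""Phantom and cohort generators: oracle equivalence, noise statistics,
calibration convergence, reproducibility."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from mibgquant import planar, spect
from mibgquant.phantom import (
    CohortCalibration,
    PlanarTruth,
    VolumeTruth,
    make_cohort,
    make_planar_pair,
    make_spect_volume,
)


def ratio_se(truth: PlanarTruth, n_heart: int, n_med: int) -> float:
    """Delta-method SE of the H/M estimate under Poisson counting."""
    r = truth.early_hm
    return r * math.sqrt(
        1.0 / (truth.he * n_heart) + 1.0 / (truth.me * n_med)
    )


class TestPlanarPhantom:
    truth = PlanarTruth(he=162.0, me=100.0, hl=122.0, ml=80.0)

    def test_noiseless_pipeline_reproduces_truth_exactly(self):
        pair = make_planar_pair(self.truth)
        m = planar.compute_metrics(pair.early, pair.late, pair.rois)
        assert m.he == self.truth.he and m.me == self.truth.me
        assert m.hl == self.truth.hl and m.ml == self.truth.ml
        assert m.early_hm == pytest.approx(1.62, abs=1e-12)
        assert m.wo_percent == pytest.approx(self.truth.wo_percent, abs=1e-12)

    def test_zero_washout_construction(self):
        he, me, ml = 221.0, 100.0, 80.0
        hl = ml + (he - me) / planar.DEFAULT_DECAY_FACTOR
        truth = PlanarTruth(he=he, me=me, hl=hl, ml=ml)
        pair = make_planar_pair(truth)
        m = planar.compute_metrics(pair.early, pair.late, pair.rois)
        # hl is painted as a rounded integer, so allow the discretization
        assert m.wo_percent == pytest.approx(0.0, abs=0.5)
        assert truth.wo_percent == pytest.approx(0.0, abs=1e-9)

    def test_poisson_estimate_within_three_se(self):
        pair = make_planar_pair(self.truth, noise=True, seed=42)
        est = planar.hm_ratio(pair.early, pair.rois.heart, pair.rois.mediastinum)
        se = ratio_se(self.truth, int(pair.heart_mask.sum()), 49)
        assert abs(est - self.truth.early_hm) < 3.0 * se

    def test_three_se_empirical_coverage(self):
        n_rep, miss = 200, 0
        se = None
        for s in range(n_rep):
            pair = make_planar_pair(self.truth, noise=True, seed=s)
            if se is None:
                se = ratio_se(self.truth, int(pair.heart_mask.sum()), 49)
            est = planar.hm_ratio(pair.early, pair.rois.heart, pair.rois.mediastinum)
            miss += abs(est - self.truth.early_hm) >= 3.0 * se
        assert miss / n_rep <= 0.02  # nominal 0.3%

    def test_bias_vanishes_with_counts(self):
        # averaged estimate stays within 3 SE of truth at three count levels
        n_rep = 25
        for scale in (1, 8, 64):
            truth = PlanarTruth(
                he=self.truth.he * scale, me=self.truth.me * scale,
                hl=self.truth.hl * scale, ml=self.truth.ml * scale,
            )
            ests = []
            for s in range(n_rep):
                pair = make_planar_pair(truth, noise=True, seed=1000 * scale + s)
                ests.append(
                    planar.hm_ratio(pair.early, pair.rois.heart, pair.rois.mediastinum)
                )
            se = ratio_se(truth, int(pair.heart_mask.sum()), 49)
            assert abs(np.mean(ests) - 1.62) < 3.0 * se / math.sqrt(n_rep)

    def test_auto_roi_lands_in_generating_band(self):
        pair = make_planar_pair(self.truth, noise=True, seed=3)
        roi = planar.auto_mediastinal_roi(pair.early)
        window = pair.mediastinum_band_mask[
            roi.row : roi.row + 7, roi.col : roi.col + 7
        ]
        assert window.all()

    def test_same_seed_byte_identical(self):
        a = make_planar_pair(self.truth, noise=True, seed=5)
        b = make_planar_pair(self.truth, noise=True, seed=5)
        assert np.array_equal(a.early.counts, b.early.counts)
        assert np.array_equal(a.late.counts, b.late.counts)
        assert a.early.counts.tobytes() == b.early.counts.tobytes()

    def test_invalid_truth_and_shape(self):
        with pytest.raises(ValueError):
            PlanarTruth(he=100.0, me=100.0, hl=50.0, ml=40.0)
        with pytest.raises(ValueError):
            PlanarTruth(he=100.0, me=50.0, hl=-1.0, ml=0.0)
        with pytest.raises(ValueError):
            make_planar_pair(self.truth, image_shape=(20, 20))


class TestSpectPhantom:
    def test_noiseless_volume_reproduces_truth(self):
        u = np.full(17, 100.0)
        u[[1, 6, 13, 16]] = [80.0, 55.0, 35.0, 60.0]
        phantom = make_spect_volume(VolumeTruth(segment_uptake=u))
        np.testing.assert_allclose(spect.segment_uptake(phantom.volume), u, atol=1e-12)

    def test_same_seed_byte_identical(self):
        truth = VolumeTruth(segment_uptake=np.full(17, 100.0))
        a = make_spect_volume(truth, noise=True, seed=11)
        b = make_spect_volume(truth, noise=True, seed=11)
        assert a.volume.counts.tobytes() == b.volume.counts.tobytes()

    def test_geometry_must_fit_volume(self):
        with pytest.raises(ValueError):
            VolumeTruth(segment_uptake=np.full(17, 100.0), outer_radius=40.0)
        with pytest.raises(ValueError):
            VolumeTruth(segment_uptake=np.full(17, 100.0), apex_slice=20, base_slice=10)

    def test_uptake_normalization_required(self):
        with pytest.raises(ValueError):
            VolumeTruth(segment_uptake=np.full(17, 90.0))


class TestCohortGenerator:
    def test_law_of_large_numbers_calibration(self):
        calib = CohortCalibration()
        df = make_cohort(calib, seed=123, n=10_000)
        n = len(df)
        for name in ("age", "lvef", "early_hm", "late_hm", "wo_percent", "ess", "lss"):
            mean, sd = getattr(calib, name if name != "wo_percent" else "wo_percent")
            col = {"wo_percent": "wo_percent"}.get(name, name)
            assert abs(df[col].mean() - mean) < 3.0 * sd / math.sqrt(n), name
        for col, p in (
            ("sex_male", calib.p_male),
            ("med_mra", calib.p_mra),
            ("ischemic", calib.p_ischemic),
        ):
            se = math.sqrt(p * (1 - p) / n)
            assert abs(df[col].mean() - p) < 3.0 * se, col

    def test_copula_correlations_recovered(self):
        df = make_cohort(seed=7, n=10_000)
        assert abs(np.corrcoef(df.ess, df.lss)[0, 1] - 0.8) < 0.05
        assert abs(np.corrcoef(df.late_hm, df.ess)[0, 1] + 0.4) < 0.05

    def test_event_type_composition_matches_calibration(self):
        calib = CohortCalibration()
        df = make_cohort(calib, seed=9, n=20_000)
        events = df[df.event_type != "none"]
        probs = dict(
            zip(
                ("sustained_VT", "appropriate_ICD_therapy", "resuscitated_arrest", "SCD"),
                calib.event_type_probs,
            )
        )
        for etype, p in probs.items():
            frac = (events.event_type == etype).mean()
            se = math.sqrt(p * (1 - p) / len(events))
            assert abs(frac - p) < 3.5 * se, etype

    def test_scores_are_integers_in_range(self):
        df = make_cohort(seed=1, n=2000)
        for col in ("ess", "lss"):
            assert df[col].dtype.kind == "i"
            assert df[col].between(0, 68).all()
        assert (df.dss == df.ess - df.lss).all()

    def test_zero_hazard_multipliers_give_no_events(self):
        calib = dataclasses.replace(
            CohortCalibration(), hm_category_multipliers=(0.0, 0.0, 0.0)
        )
        df = make_cohort(calib, seed=2, n=500)
        assert (df.event_type == "none").all()
        assert df.event_month.isna().all()

    def test_same_seed_identical_cohort(self):
        a = make_cohort(seed=42)
        b = make_cohort(seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_followup_invariants(self):
        df = make_cohort(seed=3, n=2000)
        assert (df.followup_months > 0).all()
        has_event = df.event_type != "none"
        assert np.allclose(
            df.loc[has_event, "event_month"], df.loc[has_event, "followup_months"]
        )

    def test_degenerate_n_rejected(self):
        with pytest.raises(ValueError):
            make_cohort(seed=0, n=5)

    def test_calibration_validation(self):
        with pytest.raises(ValueError):
            CohortCalibration(p_male=1.5)
        with pytest.raises(ValueError):
            CohortCalibration(event_type_probs=(0.5, 0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            CohortCalibration(ess=(31.4, 0.0))
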