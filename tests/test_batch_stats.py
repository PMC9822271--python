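"""Type distributions, histograms, drift profiles and RMS roughness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fdclass.batch_stats import (
    adhesion_histogram,
    batch_report,
    drift_profile,
    rms_roughness,
    success_rate,
    type_distribution,
)
from fdclass.preprocess import ParameterError


def results_frame(codes, f_max=None):
    return pd.DataFrame(
        {
            "class_code": list(codes),
            "f_max_pN": f_max if f_max is not None else [0.0] * len(codes),
        }
    )


class TestTypeDistribution:
    def test_two_class_split(self):
        dist = type_distribution(results_frame(["Type1", "Type3"]))
        assert dist.percentages["Type1"] == dist.percentages["Type3"] == 50.0
        assert dist.n_total == 2

    def test_single_class(self):
        dist = type_distribution(results_frame(["Type4"] * 250))
        assert dist.percentages["Type4"] == 100.0
        assert sum(dist.counts.values()) == dist.n_total == 250

    def test_percentages_sum_to_100(self):
        dist = type_distribution(results_frame(["Type1", "Type2", "Type3", "Type7", "Type7"]))
        assert sum(dist.percentages.values()) == pytest.approx(100.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            type_distribution(results_frame([]))


class TestSuccessRate:
    def test_half_successful(self):
        assert success_rate(type_distribution(results_frame(["Type1", "Type3"]))) == 0.5

    def test_all_artifacts(self):
        assert success_rate(type_distribution(results_frame(["Type7"] * 4))) == 0.0

    @given(st.lists(st.sampled_from([f"Type{i}" for i in range(1, 8)]), min_size=1, max_size=60))
    def test_success_and_failure_fractions_sum_to_one(self, codes):
        dist = type_distribution(results_frame(codes))
        failure = sum(dist.counts[c] for c in ("Type1", "Type2", "Type7")) / dist.n_total
        assert success_rate(dist) + failure == pytest.approx(1.0, abs=1e-12)


class TestAdhesionHistogram:
    def test_direct_binning(self):
        frame = results_frame(["Type2", "Type3", "Type3"], f_max=[100.0, 420.0, 430.0])
        bins, counts = adhesion_histogram(frame, bin_width=50.0)
        assert counts[np.searchsorted(bins, 100.0, "right") - 1] == 1
        assert counts[np.searchsorted(bins, 420.0, "right") - 1] == 2
        assert counts.sum() == 3

    def test_empty_all_zero(self):
        _, counts = adhesion_histogram(results_frame([]), bin_width=50.0)
        assert counts.sum() == 0

    def test_overflow_bin_conserves_counts(self):
        frame = results_frame(["Type7"] * 3, f_max=[2500.0, 3000.0, 10.0])
        _, counts = adhesion_histogram(frame, bin_width=50.0)
        assert counts.sum() == 3
        assert counts[-1] == 2

    def test_bad_bin_width(self):
        with pytest.raises(ParameterError):
            adhesion_histogram(results_frame(["Type1"]), bin_width=0.0)


class TestDriftProfile:
    def test_uniform_composition_zero_deltas(self):
        codes = (["Type1"] * 25 + ["Type3"] * 25) * 4
        profile = drift_profile(results_frame(codes), window_size=50)
        assert np.allclose(profile.deltas.to_numpy(), 0.0)

    def test_hand_computed_two_windows(self):
        codes = ["Type1"] * 50 + ["Type3"] * 50
        profile = drift_profile(results_frame(codes), window_size=50)
        assert profile.deltas["Type1"].tolist() == [50.0, -50.0]
        assert profile.deltas["Type3"].tolist() == [-50.0, 50.0]

    def test_window_larger_than_batch_rejected(self):
        with pytest.raises(ParameterError):
            drift_profile(results_frame(["Type1"] * 10), window_size=50)

    def test_partial_final_window_flagged(self):
        profile = drift_profile(results_frame(["Type1"] * 120), window_size=50)
        assert profile.complete.tolist() == [True, True, False]

    @given(
        st.lists(st.sampled_from([f"Type{i}" for i in range(1, 8)]), min_size=100, max_size=100)
    )
    def test_window_mean_zero_identity(self, codes):
        # equal partitioning windows: per-class deltas average to exactly zero
        profile = drift_profile(results_frame(codes), window_size=20)
        assert np.allclose(profile.deltas.mean(axis=0).to_numpy(), 0.0, atol=1e-12)

    def test_stationary_series_shows_no_trend(self):
        # i.i.d. class draws: regression of delta on window index should be flat
        rng = np.random.default_rng(1)
        codes = rng.choice(
            [f"Type{i}" for i in range(1, 8)], size=1000, p=[0.06, 0.04, 0.28, 0.37, 0.14, 0.1, 0.01]
        )
        profile = drift_profile(results_frame(codes), window_size=50)
        x = np.arange(len(profile.deltas))
        for code in profile.deltas.columns:
            y = profile.deltas[code].to_numpy()
            slope, intercept = np.polyfit(x, y, 1)
            resid = y - (slope * x + intercept)
            se = np.sqrt(resid.var(ddof=2) / np.sum((x - x.mean()) ** 2))
            if se > 0:
                assert abs(slope) / se < 3.0


class TestRmsRoughness:
    def test_constant_map_zero(self):
        assert rms_roughness(np.full((8, 8), 3.0)) == 0.0

    def test_checkerboard_unit(self):
        yy, xx = np.mgrid[0:16, 0:16]
        board = np.where((xx + yy) % 2 == 0, 1.0, -1.0)
        assert rms_roughness(board) == pytest.approx(1.0, abs=1e-12)

    def test_gaussian_sigma_recovered(self, rng):
        h = rng.normal(0.0, 2.0, (512, 512))
        assert rms_roughness(h) == pytest.approx(2.0, abs=0.05)

    def test_plane_correction_removes_tilt(self):
        yy, xx = np.mgrid[0:64, 0:64]
        tilted = 0.1 * xx + 0.05 * yy + 1.0
        assert rms_roughness(tilted, plane_correct=True) == pytest.approx(0.0, abs=1e-9)
        assert rms_roughness(tilted) > 1.0

    def test_invalid_maps_rejected(self):
        with pytest.raises(ValueError):
            rms_roughness(np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            rms_roughness(np.array([[1.0, np.nan], [0.0, 1.0]]))


def test_batch_report_serializable():
    import json

    codes = ["Type1"] * 20 + ["Type3"] * 60 + ["Type4"] * 20
    frame = results_frame(codes, f_max=[0.0] * 20 + [400.0] * 60 + [500.0] * 20)
    report = batch_report(frame, window_size=50, bin_width=50.0)
    text = json.dumps(report)
    assert report["n_total"] == 100
    assert report["success_rate"] == pytest.approx(0.8)
    assert "drift" in json.loads(text)
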