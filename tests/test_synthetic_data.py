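"""Worm-like-chain model, condition presets and curve generation."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fdclass.classifier import CurveClass, analyze_curve
from fdclass.synthetic_data import (
    DEFAULT_MODEL,
    TetherModel,
    preset_blocked,
    preset_pristine,
    simulate_batch,
    simulate_curve,
    simulate_curves,
    single_rupture_curve,
    wlc_extension_at_force,
    wlc_force,
)


class TestWlcForce:
    def test_zero_extension(self):
        assert wlc_force(0.0) == 0.0

    def test_half_contour(self):
        # (kT/p) * [1/(4*0.25) - 1/4 + 1/2] = (4.114/0.38) * 1.25
        assert wlc_force(25.0) == pytest.approx(4.114 / 0.38 * 1.25, rel=1e-12)
        assert wlc_force(25.0) == pytest.approx(13.53, abs=0.01)

    def test_ninety_percent_contour(self):
        # (kT/p) * [1/(4*0.01) - 1/4 + 0.9] = (4.114/0.38) * 25.65
        assert wlc_force(45.0) == pytest.approx(4.114 / 0.38 * 25.65, rel=1e-12)
        assert wlc_force(45.0) == pytest.approx(277.7, abs=0.1)

    @pytest.mark.parametrize("x", [-1.0, 50.0, 60.0])
    def test_domain_errors(self, x):
        with pytest.raises(ValueError):
            wlc_force(x)

    @given(data=st.data())
    def test_strict_monotonicity(self, data):
        x1 = data.draw(st.floats(0.0, 49.0))
        x2 = data.draw(st.floats(0.0, 49.0))
        lo, hi = sorted((x1, x2))
        if hi > lo:
            assert wlc_force(hi) > wlc_force(lo)

    def test_low_force_linear_limit(self):
        m = DEFAULT_MODEL
        for frac in (0.01, 0.03, 0.05):
            x = frac * m.contour_length
            linear = 1.5 * m.kT * x / (m.persistence_length * m.contour_length)
            assert wlc_force(x) == pytest.approx(linear, rel=0.05)

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            TetherModel(contour_length=0.3, persistence_length=0.38)


class TestWlcInverse:
    def test_zero_force(self):
        assert wlc_extension_at_force(0.0) == 0.0

    def test_half_contour_inverse(self):
        x = wlc_extension_at_force(4.114 / 0.38 * 1.25)
        assert x / 50.0 == pytest.approx(0.5, abs=1e-4)

    @pytest.mark.parametrize("force", [10.0, 100.0, 1000.0])
    def test_composition_identity(self, force):
        assert wlc_force(wlc_extension_at_force(force)) == pytest.approx(force, abs=1e-6)

    def test_negative_force_rejected(self):
        with pytest.raises(ValueError):
            wlc_extension_at_force(-1.0)


class TestPresets:
    @pytest.mark.parametrize("preset", [preset_pristine, preset_blocked])
    def test_mixture_sums_to_one(self, preset):
        assert sum(preset().mixture.values()) == pytest.approx(1.0, abs=1e-12)

    def test_pristine_frequency_ordering(self):
        m = preset_pristine().mixture
        assert (
            m[CurveClass.TYPE4] > m[CurveClass.TYPE3] > m[CurveClass.TYPE5] > m[CurveClass.TYPE6]
        )

    def test_blocked_single_outnumbers_multiple(self):
        m = preset_blocked().mixture
        assert m[CurveClass.TYPE3] > m[CurveClass.TYPE4]
        assert max(m, key=m.get) is CurveClass.TYPE1
        assert m[CurveClass.TYPE1] + m[CurveClass.TYPE2] > 0.5


NOISE_FREE = dataclasses.replace(preset_pristine(), noise_sigma=0.0, tilt_sd=0.0)


class TestSimulateCurve:
    def test_type1_no_events_noise_free(self):
        feats, cls, _ = analyze_curve(simulate_curve(CurveClass.TYPE1, condition=NOISE_FREE, rng=0))
        assert feats.n_events == 0
        assert cls is CurveClass.TYPE1

    def test_type3_single_high_event(self):
        feats, cls, _ = analyze_curve(simulate_curve(CurveClass.TYPE3, condition=NOISE_FREE, rng=7))
        assert feats.n_events == 1
        assert 200 < feats.f_max <= 650
        assert cls is CurveClass.TYPE3

    def test_type6_multiple_very_high(self):
        feats, cls, _ = analyze_curve(simulate_curve(CurveClass.TYPE6, condition=NOISE_FREE, rng=3))
        assert feats.n_events >= 2
        assert feats.f_max > 650
        assert cls is CurveClass.TYPE6

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            simulate_curve("Type9")

    def test_true_class_recorded(self):
        curve = simulate_curve(CurveClass.TYPE5, condition=preset_pristine(), rng=1)
        assert curve.metadata.true_class == "Type5"

    def test_single_rupture_curve_reaches_prescribed_force(self):
        curve = single_rupture_curve(437.0)
        feats, cls, _ = analyze_curve(curve)
        assert feats.n_events == 1
        assert feats.f_max == pytest.approx(437.0, abs=1e-6)
        assert cls is CurveClass.TYPE3


class TestSimulateBatch:
    def test_batch_files_and_manifest(self, tmp_path):
        manifest = simulate_batch(preset_pristine(), 250, tmp_path / "b", seed=1)
        assert len(manifest) == 250
        assert len(list((tmp_path / "b").glob("curve_*.tsv"))) == 250
        assert (tmp_path / "b" / "manifest.csv").exists()

    def test_batch_reproducible_byte_identical(self, tmp_path):
        simulate_batch(preset_pristine(), 20, tmp_path / "a", seed=9)
        simulate_batch(preset_pristine(), 20, tmp_path / "b", seed=9)
        assert (tmp_path / "a" / "manifest.csv").read_bytes() == (
            tmp_path / "b" / "manifest.csv"
        ).read_bytes()
        for p in sorted((tmp_path / "a").glob("curve_*.tsv")):
            assert p.read_bytes() == (tmp_path / "b" / p.name).read_bytes()

    def test_mixture_fractions_binomial(self):
        cond = preset_blocked()
        curves = simulate_curves(cond, 2000, seed=4)
        frac = np.mean([c.metadata.true_class == "Type1" for c in curves])
        p = cond.mixture[CurveClass.TYPE1]
        assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / 2000)

    def test_different_seeds_differ(self):
        a = simulate_curves(preset_pristine(), 10, seed=1)
        b = simulate_curves(preset_pristine(), 10, seed=2)
        assert any(not np.array_equal(x.force, y.force) for x, y in zip(a, b))
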