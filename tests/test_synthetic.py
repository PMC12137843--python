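"""Phantom-data generators: ground-truth contracts and determinism."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import spearmanr

from cellstiff.synthetic import (DCSequence, PhantomParams,
                                 generate_dc_sequence, generate_force_curve,
                                 generate_phantom_cell,
                                 generate_phantom_dataset, halo_contrast,
                                 hertz_force, interior_variance,
                                 param_from_stiffness, read_dc_sequence,
                                 read_force_curve, stiffness_from_param,
                                 write_dc_sequence, write_force_curve)


class TestStiffnessParamMap:
    @pytest.mark.parametrize("s,expected", [
        (0.0, 200.0),
        (1.0, 3000.0),
        (0.5, math.sqrt(200.0 * 3000.0)),  # geometric midpoint of log map
    ])
    def test_anchors(self, s, expected):
        assert stiffness_from_param(s) == pytest.approx(expected, rel=1e-12)

    def test_out_of_domain(self):
        for s in (-0.01, 1.01):
            with pytest.raises(ValueError):
                stiffness_from_param(s)

    @given(st.floats(0.0, 1.0))
    def test_bijection(self, s):
        e = stiffness_from_param(s)
        assert 200.0 <= e <= 3000.0
        assert param_from_stiffness(e) == pytest.approx(s, abs=1e-9)

    def test_strictly_increasing(self):
        grid = np.linspace(0, 1, 101)
        e = stiffness_from_param(grid)
        assert np.all(np.diff(e) > 0)


class TestPhantomCell:
    def test_soft_halo_contrast_exceeds_half_gain(self):
        p = PhantomParams(s=0.0, seed=1)
        img = generate_phantom_cell(p)
        assert halo_contrast(img, p.cell_radius) >= 0.5 * p.halo_gain

    def test_stiff_interior_variance_larger(self):
        p_soft = PhantomParams(s=0.0, seed=1)
        p_stiff = PhantomParams(s=1.0, seed=1)
        soft = generate_phantom_cell(p_soft)
        stiff = generate_phantom_cell(p_stiff)
        assert interior_variance(stiff, 30.0) > interior_variance(soft, 30.0)

    def test_seeded_determinism(self):
        p = PhantomParams(s=0.37, seed=42)
        a = generate_phantom_cell(p)
        b = generate_phantom_cell(p)
        assert np.array_equal(a.pixels, b.pixels)

    def test_label_and_modulus_ground_truth(self):
        soft = generate_phantom_cell(PhantomParams(s=0.2, seed=0))
        stiff = generate_phantom_cell(PhantomParams(s=0.8, seed=0))
        assert soft.label == "soft" and stiff.label == "stiff"
        assert soft.modulus_pa == pytest.approx(stiffness_from_param(0.2))

    def test_geometry_error(self):
        with pytest.raises(ValueError):
            PhantomParams(cell_radius=60.0, crop_size=100)

    def test_monotone_feature_link(self):
        """Interior variance rises and halo contrast falls with s
        (Spearman |rho| >= 0.9 over an s grid, fixed seed set)."""
        grid = np.linspace(0, 1, 11)
        halo, var = [], []
        for s in grid:
            imgs = [generate_phantom_cell(PhantomParams(s=s, seed=k))
                    for k in range(5)]
            halo.append(np.mean([halo_contrast(i, 30.0) for i in imgs]))
            var.append(np.mean([interior_variance(i, 30.0) for i in imgs]))
        assert spearmanr(var, grid).statistic >= 0.9
        assert spearmanr(halo, grid).statistic <= -0.9

    def test_three_channel_option(self):
        img = generate_phantom_cell(PhantomParams(s=0.1, seed=3), channels=3)
        assert img.pixels.shape == (100, 100, 3)
        assert np.array_equal(img.pixels[..., 0], img.pixels[..., 2])


class TestPhantomDataset:
    def test_counts_and_labels(self):
        imgs = generate_phantom_dataset(12, 8, seed=7)
        assert len(imgs) == 20
        assert sum(im.label == "soft" for im in imgs) == 12
        assert sum(im.label == "stiff" for im in imgs) == 8

    def test_stiff_only(self):
        imgs = generate_phantom_dataset(0, 5, seed=7)
        assert len(imgs) == 5
        assert all(im.label == "stiff" for im in imgs)

    def test_determinism(self):
        a = generate_phantom_dataset(5, 5, seed=3)
        b = generate_phantom_dataset(5, 5, seed=3)
        assert all(np.array_equal(x.pixels, y.pixels) for x, y in zip(a, b))

    def test_overlapping_intervals_warn(self):
        with pytest.warns(UserWarning, match="overlap"):
            generate_phantom_dataset(2, 2, (0.0, 0.6), (0.4, 1.0), seed=0)


class TestForceCurve:
    def test_closed_form_value(self):
        # F = (2/pi) tan(18 deg) (1000/0.75) (1e-6)^2 at full indentation
        curve = generate_force_curve(1000.0, max_indentation=1e-6,
                                     noise_sd=0.0)
        expected = (2 / math.pi) * math.tan(math.radians(18)) \
            * (1000 / 0.75) * 1e-12
        assert curve.force[-1] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(2.76e-10, rel=5e-3)

    def test_noiseless_curve_is_quadratic(self):
        curve = generate_force_curve(800.0, noise_sd=0.0)
        coef = np.polyfit(curve.indentation, curve.force, 2)
        resid = curve.force - np.polyval(coef, curve.indentation)
        assert np.max(np.abs(resid)) < 1e-18

    def test_zero_indentation_zero_force(self):
        curve = generate_force_curve(500.0, noise_sd=0.0)
        assert curve.indentation[0] == 0.0
        assert curve.force[0] == 0.0

    def test_nonpositive_modulus_rejected(self):
        with pytest.raises(ValueError):
            generate_force_curve(-10.0)

    def test_csv_round_trip(self, tmp_path):
        curve = generate_force_curve(1200.0, noise_sd=1e-12, seed=4)
        write_force_curve(curve, tmp_path / "c.csv")
        back = read_force_curve(tmp_path / "c.csv")
        np.testing.assert_allclose(back.force, curve.force, rtol=1e-12)
        assert back.true_modulus_pa == 1200.0


class TestDCSequence:
    def test_constant_speed_truth_frames(self):
        seq = generate_dc_sequence(diameter=24.0, speed_px_per_frame=2.0,
                                   constriction_x=(100, 140), start_x=0.0)
        assert seq.truth_entry_frame == 50
        assert seq.truth_exit_frame == 70
        transit = (seq.truth_exit_frame - seq.truth_entry_frame) / seq.fps
        assert transit == pytest.approx(0.08)

    def test_seeded_determinism(self):
        a = generate_dc_sequence(seed=5, noise_sd=3.0)
        b = generate_dc_sequence(seed=5, noise_sd=3.0)
        assert np.array_equal(a.frames, b.frames)

    def test_never_exits_error(self):
        with pytest.raises(ValueError, match="positive|exit"):
            generate_dc_sequence(speed_px_per_frame=0.0)

    def test_tiff_round_trip(self, tmp_path):
        seq = generate_dc_sequence(seed=1)
        write_dc_sequence(seq, tmp_path / "seq.tiff")
        back = read_dc_sequence(tmp_path / "seq.tiff")
        assert np.array_equal(back.frames, seq.frames)
        assert back.truth_entry_frame == seq.truth_entry_frame
        assert back.fps == 250.0

    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            DCSequence(frames=np.zeros((5, 10, 10), dtype=np.uint8),
                       constriction_x=(8, 20))


def test_hertz_force_linear_in_modulus():
    d = np.linspace(0, 1e-6, 20)
    np.testing.assert_allclose(hertz_force(d, 2000.0),
                               2 * hertz_force(d, 1000.0), rtol=1e-14)
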