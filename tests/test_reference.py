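"""Hertz force-curve fitting and DC transit-time extraction."""

import numpy as np
import pytest

from cellstiff.reference import (HertzFitResult, TransitRecord,
                                 bin_by_diameter, cell_modulus,
                                 extract_transit_times, fit_hertz)
from cellstiff.synthetic import (DCSequence, ForceCurve, generate_dc_sequence,
                                 generate_force_curve)


class TestHertzFit:
    def test_noiseless_round_trip_known_contact(self):
        curve = generate_force_curve(1000.0, noise_sd=0.0)
        res = fit_hertz(curve, contact_point_m=0.0)
        assert res.modulus_pa == pytest.approx(1000.0, rel=1e-12)

    def test_noiseless_round_trip_estimated_contact(self):
        curve = generate_force_curve(1000.0, noise_sd=0.0)
        res = fit_hertz(curve)
        assert res.modulus_pa == pytest.approx(1000.0, rel=1e-3)

    def test_linearity_in_modulus(self):
        curve = generate_force_curve(700.0, noise_sd=0.0)
        doubled = ForceCurve(indentation=curve.indentation,
                             force=2.0 * curve.force,
                             probe_half_angle=curve.probe_half_angle,
                             poisson_ratio=curve.poisson_ratio)
        e1 = fit_hertz(curve, contact_point_m=0.0).modulus_pa
        e2 = fit_hertz(doubled, contact_point_m=0.0).modulus_pa
        assert e2 == pytest.approx(2.0 * e1, rel=1e-12)

    def test_contact_point_recovery_with_baseline(self):
        # flat pre-contact baseline followed by the quadratic regime
        from cellstiff.synthetic import hertz_force
        contact = 3e-7
        delta = np.linspace(0, 1.3e-6, 130)
        post = np.maximum(delta - contact, 0.0)
        curve = ForceCurve(indentation=delta, force=hertz_force(post, 900.0))
        res = fit_hertz(curve)
        assert res.contact_point_m == pytest.approx(contact, abs=2e-8)
        assert res.modulus_pa == pytest.approx(900.0, rel=1e-2)

    def test_noisy_median_within_ten_percent(self):
        clean = generate_force_curve(1000.0, noise_sd=0.0)
        scale = 0.05 * clean.force.max()  # 5% relative noise
        fitted = [fit_hertz(generate_force_curve(
            1000.0, noise_sd=scale, seed=s)).modulus_pa for s in range(50)]
        assert np.median(fitted) == pytest.approx(1000.0, rel=0.10)

    def test_all_zero_force_rejected(self):
        curve = ForceCurve(indentation=np.linspace(0, 1e-6, 20),
                           force=np.zeros(20))
        with pytest.raises(ValueError):
            fit_hertz(curve)

    def test_result_requires_positive_modulus(self):
        with pytest.raises(ValueError):
            HertzFitResult(modulus_pa=-10.0, contact_point_m=0.0, rss=0.0,
                           n_points=10)


class TestCellModulus:
    def _fits(self, values):
        return [HertzFitResult(v, 0.0, 0.0, 10) for v in values]

    def test_mean_of_three(self):
        assert cell_modulus(self._fits([900, 1000, 1100])) == 1000.0

    def test_single_fit_warns(self):
        with pytest.warns(UserWarning, match="3 measurements"):
            assert cell_modulus(self._fits([800])) == 800.0

    def test_permutation_invariant(self):
        a = cell_modulus(self._fits([1, 2, 3]))
        b = cell_modulus(self._fits([3, 1, 2]))
        assert a == b

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cell_modulus([])


class TestTransitExtraction:
    def test_noiseless_matches_ground_truth(self):
        seq = generate_dc_sequence(diameter=24.0, speed_px_per_frame=2.0,
                                   constriction_x=(100, 140), start_x=0.0)
        rec = extract_transit_times(seq)
        assert rec.entry_frame == seq.truth_entry_frame == 50
        assert rec.exit_frame == seq.truth_exit_frame == 70
        assert rec.transit_s == pytest.approx(0.08)
        assert rec.fps == 250.0

    def test_noisy_frames_within_one_frame(self):
        seq = generate_dc_sequence(diameter=24.0, speed_px_per_frame=2.0,
                                   noise_sd=5.0, seed=9)
        rec = extract_transit_times(seq)
        assert abs(rec.entry_frame - seq.truth_entry_frame) <= 1
        assert abs(rec.exit_frame - seq.truth_exit_frame) <= 1

    def test_diameter_estimate(self):
        seq = generate_dc_sequence(diameter=24.0, speed_px_per_frame=2.0)
        rec = extract_transit_times(seq)
        assert rec.diameter_px == pytest.approx(24.0, rel=0.05)

    def test_two_cells_rejected(self):
        frames = np.zeros((5, 128, 256), dtype=np.uint8)
        yy, xx = np.mgrid[0:128, 0:256]
        for t in range(5):
            frames[t][(xx - 40) ** 2 + (yy - 40) ** 2 <= 100] = 200
            frames[t][(xx - 200) ** 2 + (yy - 90) ** 2 <= 100] = 200
        seq = DCSequence(frames=frames, constriction_x=(100, 140),
                         truth_entry_frame=0, truth_exit_frame=1)
        with pytest.raises(ValueError, match="multiple cells"):
            extract_transit_times(seq)

    def test_undetected_cell_rejected(self):
        frames = np.zeros((5, 128, 256), dtype=np.uint8)
        seq = DCSequence(frames=frames, constriction_x=(100, 140),
                         truth_entry_frame=0, truth_exit_frame=1)
        with pytest.raises(ValueError, match="never detected"):
            extract_transit_times(seq)


class TestDiameterBinning:
    def _records(self, diam_transit):
        return [TransitRecord(f"c{i}", d, 0, int(round(t * 250)), 250.0)
                for i, (d, t) in enumerate(diam_transit)]

    def test_half_open_bins(self):
        recs = self._records([(10.1, 0.1), (10.9, 0.2), (12.0, 0.3)])
        bins = bin_by_diameter(recs, bin_width_px=1.0)
        by_lo = {b["bin_lo_px"]: b for b in bins}
        assert by_lo[10.0]["n"] == 2
        assert by_lo[12.0]["n"] == 1
        assert 11.0 not in by_lo

    def test_single_bin_when_same_diameter(self):
        recs = self._records([(15.2, 0.1)] * 4)
        bins = bin_by_diameter(recs, bin_width_px=1.0)
        assert len(bins) == 1 and bins[0]["n"] == 4

    def test_record_conservation(self):
        rng = np.random.default_rng(0)
        recs = self._records([(float(d), float(t)) for d, t in zip(
            rng.uniform(8, 20, 40), rng.uniform(0.05, 0.5, 40))])
        bins = bin_by_diameter(recs, bin_width_px=2.0)
        assert sum(b["n"] for b in bins) == 40

    def test_median_shift_equivariance(self):
        recs = self._records([(10.5, 0.1), (10.6, 0.2), (10.7, 0.3)])
        shifted = self._records([(10.5, 0.2), (10.6, 0.3), (10.7, 0.4)])
        m0 = bin_by_diameter(recs, 1.0)[0]["median_transit_s"]
        m1 = bin_by_diameter(shifted, 1.0)[0]["median_transit_s"]
        assert m1 == pytest.approx(m0 + 0.1)

    def test_bad_width_rejected(self):
        with pytest.raises(ValueError):
            bin_by_diameter(self._records([(10.0, 0.1)]), 0.0)
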