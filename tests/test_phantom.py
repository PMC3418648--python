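"""Phantom generator: kinematics, rendering and ground-truth consistency."""

import numpy as np
import pytest
from scipy.signal import find_peaks

from imbiomark import io, phantom
from imbiomark.config import AcquisitionConfig, ConfigurationError, \
    PhantomConfig


class TestScatterers:
    def test_same_seed_identical(self, tiny_phantom, default_acq):
        s1 = phantom.generate_scatterers(tiny_phantom, default_acq)
        s2 = phantom.generate_scatterers(tiny_phantom, default_acq)
        np.testing.assert_array_equal(s1.y_um, s2.y_um)
        np.testing.assert_array_equal(s1.x_um, s2.x_um)
        np.testing.assert_array_equal(s1.amplitude, s2.amplitude)

    def test_zero_lumen_density_puts_all_scatterers_in_walls(
            self, tiny_phantom, default_acq):
        ph = tiny_phantom.replace(lumen_density_per_mm2=0.0)
        s = phantom.generate_scatterers(ph, default_acq)
        assert len(s) > 0
        assert not np.any(s.region == io.LUMEN)
        b = phantom.vessel_boundaries(ph)
        in_near = (s.y_um >= b["near_outer"]) & (s.y_um <= b["near_inner"])
        in_far = (s.y_um >= b["far_inner"]) & (s.y_um <= b["far_outer"])
        assert np.all(in_near | in_far)

    def test_count_matches_density_area_product(self, default_acq):
        ph = PhantomConfig(scatterer_density_per_mm2=1000.0, n_lines=32,
                           seed=3)
        s = phantom.generate_scatterers(ph, default_acq)
        lat_mm = ph.n_lines * default_acq.lateral_pitch_um * 1e-3
        area = (2 * ph.wall_thickness_um + ph.lumen_diameter_um) * 1e-3 \
            * lat_mm
        expected = 1000.0 * area
        assert abs(len(s) - expected) <= 3 * np.sqrt(expected)

    def test_wall_amplitudes_scaled_by_echogenicity_ratio(
            self, tiny_phantom, default_acq):
        s = phantom.generate_scatterers(tiny_phantom, default_acq)
        wall = np.isin(s.region, [io.NEAR_WALL, io.FAR_WALL])
        ratio = (np.std(s.amplitude[wall])
                 / np.std(s.amplitude[s.region == io.LUMEN]))
        assert ratio == pytest.approx(
            tiny_phantom.wall_to_lumen_echogenicity_ratio, rel=0.2)


class TestDeformation:
    def test_zero_compression_is_identity(self, tiny_phantom, default_acq):
        s = phantom.generate_scatterers(tiny_phantom, default_acq)
        moved = phantom.deform_scatterers(s, 0.0, tiny_phantom,
                                          amplitude=0.05)
        np.testing.assert_allclose(moved.y_um, s.y_um, atol=1e-12)

    def test_boundary_displacement_is_strain_times_thickness(self):
        # 2 % compression of a 500 um wall moves the inner boundary 10 um
        ph = PhantomConfig(wall_thickness_um=500.0, lumen_diameter_um=600.0)
        b = phantom.vessel_boundaries(ph)
        s = phantom.ScattererSet(
            y_um=np.array([b["near_inner"], b["far_inner"]]),
            x_um=np.zeros(2), amplitude=np.ones(2),
            region=np.array([io.NEAR_WALL, io.FAR_WALL], dtype=np.uint8))
        moved = phantom.deform_scatterers(s, 0.5, ph, amplitude=0.02)
        assert moved.y_um[0] - s.y_um[0] == pytest.approx(-10.0)
        assert moved.y_um[1] - s.y_um[1] == pytest.approx(+10.0)

    def test_interphase_strain_matches_analytic_profile(
            self, tiny_phantom, default_acq):
        # engineering strain between nearby phases from displaced wall
        # scatterers agrees with the analytic compression profile
        ph = tiny_phantom
        b = phantom.vessel_boundaries(ph)
        s = phantom.ScattererSet(
            y_um=np.array([b["near_outer"] + 10.0, b["near_inner"] - 10.0]),
            x_um=np.zeros(2), amplitude=np.ones(2),
            region=np.full(2, io.NEAR_WALL, dtype=np.uint8))
        amp = 0.06
        for ph1, ph2 in [(0.1, 0.2), (0.3, 0.35), (0.6, 0.75)]:
            m1 = phantom.deform_scatterers(s, ph1, ph, amplitude=amp)
            m2 = phantom.deform_scatterers(s, ph2, ph, amplitude=amp)
            gap1 = m1.y_um[1] - m1.y_um[0]
            gap2 = m2.y_um[1] - m2.y_um[0]
            c1 = phantom.cumulative_compression(ph1, amp)
            c2 = phantom.cumulative_compression(ph2, amp)
            expected = (1 - c2) / (1 - c1) - 1
            assert gap2 / gap1 - 1 == pytest.approx(expected, abs=1e-6)


class TestRendering:
    def test_empty_scatterer_set_renders_zero_frame(self, tiny_phantom,
                                                    default_acq):
        empty = phantom.ScattererSet(np.array([]), np.array([]),
                                     np.array([]), np.array([], np.uint8))
        frame = phantom.render_rf_frame(empty, tiny_phantom, default_acq,
                                        noise_std=0.0)
        assert np.all(frame == 0)

    def test_single_scatterer_envelope_peaks_at_its_position(
            self, tiny_phantom, default_acq):
        y_um, x_um = 400.0, 180.0
        one = phantom.ScattererSet(np.array([y_um]), np.array([x_um]),
                                   np.array([1.0]),
                                   np.array([io.LUMEN], np.uint8))
        frame = phantom.render_rf_frame(one, tiny_phantom, default_acq,
                                        noise_std=0.0)
        env = 10 ** (phantom.envelope_db(frame) / 20.0)
        iy, ix = np.unravel_index(np.argmax(env), env.shape)
        assert abs(iy - y_um / default_acq.axial_spacing_um) <= 1
        assert abs(ix - x_um / default_acq.lateral_pitch_um) <= 1

    def test_rendering_is_linear_in_amplitude(self, tiny_phantom,
                                              default_acq):
        s = phantom.generate_scatterers(tiny_phantom, default_acq)
        f1 = phantom.render_rf_frame(s, tiny_phantom, default_acq,
                                     noise_std=0.0)
        s2 = phantom.ScattererSet(s.y_um, s.x_um, 2.0 * s.amplitude,
                                  s.region)
        f2 = phantom.render_rf_frame(s2, tiny_phantom, default_acq,
                                     noise_std=0.0)
        np.testing.assert_allclose(f2, 2.0 * f1, rtol=1e-12, atol=1e-12)


class TestBMode:
    def test_pure_tone_envelope_is_flat(self):
        n = 512
        t = np.arange(n)
        rf = np.cos(2 * np.pi * 0.08 * t)[:, None] * np.ones((1, 8))
        env = 10 ** (phantom.envelope_db(rf) / 20.0)
        interior = env[50:-50]
        np.testing.assert_allclose(interior, 1.0, atol=0.01)

    def test_zero_frame_gives_floor_clipped_bmode(self):
        img = phantom.render_bmode(np.zeros((64, 8)))
        assert img.shape == (64, 8)
        assert np.all(img == 0)

    def test_tenfold_rf_scale_is_twenty_db(self, tiny_phantom, default_acq):
        s = phantom.generate_scatterers(tiny_phantom, default_acq)
        f = phantom.render_rf_frame(s, tiny_phantom, default_acq,
                                    noise_std=0.0)
        d1 = phantom.envelope_db(f)
        d10 = phantom.envelope_db(10.0 * f)
        np.testing.assert_allclose(d10 - d1, 20.0, atol=1e-9)


class TestSequence:
    def test_frame_count_arithmetic(self, default_acq):
        ph = PhantomConfig(heart_rate=360.0, n_cycles=7)
        assert phantom.n_frames_for(ph, default_acq) == 70

    def test_too_few_frames_is_configuration_error(self):
        acq = AcquisitionConfig(frame_rate=1.0)
        ph = PhantomConfig(heart_rate=300.0, n_cycles=1)
        with pytest.raises(ConfigurationError):
            phantom.n_frames_for(ph, acq)

    def test_zero_peak_strain_gives_zero_ground_truth(self, default_acq):
        ph = PhantomConfig(peak_axial_strain=0.0, n_lines=8, n_cycles=2,
                           lumen_diameter_um=300.0, margin_um=80.0,
                           scatterer_density_per_mm2=300.0, seed=1)
        _, _, gt = phantom.generate_sequence(ph, default_acq)
        np.testing.assert_array_equal(gt.true_strain, 0.0)

    def test_peak_interframe_strain_equals_configured_peak(
            self, tiny_sequence, tiny_phantom):
        _, _, gt = tiny_sequence
        assert np.max(np.abs(gt.true_strain)) == pytest.approx(
            tiny_phantom.peak_axial_strain, abs=1e-9)

    def test_ground_truth_peak_spacing_follows_heart_rate(self, default_acq):
        # 351 bpm at 60 frames/s -> ~10.26 frames per cycle
        ph = PhantomConfig(heart_rate=351.0, n_cycles=7)
        phases = phantom.frame_phases(ph, default_acq)
        amp = phantom.compression_amplitude(ph, default_acq)
        c = phantom.cumulative_compression(phases, amp)
        strain = (c[1:] - c[:-1]) / (1 - c[:-1])
        peaks, _ = find_peaks(strain)
        spacing = np.diff(peaks)
        assert set(spacing.tolist()) <= {10, 11}

    def test_sequences_are_bit_identical_across_runs(self, tiny_phantom,
                                                     default_acq):
        rf1, bm1, gt1 = phantom.generate_sequence(tiny_phantom, default_acq)
        rf2, bm2, gt2 = phantom.generate_sequence(tiny_phantom, default_acq)
        np.testing.assert_array_equal(rf1.frames, rf2.frames)
        np.testing.assert_array_equal(bm1.frames, bm2.frames)
        np.testing.assert_array_equal(gt1.true_strain, gt2.true_strain)

    def test_exported_strain_consistent_with_displacement_field(
            self, tiny_phantom, default_acq):
        # finite differences of the analytic scatterer displacement
        # across the wall reproduce the exported strain series
        ph = tiny_phantom
        _, _, gt = phantom.generate_sequence(ph, default_acq)
        b = phantom.vessel_boundaries(ph)
        s = phantom.ScattererSet(
            y_um=np.array([b["near_outer"], b["near_inner"]]),
            x_um=np.zeros(2), amplitude=np.ones(2),
            region=np.full(2, io.NEAR_WALL, dtype=np.uint8))
        amp = phantom.compression_amplitude(ph, default_acq)
        gaps = []
        for phi in gt.phase:
            m = phantom.deform_scatterers(s, phi, ph, amplitude=amp)
            gaps.append(m.y_um[1] - m.y_um[0])
        gaps = np.asarray(gaps)
        fd_strain = (gaps[:-1] - gaps[1:]) / gaps[:-1]  # compression +
        np.testing.assert_allclose(fd_strain, gt.true_strain, atol=1e-6)

    def test_strain_series_autocorrelation_peaks_at_cycle_period(
            self, tiny_sequence, tiny_phantom, default_acq):
        _, _, gt = tiny_sequence
        x = gt.true_strain - gt.true_strain.mean()
        ac = np.correlate(x, x, "full")[x.size - 1:]
        cand, _ = find_peaks(ac)
        assert cand.size > 0
        period = cand[np.argmax(ac[cand])]
        expected = 60.0 * default_acq.frame_rate / tiny_phantom.heart_rate
        assert abs(period - expected) <= 1

    def test_masks_track_the_moving_wall_boundaries(self, tiny_sequence):
        _, _, gt = tiny_sequence
        labels = gt.masks.labels
        # wall thins at mid-cycle: fewer near-wall rows at peak compression
        rows_per_frame = (labels == io.NEAR_WALL).any(axis=2).sum(axis=1)
        assert rows_per_frame.max() > rows_per_frame.min()

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ConfigurationError):
            PhantomConfig(wall_thickness_um=-5.0)
        with pytest.raises(ConfigurationError):
            PhantomConfig(peak_axial_strain=0.5)
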