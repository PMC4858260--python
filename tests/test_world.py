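"""Stimuli, sampling geometry and the corridor renderer."""

import math

import numpy as np
import pytest

from beeav.core import ConfigurationError
from beeav.detector import AVDUParams
from beeav.systems import build_full_system, build_test_system
from beeav.world import (BeePose, CorridorRenderer, CorridorWorld, Grating,
                         SubregionLayout, SurfaceGrating, TestArrayGeometry,
                         bee_to_model_frequency, grating_luminance,
                         model_to_bee_frequency, render_corridor,
                         sample_test_array)


class TestGrating:
    def test_sine_zero_crossing_gives_mean(self):
        g = Grating(waveform="sine", wavelength=40.0, angular_velocity=0.0,
                    contrast=1.0, phase0=0.0)
        assert grating_luminance(g, 0.0, 0.0) == pytest.approx(0.5)
        assert grating_luminance(g, 20.0, 0.0) == pytest.approx(0.5)

    def test_square_full_contrast_hits_zero_and_one(self):
        g = Grating(waveform="square", wavelength=40.0, angular_velocity=0.0)
        assert grating_luminance(g, 10.0, 0.0) == pytest.approx(1.0)  # bright half
        assert grating_luminance(g, 30.0, 0.0) == pytest.approx(0.0)  # dark half

    def test_drift_is_a_pure_shift(self):
        g = Grating(waveform="sine", wavelength=38.0, angular_velocity=100.0)
        angles = np.linspace(0, 200, 101)
        later = grating_luminance(g, angles, 1.0)
        shifted = grating_luminance(g, angles - 100.0, 0.0)
        assert np.allclose(later, shifted, atol=1e-12)

    def test_temporal_frequency_definition(self):
        g = Grating(wavelength=38.0, angular_velocity=-380.0)
        assert g.temporal_frequency == pytest.approx(10.0)

    def test_luminance_bounded(self):
        g = Grating(waveform="sine", wavelength=11.0, angular_velocity=500.0,
                    contrast=1.0)
        vals = grating_luminance(g, np.linspace(0, 360, 1000), 0.123)
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_invalid_wavelength(self):
        with pytest.raises(ConfigurationError):
            Grating(wavelength=0.0)


class TestTestArray:
    def test_uniform_field_samples_mean(self):
        geom = TestArrayGeometry()
        g = Grating(contrast=0.0)
        samples = sample_test_array(geom, g, 0.5)
        assert samples.shape == (2, 100)
        assert np.allclose(samples, 0.5)

    def test_rows_identical(self):
        geom = TestArrayGeometry()
        g = Grating(waveform="sine", wavelength=19.0, angular_velocity=77.0)
        s = sample_test_array(geom, g, 0.3)
        assert np.array_equal(s[0], s[1])

    def test_wavelength_twice_spacing_alternates_phase(self):
        geom = TestArrayGeometry()
        g = Grating(waveform="sine", wavelength=4.0, angular_velocity=0.0,
                    phase0=-1.0)
        s = sample_test_array(geom, g, 0.0)[0]
        assert np.allclose(s[::2], s[0])
        assert np.allclose(s[1::2], 1.0 - s[0])  # opposite phase about the mean


class TestFrequencyConvention:
    def test_model_scale_is_fivefold_smaller(self):
        assert bee_to_model_frequency(0.15) == pytest.approx(0.03)
        assert model_to_bee_frequency(0.12) == pytest.approx(0.6)

    def test_round_trip(self):
        f = 0.37
        assert model_to_bee_frequency(bee_to_model_frequency(f)) == pytest.approx(f)


class TestCorridorRenderer:
    def test_uniform_world_renders_uniform_frame(self):
        world = CorridorWorld(left_wall=SurfaceGrating(frequency=0.0),
                              right_wall=SurfaceGrating(frequency=0.0),
                              floor=SurfaceGrating(frequency=0.0))
        frame = render_corridor(world, BeePose(x=0.0, z=10.0))
        assert frame.shape == (32, 32)
        assert np.allclose(frame, 0.5)

    def test_centred_pose_gives_mirror_symmetric_frame(self):
        wall = SurfaceGrating(waveform="sine", frequency=0.03)
        world = CorridorWorld(left_wall=wall, right_wall=wall)
        frame = render_corridor(world, BeePose(x=0.0, z=10.0, y=12.3))
        assert np.allclose(frame, frame[:, ::-1], atol=1e-12)

    def test_abeam_ray_hits_wall_at_lateral_distance(self):
        """A ray pointing 90 deg left from 5 cm off the left wall must hit
        the left wall abeam: hand ray-plane intersection."""
        world = CorridorWorld()
        ren = CorridorRenderer(world)
        pose = BeePose(x=-5.0, z=10.0, y=0.0)  # 5 cm from left wall
        ren.render(pose)
        # find the ray closest to azimuth -90, elevation 0
        n = ren.N
        az = -130 + (np.arange(n) + 0.5) * 260 / n
        el = -90 + (np.arange(n) + 0.5) * 180 / n
        col = int(np.argmin(np.abs(az + 90)))
        row = int(np.argmin(np.abs(el)))
        assert ren._surface_idx[row, col] == 0  # left wall
        # hand computation: t = 5 / |dx|; along-corridor offset t * dy
        dx = math.sin(math.radians(az[col])) * math.cos(math.radians(el[row]))
        dy = math.cos(math.radians(az[col])) * math.cos(math.radians(el[row]))
        t = 5.0 / abs(dx)
        assert ren._y_offset[row, col] == pytest.approx(t * dy)
        assert t == pytest.approx(5.0, rel=0.02)  # nearly perpendicular ray

    def test_rendering_is_deterministic(self):
        wall = SurfaceGrating(waveform="square", frequency=0.05)
        world = CorridorWorld(left_wall=wall, right_wall=wall)
        pose = BeePose(x=1.0, z=7.0, y=42.0)
        f1 = render_corridor(world, pose)
        f2 = render_corridor(world, pose)
        assert np.array_equal(f1, f2)

    def test_translation_by_pattern_wavelength_reproduces_frame(self):
        freq = 0.03  # c/deg -> a fixed wavelength in cm on each surface
        wall = SurfaceGrating(waveform="sine", frequency=freq)
        world = CorridorWorld(left_wall=wall, right_wall=wall,
                              floor=SurfaceGrating(frequency=0.0))
        wavelength_cm = 1.0 / wall.cycles_per_cm(world.width / 2.0)
        ren = CorridorRenderer(world)
        f1 = ren.render(BeePose(x=2.0, z=8.0, y=0.0))
        f2 = ren.render(BeePose(x=2.0, z=8.0, y=wavelength_cm))
        assert np.allclose(f1, f2, atol=1e-9)

    def test_outside_pose_clamped_with_warning(self):
        world = CorridorWorld()
        with pytest.warns(UserWarning):
            frame = render_corridor(world, BeePose(x=15.0, z=10.0))
        assert np.isfinite(frame).all()


class TestSystemBuilders:
    def test_test_system_has_198_avdus(self):
        system = build_test_system(AVDUParams())
        assert system.n_avdus == 198

    def test_single_row_has_99_avdus(self):
        geom = TestArrayGeometry(n_rows=1)
        assert build_test_system(AVDUParams(), geom).n_avdus == 99

    def test_adjacent_pair_rule(self):
        geom = TestArrayGeometry(n_rows=1, n_cols=17)
        assert build_test_system(AVDUParams(), geom).n_avdus == 16

    def test_full_system_subregion_counts(self):
        system = build_full_system(AVDUParams())
        counts = system.n_avdus
        assert counts["left"] == 66  # 11 per row x 6 rows
        assert counts["right"] == 66
        assert counts["centre"] == 35  # 5 per column x 7 columns

    def test_empty_layout_outputs_zero(self):
        system = build_full_system(AVDUParams(), SubregionLayout.empty())
        s = system.step(np.full((32, 32), 0.7))
        assert s == (0.0, 0.0, 0.0)

    def test_overlapping_subregions_rejected(self):
        with pytest.raises(ConfigurationError):
            SubregionLayout(left_cols=(1, 25))  # collides with right block
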