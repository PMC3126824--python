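"""Stimulus rendering: gratings, RDKs, competition movies, textures."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from optomaze import (
    CombinedSpec,
    GratingSpec,
    RDKSpec,
    ResolutionError,
    ScreenGeometry,
    derive_temporal_frequency,
    michelson_contrast,
    render_combined,
    render_grating,
    render_rdk,
    synth_texture,
)
from optomaze.stimuli import _circle_offsets, _square_offsets

from conftest import circular_centroid, circular_delta, circular_shift_px


@pytest.mark.parametrize("sf,v,expected", [
    (0.016, 130.0, 2.08),   # the standard grating: derived tf, not the printed 3 Hz
    (0.0, 500.0, 0.0),
    (0.05, 20.0, 1.0),
    (0.016, -130.0, 2.08),  # speed, not signed velocity
])
def test_temporal_frequency_is_sf_times_speed(sf, v, expected):
    assert derive_temporal_frequency(sf, v) == pytest.approx(expected)


def test_temporal_frequency_rejects_negative_sf():
    with pytest.raises(ValueError):
        derive_temporal_frequency(-0.01, 100.0)


@pytest.mark.parametrize("lmax,lmin,expected", [
    (255, 0, 1.0),
    (128, 128, 0.0),
    (192, 64, 0.5),
    (0, 0, 0.0),
])
def test_michelson_contrast(lmax, lmin, expected):
    assert michelson_contrast(lmax, lmin) == pytest.approx(expected)


def test_michelson_contrast_rejects_inverted_extrema():
    with pytest.raises(ValueError):
        michelson_contrast(10, 20)


class TestGrating:
    def test_full_contrast_extrema(self, small_geometry):
        spec = GratingSpec(spatial_frequency_cpd=0.0625, fg_color=(0, 255, 0),
                           bg_color=(0, 0, 0))
        seq = render_grating(spec, small_geometry, 3)
        assert seq.frames.min() == 0 and seq.frames.max() == 255
        assert michelson_contrast(255, 0) == 1.0

    def test_static_when_velocity_zero(self, small_geometry):
        spec = GratingSpec(spatial_frequency_cpd=0.0625, velocity_dps=0.0)
        seq = render_grating(spec, small_geometry, 5)
        for frame in seq:
            np.testing.assert_array_equal(frame, seq[0])

    def test_phase_advance_matches_velocity(self):
        # 130 °/s * 2 px/° / 60 fps = 4.33 px/frame; over 3 frames = 13 px.
        geometry = ScreenGeometry(width_px=256, height_px=8,
                                  pixels_per_degree=2.0, frame_rate_hz=60.0)
        spec = GratingSpec(spatial_frequency_cpd=0.016, velocity_dps=130.0)
        seq = render_grating(spec, geometry, 4)
        lum = [f.mean(axis=-1) for f in seq]
        assert circular_shift_px(lum[0], lum[3]) == 13

    def test_pixels_are_exactly_fg_or_bg(self, small_geometry):
        spec = GratingSpec(spatial_frequency_cpd=0.0625, fg_color=(10, 200, 30),
                           bg_color=(5, 5, 5))
        seq = render_grating(spec, small_geometry, 2)
        colors = {tuple(c) for c in seq[0].reshape(-1, 3)}
        assert colors == {(10, 200, 30), (5, 5, 5)}

    def test_unrepresentable_period_raises(self, small_geometry):
        spec = GratingSpec(spatial_frequency_cpd=1.5)  # period 1.33 px at 2 px/°
        with pytest.raises(ResolutionError):
            render_grating(spec, small_geometry, 1)

    def test_zero_contrast_is_uniform(self, small_geometry):
        spec = GratingSpec(spatial_frequency_cpd=0.0625, fg_color=(40, 40, 40),
                           bg_color=(40, 40, 40))
        seq = render_grating(spec, small_geometry, 3)
        assert np.all(seq.frames == 40)

    def test_mirror_symmetry_of_motion(self, small_geometry):
        # one full cycle across the 64-px screen, so the cross-correlation
        # shift estimate is unambiguous for |shift| < 32 px
        spec_r = GratingSpec(spatial_frequency_cpd=0.03125, velocity_dps=65.0)
        spec_l = GratingSpec(spatial_frequency_cpd=0.03125, velocity_dps=-65.0)
        seq_r = render_grating(spec_r, small_geometry, 8)
        seq_l = render_grating(spec_l, small_geometry, 8)
        lum = lambda f: f.mean(axis=-1)
        dr = circular_shift_px(lum(seq_r[0]), lum(seq_r[3]))
        dl = circular_shift_px(lum(seq_l[0]), lum(seq_l[3]))
        # pixel quantization of the bar edges allows a 1-px discrepancy
        assert dr > 0 > dl and abs(dr + dl) <= 1

    @given(sf=st.floats(0.01, 0.2), v=st.floats(-200, 200),
           phase=st.floats(0, 0.999))
    def test_intensities_bounded_and_shape_constant(self, sf, v, phase):
        geometry = ScreenGeometry(width_px=32, height_px=8,
                                  pixels_per_degree=4.0, frame_rate_hz=60.0)
        seq = render_grating(GratingSpec(spatial_frequency_cpd=sf, velocity_dps=v,
                                         phase0=phase), geometry, 3)
        assert seq.frames.shape == (3, 8, 32, 3)
        assert seq.frames.min() >= 0 and seq.frames.max() <= 255


class TestRDK:
    def test_empty_field_is_background(self, small_geometry):
        spec = RDKSpec(n_dots=0, dot_diameter_deg=1.0, bg_color=(7, 7, 7))
        seq = render_rdk(spec, small_geometry, 4, seed=3)
        assert np.all(seq.frames == 7)

    def test_dot_count_conserved_across_respawn(self):
        # 1-px dots, short lifespan: respawns must keep exactly n_dots visible.
        geometry = ScreenGeometry(width_px=200, height_px=200,
                                  pixels_per_degree=1.0, frame_rate_hz=60.0)
        spec = RDKSpec(n_dots=12, dot_diameter_deg=1.0, speed_dps=30.0,
                       lifespan_s=0.1, dot_color=(255, 255, 255))
        seq = render_rdk(spec, geometry, 30, seed=5)
        for frame in seq:
            n_px = int((frame[..., 0] > 0).sum())
            assert n_px == 12  # 1-px dots rarely collide on a 200x200 field

    def test_square_and_circle_cover_equal_pixel_counts(self):
        for diameter in range(1, 30):
            circle = _circle_offsets(diameter)
            square = _square_offsets(len(circle))
            assert len(square) == len(circle)

    def test_square_and_circle_movies_equal_area(self):
        geometry = ScreenGeometry(width_px=300, height_px=300,
                                  pixels_per_degree=1.0, frame_rate_hz=60.0)
        kwargs = dict(n_dots=8, dot_diameter_deg=9.0, speed_dps=20.0,
                      dot_color=(255, 255, 255))
        seq_c = render_rdk(RDKSpec(shape="circle", **kwargs), geometry, 5, seed=11)
        seq_s = render_rdk(RDKSpec(shape="square", **kwargs), geometry, 5, seed=11)
        for fc, fs in zip(seq_c, seq_s):
            assert (fc[..., 0] > 0).sum() == (fs[..., 0] > 0).sum()

    def test_coherent_dots_translate_at_speed(self):
        geometry = ScreenGeometry(width_px=256, height_px=64,
                                  pixels_per_degree=2.0, frame_rate_hz=60.0)
        spec = RDKSpec(n_dots=1, coherence=1.0, direction_deg=0.0,
                       speed_dps=130.0, dot_diameter_deg=2.0, lifespan_s=100.0,
                       dot_color=(255, 255, 255))
        seq = render_rdk(spec, geometry, 7, seed=2)
        xs = []
        for frame in seq:
            cols = np.nonzero(frame[..., 0] > 0)[1]
            xs.append(circular_centroid(cols, geometry.width_px))
        deltas = [circular_delta(xs[i], xs[i + 1], geometry.width_px)
                  for i in range(len(xs) - 1)]
        assert np.mean(deltas) == pytest.approx(130.0 * 2.0 / 60.0, abs=0.5)

    def test_mirror_symmetry_of_dot_motion(self):
        geometry = ScreenGeometry(width_px=256, height_px=64,
                                  pixels_per_degree=2.0, frame_rate_hz=60.0)
        base = dict(n_dots=1, coherence=1.0, speed_dps=60.0, dot_diameter_deg=2.0,
                    lifespan_s=100.0, dot_color=(255, 255, 255))
        deltas = {}
        for direction in (0.0, 180.0):
            seq = render_rdk(RDKSpec(direction_deg=direction, **base), geometry,
                             6, seed=4)
            xs = [circular_centroid(np.nonzero(f[..., 0] > 0)[1], 256) for f in seq]
            deltas[direction] = np.mean([circular_delta(xs[i], xs[i + 1], 256)
                                         for i in range(5)])
        assert deltas[0.0] == pytest.approx(-deltas[180.0], abs=0.2)
        assert deltas[0.0] > 0

    def test_determinism_and_seed_sensitivity(self, small_geometry):
        spec = RDKSpec(n_dots=10, dot_diameter_deg=1.5)
        a = render_rdk(spec, small_geometry, 4, seed=9)
        b = render_rdk(spec, small_geometry, 4, seed=9)
        c = render_rdk(spec, small_geometry, 4, seed=10)
        np.testing.assert_array_equal(a.frames, b.frames)
        assert not np.array_equal(a.frames, c.frames)

    def test_subpixel_dot_raises(self):
        geometry = ScreenGeometry(width_px=64, height_px=64,
                                  pixels_per_degree=0.5, frame_rate_hz=60.0)
        with pytest.raises(ResolutionError):
            render_rdk(RDKSpec(n_dots=5, dot_diameter_deg=0.5), geometry, 1, seed=0)


class TestCombined:
    def test_relative_direction_restricted_to_eight(self):
        for ok in (0, 45, 90, 135, 180, 225, 270, 315):
            CombinedSpec(relative_direction_deg=ok)
        with pytest.raises(ValueError):
            CombinedSpec(relative_direction_deg=30)

    def test_invisible_dots_reduce_to_grating(self, small_geometry):
        grating = GratingSpec(spatial_frequency_cpd=0.0625, fg_color=(40, 40, 40),
                              bg_color=(40, 40, 40))
        rdk = RDKSpec(n_dots=20, dot_diameter_deg=1.5, dot_color=(40, 40, 40))
        combined = render_combined(CombinedSpec(grating=grating, rdk=rdk),
                                   small_geometry, 4, seed=1)
        alone = render_grating(grating, small_geometry, 4)
        np.testing.assert_array_equal(combined.frames, alone.frames)

    def test_dots_move_with_grating_when_coherent(self):
        geometry = ScreenGeometry(width_px=256, height_px=64,
                                  pixels_per_degree=2.0, frame_rate_hz=60.0)
        spec = CombinedSpec(
            grating=GratingSpec(spatial_frequency_cpd=0.016, velocity_dps=130.0),
            rdk=RDKSpec(n_dots=1, coherence=1.0, speed_dps=130.0,
                        dot_diameter_deg=2.0, lifespan_s=100.0,
                        dot_color=(0, 0, 255)),
            relative_direction_deg=0,
        )
        seq = render_combined(spec, geometry, 6, seed=3)
        # blue channel isolates the dot from the green/black grating
        xs = [circular_centroid(np.nonzero(f[..., 2] > 0)[1], 256) for f in seq]
        deltas = [circular_delta(xs[i], xs[i + 1], 256) for i in range(5)]
        assert np.mean(deltas) == pytest.approx(130.0 * 2.0 / 60.0, abs=0.5)

    def test_opposed_dots_move_against_grating(self):
        geometry = ScreenGeometry(width_px=256, height_px=64,
                                  pixels_per_degree=2.0, frame_rate_hz=60.0)
        spec = CombinedSpec(
            grating=GratingSpec(spatial_frequency_cpd=0.016, velocity_dps=130.0),
            rdk=RDKSpec(n_dots=1, coherence=1.0, speed_dps=130.0,
                        dot_diameter_deg=2.0, lifespan_s=100.0,
                        dot_color=(0, 0, 255)),
            relative_direction_deg=180,
        )
        seq = render_combined(spec, geometry, 6, seed=3)
        xs = [circular_centroid(np.nonzero(f[..., 2] > 0)[1], 256) for f in seq]
        deltas = [circular_delta(xs[i], xs[i + 1], 256) for i in range(5)]
        assert np.mean(deltas) == pytest.approx(-130.0 * 2.0 / 60.0, abs=0.5)


class TestTexture:
    def test_determinism(self, small_geometry):
        a = synth_texture(small_geometry, 2.0, 130.0, 4, seed=8)
        b = synth_texture(small_geometry, 2.0, 130.0, 4, seed=8)
        np.testing.assert_array_equal(a.frames, b.frames)

    @pytest.mark.parametrize("exponent", [0.0, 2.0])
    def test_spectral_slope_recovered(self, exponent):
        # Average log-log spectra over many seeds; restrict to the lower
        # quarter of bins to stay clear of the uint8 quantization floor.
        from optomaze import frame_power_spectrum, to_luminance
        geometry = ScreenGeometry(width_px=128, height_px=16,
                                  pixels_per_degree=2.0, frame_rate_hz=60.0)
        spectra = []
        for seed in range(100):
            seq = synth_texture(geometry, exponent, 0.0, 1, seed=seed)
            spectra.append(frame_power_spectrum(to_luminance(seq[0])))
        mean = np.mean(spectra, axis=0)
        bins = np.arange(1, 128 // 4)
        slope = np.polyfit(np.log(bins), np.log(mean[bins]), 1)[0]
        assert slope == pytest.approx(-exponent, abs=0.2)
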