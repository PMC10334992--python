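"""Phantom scene generation and DoFP sensor rendering."""

import numpy as np
import pytest
from scipy import stats

from qpli.pipeline import process_mosaic
from qpli.roi import avg_dolp
from qpli.synth import (
    SensorParams,
    generate_fiber_texture,
    generate_scene,
    render_mosaic,
    sample_axial_von_mises,
    scene_true_maps,
    uniform_scene,
)


class TestGenerateScene:
    def test_absorber_levels_set_transmissivity_directly(self):
        for level in (1.0, 0.67, 0.33):
            scene = generate_scene("aligned", transmission_level=level, shape=(16, 16), seed=0)
            np.testing.assert_allclose(scene.transmissivity, level)

    def test_degenerate_concentration_pins_all_axes_to_mean(self):
        scene = generate_scene(
            "aligned", shape=(32, 32), seed=3, kappa=1e6, mean_axis_deg=20.0
        )
        np.testing.assert_allclose(scene.fiber_axis_deg, 20.0, atol=0.5)

    def test_seed_determinism(self):
        a = generate_scene("disorganized", shape=(32, 32), seed=7)
        b = generate_scene("disorganized", shape=(32, 32), seed=7)
        c = generate_scene("disorganized", shape=(32, 32), seed=8)
        np.testing.assert_array_equal(a.fiber_axis_deg, b.fiber_axis_deg)
        assert not np.array_equal(a.fiber_axis_deg, c.fiber_axis_deg)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"collagen_density": 2.0},
            {"riboflavin_mm": 0.7},
            {"transmission_level": 0.5},
        ],
    )
    def test_unknown_factor_level_rejected(self, kwargs):
        with pytest.raises(ValueError, match="level"):
            generate_scene("aligned", shape=(16, 16), seed=0, **kwargs)

    def test_unknown_alignment_rejected(self):
        with pytest.raises(ValueError, match="alignment"):
            generate_scene("random", shape=(16, 16), seed=0)

    def test_odd_shape_rejected(self):
        with pytest.raises(ValueError, match="even"):
            generate_scene("aligned", shape=(15, 16), seed=0)

    def test_maps_constant_within_superpixels(self):
        scene = generate_scene("aligned", shape=(32, 32), seed=0)
        axes = scene.fiber_axis_deg
        assert (axes[::2, ::2] == axes[1::2, ::2]).all()
        assert (axes[::2, ::2] == axes[::2, 1::2]).all()


class TestRenderMosaic:
    def test_unpolarized_scene_renders_half_intensity_everywhere(self):
        scene = uniform_scene(shape=(16, 16), retardance_rad=0.0, depol_linear=1.0,
                              depol_circular=1.0)
        mosaic = render_mosaic(scene, noise=False)
        np.testing.assert_allclose(mosaic.pixels, 0.5, atol=1e-15)

    def test_malus_law_closed_form(self):
        # S0=1, DoLP=0.5, AoP=30 deg -> S1=0.25, S2=0.433013
        s1, s2 = 0.25, 0.5 * np.sin(np.deg2rad(60))
        expected = {
            0: 0.5 * (1 + s1),
            45: 0.5 * (1 + s2),
            90: 0.5 * (1 - s1),
            135: 0.5 * (1 - s2),
        }
        np.testing.assert_allclose(
            [expected[0], expected[45], expected[90], expected[135]],
            [0.625, 0.716506, 0.375, 0.283494],
            atol=1e-6,
        )
        # realize that state: depolarizer 0.5 after half-wave-ish retarder
        # AoP = axis + 45 for a quarter-wave retarder on RCP, so axis = -15
        scene = uniform_scene(
            shape=(8, 8), fiber_axis_deg=-15.0, retardance_rad=np.pi / 2, depol_linear=0.5
        )
        mosaic = render_mosaic(scene, noise=False)
        layout = {angle: (r, c) for r, row in enumerate(mosaic.layout) for c, angle in enumerate(row)}
        for angle, (r, c) in layout.items():
            assert mosaic.pixels[r, c] == pytest.approx(expected[angle], abs=1e-12)

    def test_noise_free_round_trip_recovers_scene_maps(self, aligned_scene):
        mosaic = render_mosaic(aligned_scene, noise=False)
        stokes = process_mosaic(mosaic, method="superpixel")
        _, dolp, aop = scene_true_maps(aligned_scene)
        np.testing.assert_allclose(stokes.dolp, dolp[::2, ::2], atol=1e-9)
        np.testing.assert_allclose(stokes.aop_deg, aop[::2, ::2], atol=1e-9)

    def test_depolarization_monotonically_reduces_avg_dolp(self):
        values = []
        for strength in (0.0, 0.25, 0.5, 0.75):
            scene = uniform_scene(shape=(16, 16), depol_linear=strength)
            stokes = process_mosaic(render_mosaic(scene, noise=False), method="superpixel")
            values.append(avg_dolp(stokes))
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_handedness_flip_shifts_recovered_aop_90_everywhere(self, aligned_scene):
        right = process_mosaic(render_mosaic(aligned_scene, input_handedness="right", noise=False),
                               method="superpixel")
        left = process_mosaic(render_mosaic(aligned_scene, input_handedness="left", noise=False),
                              method="superpixel")
        d = np.abs(right.aop_deg - left.aop_deg) % 180.0
        d = np.minimum(d, 180.0 - d)
        np.testing.assert_allclose(d, 90.0, atol=1e-9)

    def test_invalid_handedness_rejected(self, aligned_scene):
        with pytest.raises(ValueError, match="handedness"):
            render_mosaic(aligned_scene, input_handedness="up")

    def test_noise_is_seeded_and_quantized(self, aligned_scene):
        a = render_mosaic(aligned_scene, SensorParams(seed=5), noise=True)
        b = render_mosaic(aligned_scene, SensorParams(seed=5), noise=True)
        c = render_mosaic(aligned_scene, SensorParams(seed=6), noise=True)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        assert not np.array_equal(a.pixels, c.pixels)
        assert a.pixels.max() <= 65535 and a.pixels.min() >= 0

    def test_bad_layout_rejected(self):
        with pytest.raises(ValueError, match="layout"):
            SensorParams(layout=((0, 45), (90, 90)))


class TestFiberTexture:
    def test_degenerate_kappa_draws_all_angles_at_mu(self, rng):
        angles = sample_axial_von_mises(rng, 30.0, 1e6, 1000)
        np.testing.assert_allclose(angles, 30.0, atol=0.5)

    def test_kappa_zero_is_uniform(self, rng):
        angles = sample_axial_von_mises(rng, 0.0, 0.0, 5000)
        hist, _ = np.histogram(angles, bins=18, range=(-90, 90))
        assert stats.chisquare(hist).pvalue > 0.01

    def test_texture_reproducible_per_seed(self):
        a = generate_fiber_texture(2.0, seed=4, shape=(64, 64), n_fibers=50)
        b = generate_fiber_texture(2.0, seed=4, shape=(64, 64), n_fibers=50)
        c = generate_fiber_texture(2.0, seed=5, shape=(64, 64), n_fibers=50)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="kappa"):
            generate_fiber_texture(-1.0, seed=0)
        with pytest.raises(ValueError, match="n_fibers"):
            generate_fiber_texture(1.0, n_fibers=0, seed=0)
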