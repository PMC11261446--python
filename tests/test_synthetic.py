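import dataclasses

import numpy as np
import pytest

from perspire.evaporation import fit_first_order_decay
from perspire.synthetic import (
    ProbeSimConfig,
    SceneConfig,
    expected_area_per_active_droplet_mm2,
    generate_pore_layout,
    render_mwir,
    simulate_dropwise_dynamics,
    simulate_filmwise_scene,
    simulate_probe_signal,
    square_grid_spacing_mm,
)


class TestPoreLayout:
    def test_forehead_density_spacing(self):
        # 185 pores/cm² on a square grid → ~0.7 mm nearest-neighbor gap
        assert square_grid_spacing_mm(185.0) == pytest.approx(0.735, abs=0.001)

    def test_round_density_spacing(self):
        assert square_grid_spacing_mm(100.0) == pytest.approx(1.0)

    def test_zero_density_empty(self):
        assert generate_pore_layout(0.0, "poisson", 10, 10).size == 0

    def test_grid_spacing_realized(self):
        pores = generate_pore_layout(100.0, "square_grid", 10.0, 10.0)
        xs = np.unique(np.round(pores[:, 0], 6))
        assert np.allclose(np.diff(xs), 1.0)

    def test_poisson_count_matches_density(self):
        pores = generate_pore_layout(185.0, "poisson", 30.0, 30.0, rng=0)
        expected = 185.0 * 9.0  # 9 cm²
        assert pores.shape[0] == pytest.approx(expected, rel=0.1)

    def test_hard_core_spacing_respected(self):
        pores = generate_pore_layout(
            185.0, "poisson", 10.0, 10.0, rng=1, min_spacing_mm=0.45
        )
        from scipy.spatial.distance import pdist

        assert pdist(pores).min() >= 0.45

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            generate_pore_layout(-1.0, "poisson", 10, 10)


class TestDropwiseDynamics:
    def test_single_pore_event_count(self):
        cfg = SceneConfig(
            width_px=64,
            height_px=64,
            duration_s=60,
            fixed_period_s=6.0,
            pore_positions_mm=((0.85, 0.85),),
            seed=2,
        )
        truth = simulate_dropwise_dynamics(cfg)
        assert len(truth.events) == 10

    def test_truth_mask_area_consistency(self):
        cfg = SceneConfig(width_px=96, height_px=96, duration_s=10, seed=4)
        truth = simulate_dropwise_dynamics(cfg)
        counts = truth.masks.reshape(truth.masks.shape[0], -1).sum(axis=1)
        pitch_cm = cfg.pixel_pitch_um * 1e-4
        assert np.allclose(truth.wet_area_cm2, counts * pitch_cm**2)
        assert np.allclose(truth.omega, truth.wet_area_cm2 / cfg.total_area_cm2)
        assert np.all((truth.omega >= 0) & (truth.omega <= 1))

    def test_seed_reproducibility_bit_identical(self):
        cfg = SceneConfig(
            width_px=64, height_px=64, duration_s=8, seed=9, shake_amplitude_px=2.0
        )
        t1 = simulate_dropwise_dynamics(cfg)
        t2 = simulate_dropwise_dynamics(cfg)
        assert np.array_equal(t1.masks, t2.masks)
        assert t1.events.equals(t2.events)
        s1 = render_mwir(t1)
        s2 = render_mwir(t2)
        assert np.array_equal(s1.frames, s2.frames)

    def test_mean_period_self_consistency(self, droplet_statistics):
        truth = droplet_statistics["truth"]
        cfg = droplet_statistics["config"]
        assert truth.events.period_s.mean() == pytest.approx(
            cfg.expected_mean_period_s(), rel=0.10
        )

    def test_p95_diameter_tuning(self, droplet_statistics):
        truth = droplet_statistics["truth"]
        assert len(truth.events) >= 3000
        p95 = np.percentile(truth.events.max_diameter_mm, 95)
        assert p95 == pytest.approx(0.7, rel=0.10)

    def test_expected_area_analytics(self):
        cfg = SceneConfig(fixed_diameter_mm=0.43, droplet_profile="flat")
        assert expected_area_per_active_droplet_mm2(cfg) == pytest.approx(
            0.145, abs=0.001
        )


class TestFilmwiseScene:
    def test_single_puddle_cover_fraction(self):
        cfg = SceneConfig(
            width_px=200,
            height_px=200,
            duration_s=2,
            seed=3,
            film_thickness_map=(1e-3,),
            n_puddle_lobes=0,
            # radius for 30% of the 200-px square FOV
            puddle_specs=((2.67, 2.67, np.sqrt(0.3 / np.pi) * 200 * 0.0267, 0.0),),
        )
        truth = simulate_filmwise_scene(cfg)
        assert truth.omega[0] == pytest.approx(0.30, abs=0.005)

    def test_zero_puddles(self):
        cfg = SceneConfig(
            width_px=64, height_px=64, duration_s=2, seed=3, film_thickness_map=()
        )
        truth = simulate_filmwise_scene(cfg)
        assert np.all(truth.omega == 0)

    def test_missing_thickness_map_rejected(self):
        with pytest.raises(ValueError, match="thickness"):
            simulate_filmwise_scene(SceneConfig(width_px=64, height_px=64, duration_s=2))

    def test_thickness_sets_rendered_contrast_ratio(self):
        base = dict(
            width_px=160,
            height_px=64,
            duration_s=1,
            seed=6,
            n_puddle_lobes=0,
            noise_sd_gray=0.0,
            optical_blur_px=0.0,
            background_texture_gray=0.0,
            n_texture_lines=0,
        )
        base["gray_per_c"] = 200.0  # fine quantization for the ratio check
        cfg = SceneConfig(
            film_thickness_map=(0.002, 60e-6),
            puddle_specs=((1.0, 0.85, 0.5, 0.0), (3.2, 0.85, 0.5, 0.0)),
            **base,
        )
        truth = simulate_filmwise_scene(cfg)
        stack = render_mwir(truth)
        frame = stack.frames[0].astype(float)
        dry = frame.max()
        thick_drop = dry - frame[32, int(1.0 / 0.0267)]
        thin_drop = dry - frame[32, int(3.2 / 0.0267)]
        assert thick_drop / thin_drop == pytest.approx(0.002 / 60e-6, rel=0.05)

    def test_thick_puddle_renders_thermal_circuit_drop(self):
        cfg = SceneConfig(
            width_px=96,
            height_px=96,
            duration_s=1,
            seed=6,
            n_puddle_lobes=0,
            noise_sd_gray=0.0,
            optical_blur_px=0.0,
            background_texture_gray=0.0,
            n_texture_lines=0,
            film_thickness_map=(0.002,),
            puddle_specs=((1.28, 1.28, 0.6, 0.0),),
        )
        truth = simulate_filmwise_scene(cfg)
        frame = render_mwir(truth).frames[0].astype(float)
        drop_c = (frame.max() - frame.min()) / cfg.gray_per_c
        assert drop_c == pytest.approx(2.7, abs=0.1)


class TestRendering:
    def test_empty_scene_constant_frames(self):
        cfg = SceneConfig(
            width_px=48,
            height_px=48,
            duration_s=1,
            seed=0,
            pore_density_per_cm2=0.0,
            noise_sd_gray=0.0,
            background_texture_gray=0.0,
            n_texture_lines=0,
        )
        truth = simulate_dropwise_dynamics(cfg)
        frames = render_mwir(truth).frames
        assert np.all(frames == cfg.base_gray)

    def test_shake_offsets_recorded(self):
        cfg = SceneConfig(
            width_px=48, height_px=48, duration_s=3, seed=1, shake_amplitude_px=3.0
        )
        truth = simulate_dropwise_dynamics(cfg)
        offsets = truth.shake_offsets_px
        assert offsets.shape == (30, 2)
        assert np.abs(offsets[:, 0]).max() <= 3.0 + 1e-9
        assert np.abs(offsets[:, 0]).max() > 1.0

    def test_contrast_monotone_in_thickness(self):
        drops = []
        for thickness in (0.2e-3, 0.8e-3, 2e-3):
            cfg = SceneConfig(
                width_px=96,
                height_px=96,
                duration_s=1,
                seed=6,
                n_puddle_lobes=0,
                noise_sd_gray=0.0,
                background_texture_gray=0.0,
                n_texture_lines=0,
                film_thickness_map=(thickness,),
                puddle_specs=((1.28, 1.28, 0.6, 0.0),),
            )
            frame = render_mwir(simulate_filmwise_scene(cfg)).frames[0]
            drops.append(int(frame.max()) - int(frame.min()))
        assert drops[0] < drops[1] < drops[2]


class TestProbeSimulation:
    def test_steady_state_concentration(self):
        # flux 0.829 mg/min/cm² over 1.93 cm² at 0.1 L/min → 16.0 g/m³
        cfg = ProbeSimConfig(flow_schedule=((0.0, 0.1),))
        t = np.arange(0, 1200.0, 1.0)
        df = simulate_probe_signal(t, np.full(t.size, 0.829), cfg)
        assert df.cout_gm3.iloc[-1] == pytest.approx(16.0, abs=0.05)

    def test_zero_flux_decays_to_zero(self):
        cfg = ProbeSimConfig()
        t = np.arange(0, 600.0, 1.0)
        flux = np.zeros(t.size)
        df = simulate_probe_signal(t, flux, cfg)
        # initial condition is the steady state of the first sample (0)
        assert df.cout_gm3.abs().max() == 0.0

    def test_flow_step_relaxes_with_mixing_constant(self):
        from perspire.experiments import probe_step_experiment

        result = probe_step_experiment(mixing_s=90.0)
        assert result["tau_est_min"] == pytest.approx(1.5, rel=0.10)

    def test_invalid_flow_rejected(self):
        with pytest.raises(ValueError):
            ProbeSimConfig(flow_schedule=((0.0, -0.1),))

    def test_flow_schedule_lookup(self):
        cfg = ProbeSimConfig(flow_schedule=((0.0, 0.1), (60.0, 0.2)))
        flow = cfg.flow_at(np.array([0.0, 59.9, 60.0, 100.0]))
        assert np.allclose(flow, [0.1, 0.1, 0.2, 0.2])


def test_scene_config_validation():
    with pytest.raises(ValueError):
        SceneConfig(cycle_period_range_s=(5.0, 2.0))
    with pytest.raises(ValueError):
        SceneConfig(droplet_profile="square")
    with pytest.raises(ValueError):
        SceneConfig(frame_rate=0.0)
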