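"""Simulator: determinism, motion-model calibration, rendering, presets."""

import dataclasses

import numpy as np
import pytest

from chlamytrack import (
    LightBias,
    SimScenario,
    SubPop,
    UnknownStrainError,
    ValidationError,
    render_frame,
    simulate_population,
    simulate_trajectories,
    strain_preset,
)


class TestScenarioValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="sum to 1"):
            SimScenario(subpopulations=[SubPop("a", 0.5, 10.0), SubPop("b", 0.4, 20.0)])

    def test_zero_area_field_rejected(self):
        with pytest.raises(ValidationError, match="zero-area"):
            SimScenario(field_width_px=0)

    def test_light_bias_fractions_bounded(self):
        with pytest.raises(ValidationError, match="exceed 1"):
            LightBias(toward_fraction=0.7, away_fraction=0.5)

    def test_default_clip_has_225_frames(self):
        # 7.5 frames/s for 30 s
        sc = SimScenario()
        assert sc.n_frames == 225
        assert sc.frame_interval_s == pytest.approx(1 / 7.5)
        assert sc.duration_s == pytest.approx(30.0)


class TestTrajectories:
    def test_empty_population(self):
        sc = SimScenario(n_cells=0, n_frames=5, noise_sd=0.0)
        stack, truth = simulate_population(sc)
        assert truth.n_cells == 0
        assert np.all(stack.frames == int(sc.background_level))

    def test_determinism_bit_for_bit(self):
        sc = SimScenario(n_cells=15, n_frames=10, field_width_px=128,
                         field_height_px=128, noise_sd=3.0, seed=42)
        s1, t1 = simulate_population(sc)
        s2, t2 = simulate_population(sc)
        assert np.array_equal(s1.frames, s2.frames)
        assert np.array_equal(t1.positions, t2.positions)

    def test_positions_stay_inside_field(self):
        sc = SimScenario(n_cells=50, n_frames=60, field_width_px=100, field_height_px=80,
                         subpopulations=[SubPop("f", 1.0, 80.0, 10.0, 0.5)], seed=1)
        truth = simulate_trajectories(sc)
        assert truth.positions.shape == (50, 60, 2)
        assert np.all(truth.positions[..., 0] >= 0)
        assert np.all(truth.positions[..., 0] < 100)
        assert np.all(truth.positions[..., 1] >= 0)
        assert np.all(truth.positions[..., 1] < 80)

    def test_straight_swimmers_realize_assigned_speed_within_1pct(self):
        # no heading noise: displacement per frame equals the assigned step
        # except at boundary reflections, so run in a large field
        sc = SimScenario(n_cells=50, n_frames=30, field_width_px=4096,
                         field_height_px=4096,
                         subpopulations=[SubPop("s", 1.0, 40.0, 5.0, 0.0)], seed=2)
        truth = simulate_trajectories(sc)
        emp = truth.empirical_speeds_um_s()
        # exclude cells that bounced (their step sequence is not constant)
        steps = np.linalg.norm(np.diff(truth.positions, axis=1), axis=2)
        no_bounce = np.ptp(steps, axis=1) < 1e-9
        assert no_bounce.mean() > 0.5
        ratio = emp[no_bounce] / truth.speeds_um_s[no_bounce]
        assert np.all(np.abs(ratio - 1) < 0.01)

    def test_wiggly_swimmers_realize_assigned_speed_within_5pct(self):
        sc = SimScenario(n_cells=50, n_frames=60, field_width_px=4096,
                         field_height_px=4096,
                         subpopulations=[SubPop("w", 1.0, 30.0, 0.0, 0.4)], seed=3)
        truth = simulate_trajectories(sc)
        ratio = truth.empirical_speeds_um_s() / truth.speeds_um_s
        assert np.all(np.abs(ratio - 1) < 0.05)

    def test_unbiased_net_angles_are_uniform(self):
        # resultant length of n uniform angles is ~Rayleigh; 3 sigma bound
        sc = SimScenario(n_cells=800, n_frames=20, field_width_px=2048,
                         field_height_px=2048,
                         subpopulations=[SubPop("u", 1.0, 30.0, 5.0, 0.3)], seed=4)
        truth = simulate_trajectories(sc)
        ang = truth.net_displacement_angles()
        resultant = np.hypot(np.cos(ang).sum(), np.sin(ang).sum()) / len(ang)
        assert resultant < 3.0 / np.sqrt(2 * len(ang))

    def test_aggregate_members_stay_near_group_centroid(self):
        sc = SimScenario(n_cells=40, n_frames=30, field_width_px=512, field_height_px=512,
                         aggregate_fraction=0.6, cell_radius_px=4.0,
                         subpopulations=[SubPop("a", 1.0, 30.0, 5.0, 0.4)], seed=5)
        truth = simulate_trajectories(sc)
        assert set(truth.group_size) >= {1, 2, 4}
        for gid in np.unique(truth.group_id):
            members = truth.positions[truth.group_id == gid]
            centroid = members.mean(axis=0)
            d = np.linalg.norm(members - centroid, axis=2)
            assert np.all(d <= 2 * sc.cell_radius_px + 1e-9)

    def test_mixture_composition_is_exact(self):
        sc = SimScenario(n_cells=60, n_frames=2,
                         subpopulations=[SubPop("a", 0.5, 10.0), SubPop("b", 0.5, 40.0)],
                         seed=6)
        truth = simulate_trajectories(sc)
        labels = list(truth.labels)
        assert labels.count("a") == 30 and labels.count("b") == 30


class TestRenderFrame:
    def test_single_cell_peak_at_center(self):
        sc = SimScenario(field_width_px=101, field_height_px=101, noise_sd=0.0)
        img = render_frame([(50.0, 50.0, 5.0)], sc)
        assert np.unravel_index(np.argmax(img), img.shape) == (50, 50)

    def test_empty_positions_constant_background(self):
        sc = SimScenario(field_width_px=32, field_height_px=32, noise_sd=0.0,
                         background_level=77.0)
        img = render_frame([], sc)
        assert np.all(img == 77.0)

    def test_two_cells_two_local_maxima(self):
        sc = SimScenario(field_width_px=64, field_height_px=64, noise_sd=0.0)
        img = render_frame([(20.0, 32.0, 4.0), (40.0, 32.0, 4.0)], sc)
        row = img[32]
        interior = [i for i in range(1, 63) if row[i] > row[i - 1] and row[i] > row[i + 1]]
        assert interior == [20, 40]

    def test_inverted_polarity_renders_dark_cells(self):
        sc = SimScenario(field_width_px=64, field_height_px=64, noise_sd=0.0,
                         background_level=2000.0, invert=True)
        img = render_frame([(32.0, 32.0, 4.0)], sc)
        assert img[32, 32] == img.min()
        assert img[0, 0] == pytest.approx(2000.0)


class TestStrainPresets:
    @pytest.mark.parametrize(
        "strain, mean",
        [("cc124", 40.0), ("cc1036", 1.5), ("cc2228", 11.0), ("cc3663", 22.0),
         ("cc602", 2.8), ("moewusii", 48.0)],
    )
    def test_published_mean_speeds(self, strain, mean):
        assert strain_preset(strain).mean_speed_um_s == mean

    def test_unknown_strain_lists_valid_ids(self):
        with pytest.raises(UnknownStrainError, match="cc124"):
            strain_preset("cc999")


def test_scenario_toml_round_trip(tmp_path):
    from chlamytrack import read_scenario, write_scenario

    sc = SimScenario(n_cells=12, light_bias=LightBias(1.0, 0.3, 0.3, 0.2),
                     subpopulations=[SubPop("a", 0.25, 10.0, 1.0, 0.1),
                                     SubPop("b", 0.75, 40.0, 4.5, 0.2)], seed=9)
    path = tmp_path / "scenario.toml"
    write_scenario(sc, path)
    assert read_scenario(path) == sc
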