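import numpy as np
import pytest

from perspire import tracking
from perspire.tracking import (
    active_count_series,
    cycle_period_estimate,
    distribution_summary,
    event_metrics,
    filter_short_events,
    fit_area_vs_count,
    label_events,
    moving_average,
)
from ._oracles import partitions_equal, union_find_labels


def _disk_stack(n_frames, centers_radii_frames, shape=(48, 48)):
    """Stack with disks present over given frame ranges."""
    stack = np.zeros((n_frames, *shape), dtype=bool)
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    for (cy, cx, r, f0, f1) in centers_radii_frames:
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        stack[f0 : f1 + 1] |= disk
    return stack


class TestLabeling:
    def test_single_persistent_disk(self):
        stack = _disk_stack(40, [(20, 20, 5, 10, 29)])
        events, _ = label_events(stack)
        assert len(events) == 1
        assert events[0].start_frame == 10 and events[0].end_frame == 29

    def test_disjoint_disks_are_separate_events(self):
        stack = _disk_stack(10, [(10, 10, 4, 0, 9), (35, 35, 4, 0, 9)])
        events, _ = label_events(stack)
        assert len(events) == 2

    def test_empty_stack(self):
        events, labeled = label_events(np.zeros((5, 8, 8), bool))
        assert events == [] and labeled.max() == 0

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        stack = rng.uniform(size=(20, 16, 16)) < 0.2
        _, labeled = label_events(stack)
        assert partitions_equal(labeled, union_find_labels(stack))


class TestDurationFilter:
    def test_two_frame_events_removed_three_kept(self):
        stack = _disk_stack(
            20, [(10, 10, 3, 0, 1), (30, 30, 3, 5, 7)]
        )
        events, _ = label_events(stack)
        kept = filter_short_events(events)
        assert len(events) == 2 and len(kept) == 1
        assert kept[0].start_frame == 5

    def test_identity_on_long_events(self):
        stack = _disk_stack(30, [(10, 10, 3, 0, 6), (30, 30, 3, 10, 20)])
        events, _ = label_events(stack)
        assert len(filter_short_events(events)) == len(events)

    def test_invalid_min_frames(self):
        with pytest.raises(ValueError):
            filter_short_events([], min_frames=0)

    def test_area_change_small_on_synthetic_scene(self, droplet_statistics):
        truth = droplet_statistics["truth"]
        cfg = droplet_statistics["config"]
        raw, _ = label_events(truth.masks)
        kept = filter_short_events(raw)
        n = truth.masks.shape[0]
        area_all = np.zeros(n)
        area_kept = np.zeros(n)
        for ev_set, acc in ((raw, area_all), (kept, area_kept)):
            for ev in ev_set:
                acc[ev.start_frame : ev.end_frame + 1] += ev.pixel_counts
        # removal of <=2-frame noise events barely changes the area series
        assert area_kept.sum() >= 0.98 * area_all.sum()
        kept_ids = {id(ev) for ev in kept}
        removed = [ev for ev in raw if id(ev) not in kept_ids]
        assert all(ev.end_frame - ev.start_frame + 1 <= 2 for ev in removed)


class TestEventMetrics:
    def test_average_droplet_diameter(self):
        # a 0.145 mm² droplet corresponds to a 0.43 mm diameter circle
        stack = _disk_stack(10, [(20, 20, 8.05, 0, 9)])
        events, _ = label_events(stack)
        ev = event_metrics(events[0], pixel_pitch_um=26.7, frame_rate=10.0)
        assert ev.max_area_mm2 == pytest.approx(0.145, rel=0.05)
        assert ev.max_equivalent_diameter_mm == pytest.approx(0.43, abs=0.01)

    def test_unit_area_diameter(self):
        diam = np.sqrt(4 * (np.pi / 4) / np.pi)
        assert diam == pytest.approx(1.0)

    def test_duration_from_frame_span(self):
        stack = _disk_stack(30, [(20, 20, 4, 3, 19)])
        events, _ = label_events(stack)
        ev = event_metrics(events[0], 26.7, 10.0)
        assert ev.duration_s == pytest.approx(1.7)


class TestActiveCounts:
    def test_always_on_event(self):
        stack = _disk_stack(50, [(20, 20, 4, 0, 49)])
        events, _ = label_events(stack)
        counts = active_count_series(events, 50)
        assert np.all(counts == 1)
        assert np.allclose(moving_average(counts, 2.0, 10.0), 1.0)

    def test_fifty_percent_duty_cycle(self):
        spec = [(20, 20, 4, f, f + 4) for f in range(0, 200, 10)]
        stack = _disk_stack(200, spec)
        events, _ = label_events(stack)
        counts = active_count_series(events, 200)
        ma = moving_average(counts, 6.0, 10.0)
        assert np.mean(ma) == pytest.approx(0.5, abs=0.05)

    def test_onset_ramp_counts_rise(self):
        from scipy import stats

        from perspire.synthetic import SceneConfig, simulate_dropwise_dynamics

        cfg = SceneConfig(
            width_px=128, height_px=128, duration_s=60, seed=21, onset_ramp_s=60
        )
        ramp_truth = simulate_dropwise_dynamics(cfg)
        ramp_events = tracking.extract_events(ramp_truth.masks, 26.7, 10.0)
        counts = active_count_series(ramp_events, ramp_truth.masks.shape[0])
        ma = moving_average(counts, 20.0, 10.0)
        rho = stats.spearmanr(np.arange(ma.size), ma).statistic
        assert rho > 0.9


class TestAreaVsCount:
    def test_identical_disks(self):
        spec = [(12, 12, 4, 0, 9), (30, 30, 4, 5, 9), (12, 30, 4, 8, 9)]
        stack = _disk_stack(10, spec)
        events, _ = label_events(stack)
        counts = active_count_series(events, 10)
        pitch_mm = 26.7 / 1000
        area = stack.reshape(10, -1).sum(axis=1) * pitch_mm**2
        slope, intercept = fit_area_vs_count(area, counts)
        disk_area = stack[0].sum() * pitch_mm**2
        assert slope == pytest.approx(disk_area, rel=1e-6)
        assert intercept == pytest.approx(0.0, abs=1e-9)

    def test_slope_recovers_generator_mean_area(self, droplet_statistics):
        slope = droplet_statistics["area_vs_count_slope_mm2"]
        expected = droplet_statistics["expected_slope_mm2"]
        assert slope == pytest.approx(expected, rel=0.15)

    def test_constant_count_rejected(self):
        with pytest.raises(ValueError):
            fit_area_vs_count([1.0, 2.0], [3, 3])


class TestDistributions:
    def test_single_event_step_cdf(self):
        stack = _disk_stack(10, [(20, 20, 4, 0, 5)])
        events, _ = label_events(stack)
        evs = [event_metrics(e, 26.7, 10.0) for e in events]
        summary = distribution_summary(evs)
        values, probs = summary.cdf()
        assert values.size == 1 and probs[-1] == 1.0

    def test_p95_diameter_recovery(self, droplet_statistics):
        assert droplet_statistics["n_events"] >= 3000
        assert droplet_statistics["p95_max_diameter_mm"] == pytest.approx(
            0.7, rel=0.10
        )

    def test_duration_cdf_monotone(self, droplet_statistics):
        summary = distribution_summary(droplet_statistics["events"])
        values, probs = summary.cdf("duration")
        assert np.all(np.diff(values) >= 0)
        assert np.all(np.diff(probs) > 0) and probs[-1] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            distribution_summary([])


class TestCyclePeriods:
    def test_single_pore_fixed_period(self):
        spec = [(20, 20, 4, f, f + 20) for f in range(0, 600, 60)]
        stack = _disk_stack(600, spec)
        events, _ = label_events(stack)
        evs = [event_metrics(e, 26.7, 10.0) for e in events]
        result = cycle_period_estimate(evs, 10.0)
        assert result["mean_period_s"] == pytest.approx(6.0)
        assert result["n_pores"] == 1

    def test_distant_pores_never_merged(self):
        spec = [(5, 5, 3, 0, 9), (40, 40, 3, 0, 9)]
        stack = _disk_stack(20, spec, shape=(200, 200))
        events, _ = label_events(stack)
        evs = [event_metrics(e, 26.7, 10.0) for e in events]
        result = cycle_period_estimate(evs, 10.0, cluster_radius_mm=0.5)
        assert result["n_pores"] == 2

    def test_generator_mean_period_recovered(self, droplet_statistics):
        assert droplet_statistics["mean_cycle_period_s"] == pytest.approx(
            droplet_statistics["true_mean_period_s"], rel=0.10
        )
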