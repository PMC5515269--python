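"""Synthetic-experiment generator: truth dynamics, rendering, determinism."""

import math

import numpy as np
import pytest

from biofilm_flowcell.segmentation import SegmentationParams, segment_stack
from biofilm_flowcell.synthetic import (
    ImagingLayout,
    SphereCluster,
    SyntheticParams,
    evolve_clusters,
    iter_position_stacks,
    render_stack,
    simulate_experiment,
)


class TestLayout:
    def test_full_window_pixel_count(self):
        assert ImagingLayout().window_px == 506  # round(212.55 / 0.42)

    def test_flow_rate_table(self):
        for q, (z, n) in ((0.1, (12, 47)), (0.5, (14, 62)), (1.5, (14, 60)), (4.0, (16, 73))):
            lay = ImagingLayout.for_flow_rate(q)
            assert (lay.z_slices, lay.n_cycles) == (z, n)

    def test_cycle_times_ten_minute_lattice(self):
        t = ImagingLayout.for_flow_rate(0.1).cycle_times
        assert t[0] == 40.0
        assert np.all(np.diff(t) == 10.0)
        assert t[-1] == 500.0  # cycle 47 ends the 8 h 20 min experiment

    def test_unknown_flow_rate_rejected(self):
        with pytest.raises(ValueError):
            ImagingLayout.for_flow_rate(2.0)


class TestEvolution:
    def test_pure_exponential_without_shedding(self, reduced_layout):
        params = SyntheticParams.reduced_window_defaults(
            rng_seed=5, detachment_rate=0.0
        ).noise_free()
        _, truth = evolve_clusters(params, reduced_layout, 5)
        t = reduced_layout.cycle_times
        g = truth.growth_rate
        pre = t <= truth.onset_time
        expected = truth.true_volumes[0] * np.exp(g * (t[pre] - t[0]))
        assert np.allclose(truth.true_volumes[pre], expected, rtol=1e-9)

    def test_doubling_ratio_between_cycles(self, reduced_layout):
        g = math.log(2.0) / 47.0
        params = SyntheticParams.reduced_window_defaults(
            rng_seed=5, detachment_rate=0.0, growth_rate=g
        ).noise_free()
        _, truth = evolve_clusters(params, reduced_layout, 3)
        v = truth.true_volumes
        pre = reduced_layout.cycle_times <= truth.onset_time
        ratios = v[pre][1:] / v[pre][:-1]
        assert np.allclose(ratios, 2.0 ** (10.0 / 47.0), rtol=1e-9)

    def test_onset_propagates_upstream_by_63_minutes(self):
        params = SyntheticParams()
        assert params.onset_time(12) == pytest.approx(370.0)
        assert params.onset_time(1) == pytest.approx(433.0)
        onsets = [params.onset_time(x) for x in range(1, 13)]
        assert all(a >= b for a, b in zip(onsets, onsets[1:]))  # non-increasing 1 -> 12
        assert onsets[0] - onsets[-1] == pytest.approx(63.0)

    def test_decay_after_onset(self, reduced_layout):
        params = SyntheticParams.reduced_window_defaults(
            rng_seed=5, detachment_rate=0.0
        ).noise_free()
        _, truth = evolve_clusters(params, reduced_layout, 12)
        t = reduced_layout.cycle_times
        post = t > truth.onset_time
        v_post = truth.true_volumes[post]
        assert np.all(np.diff(v_post) < 0)
        # half-life: 20 min of decay halves the volume
        lam = math.log(2.0) / params.dispersal_decay_halflife
        v_peak = truth.true_volumes[~post][-1]
        expected = v_peak * np.exp(-lam * (t[post] - truth.onset_time))
        assert np.allclose(v_post, expected, rtol=1e-9)

    def test_shedding_adds_single_cells(self, reduced_layout):
        base = SyntheticParams.reduced_window_defaults(rng_seed=5, detachment_rate=0.0)
        shed = SyntheticParams.reduced_window_defaults(rng_seed=5, detachment_rate=0.3)
        _, t0 = evolve_clusters(base, reduced_layout, 6)
        _, t1 = evolve_clusters(shed, reduced_layout, 6)
        assert len(t1.birth_times) > len(t0.birth_times)
        assert all(b >= 0 for b in t1.birth_times)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SyntheticParams(growth_rate=-0.01)
        with pytest.raises(ValueError):
            SyntheticParams(cell_intensity=5.0)  # below threshold + noise floor


class TestRendering:
    def test_empty_scene_uniform_background(self, reduced_layout):
        params = SyntheticParams.reduced_window_defaults(rng_seed=1).noise_free()
        stack = render_stack([], reduced_layout, params, t=100.0)
        assert stack.shape == (12, 128, 128)
        assert np.all(stack == round(params.background_intensity))

    def test_sphere_biovolume_recovered_within_10pct(self, reduced_layout):
        # analytic volume of an r = 3 um sphere vs voxelised segmentation
        params = SyntheticParams.reduced_window_defaults(rng_seed=1).noise_free()
        r = 3.0
        v = 4.0 / 3.0 * math.pi * r**3
        sphere = SphereCluster(
            cx=30.0, cy=30.0, v0=v, birth_time=0.0, growth_rate=1e-9,
            onset_time=1e9, decay_rate=1.0,
        )
        stack = render_stack([sphere], reduced_layout, params, t=0.0)
        clusters = segment_stack(stack, SegmentationParams())
        assert len(clusters) == 1
        assert clusters[0].biovolume == pytest.approx(113.1, rel=0.10)

    def test_interior_voxels_exceed_threshold(self, reduced_layout):
        params = SyntheticParams.reduced_window_defaults(
            rng_seed=1, cell_intensity=100.0, background_intensity=2.0
        ).noise_free()
        sphere = SphereCluster(
            cx=25.0, cy=25.0, v0=200.0, birth_time=0.0, growth_rate=1e-9,
            onset_time=1e9, decay_rate=1.0,
        )
        stack = render_stack([sphere], reduced_layout, params, t=0.0)
        assert stack.max() == 100
        assert (stack >= 10).sum() > 0
        # every supra-background voxel is at full cell intensity (no blur)
        assert set(np.unique(stack)) == {2, 100}


class TestExperimentDriver:
    def test_deterministic_stacks_for_fixed_seed(self, reduced_layout):
        params = SyntheticParams.reduced_window_defaults(rng_seed=9)
        a = [s for _, _, s in iter_position_stacks(params, reduced_layout, 12)]
        b = [s for _, _, s in iter_position_stacks(params, reduced_layout, 12)]
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_simulated_files_deterministic_and_complete(self, tmp_path):
        lay = ImagingLayout.reduced(n_cycles=3, window_px=64, areas=("a", "b"))
        params = SyntheticParams.reduced_window_defaults(rng_seed=4)
        m1 = simulate_experiment(params, lay, tmp_path / "run1")
        m2 = simulate_experiment(params, lay, tmp_path / "run2")
        assert m1["n_stacks"] == 12 * 2 * 3
        for name in m1["files"]:
            b1 = (tmp_path / "run1" / name).read_bytes()
            b2 = (tmp_path / "run2" / name).read_bytes()
            assert b1 == b2
        assert (tmp_path / "run1" / "truth.json").exists()

    def test_output_collision_raises(self, tmp_path):
        lay = ImagingLayout.reduced(n_cycles=1, window_px=64)
        params = SyntheticParams.reduced_window_defaults(rng_seed=4)
        simulate_experiment(params, lay, tmp_path / "run")
        with pytest.raises(FileExistsError):
            simulate_experiment(params, lay, tmp_path / "run")

    def test_low_flow_peak_biovolume_in_plausible_band(self, reduced_layout):
        # window totals at the dispersal peak are order 1e3-1e4 um^3
        params = SyntheticParams.reduced_window_defaults(rng_seed=3)
        for xi in (1, 7, 12):
            _, truth = evolve_clusters(params, reduced_layout, xi)
            assert 5e2 <= truth.true_volumes.max() <= 1e5

    def test_downstream_peaks_before_upstream_disperses(self, reduced_layout):
        # position 12 reaches its true peak before position 1's onset
        params = SyntheticParams.reduced_window_defaults(rng_seed=2)
        _, t12 = evolve_clusters(params, reduced_layout, 12)
        _, t1 = evolve_clusters(params, reduced_layout, 1)
        assert t12.onset_time < t1.onset_time
        peak12 = reduced_layout.cycle_times[np.argmax(t12.true_volumes)]
        assert peak12 <= t1.onset_time
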