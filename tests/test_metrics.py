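"""ROI rasterisation and CR/gCNR/SNR metric behaviour."""

import numpy as np
import pytest

from pasvd.core import PixelGrid
from pasvd.metrics import (
    RoiPolygon,
    contrast_ratio,
    gcnr,
    phase_select,
    rasterize_roi,
    rst_sweep,
    snr,
)
from pasvd.phantom import roi_from_box


def _grid(nz=10, nx=10, dz=1.0, dx=1.0):
    return PixelGrid(z_mm=1.0 + dz * np.arange(nz), x_mm=dx * np.arange(nx))


def _masks_from_values(t_vals, b_vals):
    """Two disjoint masks over a shared image holding the given value lists."""
    n = len(t_vals) + len(b_vals)
    env = np.array(t_vals + b_vals, dtype=float).reshape(1, n)
    tm = np.zeros((1, n), bool)
    bm = np.zeros((1, n), bool)
    tm[0, : len(t_vals)] = True
    bm[0, len(t_vals):] = True
    return env, tm, bm


class TestRasterize:
    def test_rectangle_counts_covered_pixel_centres(self):
        grid = _grid()
        poly = RoiPolygon(vertices=((2.0, 1.0), (2.0, 5.0), (5.0, 5.0), (5.0, 1.0)))
        mask = rasterize_roi(poly, grid)
        assert mask.sum() == 4 * 5  # rows z=2..5, cols x=1..5, boundary inclusive

    def test_triangle_matches_ray_casting_oracle(self):
        grid = _grid(12, 12, 0.7, 0.9)
        verts = ((1.4, 0.5), (7.7, 1.2), (4.1, 8.3))
        poly = RoiPolygon(vertices=verts)
        mask = rasterize_roi(poly, grid)

        def inside(z, x):
            # ray casting with boundary tolerance
            cnt = 0
            pts = list(verts)
            for (z1, x1), (z2, x2) in zip(pts, pts[1:] + pts[:1]):
                d = (z2 - z1) * (x - x1) - (x2 - x1) * (z - z1)
                if abs(d) < 1e-12 and min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12:
                    return True  # on edge
                if (x1 > x) != (x2 > x):
                    z_int = z1 + (x - x1) / (x2 - x1) * (z2 - z1)
                    if z_int > z:
                        cnt += 1
            return cnt % 2 == 1

        oracle = np.array([[inside(z, x) for x in grid.x_mm] for z in grid.z_mm])
        assert np.array_equal(mask, oracle)

    def test_polygon_outside_grid_yields_empty_mask(self, caplog):
        grid = _grid()
        poly = RoiPolygon(vertices=((100.0, 100.0), (101.0, 100.0), (100.5, 101.0)))
        with caplog.at_level("WARNING"):
            mask = rasterize_roi(poly, grid)
        assert mask.sum() == 0
        assert any("no pixel" in r.message for r in caplog.records)

    def test_self_intersecting_polygon_rejected(self):
        with pytest.raises(ValueError, match="simple"):
            RoiPolygon(vertices=((0, 0), (1, 1), (1, 0), (0, 1)))

    def test_too_few_vertices_rejected(self):
        with pytest.raises(ValueError):
            RoiPolygon(vertices=((0, 0), (1, 1)))


class TestContrastRatio:
    def test_equal_means_give_zero_db(self):
        env, tm, bm = _masks_from_values([3.0, 3.0], [3.0, 3.0])
        assert contrast_ratio(env, tm, bm) == pytest.approx(0.0)

    def test_decade_gives_twenty_db(self):
        env, tm, bm = _masks_from_values([10.0, 10.0], [1.0, 1.0])
        assert contrast_ratio(env, tm, bm) == pytest.approx(20.0)

    def test_worked_example(self):
        env, tm, bm = _masks_from_values([2.0, 4.0], [1.0, 1.0])
        assert contrast_ratio(env, tm, bm) == pytest.approx(20 * np.log10(3.0))

    def test_zero_background_rejected(self):
        env, tm, bm = _masks_from_values([1.0], [0.0])
        with pytest.raises(ValueError):
            contrast_ratio(env, tm, bm)


class TestGcnr:
    def test_identical_distributions_give_zero(self, rng):
        vals = rng.random(50).tolist()
        env, tm, bm = _masks_from_values(vals, vals)
        assert gcnr(env, tm, bm) == pytest.approx(0.0)

    def test_disjoint_supports_give_one(self, rng):
        env, tm, bm = _masks_from_values((10 + rng.random(40)).tolist(), rng.random(40).tolist())
        assert gcnr(env, tm, bm) == pytest.approx(1.0)

    def test_worked_two_value_example(self):
        env, tm, bm = _masks_from_values([0.0, 1.0], [0.0, 0.0])
        assert gcnr(env, tm, bm, n_bins=100) == pytest.approx(0.5)

    def test_all_identical_values_give_zero(self):
        env, tm, bm = _masks_from_values([2.0, 2.0], [2.0, 2.0])
        assert gcnr(env, tm, bm) == 0.0

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(10):
            env, tm, bm = _masks_from_values(
                rng.normal(1, 1, 30).tolist(), rng.normal(2, 1, 30).tolist()
            )
            assert 0.0 <= gcnr(env, tm, bm) <= 1.0

    def test_invariant_under_monotone_transform_within_a_bin(self, rng):
        t = rng.normal(5, 1, 200)
        b = rng.normal(7, 1, 200)
        env, tm, bm = _masks_from_values(t.tolist(), b.tolist())
        base = gcnr(env, tm, bm)
        for f in (np.exp, np.sqrt, lambda x: x**3):
            assert gcnr(f(env - env.min() + 1e-3), tm, bm) == pytest.approx(base, abs=0.05)

    def test_monotone_as_target_translates_away(self, rng):
        b = rng.normal(0, 1, 300)
        vals = []
        for shift in (0.0, 1.0, 2.0, 4.0):
            t = rng.normal(shift, 1, 300)
            env, tm, bm = _masks_from_values(t.tolist(), b.tolist())
            vals.append(gcnr(env, tm, bm))
        assert all(b2 >= b1 - 0.03 for b1, b2 in zip(vals, vals[1:]))


class TestSnr:
    def test_unity_ratio_gives_zero_db(self):
        env, tm, bm = _masks_from_values([1.0, 1.0], [0.0, 2.0])  # sigma_b = 1 (population)
        assert snr(env, tm, bm) == pytest.approx(0.0)

    def test_population_std_convention(self):
        env, tm, bm = _masks_from_values([10.0, 10.0], [0.0, 2.0])
        assert snr(env, tm, bm) == pytest.approx(20.0)

    def test_scale_invariance(self, rng):
        env, tm, bm = _masks_from_values(rng.random(20).tolist(), rng.random(20).tolist())
        assert snr(3.7 * env, tm, bm) == pytest.approx(snr(env, tm, bm))

    def test_cr_scale_invariance(self, rng):
        env, tm, bm = _masks_from_values(rng.random(20).tolist(), (1 + rng.random(20)).tolist())
        assert contrast_ratio(5.1 * env, tm, bm) == pytest.approx(contrast_ratio(env, tm, bm))

    def test_zero_variance_background_rejected(self):
        env, tm, bm = _masks_from_values([1.0], [2.0, 2.0])
        with pytest.raises(ValueError):
            snr(env, tm, bm)


class TestPhaseSelect:
    def test_nearest_frame_per_phase(self):
        delays = np.array([0.0, 0.05, 0.10, 0.15])
        out = phase_select(delays, {"systole": 0.04, "end_systole": 0.11})
        assert out == {"systole": 1, "end_systole": 2}

    def test_single_frame_cycle_maps_everything_to_it(self):
        out = phase_select(np.array([0.02]), {"a": 0.0, "b": 0.5})
        assert out == {"a": 0, "b": 0}

    def test_delay_beyond_span_clamps_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = phase_select(np.array([0.0, 0.1]), {"late": 0.5})
        assert out == {"late": 1}
        assert any("clamped" in r.message for r in caplog.records)

    def test_empty_cycle_rejected(self):
        with pytest.raises(ValueError):
            phase_select(np.array([]), {"a": 0.0})

    def test_phantom_end_systole_has_maximal_wall_thickness(self, clutter_heavy):
        _, gt = clutter_heavy
        delays = np.arange(gt.wall_thickness_mm.size) * (gt.rr_s / gt.wall_thickness_mm.size)
        frames = phase_select(delays, gt.phase_delays_s)
        es = frames["end_systole"]
        assert gt.wall_thickness_mm[es] == pytest.approx(gt.wall_thickness_mm.max(), rel=1e-3)


class TestRstSweep:
    def test_sweep_improves_contrast_over_unfiltered(self, clutter_heavy, clutter_heavy_das):
        _, gt = clutter_heavy
        bf = clutter_heavy_das
        frames = phase_select(bf.timestamps, gt.phase_delays_s)
        rois = (
            roi_from_box(gt.target_box_mm, "target"),
            roi_from_box(gt.background_box_mm, "background"),
        )
        sweep = rst_sweep(bf, None, (0, 1, 2, 4, 6), 1e-3, rois, frames, tau_mode="relative")
        assert sorted(sweep["rst"].unique().tolist()) == [0, 1, 2, 4, 6]
        assert set(sweep["phase"]) == set(gt.phase_delays_s)
        mean_cr = sweep.groupby("rst")["cr_db"].mean()
        assert mean_cr.idxmax() != 0
        assert mean_cr.max() > mean_cr.loc[0]

    def test_null_phantom_sweep_is_flat_within_noise(self):
        from pasvd.beamform import beamform_cine
        from pasvd.phantom import PhantomConfig, simulate_channel_cine

        cfg = PhantomConfig(seed=13, wall=None, noise_sigma=0.5, n_frames=48)
        cine, gt = simulate_channel_cine(cfg)
        bf = beamform_cine(cine)
        rois = (
            roi_from_box((7.95, 8.95, -1.6, 0.0), "target"),
            roi_from_box(gt.background_box_mm, "background"),
        )
        sweep = rst_sweep(bf, None, (0, 1, 2, 4), 1e-3, rois, {"mid": 24}, tau_mode="relative")
        g = sweep["gcnr"]
        assert g.max() - g.min() < 0.2
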