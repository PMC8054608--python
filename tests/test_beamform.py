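"""DAS and MV beamformers against geometry arithmetic and brute-force oracles."""

import numpy as np
import pytest

from pasvd.beamform import (
    SubArrayConfig,
    beamform_cine,
    compute_apodization,
    compute_delays,
    das_frame,
    mv_frame,
    mv_weights_from_covariance,
    n_subarrays,
)
from pasvd.core import ArrayGeometry, ChannelCine, PixelGrid
from pasvd.phantom import PhantomConfig, simulate_channel_cine
from pasvd.phantom import _scatter_sources


def das_oracle(channels, geometry, grid, f_number=1.0):
    """Brute-force per-pixel delay-and-sum, written from the definition."""
    out = np.zeros(grid.shape, dtype=complex)
    c = geometry.speed_of_sound_m_s
    fs, fc = geometry.fs_hz, geometry.fc_hz
    t0 = geometry.sample_start_time_s
    ex = geometry.element_x_mm
    n_samples = channels.shape[0]
    for iz, z in enumerate(grid.z_mm):
        for ix, xp in enumerate(grid.x_mm):
            acc = 0.0 + 0.0j
            for e in range(geometry.n_elements):
                if abs(ex[e] - xp) > z / (2 * f_number):
                    continue
                tau = np.sqrt(z**2 + (ex[e] - xp) ** 2) * 1e-3 / c
                s = (tau - t0) * fs
                lo = int(np.floor(s))
                w = s - lo
                v = 0.0 + 0.0j
                if 0 <= lo < n_samples:
                    v += (1 - w) * channels[lo, e]
                if 0 <= lo + 1 < n_samples:
                    v += w * channels[lo + 1, e]
                acc += v * np.exp(2j * np.pi * fc * tau)
            out[iz, ix] = acc
    return out


class TestDelays:
    def test_on_axis_pixel_gives_distance_over_c(self):
        geom = ArrayGeometry(n_elements=1, depth_offset_mm=0.5, speed_of_sound_m_s=1540.0)
        grid = PixelGrid(z_mm=np.array([1.54]), x_mm=geom.element_x_mm)
        table = compute_delays(geom, grid)
        assert table.delays_s[0, 0, 0] == pytest.approx(1.0e-6)

    def test_matches_independent_distance_computation(self, rng):
        geom = ArrayGeometry(n_elements=16)
        grid = PixelGrid(z_mm=rng.uniform(2, 10, 5), x_mm=rng.uniform(-1, 1, 4))
        table = compute_delays(geom, grid)
        for iz in range(5):
            for ix in range(4):
                for e in range(16):
                    d = np.hypot(grid.z_mm[iz], grid.x_mm[ix] - geom.element_x_mm[e])
                    assert table.delays_s[iz, ix, e] == pytest.approx(
                        d * 1e-3 / 1540.0, rel=1e-12
                    )

    def test_on_axis_delay_linear_in_depth(self):
        geom = ArrayGeometry(n_elements=1)
        grid = PixelGrid(z_mm=np.array([2.0, 4.0]), x_mm=geom.element_x_mm)
        table = compute_delays(geom, grid)
        assert table.delays_s[1, 0, 0] == pytest.approx(2 * table.delays_s[0, 0, 0])

    def test_nonpositive_depth_rejected(self):
        geom = ArrayGeometry(n_elements=4)
        with pytest.raises(ValueError):
            PixelGrid(z_mm=np.array([0.0]), x_mm=np.array([0.0]))


class TestApodization:
    def test_f1_aperture_width_in_elements(self):
        # pixel midway between elements at depth 1.98 mm, f#=1, 90 um pitch:
        # aperture half-width 0.99 mm -> floor(1980/90) = 22 active elements
        geom = ArrayGeometry(n_elements=64, pitch_um=90.0)
        xp = 0.5 * (geom.element_x_mm[31] + geom.element_x_mm[32])
        grid = PixelGrid(z_mm=np.array([1.98]), x_mm=np.array([xp]))
        apod = compute_apodization(geom, grid, f_number=1.0)
        assert int(apod.weights.sum()) == 22

    def test_aperture_grows_with_depth(self):
        geom = ArrayGeometry(n_elements=64)
        grid = PixelGrid(z_mm=np.array([2.0, 4.0]), x_mm=np.array([0.0]))
        apod = compute_apodization(geom, grid, 1.0)
        assert apod.weights[1].sum() > apod.weights[0].sum()


class TestDasFrame:
    def test_single_element_zero_delay_is_identity(self):
        geom = ArrayGeometry(n_elements=1, depth_offset_mm=5.0)
        grid = PixelGrid(z_mm=np.array([5.0]), x_mm=geom.element_x_mm)
        table = compute_delays(geom, grid)
        apod = compute_apodization(geom, grid, 1.0)
        ch = np.zeros((8, 1), complex)
        tau = table.delays_s[0, 0, 0]
        ch[0, 0] = (2.0 + 1.0j) * np.exp(-2j * np.pi * geom.fc_hz * tau)
        frame = das_frame(ch, table, apod, geom)
        assert frame[0, 0] == pytest.approx(2.0 + 1.0j)

    def test_point_source_focuses_at_source_pixel(self):
        geom = ArrayGeometry(n_elements=32)
        cfg_sources = (np.array([8.0]), np.array([0.0]), np.array([1.0]))
        ch = np.zeros((200, 32), complex)
        _scatter_sources(ch, *cfg_sources, geom)
        grid = PixelGrid.default_for(geom, 200)
        table = compute_delays(geom, grid)
        apod = compute_apodization(geom, grid, 1.0)
        frame = das_frame(ch, table, apod, geom)
        env = np.abs(frame)
        iz, ix = np.unravel_index(env.argmax(), env.shape)
        assert abs(grid.z_mm[iz] - 8.0) < 2 * geom.axial_spacing_mm
        assert abs(grid.x_mm[ix]) < 2 * geom.pitch_mm

    def test_linearity_and_scaling(self, rng):
        geom = ArrayGeometry(n_elements=8)
        grid = PixelGrid(z_mm=np.linspace(5, 7, 6), x_mm=geom.element_x_mm[2:6])
        table = compute_delays(geom, grid)
        apod = compute_apodization(geom, grid, 1.0)
        x = rng.standard_normal((50, 8)) + 1j * rng.standard_normal((50, 8))
        y = rng.standard_normal((50, 8)) + 1j * rng.standard_normal((50, 8))
        fa = das_frame(x, table, apod, geom)
        fb = das_frame(y, table, apod, geom)
        fab = das_frame(2.0 * x + 3.0 * y, table, apod, geom)
        assert np.allclose(fab, 2.0 * fa + 3.0 * fb, rtol=1e-12)

    def test_matches_brute_force_oracle_on_random_data(self, rng):
        geom = ArrayGeometry(n_elements=12)
        grid = PixelGrid(z_mm=np.linspace(5.5, 8.5, 9), x_mm=geom.element_x_mm[3:9])
        ch = rng.standard_normal((120, 12)) + 1j * rng.standard_normal((120, 12))
        table = compute_delays(geom, grid)
        apod = compute_apodization(geom, grid, 1.0)
        fast = das_frame(ch, table, apod, geom)
        slow = das_oracle(ch, geom, grid)
        assert np.allclose(fast, slow, rtol=0, atol=1e-10 * np.abs(slow).max())


class TestMv:
    def test_subarray_count_64_16(self):
        assert n_subarrays(64, 16) == 49

    def test_identity_covariance_gives_uniform_weights(self):
        w = mv_weights_from_covariance(np.eye(16))
        assert np.allclose(w, np.ones(16) / 16)

    def test_distortionless_on_focused_constant_signal(self):
        geom = ArrayGeometry(n_elements=32)
        grid = PixelGrid(z_mm=np.array([8.0]), x_mm=np.array([0.0]))
        table = compute_delays(geom, grid)
        apod = compute_apodization(geom, grid, 1.0)
        s = 2.0 - 1.5j
        ch = np.zeros((240, 32), complex)
        frac = table.frac_index[0, 0]
        ph = np.exp(2j * np.pi * geom.fc_hz * table.delays_s[0, 0])
        for e in range(32):
            lo = int(np.floor(frac[e]))
            ch[lo, e] = s / ph[e]
            ch[lo + 1, e] = s / ph[e]
        out = mv_frame(ch, table, apod, geom, SubArrayConfig(ns=16, diagonal_loading=0.01))
        assert abs(out[0, 0] - s) < 1e-6

    def test_scales_linearly_with_input(self, rng):
        geom = ArrayGeometry(n_elements=16)
        grid = PixelGrid(z_mm=np.array([6.0, 7.0]), x_mm=geom.element_x_mm[6:10])
        table = compute_delays(geom, grid)
        apod = compute_apodization(geom, grid, 1.0)
        ch = rng.standard_normal((100, 16)) + 1j * rng.standard_normal((100, 16))
        cfg = SubArrayConfig(ns=4, diagonal_loading=0.01)
        f1 = mv_frame(ch, table, apod, geom, cfg)
        f3 = mv_frame(3.0 * ch, table, apod, geom, cfg)
        assert np.allclose(f3, 3.0 * f1, rtol=1e-10)

    def test_ns1_equals_das_of_element_mean_on_constant_signal(self):
        geom = ArrayGeometry(n_elements=8)
        grid = PixelGrid(z_mm=np.array([8.0]), x_mm=np.array([0.0]))
        table = compute_delays(geom, grid)
        apod = compute_apodization(geom, grid, 1.0)
        ch = np.zeros((240, 8), complex)
        frac = table.frac_index[0, 0]
        ph = np.exp(2j * np.pi * geom.fc_hz * table.delays_s[0, 0])
        for e in range(8):
            lo = int(np.floor(frac[e]))
            ch[lo, e] = 1.0 / ph[e]
            ch[lo + 1, e] = 1.0 / ph[e]
        das = das_frame(ch, table, apod, geom)
        mv = mv_frame(ch, table, apod, geom, SubArrayConfig(ns=1, diagonal_loading=0.0))
        n_active = int(apod.weights.sum())
        assert mv[0, 0] == pytest.approx(das[0, 0] / n_active, rel=1e-9)


class TestBeamformCine:
    def test_identity_gating_preserves_frame_count(self, clean_wall):
        cine, _ = clean_wall
        bf = beamform_cine(cine)
        assert bf.n_frames == cine.n_frames
        assert bf.method == "DAS"

    def test_das_and_mv_share_dimensions(self, rng):
        geom = ArrayGeometry(n_elements=8)
        data = rng.standard_normal((40, 8, 2)) + 1j * rng.standard_normal((40, 8, 2))
        cine = ChannelCine(data=data, timestamps=np.array([0.0, 0.05]), geometry=geom)
        grid = PixelGrid(z_mm=np.linspace(5, 6, 8), x_mm=geom.element_x_mm)
        das = beamform_cine(cine, method="das", grid=grid)
        mv = beamform_cine(cine, method="mv", grid=grid, subarray=SubArrayConfig(ns=4))
        assert das.shape == mv.shape
        assert np.array_equal(das.grid.z_mm, mv.grid.z_mm)

    def test_paper_sized_output_dimensions(self):
        cfg = PhantomConfig(seed=1, n_samples=296, n_frames=4)
        cine, _ = simulate_channel_cine(cfg)
        bf = beamform_cine(cine)
        assert bf.shape == (296, 64, 4)
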