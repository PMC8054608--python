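"""Delay-and-sum (DAS) and minimum-variance (MV) beamforming of IQ channel data.

Photoacoustic reception is one-way: the optical pulse excites all absorbers
simultaneously, so the delay to a pixel is just the acoustic propagation
time from the pixel to the element.  Because the channel data are complex
baseband IQ, delaying a channel requires both a fractional-sample shift
(linear interpolation) and a phase rotation by ``exp(+i 2 pi f_c tau)`` to
re-align the carrier phase removed by demodulation.

The MV beamformer estimates, per pixel, a sub-array-averaged covariance of
the delayed aperture signals and applies the distortionless
minimum-variance weights

    w = R^-1 a / (a^H R^-1 a),

with a unit (all-ones) steering vector — the steering delays have already
been applied by dynamic receive focusing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import ArrayGeometry, BeamformedCine, ChannelCine, PixelGrid
from .physio import GatedCycle

logger = logging.getLogger(__name__)

__all__ = [
    "DelayTable",
    "ApodizationMask",
    "SubArrayConfig",
    "compute_delays",
    "compute_apodization",
    "das_frame",
    "mv_frame",
    "mv_weights_from_covariance",
    "n_subarrays",
    "beamform_cine",
]


@dataclass(frozen=True)
class DelayTable:
    """One-way propagation delays, per pixel and element.

    ``delays_s`` has shape ``(Nz, Nx, n_elements)``; ``frac_index`` is the
    equivalent (fractional) IQ sample index for each delay.
    """

    delays_s: np.ndarray
    frac_index: np.ndarray
    grid: PixelGrid

    def __post_init__(self) -> None:
        if np.any(self.delays_s < 0):
            raise ValueError("delays must be nonnegative")


@dataclass(frozen=True)
class ApodizationMask:
    """Per-pixel element weights implementing dynamic f-number apodization.

    Weights are binary (uniform aperture weighting): an element is active
    at a pixel iff its lateral offset from the pixel satisfies
    ``|x_e - x_p| <= z / (2 f#)``, boundary included.
    """

    weights: np.ndarray  # (Nz, Nx, n_elements), values in [0, 1]
    f_number: float

    def __post_init__(self) -> None:
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ValueError("apodization weights must lie in [0, 1]")


@dataclass(frozen=True)
class SubArrayConfig:
    """Sub-array (spatial-smoothing) settings for the MV beamformer.

    ``diagonal_loading`` is the fraction of the covariance trace (divided
    by the sub-array length) added to the diagonal before inversion.
    """

    ns: int = 16
    diagonal_loading: float = 0.01

    def __post_init__(self) -> None:
        if self.ns < 1:
            raise ValueError("sub-array length must be >= 1")
        if self.diagonal_loading < 0:
            raise ValueError("diagonal loading must be >= 0")


def compute_delays(geometry: ArrayGeometry, grid: PixelGrid) -> DelayTable:
    """One-way delay from every pixel to every element centre.

    delay(pixel, element) = ||pixel - element|| / c.  The fractional sample
    index accounts for the acquisition depth offset.
    """
    z = grid.z_mm[:, None, None]  # (Nz,1,1)
    dx = grid.x_mm[None, :, None] - geometry.element_x_mm[None, None, :]  # (1,Nx,Ne)
    dist_mm = np.sqrt(z**2 + dx**2)
    delays = dist_mm * 1e-3 / geometry.speed_of_sound_m_s
    frac = (delays - geometry.sample_start_time_s) * geometry.fs_hz
    return DelayTable(delays_s=delays, frac_index=frac, grid=grid)


def compute_apodization(
    geometry: ArrayGeometry, grid: PixelGrid, f_number: float = 1.0
) -> ApodizationMask:
    """Binary dynamic apodization: aperture width z / f#, centred on the pixel."""
    if f_number <= 0:
        raise ValueError("f-number must be > 0")
    z = grid.z_mm[:, None, None]
    dx = np.abs(grid.x_mm[None, :, None] - geometry.element_x_mm[None, None, :])
    weights = (dx <= z / (2.0 * f_number)).astype(float)
    return ApodizationMask(weights=weights, f_number=f_number)


class _DelayInterpolator:
    """Precomputed interpolation indices/weights and phase rotation.

    Shared across the frames of a cine so the per-frame work is just two
    gathers and a weighted sum.
    """

    def __init__(self, table: DelayTable, geometry: ArrayGeometry, n_samples: int):
        frac = table.frac_index
        lo = np.floor(frac).astype(np.int64)
        self.w = frac - lo
        hi = lo + 1
        self.valid_lo = (lo >= 0) & (lo < n_samples)
        self.valid_hi = (hi >= 0) & (hi < n_samples)
        self.lo_c = np.clip(lo, 0, n_samples - 1)
        self.hi_c = np.clip(hi, 0, n_samples - 1)
        self.e_idx = np.arange(table.frac_index.shape[2])[None, None, :]
        self.phase = np.exp(2j * np.pi * geometry.fc_hz * table.delays_s)

    def __call__(self, channels: np.ndarray) -> np.ndarray:
        s_lo = channels[self.lo_c, self.e_idx] * self.valid_lo
        s_hi = channels[self.hi_c, self.e_idx] * self.valid_hi
        delayed = (1.0 - self.w) * s_lo + self.w * s_hi
        delayed *= self.phase
        return delayed


def _delayed_channels(
    channels: np.ndarray, table: DelayTable, geometry: ArrayGeometry
) -> np.ndarray:
    """Delay-compensated channel stack, shape (Nz, Nx, n_elements).

    Linear interpolation at the fractional sample index; out-of-range
    samples contribute zero.  The baseband phase rotation
    ``exp(+i 2 pi f_c tau)`` is applied.
    """
    return _DelayInterpolator(table, geometry, channels.shape[0])(channels)


def das_frame(
    channels: np.ndarray,
    delays: DelayTable,
    apod: ApodizationMask,
    geometry: ArrayGeometry,
) -> np.ndarray:
    """DAS beamform a single frame of channel data to a complex image.

    Pixel value = sum over active elements of the delayed, phase-rotated
    IQ sample.  Pixels with an empty active aperture come out zero and are
    counted in a debug log message.
    """
    channels = np.asarray(channels, dtype=np.complex128)
    delayed = _delayed_channels(channels, delays, geometry)
    frame = np.sum(delayed * apod.weights, axis=-1)
    n_empty = int(np.count_nonzero(apod.weights.sum(axis=-1) == 0))
    if n_empty:
        logger.debug("%d pixel(s) had an empty active aperture", n_empty)
    return frame


def n_subarrays(aperture_length: int, ns: int) -> int:
    """Number of overlapping length-``ns`` sub-arrays in an aperture."""
    if not 1 <= ns <= aperture_length:
        raise ValueError("require 1 <= ns <= aperture length")
    return aperture_length - ns + 1


def mv_weights_from_covariance(
    r: np.ndarray, diagonal_loading: float = 0.0
) -> np.ndarray:
    """Distortionless MV weights for covariance ``r`` and all-ones steering.

    ``w = R^-1 a / (a^H R^-1 a)`` with ``a = ones``; the formula is
    invariant to the steering vector's scale.  Diagonal loading adds
    ``loading / Ns * trace(R)`` to the diagonal.
    """
    r = np.asarray(r)
    ns = r.shape[0]
    if diagonal_loading:
        r = r + (diagonal_loading / ns) * np.trace(r).real * np.eye(ns)
    a = np.ones(ns, dtype=complex)
    w0 = np.linalg.solve(r, a)
    return w0 / (a.conj() @ w0)


def mv_frame(
    channels: np.ndarray,
    delays: DelayTable,
    apod: ApodizationMask,
    geometry: ArrayGeometry,
    config: SubArrayConfig = SubArrayConfig(),
) -> np.ndarray:
    """MV beamform a single frame with sub-array covariance averaging.

    Per pixel, the delayed active-aperture vector of length L is split
    into L - Ns + 1 overlapping sub-vectors; their averaged outer product
    (plus diagonal loading) is inverted for the MV weights, which are
    applied to the mean sub-vector.  Where fewer than Ns elements are
    active the sub-array length is clamped to the active count; a
    covariance that stays singular after loading falls back to uniform
    weights (counted in a debug log message).
    """
    channels = np.asarray(channels, dtype=np.complex128)
    delayed = _delayed_channels(channels, delays, geometry)
    return _mv_from_delayed(delayed, apod, config)


def _mv_from_delayed(
    delayed: np.ndarray, apod: ApodizationMask, config: SubArrayConfig
) -> np.ndarray:
    active = apod.weights > 0
    nz, nx, _ = delayed.shape
    out = np.zeros((nz, nx), dtype=np.complex128)
    n_fallback = 0
    for iz in range(nz):
        for ix in range(nx):
            sel = active[iz, ix]
            x = delayed[iz, ix, sel]
            L = x.size
            if L == 0:
                continue
            ns = min(config.ns, L)
            subs = np.lib.stride_tricks.sliding_window_view(x, ns)  # (L-ns+1, ns)
            r = (subs.T @ subs.conj()) / subs.shape[0]
            ybar = subs.mean(axis=0)
            try:
                w = mv_weights_from_covariance(r, config.diagonal_loading)
            except np.linalg.LinAlgError:
                n_fallback += 1
                w = np.ones(ns, dtype=complex) / ns
            out[iz, ix] = w.conj() @ ybar
    if n_fallback:
        logger.debug("MV fell back to uniform weights at %d pixel(s)", n_fallback)
    return out


def beamform_cine(
    cine: ChannelCine,
    cycle: GatedCycle | None = None,
    method: str = "das",
    *,
    grid: PixelGrid | None = None,
    f_number: float = 1.0,
    subarray: SubArrayConfig | None = None,
    element_weights: np.ndarray | None = None,
    method_tag: str | None = None,
) -> BeamformedCine:
    """Beamform a channel cine frame by frame into a :class:`BeamformedCine`.

    With a :class:`~pasvd.physio.GatedCycle` the frames are beamformed in
    gated (cardiac-delay) order and the output timestamps are the cardiac
    delays; otherwise all frames are used in acquisition order.

    ``element_weights`` (length ``n_elements``) multiplies the dynamic
    apodization — this is how the complementary PSAP sub-apertures are
    realised.
    """
    method = method.lower()
    if method not in ("das", "mv"):
        raise ValueError("method must be 'das' or 'mv'")
    geometry = cine.geometry
    if grid is None:
        grid = PixelGrid.default_for(geometry, cine.n_samples)
    table = compute_delays(geometry, grid)
    apod = compute_apodization(geometry, grid, f_number)
    if element_weights is not None:
        element_weights = np.asarray(element_weights, dtype=float)
        if element_weights.shape != (geometry.n_elements,):
            raise ValueError("element_weights must have one entry per element")
        apod = ApodizationMask(
            weights=apod.weights * element_weights[None, None, :],
            f_number=apod.f_number,
        )
    if cycle is None:
        frame_order = np.arange(cine.n_frames)
        timestamps = cine.timestamps.copy()
    else:
        if np.any(cycle.kept_indices < 0) or np.any(cycle.kept_indices >= cine.n_frames):
            raise ValueError("gated cycle indexes frames outside the cine")
        frame_order = cycle.kept_indices
        timestamps = cycle.cardiac_delays_s.copy()

    frames = np.empty((grid.shape[0], grid.shape[1], frame_order.size), dtype=np.complex128)
    cfg = subarray or SubArrayConfig()
    interp = _DelayInterpolator(table, geometry, cine.n_samples)
    for k, fi in enumerate(frame_order):
        ch = cine.data[:, :, fi]
        if method == "das":
            frames[:, :, k] = np.sum(interp(ch) * apod.weights, axis=-1)
        else:
            frames[:, :, k] = _mv_from_delayed(interp(ch), apod, cfg)
    tag = method_tag or method.upper()
    return BeamformedCine(data=frames, timestamps=timestamps, grid=grid, method=tag)
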