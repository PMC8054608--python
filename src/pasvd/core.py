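"""Core containers for linear-array photoacoustic (PA) cine data.

Conventions used throughout the package:

* Channel data are complex IQ (in-phase/quadrature baseband) arrays with
  axes ``(n_samples, n_elements, n_frames)``.
* Beamformed cines have axes ``(depth, lateral, time)``, i.e. ``(Nz, Nx, Nt)``.
* Pixel coordinates and element positions are in millimetres, element pitch
  in micrometres, frequencies in MHz — the units found on linear-array
  datasheets.  SI-unit helper properties are provided for computation.
* Photoacoustic propagation is one-way (light in, sound out), so the sample
  index along depth maps to a one-way time of flight.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ArrayGeometry",
    "PixelGrid",
    "ChannelCine",
    "BeamformedCine",
    "envelope",
]


@dataclass(frozen=True)
class ArrayGeometry:
    """Geometry and sampling parameters of a linear transducer array.

    Defaults describe a 64-element PA receive aperture of a high-frequency
    small-animal array (90 um pitch, 21 MHz centre frequency, 13-24 MHz
    bandwidth) with an assumed speed of sound of 1540 m/s.
    """

    n_elements: int = 64
    pitch_um: float = 90.0
    center_frequency_mhz: float = 21.0
    bandwidth_low_mhz: float = 13.0
    bandwidth_high_mhz: float = 24.0
    iq_sampling_rate_mhz: float = 41.0
    speed_of_sound_m_s: float = 1540.0
    depth_offset_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.n_elements < 1:
            raise ValueError("n_elements must be >= 1")
        if self.pitch_um <= 0:
            raise ValueError("pitch_um must be > 0")
        if self.speed_of_sound_m_s <= 0:
            raise ValueError("speed_of_sound_m_s must be > 0")
        if self.iq_sampling_rate_mhz <= 0:
            raise ValueError("iq_sampling_rate_mhz must be > 0")
        if not self.bandwidth_low_mhz < self.bandwidth_high_mhz:
            raise ValueError("bandwidth_low_mhz must be < bandwidth_high_mhz")

    # -- derived quantities -------------------------------------------------

    @property
    def pitch_mm(self) -> float:
        return self.pitch_um * 1e-3

    @property
    def fc_hz(self) -> float:
        return self.center_frequency_mhz * 1e6

    @property
    def fs_hz(self) -> float:
        return self.iq_sampling_rate_mhz * 1e6

    @property
    def element_x_mm(self) -> np.ndarray:
        """Lateral element-centre positions [mm], centred on the aperture."""
        n = self.n_elements
        return (np.arange(n) - (n - 1) / 2.0) * self.pitch_mm

    @property
    def axial_spacing_mm(self) -> float:
        """Depth advance per IQ sample for one-way propagation, c / fs [mm]."""
        return self.speed_of_sound_m_s / self.fs_hz * 1e3

    @property
    def sample_start_time_s(self) -> float:
        """One-way time of flight to the first sample (the depth offset)."""
        return self.depth_offset_mm * 1e-3 / self.speed_of_sound_m_s

    def sample_times_s(self, n_samples: int) -> np.ndarray:
        """One-way arrival times [s] of the IQ samples."""
        return self.sample_start_time_s + np.arange(n_samples) / self.fs_hz


@dataclass(frozen=True)
class PixelGrid:
    """Rectilinear image grid: depth coordinates ``z_mm`` by lateral ``x_mm``."""

    z_mm: np.ndarray
    x_mm: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "z_mm", np.asarray(self.z_mm, dtype=float))
        object.__setattr__(self, "x_mm", np.asarray(self.x_mm, dtype=float))
        if self.z_mm.ndim != 1 or self.x_mm.ndim != 1:
            raise ValueError("grid coordinates must be 1-D")
        if np.any(self.z_mm <= 0):
            raise ValueError("pixel depths must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.z_mm.size, self.x_mm.size)

    @classmethod
    def default_for(cls, geometry: ArrayGeometry, n_samples: int) -> "PixelGrid":
        """One A-line per element; axial spacing c/fs from the depth offset.

        With this grid a scatterer directly above element *e* at sample *m*
        beamforms back onto pixel (m, e) without interpolation error.
        """
        z = geometry.depth_offset_mm + np.arange(n_samples) * geometry.axial_spacing_mm
        return cls(z_mm=z, x_mm=geometry.element_x_mm.copy())


def _check_finite(a: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")


@dataclass
class ChannelCine:
    """Pre-beamformed complex IQ channel data over acquisition frames.

    ``data`` has shape ``(n_samples, n_elements, n_frames)``; ``timestamps``
    are the per-frame acquisition times in seconds, strictly increasing.
    """

    data: np.ndarray
    timestamps: np.ndarray
    geometry: ArrayGeometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("channel data must be (n_samples, n_elements, n_frames)")
        if self.data.shape[1] != self.geometry.n_elements:
            raise ValueError(
                f"data has {self.data.shape[1]} elements, geometry declares "
                f"{self.geometry.n_elements}"
            )
        if self.timestamps.shape != (self.data.shape[2],):
            raise ValueError("one timestamp per frame required")
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        _check_finite(self.data, "channel data")
        _check_finite(self.timestamps, "timestamps")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]


@dataclass
class BeamformedCine:
    """Complex beamformed cine ``(Nz, Nx, Nt)`` on a pixel grid.

    ``timestamps`` hold per-frame cardiac time (the delay from the nearest
    R wave once the cine has been gated, or acquisition time otherwise).
    ``method`` tags provenance: "DAS", "MV", "DAS-S1", "DAS-S2", "SVD-k",
    "PSAP-SVD", ...
    """

    data: np.ndarray
    timestamps: np.ndarray
    grid: PixelGrid
    method: str = "DAS"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.iscomplexobj(self.data):
            self.data = self.data.astype(float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("beamformed data must be (Nz, Nx, Nt)")
        if self.data.shape[:2] != self.grid.shape:
            raise ValueError("beamformed data does not match pixel grid")
        if self.timestamps.shape != (self.data.shape[2],):
            raise ValueError("one timestamp per frame required")
        if min(self.data.shape) < 1:
            raise ValueError("all cine dimensions must be >= 1")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    def frame(self, k: int) -> np.ndarray:
        return self.data[:, :, k]

    def envelope(self) -> np.ndarray:
        """Envelope (modulus) of every frame, shape ``(Nz, Nx, Nt)``."""
        return np.abs(self.data)

    def with_data(self, data: np.ndarray, method: str | None = None) -> "BeamformedCine":
        return BeamformedCine(
            data=data,
            timestamps=self.timestamps.copy(),
            grid=self.grid,
            method=self.method if method is None else method,
        )


def envelope(frame: np.ndarray) -> np.ndarray:
    """Envelope of a complex IQ frame: the elementwise modulus.

    IQ data are analytic baseband signals, so no Hilbert transform is
    needed; ``|z|`` is the detected amplitude.  The result is nonnegative
    and invariant under a global phase rotation of the input.
    """
    frame = np.asarray(frame)
    _check_finite(frame, "frame")
    return np.abs(frame)
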