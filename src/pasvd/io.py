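"""HDF5 container I/O for channel-data cines, physio traces and results.

Layout of the cine container (all datasets float64)::

    /channel_data/real   (n_samples, n_elements, n_frames)
    /channel_data/imag   (n_samples, n_elements, n_frames)
    /timestamps          (n_frames,)                 [s]
    /geometry            group; geometry fields as attributes
    /physio/ecg          optional; samples with attrs sampling_rate_hz, t0_s
    /physio/resp         optional; same attrs

Beamformed cines use ``/beamformed/{real,imag}``, ``/grid/{z_mm,x_mm}`` and
a ``method`` attribute.  Complex arrays are split into two real datasets so
the files remain readable from any HDF5 binding.
"""

from __future__ import annotations

import os
from dataclasses import fields as dataclass_fields

import h5py
import numpy as np

from .core import ArrayGeometry, BeamformedCine, ChannelCine, PixelGrid
from .physio import PhysioTrace

__all__ = [
    "read_cine",
    "write_cine",
    "read_physio",
    "read_beamformed",
    "write_beamformed",
    "geometry_from_toml",
]

_GEOMETRY_FIELDS = [f.name for f in dataclass_fields(ArrayGeometry)]


class FormatError(RuntimeError):
    """Raised when a container file does not match the documented layout."""


def _require(h5: h5py.File, key: str):
    if key not in h5:
        raise FormatError(f"container is missing required key '{key}'")
    return h5[key]


def write_cine(
    cine: ChannelCine,
    path: str | os.PathLike,
    *,
    ecg: PhysioTrace | None = None,
    resp: PhysioTrace | None = None,
    overwrite: bool = False,
) -> str:
    """Write a channel cine (and optional physio traces) to ``path``."""
    path = os.fspath(path)
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    with h5py.File(path, "w") as h5:
        g = h5.create_group("channel_data")
        g.create_dataset("real", data=cine.data.real)
        g.create_dataset("imag", data=cine.data.imag)
        h5.create_dataset("timestamps", data=cine.timestamps)
        geo = h5.create_group("geometry")
        for name in _GEOMETRY_FIELDS:
            geo.attrs[name] = getattr(cine.geometry, name)
        if ecg is not None or resp is not None:
            ph = h5.create_group("physio")
            for name, trace in (("ecg", ecg), ("resp", resp)):
                if trace is None:
                    continue
                d = ph.create_dataset(name, data=trace.samples)
                d.attrs["sampling_rate_hz"] = trace.sampling_rate_hz
                d.attrs["t0_s"] = trace.t0_s
    return path


def read_cine(path: str | os.PathLike) -> ChannelCine:
    """Read a channel cine written by :func:`write_cine`."""
    with h5py.File(os.fspath(path), "r") as h5:
        cd = _require(h5, "channel_data")
        if "real" not in cd or "imag" not in cd:
            raise FormatError("channel_data must hold 'real' and 'imag' datasets")
        data = np.asarray(cd["real"]) + 1j * np.asarray(cd["imag"])
        timestamps = np.asarray(_require(h5, "timestamps"))
        geo_group = _require(h5, "geometry")
        kwargs = {}
        for name in _GEOMETRY_FIELDS:
            if name not in geo_group.attrs:
                raise FormatError(f"geometry attribute '{name}' missing")
            val = geo_group.attrs[name]
            kwargs[name] = int(val) if name == "n_elements" else float(val)
        geometry = ArrayGeometry(**kwargs)
    return ChannelCine(data=data, timestamps=timestamps, geometry=geometry)


def read_physio(path: str | os.PathLike, which: str) -> PhysioTrace:
    """Read the 'ecg' or 'resp' trace stored alongside a cine."""
    if which not in ("ecg", "resp"):
        raise ValueError("which must be 'ecg' or 'resp'")
    with h5py.File(os.fspath(path), "r") as h5:
        d = _require(h5, f"physio/{which}")
        return PhysioTrace(
            samples=np.asarray(d),
            sampling_rate_hz=float(d.attrs["sampling_rate_hz"]),
            t0_s=float(d.attrs.get("t0_s", 0.0)),
        )


def write_beamformed(
    cine: BeamformedCine, path: str | os.PathLike, *, overwrite: bool = False
) -> str:
    path = os.fspath(path)
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    data = np.asarray(cine.data, dtype=np.complex128)
    with h5py.File(path, "w") as h5:
        g = h5.create_group("beamformed")
        g.create_dataset("real", data=data.real)
        g.create_dataset("imag", data=data.imag)
        h5.attrs["method"] = cine.method
        h5.create_dataset("timestamps", data=cine.timestamps)
        grid = h5.create_group("grid")
        grid.create_dataset("z_mm", data=cine.grid.z_mm)
        grid.create_dataset("x_mm", data=cine.grid.x_mm)
    return path


def read_beamformed(path: str | os.PathLike) -> BeamformedCine:
    with h5py.File(os.fspath(path), "r") as h5:
        bf = _require(h5, "beamformed")
        data = np.asarray(bf["real"]) + 1j * np.asarray(bf["imag"])
        timestamps = np.asarray(_require(h5, "timestamps"))
        grid = PixelGrid(
            z_mm=np.asarray(_require(h5, "grid/z_mm")),
            x_mm=np.asarray(_require(h5, "grid/x_mm")),
        )
        method = str(h5.attrs.get("method", "DAS"))
    return BeamformedCine(data=data, timestamps=timestamps, grid=grid, method=method)


def geometry_from_toml(path: str | os.PathLike) -> ArrayGeometry:
    """Load an :class:`ArrayGeometry` from a flat TOML key-value file.

    Keys match the dataclass field names; unknown keys are rejected to
    surface typos early.
    """
    import tomllib

    with open(os.fspath(path), "rb") as fh:
        raw = tomllib.load(fh)
    unknown = set(raw) - set(_GEOMETRY_FIELDS)
    if unknown:
        raise FormatError(f"unknown geometry keys: {sorted(unknown)}")
    return ArrayGeometry(**raw)
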