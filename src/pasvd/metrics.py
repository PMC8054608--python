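"""Image-quality metrics over polygonal ROIs: CR, gCNR and SNR.

All metrics are evaluated on envelope (modulus) images without log
compression.  With target mean ``mu_t``, background mean ``mu_b`` and
background standard deviation ``sigma_b``:

* contrast ratio            CR  = 20 log10(mu_t / mu_b)          [dB]
* signal-to-noise ratio     SNR = 20 log10(mu_t / sigma_b)       [dB]
* generalised CNR           gCNR = 1 - sum_l min(k_t(x_l), k_b(x_l))

where ``k_t`` and ``k_b`` are the target/background histograms over N
shared amplitude bins (default 100).  gCNR measures target detectability
as one minus the histogram overlap and is invariant to any monotone
remapping of the dynamic range; it lies in [0, 1].

The standard-deviation convention is population (divide by n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely

from .core import BeamformedCine, ChannelCine, PixelGrid
from .physio import GatedCycle
from .beamform import beamform_cine
from .svd import CutoffPair, decompose, filter_svs, from_casorati, reconstruct, select_high_cutoff, to_casorati

logger = logging.getLogger(__name__)

__all__ = [
    "RoiPolygon",
    "rasterize_roi",
    "contrast_ratio",
    "gcnr",
    "snr",
    "evaluate_frame",
    "phase_select",
    "rst_sweep",
]


@dataclass(frozen=True)
class RoiPolygon:
    """Simple polygon in image coordinates, vertices as (depth mm, lateral mm)."""

    vertices: tuple[tuple[float, float], ...]
    role: str = "target"

    def __post_init__(self) -> None:
        verts = tuple((float(z), float(x)) for z, x in self.vertices)
        object.__setattr__(self, "vertices", verts)
        if len(verts) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        if self.role not in ("target", "background"):
            raise ValueError("role must be 'target' or 'background'")
        if not self._shapely().is_valid:
            raise ValueError("polygon must be simple (non-self-intersecting)")

    def _shapely(self) -> shapely.Polygon:
        # shapely is (x, y); map lateral -> x, depth -> y
        return shapely.Polygon([(x, z) for z, x in self.vertices])


def rasterize_roi(poly: RoiPolygon, grid: PixelGrid) -> np.ndarray:
    """Boolean mask of pixels whose centre lies in the polygon (boundary in)."""
    shp = poly._shapely()
    zz, xx = np.meshgrid(grid.z_mm, grid.x_mm, indexing="ij")
    pts = shapely.points(xx.ravel(), zz.ravel())
    mask = shapely.covers(shp, pts).reshape(grid.shape)
    if not mask.any():
        logger.warning("ROI polygon covers no pixel centre on this grid")
    return mask


def _roi_values(env: np.ndarray, mask: np.ndarray) -> np.ndarray:
    env = np.asarray(env, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if env.shape != mask.shape:
        raise ValueError("mask shape does not match image")
    if not mask.any():
        raise ValueError("ROI mask is empty")
    return env[mask]


def _check_equal_area(target_mask: np.ndarray, background_mask: np.ndarray) -> None:
    nt, nb = int(target_mask.sum()), int(background_mask.sum())
    if nt != nb:
        logger.warning("target ROI (%d px) and background ROI (%d px) differ in area", nt, nb)


def contrast_ratio(env: np.ndarray, target_mask: np.ndarray, background_mask: np.ndarray) -> float:
    """CR = 20 log10(mu_t / mu_b) in dB."""
    mu_t = _roi_values(env, target_mask).mean()
    mu_b = _roi_values(env, background_mask).mean()
    if mu_b == 0:
        raise ValueError("background mean is zero; CR undefined")
    _check_equal_area(target_mask, background_mask)
    return 20.0 * np.log10(mu_t / mu_b)


def gcnr(
    env: np.ndarray,
    target_mask: np.ndarray,
    background_mask: np.ndarray,
    n_bins: int = 100,
    *,
    bin_range: tuple[float, float] | None = None,
) -> float:
    """gCNR = 1 - histogram overlap over ``n_bins`` shared bins.

    Bin edges span the pooled min..max of the two ROIs by default; pass
    ``bin_range`` to bin over e.g. the full image range instead.  If every
    pooled value is identical the distributions overlap completely and
    gCNR is 0.
    """
    t = _roi_values(env, target_mask)
    b = _roi_values(env, background_mask)
    if bin_range is None:
        lo, hi = min(t.min(), b.min()), max(t.max(), b.max())
    else:
        lo, hi = bin_range
    if hi <= lo:
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    k_t = np.histogram(np.clip(t, lo, hi), bins=edges)[0] / t.size
    k_b = np.histogram(np.clip(b, lo, hi), bins=edges)[0] / b.size
    return float(1.0 - np.minimum(k_t, k_b).sum())


def snr(env: np.ndarray, target_mask: np.ndarray, background_mask: np.ndarray) -> float:
    """SNR = 20 log10(mu_t / sigma_b) in dB, population standard deviation."""
    t = _roi_values(env, target_mask)
    b = _roi_values(env, background_mask)
    if b.size < 2:
        raise ValueError("background needs at least 2 pixels")
    sigma_b = b.std()  # population convention
    if sigma_b == 0:
        raise ValueError("background standard deviation is zero; SNR undefined")
    return 20.0 * np.log10(t.mean() / sigma_b)


def evaluate_frame(
    env: np.ndarray,
    target_mask: np.ndarray,
    background_mask: np.ndarray,
    n_bins: int = 100,
) -> dict[str, float]:
    """CR, gCNR and SNR of one envelope frame over a target/background pair."""
    return {
        "cr_db": contrast_ratio(env, target_mask, background_mask),
        "gcnr": gcnr(env, target_mask, background_mask, n_bins=n_bins),
        "snr_db": snr(env, target_mask, background_mask),
        "n_target_px": float(target_mask.sum()),
        "n_background_px": float(background_mask.sum()),
    }


def phase_select(
    cardiac_delays_s: np.ndarray | GatedCycle,
    phase_delays_s: Mapping[str, float],
) -> dict[str, int]:
    """Nearest gated-frame index for each named cardiac phase delay.

    Phases requested beyond the cycle span clamp to the last frame with a
    warning.  Typical phase names: systole, end_systole, diastole.
    """
    if isinstance(cardiac_delays_s, GatedCycle):
        delays = cardiac_delays_s.cardiac_delays_s
    else:
        delays = np.asarray(cardiac_delays_s, dtype=float)
    if delays.size == 0:
        raise ValueError("empty gated cycle")
    out: dict[str, int] = {}
    for name, d in phase_delays_s.items():
        if d > delays[-1]:
            logger.warning(
                "phase '%s' delay %.4f s beyond cycle span %.4f s; clamped to last frame",
                name, d, delays[-1],
            )
            out[name] = delays.size - 1
        else:
            out[name] = int(np.argmin(np.abs(delays - d)))
    return out


def rst_sweep(
    cine: ChannelCine | BeamformedCine,
    cycle: GatedCycle | None,
    rst_values: Sequence[int],
    tau: float,
    rois: tuple[RoiPolygon, RoiPolygon],
    phase_frames: Mapping[str, int],
    *,
    tau_mode: str = "absolute",
    n_bins: int = 100,
    f_number: float = 1.0,
) -> pd.DataFrame:
    """CR/gCNR/SNR versus the low-order cutoff ``rst``, per cardiac phase.

    Channel data are DAS-beamformed (once) and decomposed (once); each
    ``rst`` reuses the decomposition, so the sweep costs one SVD plus one
    reconstruction per cutoff.  Returns a tidy DataFrame with columns
    ``rst, phase, frame, cr_db, gcnr, snr_db``.
    """
    if isinstance(cine, ChannelCine):
        bf = beamform_cine(cine, cycle, "das", f_number=f_number)
    else:
        bf = cine
    target, background = rois
    if target.role == "background" and background.role == "target":
        target, background = background, target
    t_mask = rasterize_roi(target, bf.grid)
    b_mask = rasterize_roi(background, bf.grid)

    dec = decompose(to_casorati(bf))
    rrt = select_high_cutoff(dec.sigma, tau, mode=tau_mode)
    rows = []
    for rst in rst_values:
        filtered = from_casorati(
            reconstruct(filter_svs(dec, CutoffPair(rst=int(rst), rrt=rrt, tau=tau))),
            method=f"SVD-{rst}",
        )
        env = filtered.envelope()
        for phase, fi in phase_frames.items():
            m = evaluate_frame(env[:, :, fi], t_mask, b_mask, n_bins=n_bins)
            rows.append({"rst": int(rst), "phase": phase, "frame": int(fi), **m})
    return pd.DataFrame(rows)
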