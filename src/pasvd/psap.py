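"""Photoacoustic sub-aperture processing (PSAP) coupled with SVD filtering.

Two complementary sub-apertures (alternating blocks of two elements)
produce two independent reconstructions of the same scene.  A coherent
target appears nearly identically in both, while incoherent background
(noise, residual clutter) decorrelates between them.  The per-pixel,
per-frame zero-lag normalised cross-correlation (NCC) of the two
SVD-filtered sub-aperture cines — computed on the complex IQ data, see
:func:`ncc_weight_cine` — forms a weighting volume ``W_PSAP`` in [0, 1]
that multiplies the full-aperture SVD-processed envelope to suppress
background.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter

from .core import BeamformedCine, ChannelCine
from .physio import GatedCycle
from .beamform import beamform_cine
from .svd import svd_process

__all__ = [
    "make_subaperture_weights",
    "ncc_weight_cine",
    "apply_psap",
    "psap_svd_pipeline",
]


def make_subaperture_weights(n_elements: int) -> tuple[np.ndarray, np.ndarray]:
    """Complementary binary sub-aperture weights, alternating in blocks of two.

    ``w1 = (1,1,0,0,1,1,0,0,...)`` and ``w2`` its complement, so the two
    sub-apertures share no element and together cover the full aperture.
    """
    if n_elements < 4:
        raise ValueError("need at least 4 elements for two sub-apertures")
    idx = np.arange(n_elements)
    w1 = ((idx // 2) % 2 == 0).astype(float)
    return w1, 1.0 - w1


def ncc_weight_cine(
    cine_a: BeamformedCine,
    cine_b: BeamformedCine,
    window: tuple[int, int] = (11, 3),
) -> np.ndarray:
    """Zero-lag NCC between two cines in a local spatial window, per frame.

    NCC is computed on the complex IQ data:

        w = Re{ sum A conj(B) } / sqrt( sum |A|^2 * sum |B|^2 )

    over the local window.  Phase-coherent signal present in both
    sub-apertures scores near 1 even where the envelope is locally flat,
    while independent noise averages towards 0; this is why the
    correlation is deliberately *not* mean-removed — a mean-removed
    (envelope) correlation measures only the local fluctuations and would
    suppress the interior of a uniform coherent target.  Negative
    correlations are clamped to zero (suppress, never invert) and
    zero-energy patches get weight zero.  Returns the weighting volume
    ``(Nz, Nx, Nt)``, values in [0, 1].
    """
    if cine_a.shape != cine_b.shape:
        raise ValueError("cines must share dimensions")
    wz, wx = window
    if wz < 1 or wx < 1 or wz % 2 == 0 or wx % 2 == 0:
        raise ValueError("window sides must be odd and >= 1")
    a = np.asarray(cine_a.data, dtype=np.complex128)
    b = np.asarray(cine_b.data, dtype=np.complex128)
    size = (wz, wx)
    out = np.empty(a.shape, dtype=float)
    for k in range(a.shape[2]):
        fa, fb = a[:, :, k], b[:, :, k]
        cross = uniform_filter((fa * fb.conj()).real, size=size, mode="reflect")
        ea = uniform_filter(np.abs(fa) ** 2, size=size, mode="reflect")
        eb = uniform_filter(np.abs(fb) ** 2, size=size, mode="reflect")
        denom = np.sqrt(np.clip(ea, 0.0, None) * np.clip(eb, 0.0, None))
        scale = max(np.abs(fa).max(), np.abs(fb).max(), 1.0)
        tiny = (scale * 1e-12) ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            ncc = np.where(denom > tiny, cross / np.where(denom > tiny, denom, 1.0), 0.0)
        out[:, :, k] = np.clip(ncc, 0.0, 1.0)
    return out


def apply_psap(svd_cine: BeamformedCine, weights: np.ndarray) -> BeamformedCine:
    """Multiply the SVD-processed envelope by the PSAP weighting volume.

    The output cine holds real envelope data tagged ``"PSAP-SVD"``; since
    weights lie in [0, 1] no pixel's amplitude can increase.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape != svd_cine.shape:
        raise ValueError("weight volume does not match the cine dimensions")
    if np.any(weights < 0) or np.any(weights > 1):
        raise ValueError("PSAP weights must lie in [0, 1]")
    return svd_cine.with_data(svd_cine.envelope() * weights, method="PSAP-SVD")


def psap_svd_pipeline(
    cine: ChannelCine,
    cycle: GatedCycle | None = None,
    rst: int = 2,
    tau: float = 20.0,
    *,
    tau_mode: str = "absolute",
    window: tuple[int, int] = (11, 3),
    f_number: float = 1.0,
) -> tuple[BeamformedCine, np.ndarray]:
    """Coupled PSAP + SVD background suppression from channel data.

    The cine is DAS-beamformed three times (sub-aperture 1, sub-aperture 2,
    full aperture), each reconstruction is SVD-filtered with the same
    cutoffs, the two sub-aperture results give the NCC weighting volume,
    and the weights multiply the full-aperture SVD envelope.  Returns the
    PSAP-SVD cine and the weighting volume.
    """
    w1, w2 = make_subaperture_weights(cine.geometry.n_elements)
    parts = []
    for w, tag in ((w1, "DAS-S1"), (w2, "DAS-S2"), (None, "DAS")):
        bf = beamform_cine(
            cine, cycle, "das", f_number=f_number, element_weights=w, method_tag=tag
        )
        filt, _, _ = svd_process(bf, rst=rst, tau=tau, tau_mode=tau_mode)
        parts.append(filt)
    s1, s2, full = parts
    weights = ncc_weight_cine(s1, s2, window=window)
    return apply_psap(full, weights), weights
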