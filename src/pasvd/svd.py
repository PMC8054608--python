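"""Spatiotemporal SVD clutter filtering on the Casorati matrix.

A gated cine P (Nz, Nx, Nt) is reorganised into the Casorati matrix
S of shape (Nz*Nx, Nt), whose columns are the vectorised frames.  The
thin SVD ``S = U diag(sigma) V^H`` orders the spatiotemporal components
by energy; with gated cardiac data the lowest singular orders carry
quasi-static clutter, mid orders carry the contracting/relaxing
myocardium, and the tail carries incoherent noise and fast blood
transients.  Filtering keeps the band of singular orders
``rst < k <= rrt`` (1-based): ``rst`` leading orders are discarded and
everything above the high-order cutoff ``rrt`` is truncated, after which
the cine is reconstructed by the inverse reorganisation.

The high-order cutoff is selected from the singular value spectrum (SVS)
gradient: the last order before the backward difference
``sigma[k-1] - sigma[k]`` first drops below a threshold ``tau``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import BeamformedCine, PixelGrid

__all__ = [
    "CasoratiMatrix",
    "SvdDecomposition",
    "CutoffPair",
    "to_casorati",
    "from_casorati",
    "decompose",
    "select_high_cutoff",
    "filter_svs",
    "reconstruct",
    "svd_process",
]


@dataclass
class CasoratiMatrix:
    """Casorati reorganisation of a cine: columns are vectorised frames.

    Source-cine metadata (spatial shape, grid, timestamps, method tag) is
    retained so the inverse reorganisation rebuilds an identical cine.
    """

    matrix: np.ndarray  # (Nz*Nx, Nt)
    spatial_shape: tuple[int, int]
    grid: PixelGrid
    timestamps: np.ndarray
    method: str

    def __post_init__(self) -> None:
        nz, nx = self.spatial_shape
        if self.matrix.shape != (nz * nx, self.timestamps.size):
            raise ValueError("Casorati matrix shape inconsistent with source dims")


@dataclass
class SvdDecomposition:
    """Thin SVD of a Casorati matrix, plus the source metadata.

    ``u`` is (Nz*Nx, r), ``sigma`` length r, ``vh`` is (r, Nt) with
    r = min(Nz*Nx, Nt).  After :func:`filter_svs` the retained band of
    ``sigma`` is no longer monotone; ``filtered`` records that.
    """

    u: np.ndarray
    sigma: np.ndarray
    vh: np.ndarray
    source: CasoratiMatrix
    filtered: bool = False

    def __post_init__(self) -> None:
        r = self.sigma.size
        if self.u.shape[1] != r or self.vh.shape[0] != r:
            raise ValueError("inconsistent SVD factor shapes")
        if np.any(self.sigma < 0):
            raise ValueError("singular values must be nonnegative")
        if not self.filtered and np.any(np.diff(self.sigma) > 0):
            raise ValueError("singular values must be non-increasing")

    @property
    def rank(self) -> int:
        return self.sigma.size


@dataclass(frozen=True)
class CutoffPair:
    """Low/high singular-order cutoffs.

    ``rst`` counts discarded leading orders (0 discards none — "SVD-0"
    still truncates the tail); ``rrt`` is the last order kept, 1-based.
    """

    rst: int
    rrt: int
    tau: float = 20.0

    def __post_init__(self) -> None:
        if self.rst < 0:
            raise ValueError("rst must be >= 0")
        if not self.rst < self.rrt:
            raise ValueError("require rst < rrt")


def to_casorati(cine: BeamformedCine) -> CasoratiMatrix:
    """Reorganise (Nz, Nx, Nt) into the (Nz*Nx, Nt) Casorati matrix."""
    nz, nx, nt = cine.shape
    return CasoratiMatrix(
        matrix=cine.data.reshape(nz * nx, nt).copy(),
        spatial_shape=(nz, nx),
        grid=cine.grid,
        timestamps=cine.timestamps.copy(),
        method=cine.method,
    )


def from_casorati(cas: CasoratiMatrix, method: str | None = None) -> BeamformedCine:
    """Inverse reorganisation; exact inverse of :func:`to_casorati`."""
    nz, nx = cas.spatial_shape
    return BeamformedCine(
        data=cas.matrix.reshape(nz, nx, cas.matrix.shape[1]).copy(),
        timestamps=cas.timestamps.copy(),
        grid=cas.grid,
        method=cas.method if method is None else method,
    )


def decompose(cas: CasoratiMatrix) -> SvdDecomposition:
    """Thin SVD of the Casorati matrix."""
    if not np.all(np.isfinite(cas.matrix)):
        raise ValueError("Casorati matrix contains non-finite entries")
    try:
        u, sigma, vh = np.linalg.svd(cas.matrix, full_matrices=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rare LAPACK failure
        norm = np.linalg.norm(cas.matrix)
        raise np.linalg.LinAlgError(
            f"SVD failed to converge (matrix shape {cas.matrix.shape}, "
            f"Frobenius norm {norm:.3e})"
        ) from exc
    return SvdDecomposition(u=u, sigma=sigma, vh=vh, source=cas)


def select_high_cutoff(
    sigma: np.ndarray, tau: float, mode: str = "absolute"
) -> int:
    """High-order cutoff from the SVS gradient.

    Scanning k = 2..r (1-based), the cutoff is ``k - 1`` for the first k
    whose backward difference ``sigma[k-2] - sigma[k-1]`` falls below the
    threshold; if no difference does, all orders are kept (``rrt = r``).
    In ``mode="relative"`` the threshold is ``tau * sigma[0]``, which
    makes the rule portable across data scales.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.size < 2:
        raise ValueError("need at least two singular values")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if mode not in ("absolute", "relative"):
        raise ValueError("mode must be 'absolute' or 'relative'")
    thr = tau * sigma[0] if mode == "relative" else tau
    drops = sigma[:-1] - sigma[1:]
    below = np.nonzero(drops < thr)[0]
    if below.size == 0:
        return sigma.size
    return int(below[0]) + 1  # 1-based order before the first small drop


def filter_svs(dec: SvdDecomposition, cut: CutoffPair) -> SvdDecomposition:
    """Zero all singular orders outside ``rst < k <= rrt`` (1-based)."""
    if cut.rrt > dec.rank:
        raise ValueError("rrt exceeds the number of singular values")
    mask = np.zeros(dec.rank)
    mask[cut.rst : cut.rrt] = 1.0
    return replace(dec, sigma=dec.sigma * mask, filtered=True)


def reconstruct(dec: SvdDecomposition) -> CasoratiMatrix:
    """Rebuild the (filtered) Casorati matrix ``U diag(sigma) V^H``."""
    matrix = (dec.u * dec.sigma[None, :]) @ dec.vh
    return CasoratiMatrix(
        matrix=matrix,
        spatial_shape=dec.source.spatial_shape,
        grid=dec.source.grid,
        timestamps=dec.source.timestamps.copy(),
        method=dec.source.method,
    )


def svd_process(
    cine: BeamformedCine,
    rst: int = 4,
    tau: float = 20.0,
    *,
    tau_mode: str = "absolute",
    rrt: int | None = None,
) -> tuple[BeamformedCine, CutoffPair, np.ndarray]:
    """Full spatiotemporal SVD pipeline on a gated cine.

    Composes Casorati reorganisation, thin SVD, high-order cutoff selection
    (unless ``rrt`` is forced), band filtering, reconstruction and inverse
    reorganisation.  Returns the filtered cine (tagged ``"SVD-{rst}"``),
    the cutoffs used and the full singular value spectrum for inspection.
    """
    cas = to_casorati(cine)
    dec = decompose(cas)
    sigma = dec.sigma.copy()
    if rrt is None:
        rrt = select_high_cutoff(sigma, tau, mode=tau_mode)
    cut = CutoffPair(rst=rst, rrt=rrt, tau=tau)
    filtered = filter_svs(dec, cut)
    out = from_casorati(reconstruct(filtered), method=f"SVD-{rst}")
    return out, cut, sigma
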