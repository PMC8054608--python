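"""End-to-end orchestration: simulate/gate/beamform/filter/weight/measure.

``run_pipeline`` executes the full processing chain on a phantom (or a
cine container on disk), writing metrics, the singular value spectrum and
comparison figures into a run directory.  Every stage's parameters are
logged so a run is reproducible from its log alone.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .core import BeamformedCine, ChannelCine
from .physio import GatedCycle, detect_breaths, detect_r_waves, reorder_by_cardiac_delay, respiratory_gate, reconstruct_gated_ecg
from .beamform import SubArrayConfig, beamform_cine
from .svd import svd_process
from .psap import psap_svd_pipeline
from .metrics import contrast_ratio, gcnr, phase_select, rasterize_roi, rst_sweep, snr
from .phantom import (
    PhantomConfig,
    _clutter_heavy_config,
    roi_from_box,
    simulate_channel_cine,
    simulate_physio,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "gate_cine"]


@dataclass
class PipelineConfig:
    """Parameters for one end-to-end run on a phantom preset."""

    out_dir: str = "pasvd_run"
    seed: int = 7
    preset: str = "clutter-heavy"
    n_frames: int | None = None  # override the preset's frame count
    rst: int = 2
    rst_sweep_values: tuple[int, ...] = (0, 1, 2, 4, 6)
    tau: float = 1e-3
    tau_mode: str = "relative"
    f_number: float = 1.0
    mv_subarray: SubArrayConfig = field(default_factory=SubArrayConfig)
    psap_window: tuple[int, int] = (11, 3)
    include_mv: bool = True
    make_figures: bool = True

    def __post_init__(self) -> None:
        if self.rst < 0:
            raise ValueError("rst must be >= 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


@dataclass
class PipelineResult:
    out_dir: str
    metrics: pd.DataFrame
    sweep: pd.DataFrame
    sigma: np.ndarray
    cutoffs: tuple[int, int]


def gate_cine(
    cine: ChannelCine,
    ecg,
    resp,
    *,
    smoothing_window_s: float = 0.1,
    prominence_fraction: float = 0.3,
    min_rr_s: float = 0.12,
) -> GatedCycle:
    """Detect breaths and R waves, gate the frames and reorder by delay."""
    events = detect_breaths(resp, smoothing_window_s, prominence_fraction)
    r_times = detect_r_waves(ecg, min_rr_s)
    kept = respiratory_gate(cine.timestamps, events)
    logger.info(
        "respiratory gating kept %d / %d frames across %d breaths",
        kept.size, cine.n_frames, len(events),
    )
    cycle = reorder_by_cardiac_delay(cine.timestamps, kept, r_times)
    reconstruct_gated_ecg(ecg, cycle, cine.timestamps)
    return cycle


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full chain on the configured phantom preset.

    Produces, in ``out_dir``: ``metrics.csv`` (per method x phase),
    ``rst_sweep.csv``, ``svs.csv`` (singular value spectrum),
    ``run_config.json`` and, if enabled, ``svs.png`` plus a four-panel
    method-comparison figure at end-systole.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    if config.preset == "clutter-heavy":
        cfg = _clutter_heavy_config(seed=config.seed)
    elif config.preset == "clean-wall":
        cfg = PhantomConfig(seed=config.seed)
    else:
        raise ValueError(f"unknown preset '{config.preset}'")
    if config.n_frames is not None:
        from dataclasses import replace

        cfg = replace(cfg, n_frames=config.n_frames)

    cine, gt = simulate_channel_cine(cfg)
    if cfg.pregated:
        cycle = None
        delays = cine.timestamps
    else:
        ecg, resp, _ = simulate_physio(cfg)
        cycle = gate_cine(cine, ecg, resp)
        delays = cycle.cardiac_delays_s

    das = beamform_cine(cine, cycle, "das", f_number=config.f_number)
    svd_cine, cut, sigma = svd_process(
        das, rst=config.rst, tau=config.tau, tau_mode=config.tau_mode
    )
    svd0_cine, _, _ = svd_process(das, rst=0, tau=config.tau, tau_mode=config.tau_mode)
    psap_cine, _ = psap_svd_pipeline(
        cine, cycle, rst=config.rst, tau=config.tau,
        tau_mode=config.tau_mode, window=config.psap_window,
        f_number=config.f_number,
    )
    methods: dict[str, BeamformedCine] = {
        "DAS": das, "SVD-0": svd0_cine, f"SVD-{config.rst}": svd_cine,
        "PSAP-SVD": psap_cine,
    }
    if config.include_mv:
        phase_frames_tmp = phase_select(delays, gt.phase_delays_s)
        mv = _mv_at_frames(cine, cycle, sorted(set(phase_frames_tmp.values())), config)
        methods["MV"] = mv

    target = roi_from_box(gt.target_box_mm, "target")
    background = roi_from_box(gt.background_box_mm, "background")
    t_mask = rasterize_roi(target, das.grid)
    b_mask = rasterize_roi(background, das.grid)
    phase_frames = phase_select(delays, gt.phase_delays_s)

    rows = []
    for name, bf in methods.items():
        env = bf.envelope()
        for phase, fi in phase_frames.items():
            col = fi if name != "MV" else list(sorted(set(phase_frames.values()))).index(fi)
            rows.append(
                {"method": name, "phase": phase,
                 **_safe_metrics(env[:, :, col], t_mask, b_mask)}
            )
    metrics = pd.DataFrame(rows)
    sweep = rst_sweep(
        das, None, config.rst_sweep_values, config.tau,
        (target, background), phase_frames, tau_mode=config.tau_mode,
    )

    metrics.to_csv(os.path.join(config.out_dir, "metrics.csv"), index=False)
    sweep.to_csv(os.path.join(config.out_dir, "rst_sweep.csv"), index=False)
    pd.DataFrame({"order": np.arange(1, sigma.size + 1), "sigma": sigma}).to_csv(
        os.path.join(config.out_dir, "svs.csv"), index=False
    )
    cfg_json = asdict(config)
    cfg_json["mv_subarray"] = asdict(config.mv_subarray)
    with open(os.path.join(config.out_dir, "run_config.json"), "w") as fh:
        json.dump(cfg_json, fh, indent=2, default=str)
    if config.make_figures:
        _figures(config.out_dir, methods, phase_frames, sigma, sweep)
    logger.info("pipeline run complete: %s (cutoffs rst=%d, rrt=%d)",
                config.out_dir, cut.rst, cut.rrt)
    return PipelineResult(
        out_dir=config.out_dir, metrics=metrics, sweep=sweep,
        sigma=sigma, cutoffs=(cut.rst, cut.rrt),
    )


def _safe_metrics(env, t_mask, b_mask) -> dict:
    """All three metrics; NaN (with a log line) where a metric is undefined.

    A fully suppressed background (every ROI pixel exactly zero, as PSAP
    weighting can produce) leaves CR and SNR without a defined value.
    """
    out = {"cr_db": np.nan, "gcnr": np.nan, "snr_db": np.nan}
    for key, fn in (("cr_db", contrast_ratio), ("gcnr", gcnr), ("snr_db", snr)):
        try:
            out[key] = fn(env, t_mask, b_mask)
        except ValueError as exc:
            logger.info("metric %s undefined: %s", key, exc)
    out["n_target_px"] = float(t_mask.sum())
    out["n_background_px"] = float(b_mask.sum())
    return out


def _mv_at_frames(cine, cycle, frames, config) -> BeamformedCine:
    """MV-beamform only the frames needed for metrics (MV is per-pixel adaptive)."""
    if cycle is None:
        sub = GatedCycle(
            kept_indices=np.asarray(frames),
            cardiac_delays_s=cine.timestamps[np.asarray(frames)],
        )
    else:
        sub = GatedCycle(
            kept_indices=cycle.kept_indices[np.asarray(frames)],
            cardiac_delays_s=cycle.cardiac_delays_s[np.asarray(frames)],
        )
    return beamform_cine(
        cine, sub, "mv", f_number=config.f_number, subarray=config.mv_subarray
    )


def _figures(out_dir, methods, phase_frames, sigma, sweep) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.semilogy(np.arange(1, sigma.size + 1), sigma, "k.-")
    ax.set_xlabel("singular value order")
    ax.set_ylabel("singular value")
    ax.set_title("Singular value spectrum")
    fig.tight_layout()
    fig.savefig(os.path.join(out_dir, "svs.png"), dpi=120)
    plt.close(fig)

    es = phase_frames.get("end_systole", next(iter(phase_frames.values())))
    names = [n for n in ("DAS", "MV", "SVD-0") if n in methods]
    names += [n for n in methods if n.startswith("SVD-") and n != "SVD-0"][:1]
    fig, axes = plt.subplots(1, len(names), figsize=(3 * len(names), 4))
    for ax, name in zip(np.atleast_1d(axes), names):
        bf = methods[name]
        col = es if name != "MV" else 0
        col = min(col, bf.n_frames - 1)
        env = np.abs(bf.frame(col))
        db = 20 * np.log10(env / max(env.max(), 1e-30) + 1e-6)
        ax.imshow(
            db, vmin=-40, vmax=0, cmap="hot", aspect="auto",
            extent=[bf.grid.x_mm[0], bf.grid.x_mm[-1], bf.grid.z_mm[-1], bf.grid.z_mm[0]],
        )
        ax.set_title(name)
        ax.set_xlabel("lateral [mm]")
    np.atleast_1d(axes)[0].set_ylabel("depth [mm]")
    fig.tight_layout()
    fig.savefig(os.path.join(out_dir, "comparison_end_systole.png"), dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2))
    for ax, col, label in zip(axes, ("cr_db", "gcnr", "snr_db"), ("CR [dB]", "gCNR", "SNR [dB]")):
        for phase, grp in sweep.groupby("phase"):
            ax.plot(grp["rst"], grp[col], "o-", label=phase)
        ax.set_xlabel("rst")
        ax.set_ylabel(label)
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(os.path.join(out_dir, "rst_sweep.png"), dpi=120)
    plt.close(fig)
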