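"""Respiratory gating and ECG-R reordering of a free-running acquisition.

Simulates 15 s of free-running frames with ECG and respiration traces,
discards frames acquired during breaths and re-orders the survivors by
their delay from the nearest R wave into one reconstructed cardiac cycle.
"""

import numpy as np

from pasvd.phantom import PhantomConfig, simulate_physio
from pasvd.physio import (
    detect_breaths,
    detect_r_waves,
    reconstruct_gated_ecg,
    reorder_by_cardiac_delay,
    respiratory_gate,
)

cfg = PhantomConfig(seed=7, n_frames=300, pregated=False)
ecg, resp, gt = simulate_physio(cfg)
timestamps = np.arange(cfg.n_frames) / cfg.frame_rate_hz

events = detect_breaths(resp, smoothing_window_s=0.03)
r_times = detect_r_waves(ecg)
kept = respiratory_gate(timestamps, events)
cycle = reorder_by_cardiac_delay(timestamps, kept, r_times)
reconstruct_gated_ecg(ecg, cycle, timestamps)

print(f"breaths detected:        {len(events)}")
print(f"R waves detected:        {r_times.size} (true: {gt.r_times_s.size})")
print(f"frames kept:             {cycle.n_frames} / {cfg.n_frames}")
print(f"cardiac delays span:     0 .. {cycle.cardiac_delays_s[-1]*1e3:.0f} ms "
      f"(RR = {gt.rr_s*1e3:.0f} ms)")
# The kept frames now tile one heart cycle: their delays cover almost the
# whole RR interval even though each acquisition frame caught the heart at
# an arbitrary phase.
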