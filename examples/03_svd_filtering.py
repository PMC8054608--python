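"""Spatiotemporal SVD clutter filtering and the low-order cutoff sweep.

Runs the Casorati-SVD filter on the clutter-heavy phantom and sweeps the
low-order cutoff rst, printing CR/gCNR/SNR per cutoff: the metrics peak at
an interior rst (clutter removed, wall retained) and fall again when too
many orders — now carrying wall signal — are discarded.
"""

from pasvd.beamform import beamform_cine
from pasvd.metrics import phase_select, rst_sweep
from pasvd.phantom import _clutter_heavy_config, roi_from_box, simulate_channel_cine

cine, gt = simulate_channel_cine(_clutter_heavy_config(seed=7))
das = beamform_cine(cine)
frames = phase_select(das.timestamps, gt.phase_delays_s)
rois = (
    roi_from_box(gt.target_box_mm, "target"),
    roi_from_box(gt.background_box_mm, "background"),
)

sweep = rst_sweep(das, None, (0, 1, 2, 4, 6), 1e-3, rois, frames, tau_mode="relative")
es = sweep[sweep.phase == "end_systole"].set_index("rst")
print("end-systole metrics vs low-order cutoff rst")
print(es[["cr_db", "gcnr", "snr_db"]].round(2))
opt = es["cr_db"].idxmax()
print(f"\nbest contrast at rst = {opt}: discarding the first {opt} singular "
      "order(s) removes the quasi-static clutter while keeping the wall.")
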