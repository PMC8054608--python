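# pasvd — spatiotemporal SVD processing for cardiac photoacoustic cines

Cardiac photoacoustic imaging (PAI) of small animals suffers from strong,
nearly time-invariant clutter (chest-wall and surrounding muscle), random
noise, and incoherent transients from fast-moving chamber blood, all of
which bury the myocardial signal of interest.  `pasvd` implements the full
processing chain that recovers a clean, single-cycle cardiac cine from
free-running linear-array IQ channel data:

1. **Physiological gating** — frames acquired during breaths (between each
   inhalation onset and the post-exhalation pause onset) are discarded;
   the survivors are re-ordered by their delay from the nearest preceding
   ECG R wave, reconstructing one cardiac cycle.
2. **Beamforming** — delay-and-sum (DAS, one-way delays, dynamic f-number
   apodization) and sub-array minimum-variance (MV) beamforming of complex
   baseband IQ data, giving the cine `P (Nz × Nx × Nt)`.
3. **Spatiotemporal SVD filtering** — the cine is reorganised into the
   Casorati matrix `S ((Nz·Nx) × Nt)` and decomposed, `S = U Δ V*`.
   Quasi-static clutter concentrates in the lowest singular orders and
   noise in the tail, so the filtered spectrum `Δ_ST = Δ · I_ST` keeps only
   orders `r_st < k ≤ r_rt`: the low-order cutoff `r_st` is swept (SVD-k
   denotes `r_st = k`), the high-order cutoff `r_rt` is selected where the
   gradient of the singular value spectrum falls below a threshold τ.
   `S_ST = U Δ_ST V*` is reorganised back into the filtered cine.
4. **PSAP weighting** — two complementary sub-apertures (alternating
   two-element blocks) give independent reconstructions; their per-pixel
   zero-lag normalised cross-correlation forms a [0, 1] weight volume that
   multiplies the SVD-filtered envelope, collapsing incoherent background.
5. **Metrics** — contrast ratio `CR = 20 log10(μ_t/μ_b)`, generalised
   contrast-to-noise ratio `gCNR = 1 − Σ min(k_t, k_b)` over 100 shared
   amplitude bins, and `SNR = 20 log10(μ_t/σ_b)`, evaluated on envelope
   images over polygonal target/background ROIs at named cardiac phases
   (systole, end-systole, diastole).

A synthetic moving-wall phantom (`pasvd.phantom`) generates channel-data
cines, ECG/respiration traces and ground-truth masks with exactly this
statistical structure, so the whole chain is testable without any
acquisition hardware.

## Worked example

Sweeping the low-order cutoff on the clutter-heavy phantom
(`examples/03_svd_filtering.py`):

```
end-systole metrics vs low-order cutoff rst
     cr_db  gcnr  snr_db
rst
0    -6.33  0.27   -9.21
1    22.51  0.73   21.34
2    23.57  0.80   24.07
4    23.68  0.87   27.61
6    22.31  0.86   27.05

best contrast at rst = 4
```

At `rst = 0` (no low orders discarded) the static clutter dominates the
background ROI: contrast is negative and the target/background histograms
overlap heavily (gCNR 0.27).  Discarding the first singular orders removes
the clutter — CR jumps by ~30 dB and gCNR approaches 1 — until too many
orders are dropped and wall signal begins to leak away (`rst = 6`).
The other examples demonstrate gating (`01`), DAS/MV beamforming (`02`)
and PSAP background suppression (`04`); each prints a few numbers and a
line on what they mean.

A thin CLI wraps the same functions
(`pasvd simulate | gate | beamform | svdfilter | psap | metrics | repro-demo`);
`pasvd repro-demo` runs the clutter-heavy phantom end to end and renders a
DAS / MV / SVD-0 / SVD-k comparison panel, the singular value spectrum and
the cutoff-sweep curves.

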