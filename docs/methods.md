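# Methods

This note documents the models, conventions and numerical choices behind
`pasvd`, and what the synthetic phantom does and does not establish about
real data.

## Signal model and conventions

Channel data are complex baseband IQ: the analytic RF signal demodulated
at the array centre frequency f_c.  The envelope is therefore the plain
modulus; no Hilbert transform is applied anywhere.  Photoacoustic
propagation is one-way (optical excitation is effectively instantaneous),
so the delay from a pixel to an element is the acoustic path length over
the speed of sound (default 1540 m/s), and IQ sample *n* corresponds to a
one-way time of flight `depth_offset/c + n/f_s`.

Default geometry: 64 receive elements at 90 µm pitch, 21 MHz centre
frequency, 13–24 MHz bandwidth, 5 mm depth offset.  The IQ sampling rate
is fully user-configurable (default 41 MHz); the default pixel grid puts
one A-line on each element and one axial row per IQ sample with spacing
c/f_s, so a scatterer directly above an element beamforms back onto its
own sample row without interpolation error.  The axial spacing is the
one-way mapping deliberately: a pulse-echo (c/2f_s) grid would halve the
spacing for no benefit in a photoacoustic geometry.

## Gating

Breaths are detected on a smoothed respiration trace (centred moving
average, default 100 ms) by prominence-based peak picking (default 30 % of
the trace range).  The inhalation onset is the last pre-peak sample at or
below the local baseline plus 5 % of the peak height; the
exhalation-pause onset is the first sample after the point of steepest
descent where the downslope has decayed below 5 % of that steepest
descent.  The onset rule is a threshold crossing rather than a
zero-crossing of the detrended trace because belt-type respiration
signals are one-sided: the pause level, not the trace mean, is the
physiological baseline, and a mean-crossing rule lands tens of
milliseconds late.  The slope rule anchors at the steepest descent
because the slope is also near zero at the crest itself.

Gates are closed intervals [inhalation onset, exhalation-pause onset];
frames on the boundary are discarded (conservative rejection).  R waves
are detected by an amplitude threshold (default 0.6 × max) with greedy
suppression inside a refractory period (default 120 ms) — adequate for
high-SNR anaesthetised-rodent ECG.  Each surviving frame is assigned the
delay from the latest R wave at or before it; frames preceding the first
R wave have no defined delay and are dropped with a warning rather than
wrapped.  Sorting by delay is stable, so simultaneous-delay frames keep
acquisition order.  The gated ECG curve samples the original ECG at the
nearest sample time to each kept frame, taking the earlier sample on an
exact tie.

## Beamforming

Delaying complex baseband data needs both a fractional-sample shift
(linear interpolation; out-of-range samples contribute zero) and a phase
rotation `exp(+i 2π f_c τ)` restoring the carrier phase removed by
demodulation.  DAS sums the delayed, phase-rotated samples over the
active aperture with uniform (binary) weights; an element is active at a
pixel iff its lateral offset is within z/(2 f#) (default f# = 1, boundary
inclusive).

MV beamforming estimates, per pixel, a sub-array-averaged covariance of
the delayed active-aperture vector (sub-array length Ns = 16, so a
64-element aperture yields 49 overlapping sub-arrays) and applies
`w = R⁻¹a / (aᴴR⁻¹a)` with an all-ones steering vector — the steering
delays are already applied by dynamic focusing, and the formula is
invariant to the steering vector's scale.  Diagonal loading adds
`loading/Ns × trace(R)` to the diagonal (default loading 1/100), standard
robust-MV practice since the raw covariance from few sub-arrays can be
ill-conditioned.  Where fewer than Ns elements are active the sub-array
length clamps to the active count; a covariance that remains singular
after loading falls back to uniform weights (logged).  No
forward–backward averaging is used.

## SVD filtering

The cine is reshaped to the Casorati matrix (one vectorised frame per
column; an exact bijection) and decomposed with a thin SVD — economical
because Nt ≪ Nz·Nx.  Filtering zeroes all singular orders outside
`rst < k ≤ rrt` (1-based): `rst` counts discarded leading orders, so
"SVD-0" discards none and differs from DAS only through the high-order
truncation.  The high-order cutoff is chosen from the backward difference
of the raw (linear-amplitude) singular values: the last order before the
first difference below τ.  An absolute τ (default 20) is tied to the
amplitude scale of the data it was designed for, so a relative mode
(threshold τ × σ₁) is provided and used for all phantom work; τ = 10⁻³
relative places the cutoff where the spectrum flattens into the noise
floor.  Complex values are processed throughout; envelopes are taken only
for display and metrics.

## PSAP weighting

Two complementary binary sub-apertures (alternating blocks of two
elements) give independent DAS reconstructions that are each SVD-filtered
with the same cutoffs.  The weight volume is the per-pixel, per-frame
zero-lag NCC over a local window (default 11 axial × 3 lateral pixels,
roughly one pulse length by one beam width), computed on the **complex**
data without mean removal:

    w = Re{ Σ A·conj(B) } / sqrt( Σ|A|² · Σ|B|² ),  clamped to [0, 1].

A mean-removed (envelope) correlation was evaluated and rejected: inside
a locally uniform coherent target the mean-removed patch content is
dominated by noise, so such a weighting suppresses the target interior
more than structured background — the opposite of the intent.  The
complex, non-mean-removed form scores phase-coherent signal near 1 even
where the envelope is flat, and independent noise near 0.  Negative
correlations clamp to zero (suppress, never invert); zero-energy patches
get weight 0.  The weights multiply the full-aperture SVD envelope, so no
pixel's amplitude can increase.

## Metrics

CR, gCNR and SNR are computed on envelope images without log compression.
gCNR uses 100 shared bins spanning the pooled min–max of the two ROIs
(an option bins over a caller-supplied range instead); with all pooled
values identical the histograms overlap completely and gCNR is 0.  The
background standard deviation uses the population convention (divide by
n).  ROI polygons are rasterised by pixel-centre containment with the
boundary counted inside; self-intersecting polygons are rejected.  Equal
target/background areas are recommended and checked with a warning, not
an error.  Cardiac phases map to the gated frame nearest the requested
delay; requests beyond the cycle clamp to the last frame with a warning.

## The phantom: what it emulates, and what it does not

The generator forward-models point sources emitting Gaussian-windowed
pulses at f_c (envelope width set by the array's fractional bandwidth),
summed per element with one-way delays in baseband, plus complex white
channel noise.  The scene encodes the coherence ordering the filter
relies on:

* a wall band whose thickness breathes with the cardiac phase (half-cosine
  contraction peaking at end-systole, default 0.55 → 1.1 mm at 330 bpm) —
  the "myocardium";
* static high-amplitude clutter blobs with a small slow amplitude drift
  (5 %) — quasi-static clutter spanning the leading singular orders;
* chamber "blood": sources with positions and amplitudes redrawn
  independently every frame — temporally white;
* a respiration trace (60 breaths/min; linear inhale/exhale ramps of
  0.15 T around a 0.7 T pause) and an ECG spike train defining the true
  gates and R times.

Clutter amplitudes in the clutter-heavy preset (4.0 / 1.8 / 0.7 against a
wall of 1.0) make the leading singular order clearly static while leaving
the DAS background histogram straddling the target values, so both the
clutter-removal effect and the detectability (gCNR) improvement are
non-trivially exercised.  The `pregated` mode samples one cardiac cycle
uniformly (timestamps are cardiac delays), which is the configuration the
metric and filter studies use; the free-running mode exercises gating.

Not modelled: acoustic attenuation, element directivity, optical fluence,
speckle from diffuse sub-resolution absorbers, tissue motion other than
the wall's, and ECG artefacts.  Passing the phantom suite therefore shows
the pipeline implements its mathematics correctly and behaves as designed
under the assumed coherence ordering; it does not certify performance on
in vivo data, where clutter statistics are richer and the cutoffs must be
re-examined per dataset.

## Problem sizes and determinism

The full-size SVD identity check runs at 296 × 64 × 300 (the package's
reference cine size); beamforming-level studies use a 160 × 64 × 96
clutter-heavy cine, which preserves every structural feature at a fraction
of the cost.  The method-ordering study repeats over 20 generator seeds.
All phantom randomness flows from a single integer seed through
`numpy.random.default_rng`; a fixed config regenerates bit-identically.
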