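# Methods

This note records the model, the numerical choices and the open design
decisions behind `nufd`, in the spirit of a model-description chapter: what
the code assumes, which knobs matter, and what the built-in validation does
and does not demonstrate.

## Signal model and processing chain

The method treats each lung pixel's time course as a sum of a respiratory
oscillation (parenchymal density), a cardiac oscillation (blood volume /
inflow), slow drift and noise. Both physiological frequencies drift over
the ~1 min acquisition. The chain per component is: zero-phase Butterworth
band split → STFT ridge → virtual-time resampling → per-pixel non-uniform
Fourier transform → peak magnitude.

Key parameters (defaults chosen for 220 usable frames at 0.31 s/frame,
i.e. Nyquist 1.61 Hz):

| parameter | default | why |
| --- | --- | --- |
| steady-state discard | 20 frames | bSSFP magnetization transient at the start of the series |
| cutoff search band | 0.55–1.0 Hz | between the respiratory (~0.1–0.5 Hz) and cardiac (~0.8–1.5 Hz) bands |
| Butterworth order | 4 | steep enough to separate the bands, benign ringing; applied forward–backward so the group delay is exactly zero |
| STFT window | Hann, 64 frames (~20 s), 75 % overlap, ×4 zero-padding | resolves both ridges over 220 frames; ~0.013 Hz bin spacing |
| ridge continuity penalty | 0.05·(Δbin)² per step (log-magnitude units) | suppresses bin-hopping onto noise peaks while following chirps of ~0.1 Hz/min |
| peak window | `f_c` ± 2 spectral bins, sampled at bin/8 | see "peak extraction" below |
| factor clamp | [0.2, 5.0], clamp + warning | factors outside this range indicate drift or a failed fit, not physiology |

### Cutoff determination

The only stated constraint is that the mean lung signal determines a cutoff
in 0.55–1.0 Hz. The implementation is deterministic and auditable: the
magnitude spectrum of the demeaned mean lung signal is Gaussian-smoothed
(σ = 2 bins); the cutoff is the frequency of the in-band minimum, or the
band midpoint 0.775 Hz when the in-band spectrum is monotone (no spectral
valley, e.g. a signal with no cardiac peak). The result is always clipped
to the band. The cutoff is **subject-specific, not scan-specific**: the
pipeline determines it once on the reference scan and reuses it for that
subject's repeated scans. Rationale: the filter's residual attenuation at
the cardiac frequency depends on the cutoff, so letting the cutoff wander
between scans of the same subject would inject spurious scan-to-scan
differences into the perfusion maps that have nothing to do with
physiology.

### Ridge extraction

The instantaneous frequency is the maximum-energy path through the in-band
STFT magnitude, found by dynamic programming with a quadratic bin-jump
penalty, refined per time slice by parabolic interpolation of the
log-magnitude, and linearly interpolated back to frame resolution (edge
slices hold their value). A band with no real signal is detected by
comparing the in-band peak to 5 % of the global spectrogram peak; tracking
then fails loudly rather than returning a noise path.

### Virtual times and f_c

`t̃ₙ = (1/f_c)·∫f dt` (trapezoidal integral). `f_c` is the time-mean of the
ridge — any constant in the band would do algebraically; the time-mean
keeps `t̃` close to `t` and is stored with the times for provenance.

### Type-1 NuFFT and peak extraction

The uniform-frequency-grid transform `S_k = (2/N)·Σₙ vₙ e^{-2πi f_k t̃ₙ}`,
`f_k = k/(N·dt)`, is computed by Gaussian-gridding (2× oversampled grid,
spreading half-width 12, FFT, deconvolution) — ~1e-12 relative agreement
with the direct sum, verified against a brute-force O(N·M) oracle in the
tests. Amplitudes follow the unit-sinusoid convention: a sinusoid of
amplitude A sampled at matching times yields peak magnitude A. For uniform
times the result equals the `2/N`-scaled FFT.

For the maps themselves the transform is evaluated on a locally refined
grid (spacing bin/8) within `f_c` ± 2 bins, via a direct vectorized matrix
product over all mask pixels — mathematically the same transform. The
refinement matters: on the integer-bin grid, a peak falling between bins
loses up to ~36 % magnitude (scalloping), and since `f_c` is estimated per
scan, that loss would vary between scans and contaminate the deviation
metric with up to several percent of pure grid artifact. At bin/8 the worst
scalloping is ≈0.3 %. A `peak_mode="band"` option takes the global in-band
maximum instead of the `f_c`-local one, for signals whose ridge estimate is
unreliable.

## Diaphragm tracking and the scaling factor

Line profiles through the diaphragm are fitted with a 4-parameter logistic
`b + a/(1+e^{-(r-c)/s})`; the diaphragm position is the row of maximum
|derivative| of the fit — for the logistic, its centre `c`, which makes the
tracker sub-pixel. This matters at 3.91 mm pixels, where a full tidal
excursion of 15 mm is under 4 px peak-to-peak. Relative positions are
signed from the mid-position (mean of per-cycle maxima and minima, peaks
found with prominence ≥ 25 % of the trace range and minimum separation of
half the dominant period), positive toward inspiration (caudal).

The scaling factor uses |dS/dx| rather than the signed slope: with the
physically expected coupling (inspiration lowers parenchymal density and
signal) the raw slope is negative, and the signed formula would yield a
negative factor. The magnitude form gives the intended positive scale for
either sign convention of `S`. The per-cycle extrema of `S` are found with
the same peak-detection procedure as the diaphragm trace, for internal
consistency.

## Registration

Registration is a pluggable contract, deliberately not a contribution:
`translation` (built-in, 1-D vertical shift by profile cross-correlation —
exact for integer shifts), `external` (SimpleITK B-spline with Mattes
mutual information and a 25/50/100 % three-level multiresolution schedule)
and `none`. The phantom has no bulk in-plane tissue motion (only the
diaphragm edge moves), so the bundled demo runs with `none`; the
translation backend is validated separately on synthetically shifted
series. Frames are discarded before registration (the workflow order is
ambiguous in general; registering frames that are then thrown away would be
wasted work).

## The phantom: what it emulates, and what it does not

The generator produces two half-elliptic lung fields in a body ellipse,
4–6 vessel segments per lung (1–2 px wide) radiating from the hilum, a
heart region excluded from both masks, and a diaphragm modelled as a
logistic intensity transition whose centre follows the breathing waveform —
exactly the model the tracker fits, which deliberately makes tracker
accuracy separable from model mismatch. Parenchymal intensity follows

```
I(p,t) = B·(1 − a_v(p)·x(t)/x_ref) + a_q(p)·s_card(t) + drift·t + noise
```

so the mean lung signal is affine in the diaphragm position `x(t)` by
construction — the premise the scaling factor relies on — and the
ventilation oscillation amplitude scales linearly with breathing depth.
Defaults mirror the target protocol: 240 frames, 128×128, 0.31 s/frame,
3.91 mm pixels, 15 mm reference excursion, 0.25 Hz respiration, 1.1 Hz
cardiac. The default ventilation amplitude field is an apico-basal gradient
(0.06→0.14 fractional); vessels carry the cardiac amplitude (~20 signal
units against a lung baseline of 60) plus a small parenchymal cardiac
component (0.1 units) so parenchymal Qw is nonzero while the mean-signal
linearity stays intact. Default noise is σ = 2 signal units (SNR 30 on
parenchyma); SNR-20 experiments use σ = 3. Vessels and heart are excluded
from the ventilation mask (standard segmentation practice for Vw maps); the
perfusion mask is parenchyma ∪ vessels. The parenchyma mask stops a fixed
guard distance above the most caudal diaphragm position reachable at twice
the reference amplitude, so repeated scans at different breathing depths
share an identical mask — required for the deviation metric.

Not emulated: MR physics (bSSFP banding, coil profiles, flow effects),
through-plane motion, in-plane tissue deformation, B0/B1 inhomogeneity, and
pathology. Passing phantom tests therefore demonstrates the correctness of
the *processing*, not robustness to scanner-specific artifacts; on real
data the registration backend and segmentation quality become the dominant
uncertainties.

## Statistics

Deviation `δ_Γ` compares masked map means against the designated reference
scan; reports carry both signed and absolute deviations (analysis uses
absolute values; signed distributions are informative for over/under-
correction). The Wilcoxon signed-rank test drops zero differences,
mid-ranks ties, and uses exhaustive 2ⁿ enumeration of the null for n ≤ 12
remaining pairs (two-sided p = twice the smaller inclusive tail, capped at
1); beyond n = 12 it switches to the normal approximation with tie
correction and no continuity correction. The exact branch is oracle-tested
against an independent enumeration; the approximate branch is cross-checked
against `scipy.stats.wilcoxon(method="approx", correction=False)`.

## Numerical edge cases

* Reference-frame selection ties break to the earliest frame.
* `roi_normalize` is idempotent and unit-mean in exact arithmetic; in
  floating point both hold to ~1e-15 relative (asserted at 1e-12) because
  re-dividing by a recomputed mean is not bitwise neutral.
* Degenerate inputs fail loudly with context: empty masks, flat sigmoid
  profiles (range below 3× a local noise estimate), monotone diaphragm
  traces (< 2 cycles), bands without energy, all-zero Wilcoxon differences,
  configs without exactly one reference scan.
* Phantom intensities are clipped at 0 after noise addition (magnitude
  images are nonnegative); with default σ this affects only air pixels.

## Problem sizes used in validation

The test suite and the acceptance script run the full-protocol
normalization study at the native 128×128×240 size with 10 seeded
replicates (reference, 1.25× deeper, 0.8× shallower), and the demo config
at 96×96×160 — sizes chosen to keep a complete validation run in the
minutes range on a single CPU while exercising every stage at realistic
dimensions.

## Known limitations

* The diaphragm-factor normalization is inapplicable when diaphragm motion
  does not reflect lung volume change (e.g. diaphragmatic paralysis); use
  ROI normalization there.
* The standard six-ROI grid is a reproducible stand-in (20/50/80 % of each
  lung's vertical extent at the centroid column, minimally shifted to fit
  inside the mask); when the bounded vertical search has to widen, two
  squares of one lung can touch or overlap. User-supplied ROIs override the
  grid.
* ROI normalization assumes the ROI covers healthy, representative
  parenchyma; in diffuse disease this assumption fails and can make
  perfusion reproducibility worse than no correction.
* Signal drift shrinks the measured ventilation-signal amplitude and
  inflates the factor; the clamp surfaces but does not repair this.
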