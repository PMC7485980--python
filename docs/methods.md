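# Methods

`lumapulse` implements the analysis chain used to measure serotonergic
modulation of calcium signals in *Drosophila* lamina-neuron terminals from
single-channel two-photon GCaMP6f movies, together with a synthetic-movie
generator that reproduces the statistical structure the chain assumes.

## Pipeline model

A recording is a movie `F(x, y, t)` at 10–30 frames/s. The analysis assumes
the labeled neurons are the bright structures in the field, that in-plane
brain motion is a rigid translation plus a slow (~0.04 Hz) multiplicative
oscillation, and that calcium transients are stimulus-locked and return to
baseline before the next flash (5 s later).

**Registration.** Each frame is aligned to the temporal-mean image by phase
correlation, with 1/10-pixel upsampling, applied by spline interpolation.
Pixels shifted in from outside the frame are filled with the frame median so
the fill cannot bias the global-median threshold below. Out-of-plane motion
is not correctable in 2-D; a per-recording motion score (mean displacement,
px) is logged for manual review, and nothing is auto-discarded.

**Segmentation.** The global median over all pixels of all frames is the
background threshold: pixels whose temporal-mean intensity is below it are
discarded (ties kept). The surviving pixels are clustered by k-means
(k = 3, 10 seeded restarts, best inertia) on their z-scored time series —
z-scoring makes "similar activity" mean similar waveform rather than
similar brightness; zero-variance pixels get the zero vector. The most
populous cluster is retained (ties broken toward the lowest cluster index).
In bath mode the retained set is one pooled ROI; in visual mode a watershed
on the negative of the Gaussian-smoothed (σ = 1 px) mean image, seeded at
local maxima ≥ 3 px apart, splits it into per-terminal ROIs, dropping ROIs
under 4 px (noise suppression; there is no principled size rule, so the
default is deliberately permissive and configurable). The per-ROI trace is
the arithmetic mean of ROI pixels per frame. Manual curation is modeled
only as an explicit ROI include/exclude list in the run config.

**Filtering.** All notches are second-order IIR biquads designed from a
centre frequency and −3 dB bandwidth, applied forward–backward (zero
phase, DC gain exactly 1) with odd reflection padding of ≈ 3/bandwidth
seconds — the notch transient lasts ~1/bandwidth, so short pads would leak
ringing into the interior. The motion notch is 0.04 Hz, bandwidth
0.005 Hz. It is never applied silently: each recording carries a flag, and
an advisory (periodogram peak at 0.04 ± 0.01 Hz above 5× the median
spectral density) is logged. The stimulus-band cascade — biquads at
0.20 Hz (bw 0.02) and 0.40 Hz (bw 0.04), i.e. the bands 0.19–0.21 and
0.38–0.42 Hz — removes the fundamental and second harmonic of the 0.2 Hz
flash train for the basal-calcium readout. Two notches cannot remove
higher harmonics or the train's DC component, so trend recovery is exact
only up to an additive constant and only for responses whose power is
concentrated below ~0.5 Hz (transients ≳ 1–2 s wide); sharper response
trains leave ripple at 0.6 Hz and above. The tests reflect exactly this
contract.

**ΔF/F.** `ΔF/F = (F_t − F0)/F0`. Bath rule: F0 is the mean over the
first 60 s, before the perfusion change reaches the tissue. Visual rule:
F0 is the mean over 30 s of non-consecutive inter-stimulus baseline in
epoch 1; the segments are the 2.5 s ending 0.5 s before each of the 12
flash onsets — late in each gap, clear of the preceding flash's response.
(The exact placement within the gaps is a design choice; any placement that
avoids the post-flash second changes F0 only through residual response
tails.) F0 ≤ 0 is an error, never a silent pass-through.

**Epoch averaging.** For each 60 s epoch and polarity, per-flash windows
of [−0.5, +4.9] s around onset are linearly interpolated onto a common
grid at the recording's native frame rate, each shifted by its own mean
over [−0.5, 0) s so responses start aligned at 0, then averaged. Flashes
whose window leaves the recording are dropped with a warning; an epoch
with no usable flashes is an error.

**Transient metrics.** Measured on the epoch-average trace (average first,
then measure). The primary extremum is searched in (0, 2] s after onset —
transients return to baseline within about a second, so 2 s bounds the
primary response — while peak-to-peak and secondary searches extend to
+4.9 s. Dark: peak size (post-stimulus max − pre-stimulus baseline),
90→10% decay time of the falling limb, exponential constant, secondary
response (undershoot below baseline after the peak). Light: mirrored
(trough size as a non-negative magnitude, 10→90% rise time, secondary
overshoot). Level crossings are fractions of the post-stimulus
peak-to-peak span, located by linear interpolation searching forward from
the primary extremum (first crossing wins). The exponential
`ΔF/F(t) = c·e^{kt}` is fitted by least squares on log-transformed values
over the 10–90% span, offset by the post-stimulus minimum (decays) or
subtracted from the maximum (rises), floored at 1% of peak-to-peak to keep
the logarithm defined; k < 0 for decays and k > 0 for rises by convention.
The log-linear estimator matches a nonlinear least-squares fit on the same
windowed data at the noise levels the averaging chain produces (tested);
it degrades if fitted into a noise-dominated tail, which the 10–90% window
avoids. Metrics that are undefined on a response (flat trace, level never
crossed, < 3 samples) are flagged invalid, never silently zeroed.
Per-epoch deltas subtract each subject's epoch-1 value; epoch 1 is exactly
0 by construction.

## Statistics

*Wilcoxon rank sum*, two-tailed: exact by full enumeration of rank
assignments when the combined n ≤ 12 with no ties (≤ 924 assignments);
otherwise the normal approximation with tie correction and continuity
correction. *Mixed two-way RM-ANOVA* (between: group; within: epoch) by the
classical sums-of-squares decomposition; subjects missing epochs are
dropped with a warning, and each group needs ≥ 2 complete subjects. The
primary p-values assume sphericity; Greenhouse–Geisser-corrected p-values
(ε from the double-centered pooled within-group covariance, floored at
1/(p−1)) are reported alongside, since the original analysis tooling's
sphericity handling is unknown. With two groups, per-epoch Welch t
comparisons are Sidak-adjusted (`1 − (1−p)^m`, m = number of epochs).

## Synthetic generator

The generator emulates: shuffled 100 ms light/dark flashes every 5 s
(6 + 6 per 60 s epoch, seeded shuffle per epoch, onsets at 3 + 5j s so
epoch-1 gaps can host the 30 s baseline); biphasic terminal transients from
closed-form alpha kernels `α(t; τ) = (t/τ)·e^{1−t/τ}` (unit peak exactly at
t = τ): dark = A·α(t; 0.3) − 0.25·A·α(t − 0.8; 0.7) (peak 0.8 ΔF/F,
back near baseline within ~1 s, undershoot), light = −0.25·α(t; 0.25) +
0.3·α(t − 0.5; 0.7) (dip then delayed sustained rise); a piecewise-linear
basal ramp from the perfusion arrival time (105 s gravity rig, 45 s valve
rig) to a plateau (default 1.73 ΔF/F over ~3 min for serotonin, flat for
saline); a multiplicative 0.04 Hz whole-frame oscillation; rigid jitter
(integer-random or sinusoidal, rendered at exact sub-pixel terminal
positions, so jitter adds no interpolation artifacts); Gaussian noise with
intensity-proportional variance (Poisson optional), parameterized as peak
signal-to-noise at the spot centre so tests can sweep SNR ∈ {∞, 20, 10, 5}.
Default frame rates are 15 fps (bath) and 27 fps (visual), within the
acquisition ranges the pipeline targets. The default visual field is six
σ = 3 px terminals ≥ 12 px (4σ) apart on a 40×40 frame, with bright cores
dominating the above-median pixel set, as in recordings where the labeled
neurons fill most of the field.

Every stochastic realization is derived from the caller's seed and echoed
back in the ground-truth object, so test oracles are exact and identical
seeds give bit-identical movies.

**What the generator does not emulate** — and what passing tests therefore
do not establish about real data: out-of-plane motion, non-rigid warping,
neuropil contamination and spatially structured background, bleaching,
indicator nonlinearity/saturation, and inter-terminal response
heterogeneity beyond the per-terminal parameters. The zero-noise identity
additionally uses zero background, because a uniform background offset
attenuates pooled ΔF/F (a property of the ΔF/F definition itself, shared
with real recordings that have background fluorescence).

## Problem sizes and numerical choices

Tests and the acceptance script scale simulations to desk size as the
package's own defaults for verification runs: segmentation recovery uses
50 seeded 60 s movies at 10 fps (40×40, 6 terminals, SNR 10); visual
pipeline checks use 2 epochs, 2 terminals, 3 flies/group at 10 fps; filter
contracts are measured on 1200 s tones with 5% edge trim (the 0.005 Hz-wide
notch has a ~200 s transient, so short traces cannot show its asymptotic
rejection); the bath group analysis uses 8 flies/group at trace level.
Frozen expected values come from closed forms (ln 9/λ spans, exact
enumeration p = 0.1, Sidak 1 − 0.95^6) or independent oracles (root-finding
on analytic kernels, nonlinear curve fits, scipy's exact Mann–Whitney,
pingouin's mixed ANOVA).

Known limitations: rigid translation only (no rotation/warp); the
watershed can merge terminals closer than ~2σ (by design — smoothing
prevents over-segmentation); the exact Wilcoxon switches to the normal
approximation whenever ties occur, even at small n; the RM-ANOVA requires
a complete epoch grid per subject rather than fitting a mixed model to
unbalanced data.
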