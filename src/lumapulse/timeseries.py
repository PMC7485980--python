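"""Trace filtering, dF/F normalization, and stimulus-locked epoch averages.

Two dF/F baseline rules are supported, matching the two experiment modes:

* bath mode — F0 is the mean fluorescence over the first 60 s of the
  recording, before the perfusion change reaches the tissue;
* visual mode — F0 is the mean over 30 s of non-consecutive inter-stimulus
  baseline during epoch 1 (the pre-switch epoch), sampled late in each
  inter-flash gap to stay clear of the preceding flash response.

Notch filtering removes two nuisance bands: a slow ~0.04 Hz multiplicative
brain-motion oscillation, and (for basal-calcium readout in visual
experiments) the stimulus-response bands around 0.20 and 0.40 Hz. All
notches are second-order IIR biquads applied forward-backward, so they are
zero-phase and cannot shift transient timings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy import signal

from .segmentation import RawTrace

__all__ = [
    "StimulusProtocol",
    "DffTrace",
    "EpochResponse",
    "notch_filter",
    "remove_motion_oscillation",
    "remove_stimulus_band",
    "motion_oscillation_advisory",
    "dff_bath",
    "dff_visual",
    "stimulus_locked_epoch_average",
    "average_across_rois",
    "MOTION_NOTCH_HZ",
    "MOTION_NOTCH_BW_HZ",
    "STIMULUS_NOTCHES",
]

MOTION_NOTCH_HZ = 0.04
MOTION_NOTCH_BW_HZ = 0.005
# The stimulus-response bands 0.19-0.21 Hz and 0.38-0.42 Hz, realized as
# biquads at each band centre with the band width as -3 dB bandwidth.
STIMULUS_NOTCHES: tuple[tuple[float, float], ...] = ((0.20, 0.02), (0.40, 0.04))


@dataclass
class StimulusProtocol:
    """Full-field flash protocol: shuffled 100 ms light/dark flashes.

    Flashes arrive every ``inter_onset_s`` seconds in ``n_epochs`` epochs of
    ``epoch_length_s``; each epoch contains equal numbers of light and dark
    flashes in seeded-shuffled order. The perfusion switch happens on the
    stimulus clock at ``perfusion_switch_s`` and reaches the tissue
    ``perfusion_arrival_delay_s`` later (about 105 s for the gravity rig,
    about 45 s for the programmable valve rig).
    """

    flash_onsets_s: np.ndarray
    polarities: list[str]  # "light" | "dark" per flash
    flash_duration_s: float = 0.1
    inter_onset_s: float = 5.0
    epoch_length_s: float = 60.0
    n_epochs: int = 6
    perfusion_switch_s: float = 60.0
    perfusion_arrival_delay_s: float = 105.0

    def __post_init__(self) -> None:
        self.flash_onsets_s = np.asarray(self.flash_onsets_s, dtype=np.float64)
        if len(self.flash_onsets_s) != len(self.polarities):
            raise ValueError("one polarity per flash onset is required")
        if np.any(np.diff(self.flash_onsets_s) <= 0):
            raise ValueError("flash onsets must be strictly increasing")
        bad = set(self.polarities) - {"light", "dark"}
        if bad:
            raise ValueError(f"unknown polarities: {sorted(bad)}")
        total = self.n_epochs * self.epoch_length_s
        if np.any(self.flash_onsets_s < 0) or np.any(self.flash_onsets_s >= total):
            raise ValueError("flash onsets must lie within the epoch span")
        for e in range(1, self.n_epochs + 1):
            pol = self.epoch_polarities(e)
            if pol and pol.count("light") != pol.count("dark"):
                raise ValueError(
                    f"epoch {e}: light/dark flash counts must be balanced"
                )

    def epoch_of(self, t_s: float) -> int:
        """1-based epoch index containing stimulus-clock time ``t_s``."""
        return int(t_s // self.epoch_length_s) + 1

    def epoch_flash_indices(self, epoch: int, polarity: str | None = None) -> np.ndarray:
        if not (1 <= epoch <= self.n_epochs):
            raise IndexError(f"epoch {epoch} out of range 1..{self.n_epochs}")
        lo = (epoch - 1) * self.epoch_length_s
        hi = epoch * self.epoch_length_s
        idx = np.nonzero((self.flash_onsets_s >= lo) & (self.flash_onsets_s < hi))[0]
        if polarity is not None:
            idx = np.array([i for i in idx if self.polarities[i] == polarity],
                           dtype=int)
        return idx

    def epoch_polarities(self, epoch: int) -> list[str]:
        return [self.polarities[i] for i in self.epoch_flash_indices(epoch)]

    def to_dict(self) -> dict:
        return {
            "epoch_length_s": self.epoch_length_s,
            "n_epochs": self.n_epochs,
            "flash_duration_s": self.flash_duration_s,
            "inter_onset_s": self.inter_onset_s,
            "onsets": [{"t": float(t), "polarity": p}
                       for t, p in zip(self.flash_onsets_s, self.polarities)],
            "perfusion_switch_s": self.perfusion_switch_s,
            "perfusion_arrival_delay_s": self.perfusion_arrival_delay_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        onsets = d.get("onsets", [])
        return cls(
            flash_onsets_s=np.array([o["t"] for o in onsets]),
            polarities=[o["polarity"] for o in onsets],
            flash_duration_s=d.get("flash_duration_s", 0.1),
            inter_onset_s=d.get("inter_onset_s", 5.0),
            epoch_length_s=d.get("epoch_length_s", 60.0),
            n_epochs=d.get("n_epochs", 6),
            perfusion_switch_s=d.get("perfusion_switch_s", 60.0),
            perfusion_arrival_delay_s=d.get("perfusion_arrival_delay_s", 105.0),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StimulusProtocol":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class DffTrace:
    """dF/F = (F_t - F0)/F0, dimensionless, with the baseline it used."""

    values: np.ndarray
    f0: float
    baseline_rule: str  # "bath" | "visual"
    frame_rate_hz: float
    t0_s: float = 0.0
    subject_id: str = ""
    group: str = ""
    roi_id: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.isfinite(self.values).all():
            raise ValueError("dF/F values must be finite")
        if not (self.f0 > 0):
            raise ValueError(f"baseline F0 must be positive, got {self.f0}")
        if not (self.frame_rate_hz > 0):
            raise ValueError("frame_rate_hz must be > 0")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self)) / self.frame_rate_hz

    def replace_values(self, values: np.ndarray) -> "DffTrace":
        return replace(self, values=np.asarray(values, dtype=np.float64))


@dataclass
class EpochResponse:
    """Per-epoch stimulus-locked average, aligned to 0 pre-stimulus dF/F."""

    epoch: int
    polarity: str
    times_s: np.ndarray      # relative to flash onset, spans [-0.5, +4.9] s
    values: np.ndarray       # mean dF/F, pre-stimulus mean subtracted
    n_flashes: int
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times_s.shape != self.values.shape:
            raise ValueError("times and values must align")

    def pre_mask(self) -> np.ndarray:
        return self.times_s < 0

    def post_mask(self) -> np.ndarray:
        return self.times_s > 0


def _apply_notch(x: np.ndarray, fs: float, center_hz: float,
                 bandwidth_hz: float) -> np.ndarray:
    if not (0 < center_hz < fs / 2):
        raise ValueError(
            f"notch centre {center_hz} Hz must lie below Nyquist ({fs / 2} Hz)"
        )
    if not (bandwidth_hz > 0):
        raise ValueError("bandwidth must be positive")
    b, a = signal.iirnotch(center_hz, center_hz / bandwidth_hz, fs=fs)
    # The notch transient lasts ~1/bandwidth; reflect-pad long enough to
    # keep edge ringing out of the analyzed interior.
    padlen = int(min(len(x) - 1, round(3 * fs / bandwidth_hz)))
    return signal.filtfilt(b, a, x, padtype="odd", padlen=padlen)


def notch_filter(trace, center_hz: float, bandwidth_hz: float):
    """Zero-phase second-order notch; accepts RawTrace or DffTrace.

    The biquad is designed from the centre frequency and -3 dB bandwidth
    and applied forward-backward (DC gain exactly 1, no phase shift).
    """
    filtered = _apply_notch(trace.values, trace.frame_rate_hz,
                            center_hz, bandwidth_hz)
    return trace.replace_values(filtered)


def remove_motion_oscillation(trace):
    """Notch out the ~0.04 Hz brain-motion oscillation (bandwidth 0.005 Hz)."""
    return notch_filter(trace, MOTION_NOTCH_HZ, MOTION_NOTCH_BW_HZ)


def remove_stimulus_band(trace):
    """Notch out the flash-response bands (0.19-0.21 and 0.38-0.42 Hz).

    Used only for the basal-calcium readout in visual experiments: it
    removes the fundamental and second harmonic of the 0.2 Hz flash train
    so the slow basal trend can be read from the residual.
    """
    if trace.frame_rate_hz <= 2 * STIMULUS_NOTCHES[-1][0] + 0.04:
        raise ValueError("frame rate too low for the stimulus notch cascade")
    out = trace
    for center, bw in STIMULUS_NOTCHES:
        out = notch_filter(out, center, bw)
    return out


def motion_oscillation_advisory(
    trace,
    center_hz: float = MOTION_NOTCH_HZ,
    half_width_hz: float = 0.01,
    ratio: float = 5.0,
) -> bool:
    """Advise whether the 0.04 Hz motion notch looks warranted.

    About half of bath recordings carry the slow brain-motion oscillation;
    filtering is never applied silently. This advisory flags a recording
    when its periodogram peak within ``center_hz +/- half_width_hz`` exceeds
    ``ratio`` times the median spectral density.
    """
    x = np.asarray(trace.values, dtype=np.float64)
    x = x - x.mean()
    freqs, pxx = signal.periodogram(x, fs=trace.frame_rate_hz)
    band = (freqs >= center_hz - half_width_hz) & (freqs <= center_hz + half_width_hz)
    if not band.any():
        return False
    med = np.median(pxx[freqs > 0])
    if med <= 0:
        return bool(pxx[band].max() > 0)
    return bool(pxx[band].max() > ratio * med)


def dff_bath(trace: RawTrace, baseline_duration_s: float = 60.0) -> DffTrace:
    """dF/F with F0 = mean fluorescence over the first ``baseline_duration_s``.

    The baseline window is the pre-perfusion-change start of the recording.
    """
    t = trace.times_s - trace.t0_s
    if t[-1] < baseline_duration_s:
        raise ValueError(
            f"trace spans {t[-1]:.1f} s; needs >= {baseline_duration_s} s baseline"
        )
    base = trace.values[t < baseline_duration_s]
    f0 = float(base.mean())
    if f0 <= 0:
        raise ValueError(f"baseline F0 must be positive, got {f0}")
    return DffTrace(values=(trace.values - f0) / f0, f0=f0, baseline_rule="bath",
                    frame_rate_hz=trace.frame_rate_hz, t0_s=trace.t0_s,
                    subject_id=trace.subject_id, group=trace.group,
                    roi_id=trace.roi_id)


def visual_baseline_segments(
    protocol: StimulusProtocol,
    baseline_total_s: float = 30.0,
    guard_s: float = 0.5,
) -> list[tuple[float, float]]:
    """Inter-stimulus baseline segments for the visual dF/F rule.

    From each inter-flash gap of epoch 1, the segment of length
    ``baseline_total_s / n_flashes`` ending ``guard_s`` before the next
    flash onset is used — late in the gap, clear of the previous flash's
    response. With the default 12 flashes this yields 12 x 2.5 s = 30 s of
    non-consecutive baseline.
    """
    onsets = protocol.flash_onsets_s[protocol.epoch_flash_indices(1)]
    if onsets.size == 0:
        raise ValueError("epoch 1 contains no flashes")
    seg_len = baseline_total_s / onsets.size
    segments = []
    for on in onsets:
        start = on - guard_s - seg_len
        if start < 0:
            raise ValueError(
                "insufficient inter-stimulus time before flash at "
                f"{on:.2f} s for a {seg_len:.2f} s baseline segment"
            )
        segments.append((start, on - guard_s))
    return segments


def dff_visual(trace: RawTrace, protocol: StimulusProtocol,
               baseline_total_s: float = 30.0) -> DffTrace:
    """dF/F with F0 from non-consecutive epoch-1 inter-stimulus baseline."""
    segments = visual_baseline_segments(protocol, baseline_total_s)
    t = trace.times_s - trace.t0_s
    mask = np.zeros(len(trace), dtype=bool)
    for lo, hi in segments:
        mask |= (t >= lo) & (t < hi)
    if mask.sum() < 2:
        raise ValueError("insufficient inter-stimulus baseline samples")
    f0 = float(trace.values[mask].mean())
    if f0 <= 0:
        raise ValueError(f"baseline F0 must be positive, got {f0}")
    return DffTrace(values=(trace.values - f0) / f0, f0=f0, baseline_rule="visual",
                    frame_rate_hz=trace.frame_rate_hz, t0_s=trace.t0_s,
                    subject_id=trace.subject_id, group=trace.group,
                    roi_id=trace.roi_id)


def stimulus_locked_epoch_average(
    dff: DffTrace,
    protocol: StimulusProtocol,
    epoch: int,
    polarity: str,
    pre_s: float = 0.5,
    post_s: float = 4.9,
) -> EpochResponse:
    """Average the per-flash windows of one epoch and polarity.

    Each flash window [-pre_s, +post_s] (relative to onset) is resampled to
    a common time base at the recording's native frame rate by linear
    interpolation, shifted by its own pre-stimulus mean (the 0.5 s before
    onset) so every response starts aligned at 0 dF/F, then averaged.
    Flashes whose window leaves the recorded span are dropped with a
    warning; zero usable flashes is an error.
    """
    fs = dff.frame_rate_hz
    n_pre = int(round(pre_s * fs))
    n_post = int(round(post_s * fs))
    rel_t = np.arange(-n_pre, n_post + 1) / fs
    t = dff.times_s - dff.t0_s
    idx = protocol.epoch_flash_indices(epoch, polarity)
    if idx.size == 0:
        raise ValueError(f"epoch {epoch} has no {polarity} flashes")
    windows = []
    for i in idx:
        onset = protocol.flash_onsets_s[i]
        sample_t = onset + rel_t
        if sample_t[0] < t[0] - 1e-9 or sample_t[-1] > t[-1] + 1e-9:
            warnings.warn(
                f"flash at {onset:.2f} s dropped: window leaves the recording",
                stacklevel=2,
            )
            continue
        w = np.interp(sample_t, t, dff.values)
        w = w - w[rel_t < 0].mean()
        windows.append(w)
    if not windows:
        raise ValueError(f"no usable {polarity} flashes in epoch {epoch}")
    mean = np.mean(windows, axis=0)
    mean = mean - mean[rel_t < 0].mean()  # exact re-centering of the average
    return EpochResponse(epoch=epoch, polarity=polarity, times_s=rel_t,
                         values=mean, n_flashes=len(windows), frame_rate_hz=fs)


def average_across_rois(traces: list[DffTrace]) -> DffTrace:
    """Pointwise mean of per-ROI dF/F traces within one animal."""
    if not traces:
        raise ValueError("no traces to average")
    n = len(traces[0])
    fs = traces[0].frame_rate_hz
    for tr in traces[1:]:
        if len(tr) != n:
            raise ValueError("traces have mismatched lengths")
        if tr.frame_rate_hz != fs:
            raise ValueError("traces have mismatched frame rates")
    mean_vals = np.mean([tr.values for tr in traces], axis=0)
    f0 = float(np.mean([tr.f0 for tr in traces]))
    first = traces[0]
    return DffTrace(values=mean_vals, f0=f0, baseline_rule=first.baseline_rule,
                    frame_rate_hz=fs, t0_s=first.t0_s,
                    subject_id=first.subject_id, group=first.group, roi_id=0)
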