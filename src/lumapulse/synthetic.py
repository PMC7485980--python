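"""Synthetic GCaMP movies and traces with exported ground truth.

The generator emulates the statistical structure the analysis assumes, so
every pipeline stage can be tested against exact ground truth without raw
recordings:

* shuffled full-field 100 ms light/dark flashes every 5 s, in 60 s epochs
  of 12 flashes (6 per polarity);
* biphasic per-terminal transients — dark flashes drive a fast calcium
  rise with an optional undershoot, light flashes a dip followed by a
  delayed secondary rise — built from closed-form alpha kernels;
* a slow basal-calcium ramp starting when the perfusion change reaches the
  tissue (~105 s on the gravity rig, ~45 s on the valve rig);
* a ~0.04 Hz multiplicative whole-frame oscillation from slow brain motion;
* rigid in-plane jitter; and photon-like noise (Gaussian with
  intensity-proportional variance by default, Poisson on request).

Every stochastic realization (polarity shuffles, jitter, noise) derives
from the caller's seed and is echoed back in the ground-truth object, so
test oracles are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .movie_io import MovieStack
from .segmentation import RawTrace
from .timeseries import StimulusProtocol

__all__ = [
    "KernelParams",
    "Terminal",
    "GroundTruth",
    "make_protocol",
    "make_kernel",
    "alpha_kernel",
    "terminal_dff",
    "basal_ramp",
    "simulate_movie",
    "simulate_bath_trace",
    "default_visual_ground_truth",
    "default_bath_ground_truth",
    "BATH_PLATEAU_DFF",
]

# Default serotonin bath-application plateau (dF/F); mirrors the magnitude
# of the strong basal-calcium rise seen in L2 terminals.
BATH_PLATEAU_DFF = 1.73


def alpha_kernel(t: np.ndarray, tau_s: float) -> np.ndarray:
    """Alpha function (t/tau) * exp(1 - t/tau): unit peak exactly at t=tau."""
    t = np.asarray(t, dtype=np.float64)
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / tau_s
    out[pos] = x * np.exp(1.0 - x)
    return out


@dataclass
class KernelParams:
    """Closed-form biphasic transient shapes for one terminal.

    Dark kernel:  A * alpha(t; tau_dark) - u*A * alpha(t - d_u; tau_u)
    Light kernel: -T * alpha(t; tau_light) + o*T * alpha(t - d_o; tau_o)

    With the default time constants both kernels are below 2% of their
    amplitude by +4.9 s, the start of the next flash window.
    """

    dark_amp: float = 0.8            # dF/F at the dark-response peak (u = 0)
    dark_tau_s: float = 0.3          # alpha peak time; decay ~ exp(-t/tau)
    dark_undershoot_frac: float = 0.25
    dark_undershoot_delay_s: float = 0.8
    dark_undershoot_tau_s: float = 0.7
    light_trough: float = 0.25       # dF/F magnitude of the light-flash dip
    light_tau_s: float = 0.25
    light_overshoot_frac: float = 1.2
    light_overshoot_delay_s: float = 0.5
    light_overshoot_tau_s: float = 0.7


def make_kernel(polarity: str, params: KernelParams):
    """Analytic response function of time since flash onset (vectorized)."""
    if polarity == "dark":
        def kernel(t):
            return (params.dark_amp * alpha_kernel(t, params.dark_tau_s)
                    - params.dark_undershoot_frac * params.dark_amp
                    * alpha_kernel(t - params.dark_undershoot_delay_s,
                                   params.dark_undershoot_tau_s))
    elif polarity == "light":
        def kernel(t):
            return (-params.light_trough * alpha_kernel(t, params.light_tau_s)
                    + params.light_overshoot_frac * params.light_trough
                    * alpha_kernel(t - params.light_overshoot_delay_s,
                                   params.light_overshoot_tau_s))
    else:
        raise ValueError(f"polarity must be 'light' or 'dark', got {polarity}")
    return kernel


@dataclass
class Terminal:
    """One synaptic terminal: a Gaussian spot with its own kernel params."""

    center: tuple[float, float]      # (row, col) in pixels
    sigma_px: float = 3.0
    f0: float = 100.0                # baseline fluorescence at spot centre
    kernel: KernelParams = field(default_factory=KernelParams)


@dataclass
class GroundTruth:
    """Everything the generator used, echoed back so oracles are exact."""

    terminals: list[Terminal]
    background_level: float = 5.0
    # basal-calcium drift (dF/F units): ramp from drift_start_s at
    # drift_slope_per_s, capped at drift_plateau
    drift_start_s: float = 105.0
    drift_slope_per_s: float = 0.0
    drift_plateau: float = 0.0
    # multiplicative whole-frame brain-motion oscillation
    motion_amp_frac: float = 0.0
    motion_freq_hz: float = 0.04
    # rigid in-plane jitter: realized per-frame (dy, dx), or None
    jitter: np.ndarray | None = None
    # noise: peak-signal-to-noise ratio at the spot centre; None = noiseless
    snr: float | None = None
    noise_model: str = "gaussian"    # "gaussian" | "poisson"
    # optional per-epoch multipliers on kernel parameters, keyed by
    # "dark_amp" | "dark_tau" | "light_trough" | "light_tau"
    epoch_scales: dict[str, np.ndarray] = field(default_factory=dict)
    seed: int = 0

    def epoch_kernel(self, terminal: Terminal, epoch: int) -> KernelParams:
        """Kernel params for one epoch, with any per-epoch scaling applied."""
        kp = terminal.kernel
        if not self.epoch_scales:
            return kp
        def s(key):
            arr = self.epoch_scales.get(key)
            return 1.0 if arr is None else float(arr[epoch - 1])
        return replace(kp,
                       dark_amp=kp.dark_amp * s("dark_amp"),
                       dark_tau_s=kp.dark_tau_s * s("dark_tau"),
                       light_trough=kp.light_trough * s("light_trough"),
                       light_tau_s=kp.light_tau_s * s("light_tau"))


def make_protocol(
    seed: int,
    rig: str = "valve",
    n_epochs: int = 6,
    epoch_length_s: float = 60.0,
    inter_onset_s: float = 5.0,
    first_onset_s: float = 3.0,
    flash_duration_s: float = 0.1,
) -> StimulusProtocol:
    """Seeded flash protocol: balanced shuffled polarities per epoch.

    Each epoch holds ``epoch_length_s / inter_onset_s`` flashes on a fixed
    onset grid; the light/dark order is an independent seeded shuffle of a
    half-light, half-dark deck per epoch. The perfusion switch fires at the
    end of epoch 1 and reaches the tissue after the rig's arrival delay
    (105 s gravity, 45 s valve).
    """
    if rig not in ("gravity", "valve"):
        raise ValueError(f"rig must be 'gravity' or 'valve', got {rig}")
    per_epoch = int(round(epoch_length_s / inter_onset_s))
    if per_epoch % 2:
        raise ValueError("epoch must hold an even number of flashes")
    rng = np.random.default_rng(seed)
    onsets, polarities = [], []
    for e in range(n_epochs):
        deck = ["light"] * (per_epoch // 2) + ["dark"] * (per_epoch // 2)
        deck = [deck[i] for i in rng.permutation(per_epoch)]
        for j in range(per_epoch):
            onsets.append(e * epoch_length_s + first_onset_s + j * inter_onset_s)
            polarities.append(deck[j])
    return StimulusProtocol(
        flash_onsets_s=np.array(onsets),
        polarities=polarities,
        flash_duration_s=flash_duration_s,
        inter_onset_s=inter_onset_s,
        epoch_length_s=epoch_length_s,
        n_epochs=n_epochs,
        perfusion_switch_s=epoch_length_s,
        perfusion_arrival_delay_s=105.0 if rig == "gravity" else 45.0,
    )


def basal_ramp(t: np.ndarray, gt: GroundTruth) -> np.ndarray:
    """Piecewise-linear basal dF/F drift: flat, then ramp, then plateau."""
    t = np.asarray(t, dtype=np.float64)
    ramp = np.clip((t - gt.drift_start_s) * gt.drift_slope_per_s, 0.0, None)
    if gt.drift_plateau > 0 or gt.drift_slope_per_s >= 0:
        return np.minimum(ramp, gt.drift_plateau)
    return ramp


def terminal_dff(
    t: np.ndarray,
    terminal: Terminal,
    gt: GroundTruth,
    protocol: StimulusProtocol | None,
) -> np.ndarray:
    """Programmed dF/F time course of one terminal (the test oracle)."""
    t = np.asarray(t, dtype=np.float64)
    dff = basal_ramp(t, gt)
    if protocol is not None:
        for onset, pol in zip(protocol.flash_onsets_s, protocol.polarities):
            epoch = protocol.epoch_of(onset)
            kp = gt.epoch_kernel(terminal, epoch)
            dff = dff + make_kernel(pol, kp)(t - onset)
    return dff


def _spot(shape: tuple[int, int], center: tuple[float, float],
          sigma: float) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    r2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return np.exp(-r2 / (2.0 * sigma**2))


def _make_jitter(rng: np.random.Generator, n_frames: int, kind: str,
                 amp_px: float, freq_hz: float = 0.1,
                 fps: float = 10.0) -> np.ndarray:
    """Realize a rigid-jitter series; frame 0 is always (0, 0)."""
    if kind == "integer":
        j = rng.integers(-int(amp_px), int(amp_px) + 1, size=(n_frames, 2))
        j = j.astype(np.float64)
    elif kind == "sinusoid":
        t = np.arange(n_frames) / fps
        j = np.column_stack([amp_px * np.sin(2 * np.pi * freq_hz * t),
                             amp_px * np.sin(2 * np.pi * freq_hz * t + 1.0)])
    else:
        raise ValueError(f"unknown jitter kind {kind!r}")
    j[0] = 0.0
    return j


def simulate_movie(
    gt: GroundTruth,
    protocol: StimulusProtocol | None,
    fps: float = 27.0,
    dims: tuple[int, int] = (40, 40),
    duration_s: float | None = None,
) -> tuple[MovieStack, GroundTruth]:
    """Render a movie from ground truth; returns (movie, echoed truth).

    Each frame is ``background + sum_terminals spot(x, y) * f0 *
    (1 + dff_true(t))``, multiplied by the motion-oscillation factor,
    shifted by the rigid jitter (terminals are re-rendered at the shifted
    sub-pixel centre, so jitter introduces no interpolation artifacts), and
    degraded by seeded noise. The returned ground truth echoes the realized
    jitter so registration tests have an exact oracle.
    """
    if duration_s is None:
        if protocol is None:
            raise ValueError("duration_s required when no protocol is given")
        duration_s = protocol.n_epochs * protocol.epoch_length_s + 6.0
    n_frames = int(round(duration_s * fps))
    t = np.arange(n_frames) / fps
    h, w = dims
    for term in gt.terminals:
        if not (0 <= term.center[0] < h and 0 <= term.center[1] < w):
            raise ValueError(f"terminal centre {term.center} outside {dims}")

    jitter = gt.jitter
    if jitter is not None:
        jitter = np.asarray(jitter, dtype=np.float64)
        if jitter.shape != (n_frames, 2):
            raise ValueError(
                f"jitter must be ({n_frames}, 2); got {jitter.shape}")

    data = np.full((n_frames, h, w), float(gt.background_level))
    for term in gt.terminals:
        dff = terminal_dff(t, term, gt, protocol)
        amp = term.f0 * (1.0 + dff)
        if jitter is None:
            data += amp[:, None, None] * _spot(dims, term.center,
                                               term.sigma_px)[None]
        else:
            for i in range(n_frames):
                c = (term.center[0] + jitter[i, 0],
                     term.center[1] + jitter[i, 1])
                data[i] += amp[i] * _spot(dims, c, term.sigma_px)

    if gt.motion_amp_frac:
        factor = 1.0 + gt.motion_amp_frac * np.sin(
            2 * np.pi * gt.motion_freq_hz * t)
        data *= factor[:, None, None]

    if gt.snr is not None and np.isfinite(gt.snr):
        rng = np.random.default_rng(gt.seed)
        ref = max(term.f0 * max(term.kernel.dark_amp, gt.drift_plateau, 1.0)
                  for term in gt.terminals)
        sigma0 = ref / gt.snr
        if gt.noise_model == "gaussian":
            f0_ref = max(term.f0 for term in gt.terminals)
            local = sigma0 * np.sqrt(np.clip(data, 0, None) / f0_ref)
            data = data + rng.standard_normal(data.shape) * local
        elif gt.noise_model == "poisson":
            # scale so the centre-pixel shot noise matches sigma0
            gain = max(data.max(), 1.0) / max(sigma0**2, 1e-12)
            data = rng.poisson(np.clip(data, 0, None) * gain) / gain
        else:
            raise ValueError(f"unknown noise model {gt.noise_model!r}")
        data = np.clip(data, 0.0, None)

    movie = MovieStack(data=data, frame_rate_hz=fps, t0_s=0.0)
    return movie, replace(gt, jitter=jitter)


def simulate_bath_trace(
    gt: GroundTruth,
    duration_s: float = 360.0,
    fps: float = 15.0,
    condition: str = "serotonin",
) -> RawTrace:
    """Pooled-ROI raw trace for a bath-application experiment.

    Serotonin: a basal ramp beginning at the perfusion arrival time and
    rising to the configured plateau. Saline: flat baseline. Both carry the
    optional 0.04 Hz motion oscillation and seeded noise.
    """
    if condition not in ("serotonin", "saline"):
        raise ValueError(f"condition must be serotonin|saline, got {condition}")
    if duration_s < gt.drift_start_s + 60.0 and condition == "serotonin":
        raise ValueError("duration must cover perfusion arrival + 60 s")
    n = int(round(duration_s * fps))
    t = np.arange(n) / fps
    f0 = gt.terminals[0].f0 if gt.terminals else 100.0
    dff = basal_ramp(t, gt) if condition == "serotonin" else np.zeros_like(t)
    vals = f0 * (1.0 + dff)
    if gt.motion_amp_frac:
        vals = vals * (1.0 + gt.motion_amp_frac
                       * np.sin(2 * np.pi * gt.motion_freq_hz * t))
    if gt.snr is not None and np.isfinite(gt.snr):
        rng = np.random.default_rng(gt.seed)
        sigma = f0 * max(gt.drift_plateau, 1.0) / gt.snr
        vals = vals + rng.standard_normal(n) * sigma
    vals = np.clip(vals, 0.0, None)
    return RawTrace(values=vals, frame_rate_hz=fps, t0_s=0.0, group=condition)


def default_visual_ground_truth(
    seed: int = 0,
    n_terminals: int = 6,
    dims: tuple[int, int] = (40, 40),
    snr: float | None = 10.0,
    **overrides,
) -> GroundTruth:
    """Six bright terminals on a 40 x 40 field, >= 4 sigma apart.

    Terminals are laid out on a 2 x 3 grid (rows 13/27, columns 7/20/33)
    with sigma = 3 px, so neighbouring centres are >= 12 px apart and the
    bright cores dominate the above-median pixel set, as in recordings
    where the labeled neurons fill most of the field.
    """
    rows = (13.0, 27.0)
    cols = (7.0, 20.0, 33.0)
    centers = [(r, c) for r in rows for c in cols][:n_terminals]
    rng = np.random.default_rng(seed)
    terminals = [
        Terminal(center=(r + rng.uniform(-0.3, 0.3), c + rng.uniform(-0.3, 0.3)),
                 sigma_px=3.0, f0=100.0)
        for r, c in centers
    ]
    kwargs = dict(terminals=terminals, background_level=5.0, snr=snr, seed=seed)
    kwargs.update(overrides)
    return GroundTruth(**kwargs)


def default_bath_ground_truth(
    seed: int = 0,
    condition: str = "serotonin",
    plateau: float = BATH_PLATEAU_DFF,
    rig: str = "gravity",
    snr: float | None = 20.0,
    **overrides,
) -> GroundTruth:
    """Single pooled terminal with the serotonin basal-calcium ramp.

    The ramp starts at the perfusion arrival time (105 s gravity, 45 s
    valve) and climbs to ``plateau`` dF/F over about three minutes; saline
    runs keep a flat baseline.
    """
    arrival = 105.0 if rig == "gravity" else 45.0
    slope = plateau / 180.0 if plateau > 0 else 0.0
    term = Terminal(center=(8.0, 8.0), sigma_px=5.0, f0=100.0)
    kwargs = dict(
        terminals=[term],
        background_level=0.0,
        drift_start_s=arrival,
        drift_slope_per_s=slope if condition == "serotonin" else 0.0,
        drift_plateau=plateau if condition == "serotonin" else 0.0,
        snr=snr,
        seed=seed,
    )
    kwargs.update(overrides)
    return GroundTruth(**kwargs)
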