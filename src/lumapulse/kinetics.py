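"""Transient-kinetics metrics on stimulus-locked epoch-average responses.

Metrics are measured on the epoch-average trace (average first, then
measure). Dark flashes drive a fast calcium rise: the metrics are the peak
size, the 90% -> 10% decay time of the falling limb, an exponential constant
k fitted over that span, and the secondary response (the undershoot below
baseline after the peak). Light flashes drive a calcium dip: the mirrored
metrics are the trough size, the 10% -> 90% rise time of the recovering
limb, its exponential constant, and the secondary response (the overshoot
above baseline after the trough).

All level crossings are referenced to the post-stimulus peak-to-peak span
(post-stimulus maximum minus minimum) and located by linear interpolation,
searching forward in time from the primary extremum. The exponential model
is dF/F(t) = c * exp(k t); k < 0 for decays and k > 0 for rises by the sign
convention used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .timeseries import EpochResponse

__all__ = [
    "InvalidMetricError",
    "TransientMetrics",
    "peak_size",
    "trough_size",
    "crossing_times",
    "decay_time_90_10",
    "rise_time_10_90",
    "fit_exponential",
    "secondary_response",
    "epoch1_normalize",
    "epoch1_normalize_table",
    "compute_transient_metrics",
    "PRIMARY_WINDOW_S",
    "FULL_WINDOW_S",
]

# Primary-extremum search window after flash onset; transients return to
# basal levels within about a second, so 2 s bounds the primary response.
PRIMARY_WINDOW_S = 2.0
# Peak-to-peak and secondary searches extend to the next flash.
FULL_WINDOW_S = 4.9


class InvalidMetricError(ValueError):
    """A metric is undefined on this response (degenerate or missing data)."""


def _post(resp: EpochResponse, upto_s: float = FULL_WINDOW_S):
    m = (resp.times_s > 0) & (resp.times_s <= upto_s + 1e-9)
    if not m.any():
        raise InvalidMetricError("empty post-stimulus window")
    return resp.times_s[m], resp.values[m]


def _pre_baseline(resp: EpochResponse) -> float:
    pre = resp.pre_mask()
    return float(resp.values[pre].mean()) if pre.any() else 0.0


def peak_size(resp: EpochResponse, w_post_s: float = PRIMARY_WINDOW_S) -> float:
    """Dark-flash peak: post-stimulus maximum minus pre-stimulus baseline."""
    _, v = _post(resp, w_post_s)
    return float(v.max() - _pre_baseline(resp))


def trough_size(resp: EpochResponse, w_post_s: float = PRIMARY_WINDOW_S) -> float:
    """Light-flash trough: pre-stimulus baseline minus post-stimulus minimum.

    Reported as a non-negative magnitude; the direction (a calcium
    decrease) is carried by the polarity, not the sign.
    """
    _, v = _post(resp, w_post_s)
    return float(_pre_baseline(resp) - v.min())


def _first_crossing(t: np.ndarray, v: np.ndarray, level: float,
                    start_idx: int, rising: bool) -> float:
    """First time >= t[start_idx] at which v crosses `level`, interpolated."""
    for j in range(start_idx, len(v) - 1):
        a, b = v[j], v[j + 1]
        if rising:
            hit = (a < level <= b)
        else:
            hit = (a > level >= b)
        if hit:
            if b == a:
                return float(t[j])
            frac = (level - a) / (b - a)
            return float(t[j] + frac * (t[j + 1] - t[j]))
    # the start sample itself may sit exactly on the level
    if v[start_idx] == level:
        return float(t[start_idx])
    raise InvalidMetricError(f"level {level:.4g} never crossed")


def crossing_times(
    resp: EpochResponse,
    hi_frac: float = 0.9,
    lo_frac: float = 0.1,
    start: str | None = None,
) -> tuple[float, float]:
    """Times at which the response crosses the hi/lo peak-to-peak levels.

    The levels are ``post_min + frac * (post_max - post_min)``. The search
    runs forward from the primary extremum: from the post-stimulus maximum
    down through hi then lo for dark responses (``start='max'``), or from
    the post-stimulus minimum up through lo then hi for light responses
    (``start='min'``). By default the direction follows ``resp.polarity``.
    Returns ``(t_hi, t_lo)`` in seconds after flash onset.
    """
    if start is None:
        start = "max" if resp.polarity == "dark" else "min"
    t, v = _post(resp)
    p2p = v.max() - v.min()
    if p2p <= 0:
        raise InvalidMetricError("post-stimulus peak-to-peak span is zero")
    hi = v.min() + hi_frac * p2p
    lo = v.min() + lo_frac * p2p
    if start == "max":
        # primary extremum inside the primary window, falling limb after it
        prim = (t <= PRIMARY_WINDOW_S + 1e-9)
        i0 = int(np.argmax(np.where(prim, v, -np.inf)))
        t_hi = _first_crossing(t, v, hi, i0, rising=False)
        t_lo = _first_crossing(t, v, lo, i0, rising=False)
    elif start == "min":
        prim = (t <= PRIMARY_WINDOW_S + 1e-9)
        i0 = int(np.argmin(np.where(prim, v, np.inf)))
        t_lo = _first_crossing(t, v, lo, i0, rising=True)
        t_hi = _first_crossing(t, v, hi, i0, rising=True)
    else:
        raise ValueError("start must be 'max', 'min', or None")
    return t_hi, t_lo


def decay_time_90_10(resp: EpochResponse) -> float:
    """Seconds from 90% to 10% of peak-to-peak on the post-peak falling limb."""
    t_hi, t_lo = crossing_times(resp, start="max")
    return float(t_lo - t_hi)


def rise_time_10_90(resp: EpochResponse) -> float:
    """Seconds from 10% to 90% of peak-to-peak on the post-trough rising limb."""
    t_hi, t_lo = crossing_times(resp, start="min")
    return float(t_hi - t_lo)


def fit_exponential(
    resp: EpochResponse,
    window: tuple[float, float] | None = None,
    mode: str | None = None,
) -> tuple[float, float]:
    """Fit dF/F(t) = c * exp(k t) over the 10%-90% span; returns (c, k).

    ``mode='decay'`` fits the values offset by the post-stimulus minimum
    (k < 0); ``mode='rise'`` fits the distance below the post-stimulus
    maximum and negates the rate so k > 0. The fit is least squares on the
    log-transformed offsets, floored at 1% of peak-to-peak so the logarithm
    stays defined. By default the mode and window follow the polarity's
    crossing times.
    """
    if mode is None:
        mode = "decay" if resp.polarity == "dark" else "rise"
    if window is None:
        t_hi, t_lo = crossing_times(resp, start="max" if mode == "decay" else "min")
        window = (min(t_hi, t_lo), max(t_hi, t_lo))
    t, v = _post(resp)
    p2p = v.max() - v.min()
    if p2p <= 0:
        raise InvalidMetricError("constant post-stimulus window")
    sel = (t >= window[0] - 1e-12) & (t <= window[1] + 1e-12)
    if sel.sum() < 3:
        raise InvalidMetricError(f"fewer than 3 samples in window {window}")
    tw, vw = t[sel], v[sel]
    if mode == "decay":
        y = vw - v.min()
    elif mode == "rise":
        y = v.max() - vw
    else:
        raise ValueError("mode must be 'decay', 'rise', or None")
    floor = 0.01 * p2p
    y = np.maximum(y, floor)
    slope, intercept = np.polyfit(tw, np.log(y), 1)
    if mode == "decay":
        return float(np.exp(intercept)), float(slope)
    return float(np.exp(intercept)), float(-slope)


def secondary_response(resp: EpochResponse) -> float:
    """Magnitude of the opposite-signed excursion after the primary extremum.

    Dark: the calcium decrease below the pre-stimulus baseline after the
    initial peak. Light: the calcium increase above baseline after the
    initial trough. A monophasic response that never recrosses baseline
    yields 0 (a valid measurement, not a flag).
    """
    t, v = _post(resp)
    base = _pre_baseline(resp)
    prim = t <= PRIMARY_WINDOW_S + 1e-9
    if resp.polarity == "dark":
        i0 = int(np.argmax(np.where(prim, v, -np.inf)))
        tail = v[i0 + 1:]
        if tail.size == 0:
            raise InvalidMetricError("no samples after the primary peak")
        return float(max(0.0, base - tail.min()))
    else:
        i0 = int(np.argmin(np.where(prim, v, np.inf)))
        tail = v[i0 + 1:]
        if tail.size == 0:
            raise InvalidMetricError("no samples after the primary trough")
        return float(max(0.0, tail.max() - base))


def epoch1_normalize(values: dict[int, float]) -> dict[int, float]:
    """Per-epoch deltas relative to epoch 1: delta_n = value_n - value_1.

    Epoch 1's delta is exactly 0. An invalid (NaN) epoch-1 value makes
    every delta invalid.
    """
    if 1 not in values:
        raise InvalidMetricError("epoch 1 value required for normalization")
    v1 = values[1]
    if not np.isfinite(v1):
        return {e: float("nan") for e in values}
    out = {e: (0.0 if e == 1 else float(v - v1)) for e, v in values.items()}
    return out


METRIC_COLUMNS = ["subject_id", "group", "epoch", "polarity", "metric",
                  "value", "valid"]


def compute_transient_metrics(
    resp: EpochResponse,
    subject_id: str = "",
    group: str = "",
) -> pd.DataFrame:
    """All applicable metrics for one epoch response, as tidy rows.

    Dark responses get peak_size, decay_time_90_10_s, exp_c, exp_k_per_s and
    secondary_response; light responses get trough_size, rise_time_10_90_s
    and the same fit/secondary metrics. A metric that is undefined on the
    response appears with ``valid=False`` and a NaN value, never a silent 0.
    """
    if resp.polarity == "dark":
        plan = [("peak_size", lambda r: peak_size(r)),
                ("decay_time_90_10_s", decay_time_90_10)]
    else:
        plan = [("trough_size", lambda r: trough_size(r)),
                ("rise_time_10_90_s", rise_time_10_90)]
    plan += [
        ("exp_c", lambda r: fit_exponential(r)[0]),
        ("exp_k_per_s", lambda r: fit_exponential(r)[1]),
        ("secondary_response", secondary_response),
    ]
    rows = []
    for name, fn in plan:
        try:
            val, ok = float(fn(resp)), True
        except InvalidMetricError:
            val, ok = float("nan"), False
        rows.append({"subject_id": subject_id, "group": group,
                     "epoch": resp.epoch, "polarity": resp.polarity,
                     "metric": name, "value": val, "valid": ok})
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def epoch1_normalize_table(metrics: pd.DataFrame) -> pd.DataFrame:
    """Epoch-1-relative deltas of a tidy metrics table.

    Groups rows by (subject, group, polarity, metric) and subtracts each
    group's epoch-1 value; epoch-1 rows become exactly 0. Groups with an
    invalid epoch-1 value are marked invalid throughout.
    """
    out = []
    keys = ["subject_id", "group", "polarity", "metric"]
    for key, sub in metrics.groupby(keys, sort=False):
        sub = sub.sort_values("epoch")
        e1 = sub[sub["epoch"] == 1]
        ok1 = (not e1.empty) and bool(e1["valid"].iloc[0]) and np.isfinite(
            e1["value"].iloc[0])
        delta = sub.copy()
        if ok1:
            v1 = float(e1["value"].iloc[0])
            delta["value"] = np.where(delta["epoch"] == 1, 0.0,
                                      delta["value"] - v1)
        else:
            delta["value"] = float("nan")
            delta["valid"] = False
        out.append(delta)
    res = pd.concat(out, ignore_index=True)
    res["metric"] = res["metric"] + "_delta"
    return res
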