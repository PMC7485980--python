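"""End-to-end orchestration of bath-application and visual-stimulus runs.

Bath mode (basal calcium): register -> segment -> pooled ROI trace ->
optional 0.04 Hz motion notch -> dF/F against the first-60 s baseline ->
group mean +/- SEM and a two-tailed Wilcoxon rank-sum comparison of per-fly
dF/F at a fixed timepoint (default: the final sample).

Visual mode (flash responses): register -> segment -> per-terminal traces
-> within-animal average -> dF/F against epoch-1 inter-stimulus baseline ->
per-epoch stimulus-locked averages per polarity -> transient metrics ->
epoch-1-relative deltas -> mixed two-way RM-ANOVA with per-epoch Sidak
comparisons. A basal-calcium side channel (stimulus bands notched out) is
computed per fly.

Failures on individual recordings (e.g. segmentation finding nothing) skip
that recording and are recorded in the run log with a reason; invalid
metrics are flagged in the tables, never silently zeroed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import kinetics, segmentation, stats, timeseries
from .movie_io import MovieStack, read_movie, register_rigid
from .timeseries import DffTrace, StimulusProtocol

__all__ = ["Recording", "RunConfig", "BathResult", "VisualResult",
           "run_bath", "run_visual", "load_config"]


@dataclass
class Recording:
    """One fly's movie plus its labels and per-recording filter choice."""

    movie: MovieStack | str | Path
    subject_id: str
    group: str
    motion_notch: bool | None = None  # None = follow the advisory

    def load(self, fps: float | None = None) -> MovieStack:
        if isinstance(self.movie, MovieStack):
            return self.movie
        return read_movie(self.movie, frame_rate_hz=fps)


@dataclass
class RunConfig:
    mode: str                      # "bath" | "visual"
    recordings: list[Recording]
    fps: float | None = None       # only needed for TIFFs without metadata
    k: int = 3
    seed: int = 0
    min_roi_px: int = 4
    register: bool = True
    protocol: StimulusProtocol | None = None
    baseline_duration_s: float = 60.0      # bath F0 window
    baseline_total_s: float = 30.0         # visual F0 total
    comparison_time_s: float | None = None  # bath Wilcoxon timepoint
    roi_include: list[int] | None = None   # manual ROI curation, if any
    roi_exclude: list[int] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("bath", "visual"):
            raise ValueError(f"mode must be bath|visual, got {self.mode}")
        if self.mode == "visual" and self.protocol is None:
            raise ValueError("visual mode requires a stimulus protocol")
        if not self.recordings:
            raise ValueError("at least one recording is required")


@dataclass
class BathResult:
    traces: list[DffTrace]
    group_mean: dict[str, np.ndarray]
    group_sem: dict[str, np.ndarray]
    comparison: stats.RankSumResult | None
    comparison_values: dict[str, list[float]]
    log: list[dict] = field(default_factory=list)


@dataclass
class VisualResult:
    traces: list[DffTrace]
    metrics: pd.DataFrame
    deltas: pd.DataFrame
    anova: dict[str, stats.RmAnovaResult]
    basal: list[DffTrace]
    log: list[dict] = field(default_factory=list)


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML run file.

    Layout: ``mode``, optional ``fps``/``seed``/``k``/``min_roi_px``,
    optional ``protocol`` (path to a protocol YAML), and ``recordings`` as a
    list of ``{path, subject_id, group, motion_notch}`` entries.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    recs = [
        Recording(movie=str((path.parent / r["path"]).resolve()),
                  subject_id=str(r.get("subject_id", f"fly{i + 1}")),
                  group=str(r.get("group", "")),
                  motion_notch=r.get("motion_notch"))
        for i, r in enumerate(raw.get("recordings", []))
    ]
    protocol = None
    if raw.get("protocol"):
        protocol = StimulusProtocol.from_yaml(path.parent / raw["protocol"])
    return RunConfig(
        mode=raw["mode"], recordings=recs, fps=raw.get("fps"),
        k=int(raw.get("k", 3)), seed=int(raw.get("seed", 0)),
        min_roi_px=int(raw.get("min_roi_px", 4)),
        register=bool(raw.get("register", True)),
        protocol=protocol,
        baseline_duration_s=float(raw.get("baseline_duration_s", 60.0)),
        baseline_total_s=float(raw.get("baseline_total_s", 30.0)),
        comparison_time_s=raw.get("comparison_time_s"),
        roi_include=raw.get("roi_include"), roi_exclude=raw.get("roi_exclude"),
    )


def _maybe_motion_notch(trace, rec: Recording, log: list[dict]):
    """Apply the 0.04 Hz notch per recording flag, or advise from the data."""
    advisory = timeseries.motion_oscillation_advisory(trace)
    apply = advisory if rec.motion_notch is None else rec.motion_notch
    log.append({"event": "motion_notch", "subject": rec.subject_id,
                "advisory": bool(advisory), "applied": bool(apply)})
    return timeseries.remove_motion_oscillation(trace) if apply else trace


def _registered(movie: MovieStack, config: RunConfig, rec: Recording,
                log: list[dict]) -> MovieStack:
    if not config.register:
        return movie
    reg, shifts = register_rigid(movie)
    log.append({"event": "registration", "subject": rec.subject_id,
                "motion_score_px": shifts.motion_score()})
    return reg


def run_bath(config: RunConfig) -> BathResult:
    """Bath-application analysis: basal-calcium dF/F and group comparison."""
    log: list[dict] = []
    traces: list[DffTrace] = []
    for rec in config.recordings:
        try:
            movie = rec.load(config.fps)
            movie = _registered(movie, config, rec, log)
            mask = segmentation.active_pixel_mask(movie)
            retained = segmentation.kmeans_activity_cluster(
                movie, mask, k=config.k, seed=config.seed)
            raw = segmentation.pooled_trace(movie, retained,
                                            subject_id=rec.subject_id,
                                            group=rec.group)
            raw = _maybe_motion_notch(raw, rec, log)
            traces.append(timeseries.dff_bath(
                raw, baseline_duration_s=config.baseline_duration_s))
        except (ValueError, IndexError) as exc:
            log.append({"event": "skipped", "subject": rec.subject_id,
                        "reason": str(exc)})
            warnings.warn(f"recording {rec.subject_id} skipped: {exc}",
                          stacklevel=2)
    if not traces:
        raise ValueError("no recordings survived the bath pipeline")

    groups = sorted({tr.group for tr in traces})
    group_mean, group_sem, comp_vals = {}, {}, {}
    for g in groups:
        vals = np.array([tr.values for tr in traces if tr.group == g])
        group_mean[g] = vals.mean(axis=0)
        group_sem[g] = (vals.std(axis=0, ddof=1) / np.sqrt(vals.shape[0])
                        if vals.shape[0] > 1 else np.zeros(vals.shape[1]))
        picked = []
        for tr in traces:
            if tr.group != g:
                continue
            if config.comparison_time_s is None:
                picked.append(float(tr.values[-1]))
            else:
                idx = int(round((config.comparison_time_s - tr.t0_s)
                                * tr.frame_rate_hz))
                idx = int(np.clip(idx, 0, len(tr) - 1))
                picked.append(float(tr.values[idx]))
        comp_vals[g] = picked

    comparison = None
    if len(groups) == 2:
        a, b = comp_vals[groups[0]], comp_vals[groups[1]]
        if min(len(a), len(b)) < 2:
            log.append({"event": "small_n_warning",
                        "reason": "fewer than 2 flies in a group"})
        comparison = stats.wilcoxon_rank_sum(a, b)
    return BathResult(traces=traces, group_mean=group_mean,
                      group_sem=group_sem, comparison=comparison,
                      comparison_values=comp_vals, log=log)


def _curate(rois: segmentation.RoiSet, config: RunConfig) -> segmentation.RoiSet:
    """Apply the declared manual include/exclude ROI lists, if any."""
    if config.roi_include is None and config.roi_exclude is None:
        return rois
    labels = rois.labels.copy()
    for rid in list(rois.roi_ids):
        drop = ((config.roi_include is not None and rid not in config.roi_include)
                or (config.roi_exclude is not None and rid in config.roi_exclude))
        if drop:
            labels[labels == rid] = 0
    return segmentation.RoiSet(labels=labels)


def run_visual(config: RunConfig) -> VisualResult:
    """Visual-stimulus analysis: per-epoch transient metrics and RM-ANOVA."""
    protocol = config.protocol
    log: list[dict] = []
    fly_traces: list[DffTrace] = []
    basal: list[DffTrace] = []
    metric_rows: list[pd.DataFrame] = []
    for rec in config.recordings:
        try:
            movie = rec.load(config.fps)
            movie = _registered(movie, config, rec, log)
            retained, rois = segmentation.segment_movie(
                movie, k=config.k, seed=config.seed,
                min_roi_px=config.min_roi_px)
            rois = _curate(rois, config)
            if rois.n_rois == 0:
                raise ValueError("no ROIs left after curation")
            raws = segmentation.extract_traces(movie, rois,
                                               subject_id=rec.subject_id,
                                               group=rec.group)
            raws = [_maybe_motion_notch(r, rec, log) for r in raws]
            dffs = [timeseries.dff_visual(r, protocol,
                                          baseline_total_s=config.baseline_total_s)
                    for r in raws]
            fly = timeseries.average_across_rois(dffs)
            fly_traces.append(fly)
            basal.append(timeseries.remove_stimulus_band(fly))
            for epoch in range(1, protocol.n_epochs + 1):
                for pol in ("dark", "light"):
                    try:
                        resp = timeseries.stimulus_locked_epoch_average(
                            fly, protocol, epoch, pol)
                    except ValueError as exc:
                        log.append({"event": "epoch_skipped",
                                    "subject": rec.subject_id, "epoch": epoch,
                                    "polarity": pol, "reason": str(exc)})
                        continue
                    metric_rows.append(kinetics.compute_transient_metrics(
                        resp, subject_id=rec.subject_id, group=rec.group))
        except (ValueError, IndexError) as exc:
            log.append({"event": "skipped", "subject": rec.subject_id,
                        "reason": str(exc)})
            warnings.warn(f"recording {rec.subject_id} skipped: {exc}",
                          stacklevel=2)
    if not metric_rows:
        raise ValueError("no recordings survived the visual pipeline")
    metrics = pd.concat(metric_rows, ignore_index=True)
    deltas = kinetics.epoch1_normalize_table(metrics)

    anova: dict[str, stats.RmAnovaResult] = {}
    n_groups = metrics["group"].nunique()
    if n_groups >= 2:
        for metric_name, sub in deltas.groupby("metric", sort=False):
            ok = sub[sub["valid"]]
            try:
                anova[metric_name] = stats.rm_two_way_anova(ok)
            except ValueError as exc:
                log.append({"event": "anova_skipped", "metric": metric_name,
                            "reason": str(exc)})
    return VisualResult(traces=fly_traces, metrics=metrics, deltas=deltas,
                        anova=anova, basal=basal, log=log)
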