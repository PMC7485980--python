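"""Activity-based ROI discovery: threshold -> k-means -> watershed.

The segmentation recipe targets recordings in which the labeled neurons are
the bright structures in the field of view:

1. The median intensity over *all* pixels of *all* frames is a global
   threshold; pixels whose temporal-mean intensity falls below it are
   discarded as background (ties are kept).
2. k-means (k = 3) on the per-pixel time series, z-scored so "similar
   activity" means similar waveform rather than similar brightness, groups
   the surviving pixels; the most populous cluster is retained as the
   active-pixel set.
3. In terminal mode, a watershed on the (negative, smoothed) temporal-mean
   image splits the retained set into one ROI per synaptic terminal. In bath
   mode, the retained set is used whole as a single pooled ROI.

Each ROI's trace is the arithmetic mean of its pixels per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.segmentation import watershed
from sklearn.cluster import KMeans

from .movie_io import MovieStack

__all__ = [
    "RoiSet",
    "RawTrace",
    "global_median_threshold",
    "active_pixel_mask",
    "kmeans_activity_cluster",
    "watershed_split",
    "extract_traces",
    "pooled_trace",
    "segment_movie",
]


@dataclass
class RawTrace:
    """Mean ROI fluorescence per frame, in raw intensity units."""

    values: np.ndarray
    frame_rate_hz: float
    t0_s: float = 0.0
    subject_id: str = ""
    group: str = ""
    roi_id: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("trace values must be 1-D")
        if not np.isfinite(self.values).all():
            raise ValueError("trace values must be finite")
        if not (self.frame_rate_hz > 0):
            raise ValueError("frame_rate_hz must be > 0")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self)) / self.frame_rate_hz

    def replace_values(self, values: np.ndarray) -> "RawTrace":
        return RawTrace(values=values, frame_rate_hz=self.frame_rate_hz,
                        t0_s=self.t0_s, subject_id=self.subject_id,
                        group=self.group, roi_id=self.roi_id)


@dataclass
class RoiSet:
    """Disjoint labeled ROIs: 0 = background, 1..n = ROI ids."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label image must be 2-D")

    @property
    def roi_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_rois(self) -> int:
        return self.roi_ids.size

    def pixel_counts(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    def centroids(self) -> dict[int, tuple[float, float]]:
        """ROI centroids as (row, col), pixel-count weighted."""
        out = {}
        for rid in self.roi_ids:
            rr, cc = np.nonzero(self.labels == rid)
            out[int(rid)] = (float(rr.mean()), float(cc.mean()))
        return out

    def manifest(self) -> pd.DataFrame:
        cents = self.centroids()
        counts = self.pixel_counts()
        rows = [
            {"roi_id": int(rid), "n_pixels": counts[int(rid)],
             "centroid_row": cents[int(rid)][0], "centroid_col": cents[int(rid)][1]}
            for rid in self.roi_ids
        ]
        return pd.DataFrame(rows, columns=["roi_id", "n_pixels",
                                           "centroid_row", "centroid_col"])


def global_median_threshold(movie: MovieStack) -> float:
    """Median intensity over the full frames x height x width sample."""
    return float(np.median(movie.data))


def active_pixel_mask(movie: MovieStack, threshold: float | None = None) -> np.ndarray:
    """Boolean mask of pixels whose temporal-mean intensity is >= threshold.

    The default threshold is :func:`global_median_threshold`. Pixels exactly
    at the threshold are retained (only strictly sub-threshold pixels are
    discarded as background).
    """
    if threshold is None:
        threshold = global_median_threshold(movie)
    mask = movie.mean_image() >= threshold
    if not mask.any():
        raise ValueError("no pixels above threshold")
    return mask


def _zscore_features(movie: MovieStack, mask: np.ndarray) -> np.ndarray:
    """Per-pixel time series, z-scored; zero-variance pixels map to zeros."""
    series = movie.data[:, mask].T.astype(np.float64)  # (n_pixels, n_frames)
    mu = series.mean(axis=1, keepdims=True)
    sd = series.std(axis=1, keepdims=True)
    out = np.zeros_like(series)
    nz = sd[:, 0] > 0
    out[nz] = (series[nz] - mu[nz]) / sd[nz]
    return out


def kmeans_activity_cluster(
    movie: MovieStack,
    mask: np.ndarray,
    k: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Retain the largest of k activity clusters of the masked pixels.

    Pixels are clustered on their z-scored time series so that grouping
    reflects waveform, not brightness. k-means runs 10 seeded restarts and
    keeps the best inertia; if two clusters tie for the largest population
    the lowest cluster index wins. Returns a boolean mask (subset of
    ``mask``) of the retained pixels.
    """
    mask = np.asarray(mask, dtype=bool)
    n_px = int(mask.sum())
    if n_px < k:
        raise ValueError(f"mask has {n_px} pixels; need at least k={k}")
    feats = _zscore_features(movie, mask)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(feats)
    counts = np.bincount(labels, minlength=k)
    keep = int(np.argmax(counts))  # argmax takes the lowest index on ties
    retained = np.zeros_like(mask)
    retained[mask] = labels == keep
    return retained


def watershed_split(
    retained: np.ndarray,
    movie: MovieStack,
    min_roi_px: int = 4,
    smooth_sigma_px: float = 1.0,
    min_peak_separation_px: int = 3,
) -> RoiSet:
    """Split the retained pixel set into per-terminal ROIs by watershed.

    The watershed surface is the negative of the Gaussian-smoothed temporal
    mean image, so intensity basins correspond to terminal centres. Seeds
    are local maxima of the smoothed image within the retained set, at least
    ``min_peak_separation_px`` apart. ROIs smaller than ``min_roi_px``
    pixels are dropped as noise.
    """
    retained = np.asarray(retained, dtype=bool)
    if not retained.any():
        raise ValueError("retained pixel set is empty")
    surface = ndi.gaussian_filter(movie.mean_image(), smooth_sigma_px)
    coords = peak_local_max(surface, min_distance=min_peak_separation_px,
                            labels=retained, exclude_border=False)
    markers = np.zeros(retained.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        # flat surface within the mask: single basin
        markers[tuple(np.argwhere(retained)[0])] = 1
    labels = watershed(-surface, markers=markers, mask=retained)
    # drop undersized ROIs and relabel contiguously
    out = np.zeros_like(labels)
    next_id = 1
    for rid in np.unique(labels[labels > 0]):
        px = labels == rid
        if px.sum() >= min_roi_px:
            out[px] = next_id
            next_id += 1
    if next_id == 1:
        raise ValueError("no ROIs survive size filter")
    return RoiSet(labels=out)


def extract_traces(movie: MovieStack, rois: RoiSet, subject_id: str = "",
                   group: str = "") -> list[RawTrace]:
    """One trace per ROI: mean intensity of the ROI's pixels per frame."""
    if rois.labels.shape != movie.shape[1:]:
        raise ValueError("ROI label image does not match movie frame shape")
    traces = []
    for rid in rois.roi_ids:
        px = rois.labels == rid
        vals = movie.data[:, px].mean(axis=1)
        traces.append(RawTrace(values=vals, frame_rate_hz=movie.frame_rate_hz,
                               t0_s=movie.t0_s, subject_id=subject_id,
                               group=group, roi_id=int(rid)))
    return traces


def pooled_trace(movie: MovieStack, retained: np.ndarray, subject_id: str = "",
                 group: str = "") -> RawTrace:
    """Single trace over the whole retained pixel set (bath-application mode).

    Equals the pixel-count-weighted mean of per-ROI traces over any
    partition of the same pixel set.
    """
    retained = np.asarray(retained, dtype=bool)
    if not retained.any():
        raise ValueError("retained pixel set is empty")
    vals = movie.data[:, retained].mean(axis=1)
    return RawTrace(values=vals, frame_rate_hz=movie.frame_rate_hz,
                    t0_s=movie.t0_s, subject_id=subject_id, group=group,
                    roi_id=0)


def segment_movie(
    movie: MovieStack,
    k: int = 3,
    seed: int = 0,
    min_roi_px: int = 4,
    threshold: float | None = None,
) -> tuple[np.ndarray, RoiSet]:
    """Full threshold -> k-means -> watershed chain.

    Returns the retained active-pixel mask and the watershed :class:`RoiSet`.
    """
    mask = active_pixel_mask(movie, threshold)
    retained = kmeans_activity_cluster(movie, mask, k=k, seed=seed)
    rois = watershed_split(retained, movie, min_roi_px=min_roi_px)
    return retained, rois
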