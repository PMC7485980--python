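"""Movie I/O and rigid in-plane motion correction.

A recording is a single-channel multi-page TIFF plus a frame rate. Brain
motion within the imaging plane is corrected by phase-correlation rigid
registration against a reference image (default: the temporal mean), the
standard approach for slow in-plane drift at these frame rates. Out-of-plane
motion cannot be corrected in 2-D data; a per-recording motion score is
reported so such preparations can be reviewed, but nothing is auto-discarded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage.registration import phase_cross_correlation

__all__ = [
    "MovieStack",
    "ShiftSeries",
    "read_movie",
    "write_movie",
    "register_rigid",
]


@dataclass
class MovieStack:
    """A fluorescence movie: (frames, height, width) intensities plus timing.

    Parameters
    ----------
    data:
        Non-negative fluorescence intensities, shape ``(n_frames, h, w)``.
    frame_rate_hz:
        Acquisition rate in frames per second (must be positive).
    t0_s:
        Time of the first frame on the experiment clock, in seconds.
    """

    data: np.ndarray
    frame_rate_hz: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"movie data must be (frames, height, width); got shape {self.data.shape}"
            )
        if self.data.shape[0] < 2:
            raise ValueError("a movie needs at least 2 frames")
        if not np.isfinite(self.data).all():
            raise ValueError("movie intensities must be finite")
        if (self.data < 0).any():
            raise ValueError("movie intensities must be non-negative")
        if not (self.frame_rate_hz > 0):
            raise ValueError(f"frame_rate_hz must be > 0, got {self.frame_rate_hz}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def times_s(self) -> np.ndarray:
        """Per-frame acquisition times on the experiment clock."""
        return self.t0_s + np.arange(self.n_frames) / self.frame_rate_hz

    def mean_image(self) -> np.ndarray:
        return self.data.mean(axis=0)


@dataclass
class ShiftSeries:
    """Per-frame (dy, dx) displacements applied during registration."""

    shifts: np.ndarray  # (n_frames, 2), rows are (dy, dx)
    reference: int | None = None

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=np.float64)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 2:
            raise ValueError("shifts must have shape (n_frames, 2)")

    def __len__(self) -> int:
        return self.shifts.shape[0]

    def max_abs(self) -> float:
        return float(np.abs(self.shifts).max()) if len(self) else 0.0

    def motion_score(self) -> float:
        """Mean per-frame displacement magnitude in pixels (QC aid)."""
        return float(np.hypot(self.shifts[:, 0], self.shifts[:, 1]).mean())

    def to_csv(self, path: str | Path) -> None:
        n = len(self)
        out = np.column_stack([np.arange(n), self.shifts])
        header = "frame,dy,dx"
        np.savetxt(path, out, delimiter=",", header=header, comments="",
                   fmt=["%d", "%.4f", "%.4f"])


def write_movie(path: str | Path, movie: MovieStack) -> None:
    """Write a movie as a multi-page float32 TIFF with timing metadata.

    The frame rate and start time are stored in the TIFF ImageDescription as
    JSON so that :func:`read_movie` can round-trip them without a sidecar.
    """
    meta = {"frame_rate_hz": movie.frame_rate_hz, "t0_s": movie.t0_s}
    tifffile.imwrite(
        Path(path),
        movie.data.astype(np.float32),
        photometric="minisblack",
        description=json.dumps(meta),
    )


def read_movie(path: str | Path, frame_rate_hz: float | None = None,
               t0_s: float | None = None) -> MovieStack:
    """Read a single-channel multi-page TIFF as a :class:`MovieStack`.

    The frame rate is taken from the ``frame_rate_hz`` argument if given,
    otherwise from JSON metadata in the TIFF ImageDescription. A missing
    frame rate is an error: timing is meaningless without it.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description or ""
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if data.ndim == 2:
        raise ValueError(f"{path}: single-frame TIFF; a movie needs at least 2 frames")
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a single-channel multi-page TIFF "
            f"(frames, height, width); got shape {data.shape}"
        )
    fps = frame_rate_hz if frame_rate_hz is not None else meta.get("frame_rate_hz")
    if fps is None:
        raise ValueError(
            f"{path}: frame rate not found; supply frame_rate_hz= or embed "
            "'frame_rate_hz' metadata"
        )
    if not (float(fps) > 0):
        raise ValueError(f"{path}: frame_rate_hz must be > 0, got {fps}")
    t0 = t0_s if t0_s is not None else float(meta.get("t0_s", 0.0))
    return MovieStack(data=np.asarray(data, dtype=np.float64),
                      frame_rate_hz=float(fps), t0_s=t0)


def register_rigid(
    movie: MovieStack,
    reference: int | None = None,
    upsample_factor: int = 10,
    max_shift_px: float | None = None,
) -> tuple[MovieStack, ShiftSeries]:
    """Rigid in-plane registration by phase correlation.

    Each frame is translated to align with a reference image: the temporal
    mean by default, or a chosen frame index. Shifts are estimated to
    ``1/upsample_factor`` pixel and applied by spline interpolation; pixels
    shifted in from outside the frame are filled with that frame's median so
    the fill does not bias the downstream global-median intensity threshold.

    Returns the registered movie and the applied :class:`ShiftSeries`
    (``(dy, dx)`` per frame; a degenerate correlation yields zero shift).
    """
    if reference is not None and not (0 <= reference < movie.n_frames):
        raise IndexError(f"reference frame {reference} out of range")
    ref_img = movie.mean_image() if reference is None else movie.data[reference]

    n = movie.n_frames
    shifts = np.zeros((n, 2))
    out = np.empty_like(movie.data)
    for i in range(n):
        frame = movie.data[i]
        try:
            shift, _, _ = phase_cross_correlation(
                ref_img, frame, upsample_factor=upsample_factor,
                normalization=None,
            )
        except (ValueError, ZeroDivisionError):
            shift = np.zeros(2)
        if not np.isfinite(shift).all():
            shift = np.zeros(2)
        if max_shift_px is not None and np.abs(shift).max() > max_shift_px:
            shift = np.zeros(2)
        shifts[i] = shift
        if shift[0] == 0 and shift[1] == 0:
            out[i] = frame
        else:
            out[i] = ndi.shift(frame, shift, order=1, mode="constant",
                               cval=float(np.median(frame)))
    out = np.clip(out, 0.0, None)
    reg = MovieStack(data=out, frame_rate_hz=movie.frame_rate_hz, t0_s=movie.t0_s)
    return reg, ShiftSeries(shifts=shifts, reference=reference)
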