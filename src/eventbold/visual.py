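"""Frame-wise edge-density nuisance regressor for movie-watching fMRI.

Low-level visual change (cuts, motion, clutter) drives widespread BOLD
activity and co-occurs with many event boundaries.  To keep boundary-evoked
estimates from being contaminated by it, the proportion of edge pixels in
each stimulus frame is computed and resampled to the fMRI TR grid, yielding a
continuous nuisance regressor entered into the GLM unconvolved.

Edges are defined by a thresholded Sobel gradient magnitude on unit-scaled
intensities; the module is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "EdgeSeries",
    "edge_map",
    "edge_proportion",
    "edge_regressor",
    "edge_series_from_proportions",
    "read_edge_csv",
]

#: default gradient-magnitude threshold on unit-scaled intensities
DEFAULT_GRAD_THRESHOLD = 0.2


@dataclass(frozen=True)
class EdgeSeries:
    """Per-frame and per-TR edge-pixel proportions."""

    per_frame: np.ndarray
    frame_rate: float
    per_tr: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        for name in ("per_frame", "per_tr"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.size and (v.min() < 0 or v.max() > 1):
                raise ValueError(f"{name} values must lie in [0, 1]")


def _check_frame(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.size == 0:
        raise ValueError("frame must be a non-empty 2-D array")
    if frame.min() < -1e-9 or frame.max() > 1 + 1e-9:
        raise ValueError("frame intensities must lie in [0, 1]")
    return frame


def edge_map(frame: np.ndarray, grad_threshold: float = DEFAULT_GRAD_THRESHOLD) -> np.ndarray:
    """Binary edge mask: Sobel gradient magnitude above threshold.

    The Sobel responses along each axis are scaled by 1/8 so that a clean
    unit step yields a gradient magnitude of 0.5 at the pixels flanking it.
    """
    frame = _check_frame(frame)
    if grad_threshold <= 0:
        raise ValueError("grad_threshold must be positive")
    gx = ndimage.sobel(frame, axis=0, mode="reflect") / 8.0
    gy = ndimage.sobel(frame, axis=1, mode="reflect") / 8.0
    return np.hypot(gx, gy) > grad_threshold


def edge_proportion(frame: np.ndarray, grad_threshold: float = DEFAULT_GRAD_THRESHOLD) -> float:
    """Proportion of edge pixels to total pixel count, in [0, 1]."""
    return float(edge_map(frame, grad_threshold).mean())


def edge_series_from_proportions(
    per_frame: np.ndarray,
    frame_rate: float,
    tr_s: float,
    n_tr: int,
) -> EdgeSeries:
    """Resample per-frame edge proportions to the TR grid.

    Frame i is assigned to the half-open TR interval containing its temporal
    midpoint (i + 0.5)/frame_rate; the per-TR value is the mean over assigned
    frames.  A trailing interval with no frames carries the previous value
    forward.
    """
    per_frame = np.asarray(per_frame, dtype=float).ravel()
    if n_tr <= 0:
        raise ValueError("n_tr must be positive")
    if frame_rate <= 0 or tr_s <= 0:
        raise ValueError("frame_rate and tr_s must be positive")
    duration = per_frame.size / frame_rate
    if duration < (n_tr - 1) * tr_s:
        raise ValueError(
            f"frames cover only {duration:.2f} s but {n_tr} TRs of {tr_s} s "
            "were requested"
        )
    midpoints = (np.arange(per_frame.size) + 0.5) / frame_rate
    bins = np.floor(midpoints / tr_s).astype(int)
    per_tr = np.full(n_tr, np.nan)
    for i in range(n_tr):
        sel = bins == i
        if sel.any():
            per_tr[i] = per_frame[sel].mean()
    if np.isnan(per_tr[0]):
        raise ValueError("first TR interval contains no frame midpoints")
    for i in range(1, n_tr):
        if np.isnan(per_tr[i]):
            per_tr[i] = per_tr[i - 1]
    return EdgeSeries(per_frame=per_frame, frame_rate=frame_rate, per_tr=per_tr, tr_s=tr_s)


def edge_regressor(
    frames,
    tr_s: float = 2.47,
    n_tr: int | None = None,
    grad_threshold: float = DEFAULT_GRAD_THRESHOLD,
) -> EdgeSeries:
    """Edge-proportion nuisance regressor for a frame sequence.

    ``frames`` is any object with ``frames`` (n, h, w array) and
    ``frame_rate`` attributes (e.g. :class:`eventbold.synth.FrameSequence`).
    """
    if n_tr is None or n_tr <= 0:
        raise ValueError("n_tr must be a positive integer")
    per_frame = np.array(
        [edge_proportion(f, grad_threshold) for f in frames.frames]
    )
    return edge_series_from_proportions(per_frame, frames.frame_rate, tr_s, n_tr)


def read_edge_csv(path) -> np.ndarray:
    """Read per-frame edge proportions from CSV (frame_index, edge_proportion)."""
    df = pd.read_csv(path)
    required = {"frame_index", "edge_proportion"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    df = df.sort_values("frame_index")
    return df["edge_proportion"].to_numpy(dtype=float)


def write_edge_tsv(series: EdgeSeries, path) -> None:
    pd.DataFrame({"edge_per_tr": series.per_tr}).to_csv(path, sep="\t", index=False)
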