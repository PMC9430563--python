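"""Colony leading-edge quantification.

Colony expansion is read off 2-D projections of the cropped stack: at each
timepoint the colony mask is segmented, and the leading edge is the extremal
foreground coordinate along the axis of advance.  Edge positions over time
give expansion rates (μm/h), which are smoothed with a trailing 4-value
moving average advancing one timepoint at a time; several regions of the
same colony are combined as mean ± sample SD.  The gap between two
approaching colonies is the closest-point distance between their masks.

Negative rates are legitimate: a colony retreating from an antagonist shows
up as a negative front velocity, not an error.  Absence is likewise a value:
a blank field (colony not yet arrived, or gone) yields NaN positions which
propagate through rates rather than raising.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass

from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import label

from .stack_io import Calibration, HyperStack, UncalibratedError

__all__ = [
    "FrontTrack",
    "RateSeries",
    "detect_front",
    "track_fronts",
    "expansion_rate",
    "average_regions",
    "front_distance",
]


@dataclass
class FrontTrack:
    """Leading-edge position per timepoint for one colony region.

    ``positions`` are μm along the advance axis (NaN = undetected).
    """

    channel: int
    positions: np.ndarray  # float μm, NaN where absent
    advance_axis: str  # "x" or "y"
    direction: str  # "+" or "-"
    pixel_size: float  # μm
    region: str = ""
    projection: str = "max"

    def to_frame(self, cal: Calibration | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"timepoint": np.arange(len(self.positions)), "position_um": self.positions})
        if cal is not None:
            df.insert(1, "hours", [cal.timepoint_to_hours(t) for t in df["timepoint"]])
        return df


@dataclass
class RateSeries:
    """Raw and smoothed front velocities in μm/h.

    ``raw_rates[i]`` is the velocity over the gap between timepoints *i* and
    *i+1*; ``smoothed_rates[i]`` is the trailing moving average of the
    ``window`` most recent raw rates ending at *i* (shorter at the head).
    """

    raw_rates: np.ndarray
    smoothed_rates: np.ndarray
    window: int = 4

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gap": np.arange(len(self.raw_rates)),
                "raw_rate_um_per_h": self.raw_rates,
                "smoothed_rate_um_per_h": self.smoothed_rates,
            }
        )


def _binarize(plane: np.ndarray, threshold) -> np.ndarray | None:
    plane = np.asarray(plane)
    if plane.size == 0 or plane.min() == plane.max():
        return None  # blank field: nothing to segment
    if threshold == "otsu":
        thr = threshold_otsu(plane)
    else:
        thr = float(threshold)
    mask = plane > thr
    return mask if mask.any() else None


def detect_front(
    plane: np.ndarray,
    axis: str = "x",
    direction: str = "+",
    threshold="otsu",
    min_component_px: int = 5,
    pixel_size: float = 1.0,
) -> float:
    """Leading-edge position (μm) in a single 2-D plane, or NaN if absent.

    The plane is binarised (Otsu by default, or a fixed value), connected
    components smaller than ``min_component_px`` pixels (8-connectivity) are
    discarded as noise, and the front is the extremal surviving foreground
    coordinate along *axis* in *direction*, scaled to μm.
    """
    if axis not in ("x", "y"):
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")
    if direction not in ("+", "-"):
        raise ValueError(f"direction must be '+' or '-', got {direction!r}")
    mask = _binarize(plane, threshold)
    if mask is None:
        return float("nan")
    labels = label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= max(1, int(min_component_px)))
    keep = keep[keep != 0]
    if keep.size == 0:
        return float("nan")
    ys, xs = np.nonzero(np.isin(labels, keep))
    coords = xs if axis == "x" else ys
    front_px = coords.max() if direction == "+" else coords.min()
    return float(front_px) * float(pixel_size)


def _project(stack: HyperStack, t: int, channel: int, projection: str) -> np.ndarray:
    z_dim = stack.dims[2]
    planes = [stack.get_plane(t, channel, z).astype(np.float64) for z in range(z_dim)]
    vol = np.stack(planes)
    if projection == "max":
        return vol.max(axis=0)
    if projection == "mean":
        return vol.mean(axis=0)
    raise ValueError(f"projection must be 'max' or 'mean', got {projection!r}")


def track_fronts(
    stack: HyperStack,
    channel: int,
    projection: str = "max",
    axis: str = "x",
    direction: str = "+",
    threshold="otsu",
    min_component_px: int = 5,
    region: str = "",
) -> FrontTrack:
    """Leading-edge position per timepoint on Z-projections of one channel."""
    if stack.calibration.uncalibrated:
        raise UncalibratedError("front positions in μm need a calibrated stack")
    if not 0 <= channel < stack.dims[1]:
        raise IndexError(f"channel {channel} out of range for C={stack.dims[1]}")
    px = stack.calibration.pixel_size_xy
    positions = np.array(
        [
            detect_front(
                _project(stack, t, channel, projection),
                axis=axis,
                direction=direction,
                threshold=threshold,
                min_component_px=min_component_px,
                pixel_size=px,
            )
            for t in range(stack.dims[0])
        ]
    )
    return FrontTrack(
        channel=channel,
        positions=positions,
        advance_axis=axis,
        direction=direction,
        pixel_size=px,
        region=region,
        projection=projection,
    )


def expansion_rate(track: FrontTrack, cal: Calibration, window: int = 4) -> RateSeries:
    """Front velocities from a position track, with trailing moving average.

    ``raw_rates[i] = (pos[i+1] − pos[i]) / Δt_h``; a gap (NaN position) makes
    the adjacent raw rates NaN.  ``smoothed_rates[i]`` averages the present
    values among the ``window`` most recent raw rates ending at *i* (the
    head of the series uses the shorter available window) and is NaN exactly
    where the raw rate is.
    """
    pos = np.asarray(track.positions, dtype=float)
    if np.sum(np.isfinite(pos)) < 2:
        raise ValueError("need at least 2 detected positions to compute rates")
    if window < 1:
        raise ValueError("window must be >= 1")
    dt_h = cal.time_interval / 60.0
    raw = np.diff(pos) / dt_h
    smoothed = np.full_like(raw, np.nan)
    for i in range(len(raw)):
        if not np.isfinite(raw[i]):
            continue
        recent = raw[max(0, i - window + 1) : i + 1]
        smoothed[i] = np.nanmean(recent)
    return RateSeries(raw_rates=raw, smoothed_rates=smoothed, window=int(window))


def average_regions(series: list) -> pd.DataFrame:
    """Pointwise mean ± sample SD of rate series from several colony regions.

    Accepts :class:`RateSeries` objects (their smoothed rates are used) or
    plain 1-D arrays.  All series must share the same timebase (length);
    with a single region the SD column is NaN.
    """
    if len(series) < 1:
        raise ValueError("need at least one rate series")
    arrays = [
        np.asarray(s.smoothed_rates if isinstance(s, RateSeries) else s, dtype=float)
        for s in series
    ]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError(f"mismatched timebases: lengths {[len(a) for a in arrays]}")
    mat = np.vstack(arrays)
    mean = np.nanmean(mat, axis=0)
    if len(arrays) == 1:
        sd = np.full(n, np.nan)
    else:
        sd = np.nanstd(mat, axis=0, ddof=1)
    return pd.DataFrame({"timepoint": np.arange(n), "mean": mean, "sd": sd, "n": len(arrays)})


def front_distance(mask_a: np.ndarray, mask_b: np.ndarray, pixel_size: float = 1.0) -> float:
    """Closest-point distance (μm) between two colony masks.

    Minimum Euclidean distance between any foreground pixel of *mask_a* and
    any of *mask_b*; 0 when the masks touch or overlap, NaN when either is
    empty (colony not yet in the field).
    """
    a = np.argwhere(np.asarray(mask_a, dtype=bool))
    b = np.argwhere(np.asarray(mask_b, dtype=bool))
    if a.size == 0 or b.size == 0:
        return float("nan")
    dist, _ = cKDTree(b).query(a, k=1)
    return float(dist.min()) * float(pixel_size)
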