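"""Estimating the axial displacement of the agar surface.

As solid medium evaporates and is consumed, the plate surface — and the
colony on it — sinks at a near-constant speed, so the best-focus slice
drifts linearly through the acquired Z-range.  This module fits that line:
the *displacement value* is the slope in slices per timepoint, and
:func:`surface_slice` predicts the (real-valued) surface slice at any
timepoint, including extrapolation beyond the fitted range.

Two estimation routes are provided.  The automatic route takes, at each
reference timepoint, the Z-slice with the highest mean intensity in a chosen
channel (the bright agar/colony layer) and fits a least-squares line through
those maxima.  The manual route fits the same line through user-picked
best-focus slices, which also works on transmitted-light data or when
fluorescence is too weak for a reliable intensity maximum.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass

import numpy as np

from .stack_io import Calibration, UncalibratedError
from .zprofile import IntensityProfile

__all__ = [
    "DriftModel",
    "estimate_manual",
    "estimate_auto",
    "surface_slice",
    "rate_um_per_hour",
    "FlatProfileWarning",
]


class FlatProfileWarning(UserWarning):
    """A reference timepoint had an all-equal intensity profile and was dropped."""


@dataclass(frozen=True)
class DriftModel:
    """Linear surface-position model: slice(t) = anchor + rate × (t − t0).

    ``displacement_value`` is in slices per timepoint and may be negative
    (upright configurations, or swelling media, move the surface the other
    way).  ``fit_residual_rms`` is present only when more than two points
    were fitted.
    """

    displacement_value: float
    anchor_slice: float
    anchor_timepoint: int
    method: str  # "automatic" | "manual" | "user_specified"
    fit_residual_rms: float | None = None

    def to_dict(self) -> dict:
        return {
            "displacement_value": self.displacement_value,
            "anchor_slice": self.anchor_slice,
            "anchor_timepoint": self.anchor_timepoint,
            "method": self.method,
            "fit_residual_rms": self.fit_residual_rms,
        }

    def save(self, path: str | os.PathLike) -> str:
        path = os.fspath(path)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        return path

    @classmethod
    def load(cls, path: str | os.PathLike) -> "DriftModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def _fit_line(points: list[tuple[int, float]], method: str) -> DriftModel:
    ts = np.array([p[0] for p in points], dtype=float)
    zs = np.array([p[1] for p in points], dtype=float)
    if len(points) == 2:
        slope = (zs[1] - zs[0]) / (ts[1] - ts[0])
        resid = None
    else:
        slope, intercept = np.polyfit(ts, zs, 1)
        resid = float(np.sqrt(np.mean((intercept + slope * ts - zs) ** 2)))
    t0 = int(ts.min())
    if len(points) == 2:
        anchor = float(zs[np.argmin(ts)])
    else:
        anchor = float(intercept + slope * t0)
    return DriftModel(
        displacement_value=float(slope),
        anchor_slice=anchor,
        anchor_timepoint=t0,
        method=method,
        fit_residual_rms=resid,
    )


def estimate_manual(anchors: list[tuple[int, float]]) -> DriftModel:
    """Fit the drift line through user-selected (timepoint, best-focus slice) pairs.

    Two anchors give the exact two-point slope; more are combined by
    ordinary least squares.  The anchor timepoint of the returned model is
    the earliest anchor.
    """
    if len(anchors) < 2:
        raise ValueError(
            "need at least 2 anchors to estimate a rate; with a single best-focus "
            "slice, construct DriftModel directly with a known displacement_value"
        )
    ts = [int(t) for t, _ in anchors]
    if len(set(ts)) != len(ts):
        raise ValueError(f"anchor timepoints must be distinct, got {ts}")
    points = sorted(((int(t), float(z)) for t, z in anchors), key=lambda p: p[0])
    return _fit_line(points, "manual")


def estimate_auto(
    profile: IntensityProfile,
    channel: int,
    ref_timepoints: list[int] | None = None,
) -> DriftModel:
    """Estimate drift from per-timepoint intensity maxima.

    For each reference timepoint the surface is placed at the Z with the
    highest mean intensity in *channel* (ties resolved toward lower Z — the
    side from which the surface is first encountered).  Timepoints whose
    profile is flat carry no focus information and are dropped with a
    :class:`FlatProfileWarning`.
    """
    t_dim, c_dim, _ = profile.dims
    if not 0 <= channel < c_dim:
        raise IndexError(f"channel {channel} out of range for C={c_dim}")
    if ref_timepoints is None:
        ref_timepoints = [t for t in range(t_dim) if profile.is_present(t, channel)]
    points: list[tuple[int, float]] = []
    for t in sorted(set(int(t) for t in ref_timepoints)):
        curve = profile.values[t, channel]
        if not np.all(np.isfinite(curve)):
            raise ValueError(f"channel {channel} not profiled at timepoint {t}")
        if np.ptp(curve) == 0:
            warnings.warn(
                f"flat intensity profile at timepoint {t}; excluded from drift fit",
                FlatProfileWarning,
                stacklevel=2,
            )
            continue
        points.append((t, float(np.argmax(curve))))  # argmax -> lowest Z on ties
    if len(points) < 2:
        raise ValueError(
            f"only {len(points)} usable reference timepoints; automatic estimation "
            "needs at least 2 — consider manual best-focus anchors (estimate_manual), "
            "which also work on transmitted light or weak fluorescence"
        )
    model = _fit_line(points, "automatic")
    return model


def surface_slice(model: DriftModel, t: float) -> float:
    """Predicted (real-valued, unclamped) surface slice at timepoint *t*."""
    return model.anchor_slice + model.displacement_value * (t - model.anchor_timepoint)


def rate_um_per_hour(model: DriftModel, cal: Calibration) -> float:
    """Convert the displacement value to μm of surface descent per hour."""
    if cal.uncalibrated:
        raise UncalibratedError(
            "stack has no real-world calibration; rate in μm/h is undefined"
        )
    return model.displacement_value * cal.z_step / (cal.time_interval / 60.0)
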