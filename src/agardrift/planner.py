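"""Acquisition-planning arithmetic.

Before a multi-day time-lapse is started, the acquisition volume has to be
sized for the drift it must absorb: the surface descends at a roughly
constant rate, so a run of duration *d* hours needs the colony's own depth
plus ``rate × d`` μm of headroom, divided by the Z-step to give a slice
count, which in turn sets the per-timepoint acquisition time, the image
count, and the data volume.  These are the numbers that decide whether an
experiment fits the interval and the disk before any data are taken.

Byte figures use decimal units (1 Gb = 10**9 bytes).  Per-timepoint size is
always a user input: real acquisitions carry container/metadata overhead, so
it is not derivable from pixel dimensions alone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "AcquisitionPlan",
    "predict_total_drift",
    "required_slices",
    "plan_counts",
    "IntervalOverrunWarning",
]

GB = 10**9  # decimal gigabyte


class IntervalOverrunWarning(UserWarning):
    """Acquiring one timepoint takes longer than the time-lapse interval."""


def predict_total_drift(rate_um_per_h: float, duration_h: float) -> float:
    """Total axial surface descent in μm over an experiment."""
    if rate_um_per_h < 0 or duration_h < 0:
        raise ValueError("rate and duration must be >= 0")
    return rate_um_per_h * duration_h


def required_slices(thickness_um: float, z_step_um: float) -> int:
    """Number of Z-slices needed to cover *thickness_um* at *z_step_um* spacing."""
    if thickness_um <= 0 or z_step_um <= 0:
        raise ValueError("thickness and z_step must be > 0")
    return math.ceil(thickness_um / z_step_um)


@dataclass(frozen=True)
class AcquisitionPlan:
    """A fully specified multi-day 3-D time-lapse acquisition.

    Derived counts follow ``n_slices = ceil(thickness/z_step)`` and
    ``n_timepoints = floor(duration·60/interval)`` (acquisition intervals,
    not fence-posts) unless given explicitly — microscope software sometimes
    reports slice/timepoint counts that differ from the raw arithmetic, and
    the explicit values then take precedence.
    """

    drift_rate: float  # μm/h
    duration: float  # h
    interval: float  # min between timepoints
    z_step: float  # μm
    n_channels: int
    sec_per_slice: float  # s to acquire one multichannel slice
    bytes_per_timepoint: float  # bytes (user input, never derived)
    safety_margin: float = 0.0  # extra μm beyond predicted drift
    thickness: float | None = None  # μm; default: predicted drift + margin
    n_slices: int | None = None  # default: ceil(thickness / z_step)
    n_timepoints: int | None = None  # default: floor(duration·60 / interval)

    def __post_init__(self) -> None:
        if min(self.duration, self.interval, self.z_step, self.sec_per_slice) <= 0:
            raise ValueError("duration, interval, z_step, sec_per_slice must be > 0")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.resolved_n_slices < 1 or self.resolved_n_timepoints < 1:
            raise ValueError("slice and timepoint counts must be >= 1")

    @property
    def resolved_thickness(self) -> float:
        if self.thickness is not None:
            return self.thickness
        return predict_total_drift(self.drift_rate, self.duration) + self.safety_margin

    @property
    def resolved_n_slices(self) -> int:
        if self.n_slices is not None:
            return int(self.n_slices)
        return required_slices(self.resolved_thickness, self.z_step)

    @property
    def resolved_n_timepoints(self) -> int:
        if self.n_timepoints is not None:
            return int(self.n_timepoints)
        return math.floor(self.duration * 60.0 / self.interval)


def plan_counts(plan: AcquisitionPlan) -> dict:
    """Totals for a plan: timepoints, images, minutes per timepoint, bytes.

    ``total_images = n_timepoints × n_slices × n_channels`` and
    ``total_bytes = bytes_per_timepoint × n_timepoints``.  When one
    timepoint takes longer to acquire than the interval, an
    :class:`IntervalOverrunWarning` is raised — in a multiposition run every
    stack must finish within the interval or timepoints slip.
    """
    n_t = plan.resolved_n_timepoints
    n_z = plan.resolved_n_slices
    minutes_per_timepoint = n_z * plan.sec_per_slice / 60.0
    if minutes_per_timepoint > plan.interval:
        warnings.warn(
            f"one timepoint takes {minutes_per_timepoint:.1f} min but the interval "
            f"is {plan.interval:g} min; acquisition cannot keep up",
            IntervalOverrunWarning,
            stacklevel=2,
        )
    total_bytes = plan.bytes_per_timepoint * n_t
    return {
        "n_timepoints": n_t,
        "n_slices": n_z,
        "n_channels": plan.n_channels,
        "total_images": n_t * n_z * plan.n_channels,
        "minutes_per_timepoint": minutes_per_timepoint,
        "predicted_drift_um": predict_total_drift(plan.drift_rate, plan.duration),
        "thickness_um": plan.resolved_thickness,
        "total_bytes": total_bytes,
        "total_gb": total_bytes / GB,
    }
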