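"""Floating-window Z-crop.

Given a fitted drift model, each timepoint keeps only a window of
``window_thickness`` Z-slices positioned so that the predicted agar surface
stays at a fixed plane of the output stack.  A 150-slice acquisition volume
that existed only to cover several days of surface descent typically
collapses to the 15-20 slices that actually contain the colony, shrinking
the data set by the ratio Z/W while remaining bit-exact within the window.

Cropping is chunked: timepoints are staged as temporary single-timepoint
TIFFs and then reassembled, so peak memory is bounded by one timepoint
regardless of how long the time-lapse is, and an interrupted run can resume
from its manifest instead of starting over.
"""

from __future__ import annotations

import json
import os
import shutil
from dataclasses import dataclass, field

import numpy as np
import tifffile

from . import stack_io
from .drift import DriftModel, surface_slice
from .stack_io import HyperStack

__all__ = ["CropPlan", "plan_crop", "apply_crop", "reduction_report"]


def _round_half_away(x: np.ndarray | float) -> np.ndarray:
    """Round halves away from zero (round(6.5)=7, round(-6.5)=-7)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass
class CropPlan:
    """Per-timepoint Z-window realising the floating crop.

    ``start_slices[t]`` is the first kept source slice at timepoint *t*;
    the window is ``[start, start + window_thickness)``.  Timepoints where
    the ideal window ran off the acquired volume and was clamped to the edge
    are listed in ``clamped_timepoints``.
    """

    window_thickness: int
    start_slices: list[int]
    source_dims: tuple[int, ...]
    clamped_timepoints: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        z = self.source_dims[2]
        w = self.window_thickness
        if not 1 <= w <= z:
            raise ValueError(f"window_thickness must be in [1, Z={z}], got {w}")
        for t, s in enumerate(self.start_slices):
            if not 0 <= s <= z - w:
                raise ValueError(f"start_slices[{t}]={s} outside [0, {z - w}]")

    def to_dict(self) -> dict:
        return {
            "window_thickness": self.window_thickness,
            "start_slices": [int(s) for s in self.start_slices],
            "source_dims": list(self.source_dims),
            "clamped_timepoints": [int(t) for t in self.clamped_timepoints],
        }

    def save(self, path: str | os.PathLike) -> str:
        path = os.fspath(path)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "CropPlan":
        return cls(
            window_thickness=int(d["window_thickness"]),
            start_slices=[int(s) for s in d["start_slices"]],
            source_dims=tuple(d["source_dims"]),
            clamped_timepoints=[int(t) for t in d["clamped_timepoints"]],
        )


def plan_crop(
    model: DriftModel,
    stack: HyperStack,
    window_thickness: int,
    start_override: float | None = None,
    offset: float | None = None,
) -> CropPlan:
    """Plan the per-timepoint window positions from the drift model.

    The window start at timepoint *t* is
    ``clamp(round(surface_slice(model, t) + offset), 0, Z − W)``, rounding
    computed per-timepoint on the real-valued prediction (no accumulation of
    rounded steps) with halves away from zero.  The default offset of
    ``−W/4`` puts the predicted surface a quarter of the window above the
    output bottom, leaving most of the window for the colony growing upward;
    pass ``offset=0`` to start the window exactly at the surface.
    ``start_override`` replaces the model's predicted position at t=0 while
    keeping its displacement value.
    """
    t_dim, _, z_dim = stack.dims[0], stack.dims[1], stack.dims[2]
    w = int(window_thickness)
    if not 1 <= w <= z_dim:
        raise ValueError(f"window_thickness must be in [1, Z={z_dim}], got {w}")
    if offset is None:
        offset = -w / 4.0
    ts = np.arange(t_dim)
    if start_override is not None:
        ideal = float(start_override) + model.displacement_value * ts
    else:
        ideal = np.array([surface_slice(model, t) + offset for t in ts])
    rounded = _round_half_away(ideal).astype(int)
    starts = np.clip(rounded, 0, z_dim - w)
    clamped = [int(t) for t in ts[rounded != starts]]
    return CropPlan(
        window_thickness=w,
        start_slices=[int(s) for s in starts],
        source_dims=tuple(stack.dims),
        clamped_timepoints=clamped,
    )


def _manifest_path(out: str) -> str:
    return out + ".manifest.json"


def apply_crop(stack: HyperStack, plan: CropPlan, out: str | os.PathLike) -> HyperStack:
    """Execute the floating-window crop, writing the reduced stack to *out*.

    Each timepoint is extracted in turn and staged as a temporary TIFF next
    to *out* before the final OME-TIFF is assembled with the source
    calibration and channel colors; pixels inside the window are copied
    bit-exactly.  A JSON manifest tracks completed timepoints, so a run
    interrupted mid-way resumes where it stopped instead of leaving a
    corrupt output; temporary files are removed on success.  The returned
    stack is opened lazily from *out*.
    """
    if tuple(plan.source_dims) != tuple(stack.dims):
        raise ValueError(f"plan source dims {plan.source_dims} != stack dims {stack.dims}")
    out = os.fspath(out)
    t_dim, c_dim, _, y_dim, x_dim = stack.dims
    w = plan.window_thickness
    tmp_dir = out + ".tmp"
    manifest_path = _manifest_path(out)

    done: set[int] = set()
    if os.path.exists(manifest_path) and os.path.isdir(tmp_dir):
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        if manifest.get("plan") == plan.to_dict():
            done = {int(t) for t in manifest.get("completed", [])}
        else:
            shutil.rmtree(tmp_dir, ignore_errors=True)
    os.makedirs(tmp_dir, exist_ok=True)

    def tmp_path(t: int) -> str:
        return os.path.join(tmp_dir, f"t{t:05d}.tif")

    for t in range(t_dim):
        if t in done and os.path.exists(tmp_path(t)):
            continue
        start = plan.start_slices[t]
        chunk = np.empty((c_dim, w, y_dim, x_dim), dtype=stack.dtype)
        for c in range(c_dim):
            for wi in range(w):
                chunk[c, wi] = stack.get_plane(t, c, start + wi)
        tifffile.imwrite(tmp_path(t), chunk, photometric="minisblack")
        done.add(t)
        with open(manifest_path, "w") as fh:
            json.dump({"plan": plan.to_dict(), "completed": sorted(done)}, fh)

    out_stack_meta = HyperStack(
        dims=(t_dim, c_dim, w, y_dim, x_dim),
        calibration=stack.calibration,
        channels=stack.channels,
        pixels=None,
        lazy=True,
        _backend=_TempChunkBackend(tmp_dir, (t_dim, c_dim, w, y_dim, x_dim)),
    )
    stack_io.write_hyperstack(out_stack_meta, out)
    out_stack_meta.close()
    shutil.rmtree(tmp_dir, ignore_errors=True)
    os.remove(manifest_path)
    return stack_io.read_hyperstack(out, lazy=True)


class _TempChunkBackend:
    """Plane access over the staged per-timepoint temp files."""

    def __init__(self, tmp_dir: str, dims: tuple[int, ...]):
        self._tmp_dir = tmp_dir
        self._dims = dims
        self._cache_t: int | None = None
        self._cache: np.ndarray | None = None

    def plane(self, t: int, c: int, z: int) -> np.ndarray:
        if self._cache_t != t:
            self._cache = tifffile.imread(os.path.join(self._tmp_dir, f"t{t:05d}.tif"))
            self._cache_t = t
        return self._cache[c, z]

    def close(self) -> None:
        self._cache = None
        self._cache_t = None


def reduction_report(plan: CropPlan, bytes_per_plane: int | None = None) -> dict:
    """Summarise how much the crop shrinks the data set.

    Returns input/output plane counts, the slice-reduction ratio Z/W, and —
    when ``bytes_per_plane`` is given — estimated byte sizes.
    """
    t_dim, c_dim, z_dim = plan.source_dims[0], plan.source_dims[1], plan.source_dims[2]
    w = plan.window_thickness
    report = {
        "input_planes": t_dim * c_dim * z_dim,
        "output_planes": t_dim * c_dim * w,
        "slice_ratio": z_dim / w,
        "window_thickness": w,
        "clamped_timepoints": len(plan.clamped_timepoints),
    }
    if bytes_per_plane is not None:
        report["input_bytes"] = report["input_planes"] * int(bytes_per_plane)
        report["output_bytes"] = report["output_planes"] * int(bytes_per_plane)
    return report
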