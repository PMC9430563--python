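"""Fluorescent focus (spot) detection and height-above-surface analysis.

Labelled subpopulations inside a colony show up as bright foci in their
reporter channel.  Spots are detected as 3-D local intensity maxima
(26-connectivity) above a minimum intensity, thinned so that no two spots
lie closer than a minimum separation measured in μm — the exclusion
distance is anisotropy-aware, since Z-steps of 1-3 μm dwarf sub-μm XY
pixels.  Each spot's height is its distance above the drift-model surface
prediction, so stratified subpopulations (matrix producers riding high on
the colony, motile cells hugging the agar) separate into distinct height
bands over time.

Spot tables and height series are plain :class:`pandas.DataFrame` objects,
directly exportable to CSV for spreadsheet or stats tools.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter

from .drift import DriftModel, surface_slice
from .stack_io import Calibration, HyperStack, UncalibratedError

__all__ = ["detect_spots", "spot_heights"]

#: Columns of a spot table.
SPOT_COLUMNS = ["timepoint", "channel", "z", "y", "x", "intensity"]


def detect_spots(
    stack: HyperStack,
    t: int,
    channel: int,
    min_intensity: float,
    min_separation: float,
) -> pd.DataFrame:
    """Detect fluorescent foci in one (timepoint, channel) volume.

    Candidates are voxels at least as bright as all 26 neighbours and with
    intensity ≥ ``min_intensity``.  Among candidates closer than
    ``min_separation`` μm (Euclidean distance using the real voxel
    anisotropy), the brighter survives; exact intensity ties go to the
    lexicographically lower (z, y, x).  An empty table is a valid result.
    """
    if stack.calibration.uncalibrated:
        raise UncalibratedError("spot separation in μm needs a calibrated stack")
    if min_separation < 0:
        raise ValueError("min_separation must be >= 0")
    z_dim = stack.dims[2]
    vol = np.stack([stack.get_plane(t, channel, z) for z in range(z_dim)]).astype(np.float64)

    local_max = vol == maximum_filter(vol, size=3, mode="constant", cval=-np.inf)
    candidates = np.argwhere(local_max & (vol >= float(min_intensity)))
    if candidates.size == 0:
        return pd.DataFrame(columns=SPOT_COLUMNS)

    cal = stack.calibration
    scale = np.array([cal.z_step, cal.pixel_size_xy, cal.pixel_size_xy])
    intensities = vol[tuple(candidates.T)]
    # brightest first; (z, y, x) ascending breaks exact ties deterministically
    order = np.lexsort((candidates[:, 2], candidates[:, 1], candidates[:, 0], -intensities))
    candidates = candidates[order]
    intensities = intensities[order]

    kept_um: list[np.ndarray] = []
    kept_idx: list[int] = []
    min_sep2 = float(min_separation) ** 2
    for i, coord in enumerate(candidates):
        um = coord * scale
        if all(np.sum((um - k) ** 2) >= min_sep2 for k in kept_um):
            kept_um.append(um)
            kept_idx.append(i)

    kept = candidates[kept_idx]
    return pd.DataFrame(
        {
            "timepoint": int(t),
            "channel": int(channel),
            "z": kept[:, 0],
            "y": kept[:, 1],
            "x": kept[:, 2],
            "intensity": intensities[kept_idx],
        }
    )[SPOT_COLUMNS]


def spot_heights(spots: pd.DataFrame, model: DriftModel, cal: Calibration) -> pd.DataFrame:
    """Aggregate spot heights above the agar surface per (timepoint, channel).

    Height is ``(z_spot − surface_slice(model, t)) × z_step`` in μm; the
    surface reference is the drift-model prediction, not a per-timepoint
    re-detection, so it stays stable even when colony fluorescence swamps
    the surface signal.  Negative heights (spots below the fitted surface)
    are legitimate and counted in ``n_below_surface``.

    Returns one row per (timepoint, channel) with mean_height_um, sd_um
    (sample SD, NaN for a single spot), n_spots, and n_below_surface.
    """
    if spots.empty:
        return pd.DataFrame(
            columns=["timepoint", "channel", "mean_height_um", "sd_um", "n_spots", "n_below_surface"]
        )
    df = spots.copy()
    df["height_um"] = (
        df["z"].astype(float) - df["timepoint"].map(lambda t: surface_slice(model, t))
    ) * cal.z_step
    grouped = df.groupby(["timepoint", "channel"])["height_um"]
    out = grouped.agg(
        mean_height_um="mean",
        sd_um=lambda h: h.std(ddof=1),
        n_spots="size",
        n_below_surface=lambda h: int((h < 0).sum()),
    ).reset_index()
    return out
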