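"""Mean intensity by channel, Z-position, and time.

The axial intensity profile is the evidence from which the agar surface is
tracked: the bright agar/colony layer shows up as a peak in mean plane
intensity, and the peak's drift down the stack over time is the surface
descent.  Profiles also let a user pick sensible reference timepoints and
channels before committing to a crop.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stack_io import Calibration, HyperStack

__all__ = ["IntensityProfile", "compute_profile", "plot_profile"]


@dataclass
class IntensityProfile:
    """Mean plane intensity indexed [t, c, z]; unselected entries are NaN."""

    values: np.ndarray  # float64 (T, C, Z), NaN where not computed
    dims: tuple[int, int, int]
    source_calibration: Calibration

    def __post_init__(self) -> None:
        if tuple(self.values.shape) != tuple(self.dims):
            raise ValueError(f"values shape {self.values.shape} != dims {self.dims}")

    def is_present(self, t: int, c: int) -> bool:
        return bool(np.all(np.isfinite(self.values[t, c])))

    def to_frame(self) -> pd.DataFrame:
        """Long-form table (t, c, z, mean_intensity); absent entries omitted."""
        t, c, z = self.dims
        ti, ci, zi = np.meshgrid(np.arange(t), np.arange(c), np.arange(z), indexing="ij")
        df = pd.DataFrame(
            {
                "t": ti.ravel(),
                "c": ci.ravel(),
                "z": zi.ravel(),
                "mean_intensity": self.values.ravel(),
            }
        )
        return df[np.isfinite(df["mean_intensity"])].reset_index(drop=True)


def compute_profile(
    stack: HyperStack,
    timepoints: list[int] | None = None,
    channels: list[int] | None = None,
) -> IntensityProfile:
    """Mean (Y, X)-plane intensity for each requested (t, c, z).

    Means are accumulated in double precision regardless of pixel depth, so
    8-bit planes cannot overflow.  Entries outside the requested timepoint
    and channel selection are NaN (absent), never zero.
    """
    t, c, z, _, _ = stack.dims
    ts = list(range(t)) if timepoints is None else sorted(set(int(i) for i in timepoints))
    cs = list(range(c)) if channels is None else sorted(set(int(i) for i in channels))
    if not ts or not cs:
        raise ValueError("empty timepoint or channel selection")
    for i in ts:
        if not 0 <= i < t:
            raise IndexError(f"timepoint {i} out of range for T={t}")
    for i in cs:
        if not 0 <= i < c:
            raise IndexError(f"channel {i} out of range for C={c}")

    values = np.full((t, c, z), np.nan)
    if stack.pixels is not None and timepoints is None and channels is None:
        values[:] = stack.pixels.mean(axis=(3, 4), dtype=np.float64)
    else:
        for ti in ts:
            for ci in cs:
                for zi in range(z):
                    values[ti, ci, zi] = stack.get_plane(ti, ci, zi).mean(dtype=np.float64)
    return IntensityProfile(values=values, dims=(t, c, z), source_calibration=stack.calibration)


def plot_profile(profile: IntensityProfile, out: str | os.PathLike) -> tuple[str, str]:
    """Write an intensity-vs-Z plot (one curve per (t, c)) plus a CSV table.

    Returns ``(plot_path, table_path)``; the table is *out* with a ``.csv``
    suffix and re-parses to the profile values exactly.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = profile.to_frame()
    if df.empty:
        raise ValueError("profile has no present entries")
    out = os.fspath(out)
    table_path = os.path.splitext(out)[0] + ".csv"
    df.to_csv(table_path, index=False, float_format="%.12g")

    fig, ax = plt.subplots(figsize=(7, 4.5))
    nt = df["t"].nunique()
    for (ti, ci), grp in df.groupby(["t", "c"]):
        alpha = 0.25 + 0.75 * (ti + 1) / nt
        ax.plot(grp["z"], grp["mean_intensity"], color=f"C{ci % 10}", alpha=alpha, lw=1)
    ax.set_xlabel("Z slice (0 = nearest objective)")
    ax.set_ylabel("mean intensity")
    ax.set_title("Axial intensity profile by channel and time")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out, table_path
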