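"""Synthetic time-lapse generator with exported ground truth.

Real multi-day acquisitions of colonies on agar are tens of gigabytes and
not practical to ship; this module generates small hyperstacks that carry
the statistical structure the processing pipeline assumes, together with
the exact ground truth used to build them, so every stage (drift
estimation, cropping, front tracking, spot detection) can be tested for
*recovery* of known quantities.

The scene model is deliberately minimal:

* a flat bright **agar surface** slab whose axial position descends
  linearly, ``z_um(t) = surface_z0 − descent_rate · hours(t)`` — positive
  rates move the surface toward the objective (decreasing Z index), the
  way evaporating/consumed medium behaves on an inverted microscope;
* one or more **colonies**: discs of radius ``r0 + v·hours(t)`` attached to
  the surface, rendered either as a solid pancake of configurable thickness
  (for front tracking) or as discrete Gaussian foci at normally distributed
  heights above the surface (for subpopulation analysis);
* a uniform **background** level plus additive Gaussian noise, clipped to
  the pixel range.

Sub-slice surface positions are rendered by intensity-weighted splitting
of the slab across the overlapping slices, so drift can be exercised at
non-integer per-timepoint shifts (e.g. 0.625 slices/timepoint).  A given
seed reproduces the stack bit-for-bit.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stack_io import Calibration, ChannelMeta, HyperStack, write_hyperstack

__all__ = ["ColonySpec", "SynthConfig", "GroundTruth", "generate", "write_fixture_suite"]


@dataclass(frozen=True)
class ColonySpec:
    """One expanding colony disc.

    ``mean_height_um`` is the height of the labelled cells above the agar
    surface; in solid mode the colony is a pancake spanning
    ``[0, mean_height_um]`` above the surface, in spot mode discrete foci
    are planted at heights ~ N(mean_height_um, height_sd_um).
    """

    center_um: tuple[float, float]  # (y, x) μm
    initial_radius_um: float
    expansion_rate_um_per_h: float
    channel: int
    brightness: float = 150.0
    mean_height_um: float = 4.0
    height_sd_um: float = 0.0
    solid: bool = True
    spot_density_per_um2: float = 0.0  # spot mode: expected spots per μm² of disc
    spot_min_spacing_um: float = 0.0  # spot mode: enforced minimum spacing

    def radius_at(self, hours: float) -> float:
        return max(0.0, self.initial_radius_um + self.expansion_rate_um_per_h * hours)


@dataclass(frozen=True)
class SynthConfig:
    """Full scene description; the seed determines the stack bit-for-bit."""

    dims: tuple[int, int, int, int, int]  # (T, C, Z, Y, X)
    calibration: Calibration
    descent_rate_um_per_h: float = 2.5
    surface_z0_um: float | None = None  # default: 3/4 of the volume depth
    surface_brightness: float = 120.0
    surface_thickness_um: float = 4.0
    surface_channel: int = 0
    colonies: tuple[ColonySpec, ...] = ()
    background: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0
    channels: tuple[ChannelMeta, ...] | None = None

    @property
    def surface_z0(self) -> float:
        if self.surface_z0_um is not None:
            return self.surface_z0_um
        return 0.75 * self.dims[2] * self.calibration.z_step

    def surface_um(self, t: int) -> float:
        hours = t * self.calibration.time_interval / 60.0
        return self.surface_z0 - self.descent_rate_um_per_h * hours

    def surface_slice(self, t: int) -> float:
        return self.surface_um(t) / self.calibration.z_step


@dataclass
class GroundTruth:
    """What the generator actually drew — the recovery-test oracle."""

    surface_slice: np.ndarray  # (T,) real slice index
    surface_um: np.ndarray  # (T,) μm
    descent_rate_um_per_h: float
    displacement_slices_per_timepoint: float  # signed slope of surface_slice
    colony_radius_um: np.ndarray  # (T, n_colonies)
    front_position_um: np.ndarray  # (T, n_colonies), along +x
    spots: pd.DataFrame  # per planted focus: timepoint, colony, channel, z,y,x (px), height_um
    config: SynthConfig = field(repr=False, default=None)

    def to_json(self, path: str | os.PathLike) -> str:
        path = os.fspath(path)
        payload = {
            "surface_slice": self.surface_slice.tolist(),
            "surface_um": self.surface_um.tolist(),
            "descent_rate_um_per_h": self.descent_rate_um_per_h,
            "displacement_slices_per_timepoint": self.displacement_slices_per_timepoint,
            "colony_radius_um": self.colony_radius_um.tolist(),
            "front_position_um": self.front_position_um.tolist(),
            "spots": self.spots.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return path


_SPOT_COLUMNS = ["timepoint", "colony", "channel", "z", "y", "x", "height_um"]


def _slab_weights(z_centers_lo: np.ndarray, z_step: float, lo_um: float, hi_um: float) -> np.ndarray:
    """Fractional overlap of each slice's μm interval with [lo_um, hi_um]."""
    slice_lo = z_centers_lo
    slice_hi = z_centers_lo + z_step
    overlap = np.minimum(slice_hi, hi_um) - np.maximum(slice_lo, lo_um)
    return np.clip(overlap / z_step, 0.0, 1.0)


def _sample_disc_points(
    rng: np.random.Generator,
    n: int,
    center: tuple[float, float],
    radius: float,
    min_spacing: float,
    bounds_um: tuple[float, float],
    margin_um: float,
) -> np.ndarray:
    """Uniform points in a disc (μm), within the field, optionally spaced.

    Points falling outside the imaged field (minus a rendering margin) are
    rejected so the exported ground truth lists only foci that are actually
    drawn in the stack.
    """
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n and tries < 200 * max(n, 1):
        tries += 1
        r = radius * np.sqrt(rng.uniform())
        theta = rng.uniform(0, 2 * np.pi)
        p = np.array([center[0] + r * np.sin(theta), center[1] + r * np.cos(theta)])
        if not (margin_um <= p[0] <= bounds_um[0] - margin_um and margin_um <= p[1] <= bounds_um[1] - margin_um):
            continue
        if min_spacing > 0 and any(np.hypot(*(p - q)) < min_spacing for q in pts):
            continue
        pts.append(p)
    return np.array(pts) if pts else np.empty((0, 2))


def generate(config: SynthConfig) -> tuple[HyperStack, GroundTruth]:
    """Render the configured scene into a hyperstack plus its ground truth.

    Raises if the surface would leave the acquired volume at any timepoint,
    naming the first offending timepoint.
    """
    t_dim, c_dim, z_dim, y_dim, x_dim = config.dims
    cal = config.calibration
    z_step, px = cal.z_step, cal.pixel_size_xy

    for t in range(t_dim):
        s = config.surface_um(t)
        if not 0.0 <= s <= z_dim * z_step:
            raise ValueError(
                f"surface leaves the volume at timepoint {t}: {s:.2f} μm "
                f"outside [0, {z_dim * z_step:.2f}]"
            )
    for col in config.colonies:
        if not 0 <= col.channel < c_dim:
            raise ValueError(f"colony channel {col.channel} out of range for C={c_dim}")
    if not 0 <= config.surface_channel < c_dim:
        raise ValueError(f"surface_channel {config.surface_channel} out of range for C={c_dim}")

    rng = np.random.default_rng(config.seed)
    vol = np.full(config.dims, float(config.background))

    # slice i is a sample plane at depth i·z_step; its integration window is
    # [i−1/2, i+1/2]·z_step, so a surface at fractional slice position s puts
    # the intensity maximum at the nearest integer slice
    z_lo = (np.arange(z_dim) - 0.5) * z_step
    yy, xx = np.meshgrid(np.arange(y_dim) * px, np.arange(x_dim) * px, indexing="ij")

    hours = np.arange(t_dim) * cal.time_interval / 60.0
    surface_um = config.surface_z0 - config.descent_rate_um_per_h * hours
    n_col = len(config.colonies)
    radius = np.zeros((t_dim, n_col))
    front = np.zeros((t_dim, n_col))
    spot_rows: list[dict] = []

    for t in range(t_dim):
        s_um = surface_um[t]
        # agar surface slab, split across slices by fractional overlap
        w = _slab_weights(z_lo, z_step, s_um - config.surface_thickness_um / 2, s_um + config.surface_thickness_um / 2)
        vol[t, config.surface_channel] += config.surface_brightness * w[:, None, None]

        for ci, col in enumerate(config.colonies):
            r = col.radius_at(hours[t])
            radius[t, ci] = r
            front[t, ci] = col.center_um[1] + r
            if r <= 0:
                continue
            disc = (yy - col.center_um[0]) ** 2 + (xx - col.center_um[1]) ** 2 <= r**2
            if col.solid:
                wz = _slab_weights(z_lo, z_step, s_um, s_um + col.mean_height_um)
                vol[t, col.channel] += col.brightness * wz[:, None, None] * disc[None, :, :]
            else:
                n_spots = int(round(col.spot_density_per_um2 * np.pi * r**2))
                pts = _sample_disc_points(
                    rng,
                    n_spots,
                    col.center_um,
                    r,
                    col.spot_min_spacing_um,
                    bounds_um=((y_dim - 1) * px, (x_dim - 1) * px),
                    margin_um=3 * px,
                )
                for py_um, px_um in pts:
                    h = col.mean_height_um + col.height_sd_um * rng.standard_normal()
                    h = max(0.0, h)
                    zi = (s_um + h) / z_step
                    yi, xi = py_um / px, px_um / px
                    _render_focus(vol[t, col.channel], col.brightness, zi, yi, xi)
                    spot_rows.append(
                        {
                            "timepoint": t,
                            "colony": ci,
                            "channel": col.channel,
                            "z": int(round(zi)),
                            "y": int(round(yi)),
                            "x": int(round(xi)),
                            "height_um": h,
                        }
                    )

    if config.noise_sd > 0:
        vol += rng.normal(0.0, config.noise_sd, size=vol.shape)

    pixels = np.clip(np.rint(vol), 0, 255).astype(np.uint8)
    if config.channels is not None:
        channels = list(config.channels)
    else:
        channels = [ChannelMeta(name=f"C{i}") for i in range(c_dim)]
    stack = HyperStack(dims=config.dims, calibration=cal, channels=channels, pixels=pixels)

    dv = -config.descent_rate_um_per_h * (cal.time_interval / 60.0) / z_step
    truth = GroundTruth(
        surface_slice=surface_um / z_step,
        surface_um=surface_um,
        descent_rate_um_per_h=config.descent_rate_um_per_h,
        displacement_slices_per_timepoint=dv,
        colony_radius_um=radius,
        front_position_um=front,
        spots=pd.DataFrame(spot_rows, columns=_SPOT_COLUMNS),
        config=config,
    )
    return stack, truth


def _render_focus(channel_vol: np.ndarray, amplitude: float, zi: float, yi: float, xi: float) -> None:
    """Add a small 3-D Gaussian focus centred at voxel coords (zi, yi, xi)."""
    z_dim, y_dim, x_dim = channel_vol.shape
    sz, sxy = 0.6, 0.8  # voxel-space widths: foci are ~cell-sized, under-sampled in Z
    z0, z1 = max(0, int(zi) - 2), min(z_dim, int(zi) + 3)
    y0, y1 = max(0, int(yi) - 3), min(y_dim, int(yi) + 4)
    x0, x1 = max(0, int(xi) - 3), min(x_dim, int(xi) + 4)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    zz, yy, xx = np.meshgrid(np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij")
    g = np.exp(
        -((zz - zi) ** 2 / (2 * sz**2) + (yy - yi) ** 2 / (2 * sxy**2) + (xx - xi) ** 2 / (2 * sxy**2))
    )
    channel_vol[z0:z1, y0:y1, x0:x1] += amplitude * g


# ---------------------------------------------------------------------------
# Canonical fixture scenes
#
# The defaults mirror the imaging conditions the pipeline targets: 2 μm
# Z-step, 30-minute frames, a surface descending at 2.5 μm/h, colony fronts
# advancing at tens of μm/h, and two height-stratified subpopulations
# (upper ~6 μm, lower ~1 μm above the surface).


def drift_only_config(
    t_dim: int = 25,
    z_dim: int = 40,
    noise_sd: float = 0.0,
    seed: int = 0,
    descent_rate_um_per_h: float = 2.5,
) -> SynthConfig:
    """Bare descending-surface scene (no colonies) for drift recovery.

    The surface starts high enough to stay inside the volume for the whole
    run: z0 = total descent + 3 Z-steps of headroom above the floor.
    """
    cal = Calibration(pixel_size_xy=1.0, z_step=2.0, time_interval=30.0)
    total_descent = descent_rate_um_per_h * (t_dim - 1) * cal.time_interval / 60.0
    z0 = total_descent + 3 * cal.z_step
    if z0 + 2 * cal.z_step > z_dim * cal.z_step:
        raise ValueError(
            f"z_dim={z_dim} too shallow for {total_descent:.0f} μm of descent; "
            f"need at least {int(np.ceil(z0 / cal.z_step)) + 2} slices"
        )
    return SynthConfig(
        dims=(t_dim, 1, z_dim, 16, 16),
        calibration=cal,
        descent_rate_um_per_h=descent_rate_um_per_h,
        surface_z0_um=z0,
        noise_sd=noise_sd,
        seed=seed,
    )


def two_colony_config(seed: int = 0, noise_sd: float = 0.0) -> SynthConfig:
    """Two colonies approaching head-on, distinct channels, for front analytics."""
    cal = Calibration(pixel_size_xy=2.0, z_step=2.0, time_interval=30.0)
    return SynthConfig(
        dims=(13, 3, 24, 64, 128),
        calibration=cal,
        descent_rate_um_per_h=2.5,
        surface_channel=2,
        colonies=(
            ColonySpec(center_um=(64.0, 30.0), initial_radius_um=20.0, expansion_rate_um_per_h=10.0, channel=0),
            ColonySpec(center_um=(64.0, 226.0), initial_radius_um=30.0, expansion_rate_um_per_h=-4.0, channel=1),
        ),
        noise_sd=noise_sd,
        seed=seed,
        channels=(
            ChannelMeta("cfp", (0, 255, 255)),
            ChannelMeta("gfp", (0, 255, 0)),
            ChannelMeta("trans", (255, 255, 255), "transmitted"),
        ),
    )


def two_population_config(seed: int = 0, noise_sd: float = 2.0) -> SynthConfig:
    """One colony footprint carrying two spot populations at 6 μm and 1 μm."""
    cal = Calibration(pixel_size_xy=1.0, z_step=2.0, time_interval=30.0)
    common = dict(
        center_um=(32.0, 32.0),
        initial_radius_um=18.0,
        expansion_rate_um_per_h=6.0,
        solid=False,
        spot_density_per_um2=0.008,
        spot_min_spacing_um=8.0,
        brightness=200.0,
    )
    return SynthConfig(
        dims=(9, 3, 24, 64, 64),
        calibration=cal,
        descent_rate_um_per_h=2.5,
        surface_channel=2,
        surface_z0_um=36.0,
        colonies=(
            ColonySpec(channel=0, mean_height_um=6.0, height_sd_um=0.5, **common),
            ColonySpec(channel=1, mean_height_um=1.0, height_sd_um=0.5, **common),
        ),
        noise_sd=noise_sd,
        seed=seed,
        channels=(
            ChannelMeta("matrix", (255, 0, 0)),
            ChannelMeta("motile", (255, 255, 0)),
            ChannelMeta("trans", (255, 255, 255), "transmitted"),
        ),
    )


def write_fixture_suite(out_dir: str | os.PathLike, seed: int = 0) -> dict[str, dict[str, str]]:
    """Write the canonical small fixtures (stack + ground-truth JSON each).

    Emits three named scenes — ``drift_only``, ``two_colony``,
    ``two_population`` — and returns {name: {"stack": path, "truth": path}}.
    Re-running with the same seed reproduces byte-identical TIFFs.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    configs = {
        "drift_only": drift_only_config(seed=seed),
        "two_colony": two_colony_config(seed=seed),
        "two_population": two_population_config(seed=seed),
    }
    written: dict[str, dict[str, str]] = {}
    for name, cfg in configs.items():
        stack, truth = generate(cfg)
        stack_path = os.path.join(out_dir, f"{name}.ome.tif")
        truth_path = os.path.join(out_dir, f"{name}.truth.json")
        write_hyperstack(stack, stack_path)
        truth.to_json(truth_path)
        written[name] = {"stack": stack_path, "truth": truth_path}
    return written
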