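"""Calibrated 5-D hyperstack I/O.

Every downstream stage operates on one data model: a :class:`HyperStack`
holding a (T, C, Z, Y, X) intensity array together with its spatial/temporal
calibration and per-channel metadata.  Stacks are stored on disk as OME-TIFF
(readable by FIJI, Imaris, BiofilmQ etc.); ImageJ-style and plain TIFFs are
accepted on read.

Axis conventions
----------------
Canonical in-memory order is always ``(T, C, Z, Y, X)``; files written in
other orders are permuted on read.  All indices are 0-based.  Z index 0 is
the slice nearest the objective — for an inverted microscope imaging through
the agar this is the bottom of the dish, so the agar surface and colony lie
at *increasing* Z.
"""

from __future__ import annotations

import os
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = [
    "Calibration",
    "ChannelMeta",
    "HyperStack",
    "read_hyperstack",
    "write_hyperstack",
    "get_plane",
    "AxisOrderError",
    "UncalibratedError",
]

_CANONICAL_AXES = "TCZYX"


class AxisOrderError(ValueError):
    """File axes cannot be unambiguously mapped onto (T, C, Z, Y, X)."""


class UncalibratedError(ValueError):
    """Operation requires real-world calibration but the stack has none."""


@dataclass(frozen=True)
class Calibration:
    """Spatial and temporal calibration of a hyperstack.

    Parameters
    ----------
    pixel_size_xy : float
        Lateral pixel size in μm/pixel.  Must be > 0.
    z_step : float
        Axial spacing in μm/slice.  Must be > 0.
    time_interval : float
        Minutes between consecutive timepoints.  Must be > 0.
    time_origin : float
        Hours of incubation before the first frame (≥ 0); lets exported
        tables report absolute colony age.
    uncalibrated : bool
        True when the file carried no calibration and unit defaults were
        substituted.  Real-world conversions raise on such stacks.
    """

    pixel_size_xy: float
    z_step: float
    time_interval: float
    time_origin: float = 0.0
    uncalibrated: bool = False

    def __post_init__(self) -> None:
        for name in ("pixel_size_xy", "z_step", "time_interval"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if self.time_origin < 0:
            raise ValueError(f"time_origin must be >= 0, got {self.time_origin!r}")

    def slice_to_um(self, z: float) -> float:
        """Axial position in μm of (fractional) slice index *z*."""
        return z * self.z_step

    def um_to_slice(self, um: float) -> float:
        return um / self.z_step

    def timepoint_to_hours(self, t: float) -> float:
        """Absolute time in hours of (fractional) timepoint index *t*."""
        return self.time_origin + t * self.time_interval / 60.0


#: Calibration substituted for files carrying no metadata (1 μm pixels and
#: slices, 1 min frames), flagged so real-world conversions refuse it.
DEFAULT_UNCALIBRATED = Calibration(1.0, 1.0, 1.0, 0.0, uncalibrated=True)


@dataclass(frozen=True)
class ChannelMeta:
    """Display/semantic metadata for one channel."""

    name: str
    color: tuple[int, int, int] = (255, 255, 255)
    kind: str = "fluorescence"  # or "transmitted"

    def __post_init__(self) -> None:
        if self.kind not in ("fluorescence", "transmitted"):
            raise ValueError(f"kind must be 'fluorescence' or 'transmitted', got {self.kind!r}")
        if len(self.color) != 3 or any(not 0 <= int(v) <= 255 for v in self.color):
            raise ValueError(f"color must be an RGB triple in 0-255, got {self.color!r}")


def _default_channels(c: int) -> list[ChannelMeta]:
    return [ChannelMeta(name=f"C{i}") for i in range(c)]


class _LazyTiffPixels:
    """Plane-on-demand backend: maps (t, c, z) to a TIFF page and reads it.

    Keeps the :class:`tifffile.TiffFile` open between calls so repeated plane
    access never re-parses the file, and never materialises more than one
    plane at a time.
    """

    def __init__(self, path: str, axes: str, shape: tuple[int, ...]):
        self._path = path
        self._tif: tifffile.TiffFile | None = None
        # strides over the non-spatial axes, in file page order
        order = [a for a in axes if a not in "YX"]
        sizes = [shape[axes.index(a)] for a in order]
        strides: dict[str, int] = {}
        stride = 1
        for a, n in zip(reversed(order), reversed(sizes)):
            strides[a] = stride
            stride *= n
        self._strides = strides

    def _file(self) -> tifffile.TiffFile:
        if self._tif is None:
            self._tif = tifffile.TiffFile(self._path)
        return self._tif

    def page_index(self, t: int, c: int, z: int) -> int:
        idx = 0
        for a, i in (("T", t), ("C", c), ("Z", z)):
            idx += i * self._strides.get(a, 0)
        return idx

    def plane(self, t: int, c: int, z: int) -> np.ndarray:
        series = self._file().series[0]
        return np.asarray(series.pages[self.page_index(t, c, z)].asarray())

    def close(self) -> None:
        if self._tif is not None:
            self._tif.close()
            self._tif = None


@dataclass
class HyperStack:
    """A calibrated 5-D (T, C, Z, Y, X) intensity stack.

    ``pixels`` is the eager array; for lazily opened stacks it is ``None``
    and planes are fetched from disk on demand via :meth:`get_plane`.
    """

    dims: tuple[int, int, int, int, int]
    calibration: Calibration
    channels: list[ChannelMeta]
    pixels: np.ndarray | None = None
    lazy: bool = False
    _backend: _LazyTiffPixels | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        t, c, z, y, x = self.dims
        if any(int(d) < 1 for d in self.dims):
            raise ValueError(f"all dims must be >= 1, got {self.dims}")
        if len(self.channels) != c:
            raise ValueError(f"len(channels)={len(self.channels)} != C={c}")
        names = [ch.name for ch in self.channels]
        if len(set(names)) != len(names):
            raise ValueError(f"channel names must be unique, got {names}")
        if self.pixels is not None:
            if tuple(self.pixels.shape) != tuple(self.dims):
                raise ValueError(f"pixels shape {self.pixels.shape} != dims {self.dims}")
            if self.pixels.dtype not in (np.uint8, np.uint16):
                raise ValueError(f"pixels must be uint8 or uint16, got {self.pixels.dtype}")
        elif self._backend is None:
            raise ValueError("HyperStack needs either pixels or a lazy backend")

    @classmethod
    def from_array(
        cls,
        pixels: np.ndarray,
        calibration: Calibration | None = None,
        channels: list[ChannelMeta] | None = None,
    ) -> "HyperStack":
        """Wrap a 5-D (T,C,Z,Y,X) array, filling in default metadata."""
        pixels = np.asarray(pixels)
        if pixels.ndim != 5:
            raise ValueError(f"expected a 5-D (T,C,Z,Y,X) array, got ndim={pixels.ndim}")
        dims = tuple(int(d) for d in pixels.shape)
        if calibration is None:
            calibration = DEFAULT_UNCALIBRATED
        if channels is None:
            channels = _default_channels(dims[1])
        return cls(dims=dims, calibration=calibration, channels=channels, pixels=pixels)

    @property
    def dtype(self) -> np.dtype:
        if self.pixels is not None:
            return self.pixels.dtype
        return self.get_plane(0, 0, 0).dtype

    def _check_index(self, t: int, c: int, z: int) -> None:
        for axis, i, n in (("T", t, self.dims[0]), ("C", c, self.dims[1]), ("Z", z, self.dims[2])):
            if not 0 <= int(i) < n:
                raise IndexError(f"index {i} out of range for axis {axis} (size {n})")

    def get_plane(self, t: int, c: int, z: int) -> np.ndarray:
        """Return the (Y, X) plane at (t, c, z), loading it on demand if lazy."""
        self._check_index(t, c, z)
        if self.pixels is not None:
            return self.pixels[t, c, z]
        assert self._backend is not None
        return self._backend.plane(int(t), int(c), int(z))

    def asarray(self) -> np.ndarray:
        """Materialise the full (T,C,Z,Y,X) array (loads everything if lazy)."""
        if self.pixels is not None:
            return self.pixels
        t, c, z, y, x = self.dims
        out = np.empty(self.dims, dtype=self.get_plane(0, 0, 0).dtype)
        for ti in range(t):
            for ci in range(c):
                for zi in range(z):
                    out[ti, ci, zi] = self.get_plane(ti, ci, zi)
        return out

    def close(self) -> None:
        if self._backend is not None:
            self._backend.close()

    def __enter__(self) -> "HyperStack":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


# ---------------------------------------------------------------------------
# OME metadata helpers

_OMENS = "{http://www.openmicroscopy.org/Schemas/OME/2016-06}"


def _rgb_to_ome_color(rgb: tuple[int, int, int]) -> int:
    r, g, b = (int(v) for v in rgb)
    value = (r << 24) | (g << 16) | (b << 8) | 255
    return value - (1 << 32) if value >= (1 << 31) else value


def _ome_color_to_rgb(value: int) -> tuple[int, int, int]:
    value = int(value) & 0xFFFFFFFF
    return ((value >> 24) & 255, (value >> 16) & 255, (value >> 8) & 255)


def _parse_ome(xml: str) -> tuple[Calibration | None, list[ChannelMeta] | None]:
    try:
        root = ET.fromstring(xml)
    except ET.ParseError:
        return None, None
    pixels = root.find(f"{_OMENS}Image/{_OMENS}Pixels")
    if pixels is None:
        return None, None
    cal = None
    px = pixels.get("PhysicalSizeX")
    zs = pixels.get("PhysicalSizeZ")
    ti = pixels.get("TimeIncrement")
    if px is not None and zs is not None and ti is not None:
        interval_min = float(ti)
        if pixels.get("TimeIncrementUnit", "s") == "s":
            interval_min /= 60.0
        desc = root.find(f"{_OMENS}Image/{_OMENS}Description")
        origin = 0.0
        if desc is not None and desc.text:
            for token in desc.text.split():
                if token.startswith("time_origin_h="):
                    origin = float(token.split("=", 1)[1])
        cal = Calibration(float(px), float(zs), interval_min, origin)
    channels = []
    for i, ch in enumerate(pixels.findall(f"{_OMENS}Channel")):
        name = ch.get("Name") or f"C{i}"
        color = ch.get("Color")
        rgb = _ome_color_to_rgb(int(color)) if color is not None else (255, 255, 255)
        kind = "transmitted" if ch.get("IlluminationType") == "Transmitted" else "fluorescence"
        channels.append(ChannelMeta(name=name, color=rgb, kind=kind))
    return cal, (channels or None)


def _parse_imagej(tif: tifffile.TiffFile) -> tuple[Calibration | None, list[ChannelMeta] | None]:
    meta = tif.imagej_metadata or {}
    page0 = tif.pages[0]
    pixel_size = None
    tag = page0.tags.get("XResolution")
    if tag is not None:
        num, den = tag.value
        if num:
            pixel_size = den / num
    z_step = meta.get("spacing")
    finterval = meta.get("finterval")  # seconds
    cal = None
    if pixel_size and z_step and finterval:
        cal = Calibration(float(pixel_size), float(z_step), float(finterval) / 60.0)
    channels = None
    luts = meta.get("LUTs")
    if luts:
        channels = [
            ChannelMeta(name=f"C{i}", color=tuple(int(v) for v in np.asarray(lut).reshape(3, -1)[:, -1]))
            for i, lut in enumerate(luts)
        ]
    return cal, channels


def _resolve_axes(axes: str, shape: tuple[int, ...]) -> tuple[str, tuple[int, ...]]:
    """Map a tifffile series axes string onto a subset of T,C,Z,Y,X.

    Singleton unknown axes are dropped; one non-singleton unknown axis (the
    anonymous stack dimension of metadata-free multi-page TIFFs) is read as
    Z; more than one is ambiguous and refused.
    """
    if "Y" not in axes or "X" not in axes:
        raise AxisOrderError(f"axis order unresolvable: no YX plane axes in {axes!r}")
    out_axes, out_shape, unknown = [], [], []
    for a, n in zip(axes, shape):
        if a in _CANONICAL_AXES:
            out_axes.append(a)
            out_shape.append(n)
        elif n == 1:
            continue
        else:
            unknown.append(a)
            out_axes.append("Z" if "Z" not in axes else a)
            out_shape.append(n)
    if len(unknown) > 1 or (unknown and "Z" in axes):
        raise AxisOrderError(
            f"axis order unresolvable: unknown non-singleton axes {unknown} in {axes!r}; "
            "write the file with explicit OME or ImageJ axis metadata"
        )
    return "".join(out_axes), tuple(out_shape)


def read_hyperstack(path: str | os.PathLike, lazy: bool = False) -> HyperStack:
    """Read a TIFF/OME-TIFF into a :class:`HyperStack`.

    Parameters
    ----------
    path : str
        TIFF whose axes resolve to a subset of (T, C, Z, Y, X); missing axes
        are imputed as size 1.
    lazy : bool
        When True, pixel planes are read from disk on demand instead of up
        front; peak memory is then one plane regardless of stack size.

    Raises
    ------
    AxisOrderError
        When the file's axis order cannot be resolved unambiguously.
    """
    path = os.fspath(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        axes, shape = _resolve_axes(series.axes, tuple(series.shape))
        cal = channels = None
        if tif.ome_metadata:
            cal, channels = _parse_ome(tif.ome_metadata)
        elif tif.is_imagej:
            cal, channels = _parse_imagej(tif)
    if cal is None:
        cal = DEFAULT_UNCALIBRATED
        warnings.warn(f"{path}: no calibration metadata; using 1 μm / 1 min unit defaults", stacklevel=2)

    sizes = dict(zip(axes, shape))
    dims = tuple(sizes.get(a, 1) for a in _CANONICAL_AXES)
    if channels is None:
        channels = _default_channels(dims[1])
    elif len(channels) != dims[1]:
        channels = _default_channels(dims[1])

    if lazy:
        backend = _LazyTiffPixels(path, axes, shape)
        return HyperStack(dims=dims, calibration=cal, channels=channels, lazy=True, _backend=backend)

    data = tifffile.imread(path)
    data = data.reshape(shape)
    # permute to canonical order, then insert missing axes as size 1
    present = [a for a in _CANONICAL_AXES if a in axes]
    data = np.transpose(data, [axes.index(a) for a in present])
    data = data.reshape(dims)
    if data.dtype not in (np.uint8, np.uint16):
        raise ValueError(f"{path}: unsupported pixel type {data.dtype} (need uint8/uint16)")
    return HyperStack(dims=dims, calibration=cal, channels=channels, pixels=data)


def _ome_metadata(stack: HyperStack) -> dict:
    import uuid

    cal = stack.calibration
    # deterministic UUID so identical stacks produce byte-identical files
    fingerprint = f"{stack.dims}|{cal}|{[ch.name for ch in stack.channels]}"
    file_uuid = uuid.uuid5(uuid.NAMESPACE_URL, "agardrift:" + fingerprint)
    meta: dict = {"axes": "TCZYX", "UUID": f"urn:uuid:{file_uuid}"}
    if not cal.uncalibrated:
        meta.update(
            PhysicalSizeX=cal.pixel_size_xy,
            PhysicalSizeXUnit="µm",
            PhysicalSizeY=cal.pixel_size_xy,
            PhysicalSizeYUnit="µm",
            PhysicalSizeZ=cal.z_step,
            PhysicalSizeZUnit="µm",
            TimeIncrement=cal.time_interval,
            TimeIncrementUnit="min",
            Description=f"time_origin_h={cal.time_origin}",
        )
    meta["Channel"] = {
        "Name": [ch.name for ch in stack.channels],
        "Color": [_rgb_to_ome_color(ch.color) for ch in stack.channels],
        "IlluminationType": [
            "Transmitted" if ch.kind == "transmitted" else "Epifluorescence" for ch in stack.channels
        ],
    }
    return meta


def write_hyperstack(stack: HyperStack, path: str | os.PathLike) -> str:
    """Write *stack* to *path* as OME-TIFF, preserving calibration and colors.

    Planes are streamed one at a time, so writing a lazy (disk-backed) stack
    never materialises more than a single timepoint; a partially written file
    is removed if the write fails.
    """
    path = os.fspath(path)
    t, c, z, y, x = stack.dims

    def plane_iter():
        for ti in range(t):
            for ci in range(c):
                for zi in range(z):
                    yield stack.get_plane(ti, ci, zi)

    try:
        tifffile.imwrite(
            path,
            plane_iter(),
            shape=stack.dims,
            dtype=stack.dtype,
            ome=True,
            photometric="minisblack",
            metadata=_ome_metadata(stack),
        )
    except BaseException:
        if os.path.exists(path):
            try:
                os.remove(path)
            except OSError:
                pass
        raise
    return path


def get_plane(stack: HyperStack, t: int, c: int, z: int) -> np.ndarray:
    """Functional alias for :meth:`HyperStack.get_plane`."""
    return stack.get_plane(t, c, z)
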