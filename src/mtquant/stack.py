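"""Calibrated n-dimensional image stacks and TIFF I/O.

An :class:`ImageStack` couples a non-negative intensity array with named axes
(a subset of ``t``, ``z``, ``y``, ``x``) and the physical calibration needed by
every downstream measurement: pixel size in µm, z-step in µm and frame
interval in seconds.  Calibration is never assumed: reading a TIFF without a
pixel size (from in-file metadata, a sidecar JSON, or an explicit override)
raises :class:`CalibrationError`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack", "CalibrationError", "read_stack", "write_stack"]

_VALID_AXES = ("t", "z", "y", "x")


class CalibrationError(ValueError):
    """Raised when physical calibration is missing or invalid."""


@dataclass
class ImageStack:
    """Fluorescence image stack with axis semantics and physical calibration.

    Parameters
    ----------
    pixels
        Non-negative intensity array; one dimension per character of ``axes``.
    axes
        Axis names in array order, e.g. ``"tzyx"`` or ``"yx"``.  Must be a
        subset of ``t``, ``z``, ``y``, ``x`` with no repeats, and must end in
        ``yx``.
    pixel_size_um
        Lateral pixel size (µm/px), identical for y and x.
    z_step_um
        Axial spacing (µm); required iff ``z`` is present.
    frame_interval_s
        Time between frames (s); required iff ``t`` is present.
    """

    pixels: np.ndarray
    axes: str
    pixel_size_um: float
    z_step_um: float | None = None
    frame_interval_s: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != len(self.axes):
            raise ValueError(
                f"axes {self.axes!r} do not match array of ndim {self.pixels.ndim}"
            )
        if len(set(self.axes)) != len(self.axes):
            raise ValueError(f"duplicate axis names in {self.axes!r}")
        for a in self.axes:
            if a not in _VALID_AXES:
                raise ValueError(f"unknown axis {a!r}; allowed: {_VALID_AXES}")
        if not self.axes.endswith("yx"):
            raise ValueError(f"axes must end in 'yx', got {self.axes!r}")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")
        if not (self.pixel_size_um and self.pixel_size_um > 0):
            raise CalibrationError("pixel_size_um must be > 0")
        if "z" in self.axes and not (self.z_step_um and self.z_step_um > 0):
            raise CalibrationError("z axis present but z_step_um missing or <= 0")
        if "t" in self.axes and not (
            self.frame_interval_s and self.frame_interval_s > 0
        ):
            raise CalibrationError("t axis present but frame_interval_s missing or <= 0")

    # -- convenience -------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    def axis_index(self, axis: str) -> int:
        if axis not in self.axes:
            raise ValueError(f"axis {axis!r} not present in {self.axes!r}")
        return self.axes.index(axis)

    def frame(self, **index: int) -> "ImageStack":
        """Slice out one plane along the given named axes (e.g. ``t=0, z=2``)."""
        sl: list[object] = [slice(None)] * self.pixels.ndim
        new_axes = self.axes
        for a, i in index.items():
            sl[self.axis_index(a)] = i
            new_axes = new_axes.replace(a, "")
        return replace(self, pixels=self.pixels[tuple(sl)], axes=new_axes)

    def copy(self) -> "ImageStack":
        return replace(self, pixels=self.pixels.copy())


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a multi-page TIFF plus a sidecar JSON carrying the calibration.

    Pixels round-trip exactly; calibration round-trips to 6 decimals.
    """
    path = Path(path)
    meta = {
        "axes": stack.axes,
        "pixel_size_um": round(float(stack.pixel_size_um), 6),
        "z_step_um": None if stack.z_step_um is None else round(float(stack.z_step_um), 6),
        "frame_interval_s": None
        if stack.frame_interval_s is None
        else round(float(stack.frame_interval_s), 6),
    }
    tifffile.imwrite(path, stack.pixels, metadata=meta, photometric="minisblack")
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_stack(
    path: str | Path,
    *,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
    frame_interval_s: float | None = None,
    axes: str | None = None,
) -> ImageStack:
    """Read a TIFF stack with calibration.

    Calibration precedence (highest first): explicit keyword overrides,
    sidecar JSON next to the file, in-file TIFF metadata.  A stack whose
    pixel size cannot be resolved from any source raises
    :class:`CalibrationError` rather than silently assuming 1 µm/px.
    """
    path = Path(path)
    pixels = tifffile.imread(path)

    meta: dict = {}
    # in-file metadata (lowest precedence)
    try:
        with tifffile.TiffFile(path) as tf:
            if tf.shaped_metadata:
                meta.update(tf.shaped_metadata[0])
            elif tf.imagej_metadata:
                meta.update(tf.imagej_metadata)
    except Exception:
        pass
    # sidecar overrides in-file values
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    # explicit overrides win over everything
    if pixel_size_um is not None:
        meta["pixel_size_um"] = pixel_size_um
    if z_step_um is not None:
        meta["z_step_um"] = z_step_um
    if frame_interval_s is not None:
        meta["frame_interval_s"] = frame_interval_s
    if axes is not None:
        meta["axes"] = axes

    resolved_axes = meta.get("axes")
    if resolved_axes is None:
        # fall back on dimensionality: yx, zyx, tzyx
        resolved_axes = {2: "yx", 3: "zyx", 4: "tzyx"}.get(pixels.ndim)
        if resolved_axes is None:
            raise ValueError(f"cannot infer axes for ndim {pixels.ndim}")

    if meta.get("pixel_size_um") is None:
        raise CalibrationError(
            f"{path}: no pixel size in file metadata, sidecar, or override"
        )
    return ImageStack(
        pixels=pixels,
        axes=resolved_axes,
        pixel_size_um=float(meta["pixel_size_um"]),
        z_step_um=None if meta.get("z_step_um") is None else float(meta["z_step_um"]),
        frame_interval_s=None
        if meta.get("frame_interval_s") is None
        else float(meta["frame_interval_s"]),
    )
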