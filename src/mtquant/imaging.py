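"""Projection, intensity normalization and filament segmentation.

The bundling and depolymerization measurements all start from the same three
steps: maximum-intensity projection of the z-stack, robust percentile
normalization to a dimensionless [0, 1] scale, and global thresholding into
8-connected regions of interest (ROIs), each a candidate filament or bundle.
Mean ROI intensity on the normalized scale is what the 0.4 bundling threshold
is applied to, so the normalization contract matters: it is a monotone affine
map of the [P_low, P_high] percentile window onto [0, 1] with clipping, which
makes every downstream statistic invariant to affine rescaling of the raw
intensities (gain/exposure changes).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .stack import ImageStack

__all__ = [
    "FilamentROI",
    "max_project",
    "robust_normalize",
    "pooled_percentile_scale",
    "segment_filaments",
    "rois_to_dataframe",
]


@dataclass(frozen=True)
class FilamentROI:
    """One 8-connected segmented region.

    ``mean_intensity`` is measured on the normalized image, hence
    dimensionless in [0, 1]. ``coords`` are (row=y, col=x) pixel indices.
    """

    roi_id: int
    coords: np.ndarray  # (n, 2) int array of (y, x)
    area_px: int
    mean_intensity: float
    centroid_yx_px: tuple[float, float]

    def centroid_um(self, pixel_size_um: float) -> tuple[float, float]:
        """Physical centroid (x_um, y_um); pixel centers at (index + 0.5)·px."""
        cy, cx = self.centroid_yx_px
        return ((cx + 0.5) * pixel_size_um, (cy + 0.5) * pixel_size_um)


def max_project(stack: ImageStack, axis: str = "z") -> ImageStack:
    """Maximum-intensity projection along a named axis (axis is removed)."""
    idx = stack.axis_index(axis)
    pixels = stack.pixels.max(axis=idx)
    new = replace(stack, pixels=pixels, axes=stack.axes.replace(axis, ""))
    if axis == "z":
        new.z_step_um = None
    if axis == "t":
        new.frame_interval_s = None
    return new


def robust_normalize(
    image: np.ndarray,
    low_pct: float = 0.5,
    high_pct: float = 99.9,
    scale: tuple[float, float] | None = None,
) -> np.ndarray:
    """Clip-scale an image to [0, 1] between two intensity percentiles.

    Values below the ``low_pct`` percentile map to 0, above ``high_pct`` to 1,
    linearly in between.  A constant image maps to all zeros (degenerate
    contract: there is no contrast to scale).

    When comparing conditions acquired under identical settings, pass a
    shared ``scale=(lo, hi)`` (e.g. from :func:`pooled_percentile_scale` over
    all images of the experiment) so that "relative intensity units" — and
    any absolute threshold applied to them, such as the 0.4 bundling
    cutoff — mean the same thing in every image.
    """
    if high_pct <= low_pct:
        raise ValueError("high_pct must exceed low_pct")
    image = np.asarray(image, dtype=float)
    lo, hi = (
        scale if scale is not None else np.percentile(image, [low_pct, high_pct])
    )
    if hi <= lo:
        return np.zeros_like(image)
    return np.clip((image - lo) / (hi - lo), 0.0, 1.0)


def pooled_percentile_scale(
    images: list[np.ndarray], low_pct: float = 0.5, high_pct: float = 99.9
) -> tuple[float, float]:
    """Normalization bounds from the pooled pixels of many images.

    Use one shared scale for every image of an experiment acquired under
    identical settings, so mean-intensity thresholds are comparable across
    conditions.
    """
    pooled = np.concatenate([np.asarray(im, dtype=float).ravel() for im in images])
    lo, hi = np.percentile(pooled, [low_pct, high_pct])
    return float(lo), float(hi)


def segment_filaments(
    image2d_normalized: np.ndarray,
    threshold_method: str = "otsu",
    min_area_px: int = 5,
    threshold_value: float | None = None,
) -> list[FilamentROI]:
    """Threshold a normalized 2D image into 8-connected filament ROIs.

    Parameters
    ----------
    image2d_normalized
        2D image on the [0, 1] normalized scale.
    threshold_method
        ``"otsu"`` (global Otsu, default) or ``"fixed"`` (requires
        ``threshold_value``).
    min_area_px
        Components smaller than this are discarded (speckle rejection).
    threshold_value
        Absolute threshold on the normalized scale when ``threshold_method``
        is ``"fixed"``.

    Returns
    -------
    list of FilamentROI, ordered by label; empty list if nothing is above
    threshold (an empty field is a valid observation, not an error).
    """
    img = np.asarray(image2d_normalized, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D image; project the stack first")
    if threshold_method == "otsu":
        if img.max() <= 0 or np.ptp(img) == 0:
            return []
        thr = threshold_otsu(img)
    elif threshold_method == "fixed":
        if threshold_value is None:
            raise ValueError("threshold_method='fixed' requires threshold_value")
        thr = float(threshold_value)
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")

    mask = img > thr
    if not mask.any():
        return []
    labels = label(mask, connectivity=2)  # 8-connectivity
    rois: list[FilamentROI] = []
    for rp in regionprops(labels, intensity_image=img):
        if rp.area < min_area_px:
            continue
        rois.append(
            FilamentROI(
                roi_id=len(rois),
                coords=rp.coords.copy(),
                area_px=int(rp.area),
                mean_intensity=float(rp.intensity_mean),
                centroid_yx_px=(float(rp.centroid[0]), float(rp.centroid[1])),
            )
        )
    return rois


def rois_to_dataframe(rois: list[FilamentROI], pixel_size_um: float) -> pd.DataFrame:
    """Tabulate ROIs as (roi_id, area_px, mean_intensity, centroid_x_um, centroid_y_um)."""
    rows = []
    for r in rois:
        x_um, y_um = r.centroid_um(pixel_size_um)
        rows.append(
            {
                "roi_id": r.roi_id,
                "area_px": r.area_px,
                "mean_intensity": r.mean_intensity,
                "centroid_x_um": x_um,
                "centroid_y_um": y_um,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["roi_id", "area_px", "mean_intensity", "centroid_x_um", "centroid_y_um"],
    )
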