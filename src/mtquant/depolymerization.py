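"""Microtubule shrinkage-rate estimation from two time points.

The assay measures filament lengths at two times (0 s and 400 s in the
original protocol) and reports the per-filament rate
(L(t0) − L(t1)) / (t1 − t0), converted to µm/min, summarized as mean ± SEM.

Two length estimators are provided.  The default (``method="axis"``)
projects the ROI's pixels onto their principal axis and takes the extent —
for the straight, rigid filaments of this assay it is free of the
staircase quantization error of digital-curve length measures, so its end
error is purely additive and cancels in the two-time-point difference.
The alternative (``method="skeleton"``) counts morphological-skeleton
steps (1 px orthogonal, √2 diagonal), rescaled by the exact chain-code
overestimate factor for a straight digital line at the skeleton's
orientation; it generalizes to gently curved structures but retains a few
tenths of a percent of orientation-quantization bias.  In both cases the
skeleton provides the branch flag: blob-like ROIs whose skeleton has more
than two endpoints (crossing or aggregated filaments) are flagged and
excluded from rate statistics.

Filament identity across the two time points is recovered by
nearest-midpoint matching (shrinkage is symmetric about the midpoint, so
midpoints are stable); when identities cannot be matched, a population-mean
rate over unmatched length pools is available.  Filaments present at t0 but
absent at t1 (fully depolymerized) are censored: they are excluded from the
per-filament rate by default — including them at their last length would
bias the rate downward, while the exclusion biases upward only when the
true loss exceeds the initial length — and their count is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.morphology import skeletonize

from .imaging import FilamentROI, segment_filaments

__all__ = [
    "LengthRecord",
    "LengthMeasurement",
    "RateSummary",
    "skeleton_length_um",
    "axis_extent_length_um",
    "measure_lengths",
    "match_filaments",
    "shrinkage_rate",
    "population_shrinkage_rate",
]

# offsets covering each 8-neighbor pair exactly once
_FORWARD_NEIGHBORS = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass(frozen=True)
class LengthRecord:
    """Measured length of one segmented filament."""

    roi_id: int
    length_um: float
    centroid_x_um: float
    centroid_y_um: float
    branched: bool  # skeleton has >2 endpoints; excluded from rate statistics


@dataclass(frozen=True)
class LengthMeasurement:
    """Lengths of one filament at two time points."""

    filament_id: int
    length_t0_um: float
    length_t1_um: float
    t0_s: float
    t1_s: float

    def __post_init__(self) -> None:
        if self.t1_s <= self.t0_s:
            raise ValueError("t1 must exceed t0")
        if self.length_t0_um < 0 or self.length_t1_um < 0:
            raise ValueError("lengths must be >= 0")

    @property
    def rate_um_per_min(self) -> float:
        return (self.length_t0_um - self.length_t1_um) / (self.t1_s - self.t0_s) * 60.0


@dataclass(frozen=True)
class RateSummary:
    """Shrinkage-rate summary: mean ± SEM over n filaments."""

    mean_rate_um_per_min: float
    sem_um_per_min: float
    n: int
    n_censored: int = 0


def _skeleton_graph(roi: FilamentROI) -> tuple[set, dict, float]:
    """Skeletonize one ROI; return (skeleton pixels, degree map, chain length)."""
    ys, xs = roi.coords[:, 0], roi.coords[:, 1]
    y0, x0 = ys.min(), xs.min()
    mask = np.zeros((ys.max() - y0 + 3, xs.max() - x0 + 3), dtype=bool)
    mask[ys - y0 + 1, xs - x0 + 1] = True
    skel = skeletonize(mask)
    pts = set(zip(*np.nonzero(skel)))
    length_px = 0.0
    degree = {p: 0 for p in pts}
    for r, c in pts:
        for dr, dc in _FORWARD_NEIGHBORS:
            q = (r + dr, c + dc)
            if q in pts:
                length_px += math.hypot(dr, dc)
                degree[(r, c)] += 1
                degree[q] += 1
    return pts, degree, length_px


def skeleton_length_um(
    roi: FilamentROI, pixel_size_um: float, end_correction_px: float = 1.0
) -> tuple[float, bool]:
    """Length of one ROI from its skeleton, with a branching flag.

    Returns ``(length_um, branched)``.  Length = Σ step lengths along the
    skeleton (1 px orthogonal, √2 diagonal), rescaled by the exact
    chain-code overestimate factor for a straight digital line at the
    skeleton's end-to-end orientation (the raw (1, √2) weighting
    overestimates straight segments by up to ~8% depending on angle),
    + ``end_correction_px`` per free end for the skeleton's end-trimming.
    ``branched`` is True when the skeleton has more than two endpoints.
    """
    pts, degree, length_px = _skeleton_graph(roi)
    if not pts:
        return 0.0, False
    ends = [p for p, d in degree.items() if d <= 1]
    branched = len(ends) > 2
    if len(ends) == 2:
        dy = abs(ends[1][0] - ends[0][0])
        dx = abs(ends[1][1] - ends[0][1])
        a, b = max(dx, dy), min(dx, dy)
        if a > 0:
            length_px /= ((a - b) + math.sqrt(2) * b) / math.hypot(a, b)
    length_px += end_correction_px * min(len(ends), 2)
    return length_px * pixel_size_um, branched


def axis_extent_length_um(roi: FilamentROI, pixel_size_um: float) -> tuple[float, bool]:
    """Length of one ROI as the pixel extent along its principal axis.

    Exact (up to an additive end-extension that cancels in two-time-point
    differences) for straight filaments; the skeleton is still computed for
    the branching flag.  Returns ``(length_um, branched)``.
    """
    pts, degree, _ = _skeleton_graph(roi)
    ends = sum(1 for d in degree.values() if d <= 1)
    branched = ends > 2
    co = roi.coords.astype(float)
    co = co - co.mean(axis=0)
    _, _, vt = np.linalg.svd(co, full_matrices=False)
    proj = co @ vt[0]
    return float(proj.max() - proj.min()) * pixel_size_um, branched


def measure_lengths(
    image2d_normalized: np.ndarray,
    pixel_size_um: float,
    threshold_method: str = "otsu",
    min_area_px: int = 5,
    threshold_value: float | None = None,
    method: str = "axis",
) -> list[LengthRecord]:
    """Segment a normalized 2D image and measure each filament's length.

    ``method`` selects the estimator: ``"axis"`` (principal-axis extent,
    default) or ``"skeleton"`` (calibrated chain-code).  Branched
    (blob-like) ROIs are included in the list but flagged; an empty image
    yields an empty list.
    """
    if method not in ("axis", "skeleton"):
        raise ValueError(f"unknown length method {method!r}")
    measure = axis_extent_length_um if method == "axis" else skeleton_length_um
    rois = segment_filaments(
        image2d_normalized,
        threshold_method=threshold_method,
        min_area_px=min_area_px,
        threshold_value=threshold_value,
    )
    records = []
    for roi in rois:
        length, branched = measure(roi, pixel_size_um)
        cx, cy = roi.centroid_um(pixel_size_um)
        records.append(
            LengthRecord(
                roi_id=roi.roi_id,
                length_um=length,
                centroid_x_um=cx,
                centroid_y_um=cy,
                branched=branched,
            )
        )
    return records


def match_filaments(
    records_t0: list[LengthRecord],
    records_t1: list[LengthRecord],
    t0_s: float,
    t1_s: float,
    max_shift_um: float = 1.5,
) -> tuple[list[LengthMeasurement], int]:
    """Pair filaments across two time points by nearest midpoint.

    Greedy nearest-centroid matching within ``max_shift_um``; branched ROIs
    are skipped.  Returns the matched measurements and the number of
    censored filaments (unbranched at t0 but unmatched at t1 — typically
    fully depolymerized).
    """
    a = [r for r in records_t0 if not r.branched]
    b = [r for r in records_t1 if not r.branched]
    measurements: list[LengthMeasurement] = []
    used: set[int] = set()
    n_censored = 0
    for r0 in a:
        best_j, best_d = None, max_shift_um
        for j, r1 in enumerate(b):
            if j in used:
                continue
            d = math.hypot(
                r1.centroid_x_um - r0.centroid_x_um, r1.centroid_y_um - r0.centroid_y_um
            )
            if d < best_d:
                best_j, best_d = j, d
        if best_j is None:
            n_censored += 1
            continue
        used.add(best_j)
        measurements.append(
            LengthMeasurement(
                filament_id=r0.roi_id,
                length_t0_um=r0.length_um,
                length_t1_um=b[best_j].length_um,
                t0_s=t0_s,
                t1_s=t1_s,
            )
        )
    return measurements, n_censored


def shrinkage_rate(
    measurements: list[LengthMeasurement], n_censored: int = 0
) -> RateSummary:
    """Mean ± SEM shrinkage rate (µm/min) over per-filament measurements."""
    if len(measurements) < 2:
        raise ValueError("need at least 2 length measurements")
    rates = np.array([m.rate_um_per_min for m in measurements])
    return RateSummary(
        mean_rate_um_per_min=float(rates.mean()),
        sem_um_per_min=float(rates.std(ddof=1) / math.sqrt(rates.size)),
        n=int(rates.size),
        n_censored=n_censored,
    )


def population_shrinkage_rate(
    lengths_t0_um, lengths_t1_um, t0_s: float, t1_s: float
) -> float:
    """Population-mean rate when filament identities are unavailable:
    (mean L(t0) − mean L(t1)) / Δt, in µm/min.  Valid only when the same
    population is measured at both times (no filament lost in between)."""
    if t1_s <= t0_s:
        raise ValueError("t1 must exceed t0")
    l0 = float(np.mean(np.asarray(lengths_t0_um, dtype=float)))
    l1 = float(np.mean(np.asarray(lengths_t1_um, dtype=float)))
    return (l0 - l1) / (t1_s - t0_s) * 60.0
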