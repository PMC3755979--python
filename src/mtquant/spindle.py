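"""Mitotic-spindle and kinetochore geometry metrics.

Given the XY centroids of a cell's kinetochores (µm), these routines fit the
spindle-equator line, measure the distribution of perpendicular kinetochore
distances to it, align many cells into a common frame for pooled
distributions, compute spindle dimension metrics (SL, SW, KW, SD, AvgDist),
classify metaphase plates, and score lagging kinetochores in anaphase.

The equator line is fitted by total least squares — the principal axis of the
point covariance through the centroid — because the downstream statistic is
the *perpendicular* distance of each kinetochore to that line; ordinary
least squares would make the fit depend on the arbitrary image axes.  An OLS
variant is kept behind a flag for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.feature import peak_local_max

from .stack import ImageStack
from .imaging import max_project

__all__ = [
    "KinetochoreSet",
    "EquatorLine",
    "SpindleMetrics",
    "fit_equator",
    "kinetochore_distances",
    "align_cells",
    "detect_poles",
    "spindle_metrics",
    "score_lagging",
    "select_metaphase",
    "read_kinetochore_csv",
    "write_kinetochore_csv",
]


@dataclass
class KinetochoreSet:
    """XY kinetochore centroids of one cell (µm), with optional pole positions."""

    cell_id: str
    points: np.ndarray  # (n, 2) array of (x_um, y_um)
    stage: str = "metaphase"
    pole_positions: np.ndarray | None = None  # (2, 2) array of (x_um, y_um)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.pole_positions is not None:
            self.pole_positions = np.asarray(self.pole_positions, dtype=float).reshape(2, 2)
            if np.allclose(self.pole_positions[0], self.pole_positions[1]):
                raise ValueError("pole positions must be distinct")


@dataclass(frozen=True)
class EquatorLine:
    """Spindle-equator line: point + unit direction + unit normal."""

    centroid: np.ndarray  # (2,)
    direction: np.ndarray  # (2,), unit, along the equator
    normal: np.ndarray  # (2,), unit, perpendicular

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        return (pts - self.centroid) @ self.normal


@dataclass(frozen=True)
class SpindleMetrics:
    """Per-cell spindle dimension metrics, all in µm.

    SL: pole-to-pole spindle length.  SW: spindle width, the extent of the
    above-threshold tubulin mask perpendicular to the pole axis.  KW:
    kinetochore-distribution width parallel to the equator (2nd–98th
    percentile range).  SD: population standard deviation of perpendicular
    kinetochore distances to the equator.  AvgDist: mean absolute
    perpendicular distance.
    """

    SL: float
    SW: float
    KW: float
    SD: float
    AvgDist: float


def _principal_axes(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T, bias=True)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    return centroid, evals, evecs


def fit_equator(kset: KinetochoreSet, method: str = "tls") -> EquatorLine:
    """Fit the spindle-equator line to all kinetochore positions.

    ``method="tls"`` (default) minimizes the sum of squared *perpendicular*
    residuals: the line through the centroid along the major principal axis
    of the point covariance.  ``method="ols"`` regresses y on x (axis
    dependent; for comparison only).

    The direction sign is fixed to positive x-component (positive y if the
    line is vertical); when pole positions are available the sign is chosen
    so the pole-to-pole vector has non-negative projection on the direction.
    """
    pts = kset.points
    if len(pts) < 3:
        raise ValueError("need at least 3 kinetochores to fit an equator")
    centroid, evals, evecs = _principal_axes(pts)
    if np.allclose(evals, 0.0):
        raise ValueError("all kinetochore positions coincident; equator undefined")

    if method == "tls":
        direction = evecs[:, 1]  # major axis
    elif method == "ols":
        x, y = pts[:, 0], pts[:, 1]
        if np.ptp(x) == 0:
            direction = np.array([0.0, 1.0])
        else:
            slope = np.polyfit(x, y, 1)[0]
            direction = np.array([1.0, slope])
            direction /= np.linalg.norm(direction)
    else:
        raise ValueError(f"unknown method {method!r}")

    # deterministic sign convention
    if kset.pole_positions is not None:
        pole_vec = kset.pole_positions[1] - kset.pole_positions[0]
        if float(direction @ pole_vec) < 0:
            direction = -direction
    elif direction[0] < 0 or (direction[0] == 0 and direction[1] < 0):
        direction = -direction
    normal = np.array([-direction[1], direction[0]])
    return EquatorLine(centroid=centroid, direction=direction, normal=normal)


def kinetochore_distances(
    kset: KinetochoreSet, line: EquatorLine
) -> tuple[np.ndarray, float, float]:
    """Signed perpendicular distances to the equator, with (SD, AvgDist).

    SD is the population standard deviation of the signed distances and
    AvgDist the mean absolute distance, both in µm.
    """
    d = line.signed_distance(kset.points)
    return d, float(np.std(d)), float(np.mean(np.abs(d)))


def _is_isotropic(evals: np.ndarray, rtol: float = 1e-9) -> bool:
    return (evals[1] - evals[0]) <= rtol * max(evals[1], 1e-300)


def align_cells(sets: list[KinetochoreSet], method: str = "tls") -> pd.DataFrame:
    """Pool many cells into a common frame: centroid at origin, equator along x.

    Each cell is rigidly transformed (rotation + translation only, so all
    within-cell distances are preserved exactly) by mapping its kinetochore
    centroid to the origin and rotating its fitted equator direction onto the
    +x axis.  Cells with an isotropic kinetochore covariance have no defined
    equator direction and are skipped with a warning.

    Returns a long-format frame with columns (cell_id, kt_id, x_um, y_um).
    """
    rows = []
    for kset in sets:
        _, evals, _ = _principal_axes(kset.points)
        if _is_isotropic(evals):
            warnings.warn(
                f"cell {kset.cell_id}: isotropic kinetochore covariance, "
                "equator direction ambiguous; skipped"
            )
            continue
        line = fit_equator(kset, method=method)
        rel = kset.points - line.centroid
        aligned = np.column_stack([rel @ line.direction, rel @ line.normal])
        for i, (x, y) in enumerate(aligned):
            rows.append({"cell_id": kset.cell_id, "kt_id": i, "x_um": x, "y_um": y})
    return pd.DataFrame(rows, columns=["cell_id", "kt_id", "x_um", "y_um"])


def detect_poles(
    tubulin: ImageStack, smooth_um: float = 0.5, min_separation_um: float = 2.0
) -> np.ndarray:
    """Locate the spindle poles as the two strongest maxima of the smoothed
    tubulin projection, at least ``min_separation_um`` apart.

    Returns a (2, 2) array of (x_um, y_um).  Raises if fewer than two
    candidates are found (caller should then supply poles manually).
    """
    img = tubulin
    if "z" in img.axes:
        img = max_project(img, "z")
    if img.axes != "yx":
        raise ValueError("expected a single-timepoint image (axes yx or zyx)")
    px = img.pixel_size_um
    sm = gaussian_filter(np.asarray(img.pixels, dtype=float), smooth_um / px)
    peaks = peak_local_max(
        sm, min_distance=max(1, int(round(min_separation_um / px))), num_peaks=2
    )
    if len(peaks) < 2:
        raise ValueError(
            "fewer than two pole candidates detected; supply pole positions manually"
        )
    # (row, col) -> physical (x, y), pixel-centered
    return np.array([[(c + 0.5) * px, (r + 0.5) * px] for r, c in peaks])


def spindle_metrics(
    kset: KinetochoreSet,
    poles: np.ndarray | None = None,
    tubulin: ImageStack | None = None,
    mask_fraction_of_max: float = 0.5,
    kw_percentiles: tuple[float, float] = (2.0, 98.0),
) -> SpindleMetrics:
    """Compute SL, SW, KW, SD and AvgDist for one cell.

    Poles are taken from ``poles``, else from ``kset.pole_positions``, else
    detected from the tubulin image.  SW requires a tubulin image (NaN
    otherwise): the projection is thresholded at ``mask_fraction_of_max`` of
    its smoothed maximum and the mask extent perpendicular to the pole axis
    is measured.
    """
    if poles is None:
        poles = kset.pole_positions
    if poles is None:
        if tubulin is None:
            raise ValueError("need pole positions or a tubulin image to find them")
        poles = detect_poles(tubulin)
    poles = np.asarray(poles, dtype=float).reshape(2, 2)

    sl = float(np.linalg.norm(poles[1] - poles[0]))
    pole_axis = (poles[1] - poles[0]) / sl
    pole_normal = np.array([-pole_axis[1], pole_axis[0]])

    line = fit_equator(kset)
    _, sd, avg_dist = kinetochore_distances(kset, line)
    proj = (kset.points - line.centroid) @ line.direction
    lo, hi = np.percentile(proj, kw_percentiles)
    kw = float(hi - lo)

    sw = float("nan")
    if tubulin is not None:
        img = tubulin
        if "z" in img.axes:
            img = max_project(img, "z")
        px = img.pixel_size_um
        sm = gaussian_filter(np.asarray(img.pixels, dtype=float), 0.25 / px)
        mask = sm >= mask_fraction_of_max * sm.max()
        rr, cc = np.nonzero(mask)
        coords = np.column_stack([(cc + 0.5) * px, (rr + 0.5) * px])
        perp = (coords - poles[0]) @ pole_normal
        sw = float(perp.max() - perp.min())

    return SpindleMetrics(SL=sl, SW=sw, KW=kw, SD=sd, AvgDist=avg_dist)


def score_lagging(
    kset: KinetochoreSet, poles: np.ndarray | None = None, lag_fraction: float = 0.2
) -> bool:
    """Score one anaphase cell for lagging kinetochores.

    A kinetochore lags if its distance to the *nearer* pole strictly exceeds
    ``lag_fraction`` of the spindle length; the cell is lagging-positive if
    at least one kinetochore lags.  A kinetochore exactly at the threshold
    does not lag (strict inequality).
    """
    if poles is None:
        poles = kset.pole_positions
    if poles is None:
        raise ValueError("pole positions are required to score lagging kinetochores")
    poles = np.asarray(poles, dtype=float).reshape(2, 2)
    sl = float(np.linalg.norm(poles[1] - poles[0]))
    d0 = np.linalg.norm(kset.points - poles[0], axis=1)
    d1 = np.linalg.norm(kset.points - poles[1], axis=1)
    nearest = np.minimum(d0, d1)
    return bool(np.any(nearest > lag_fraction * sl))


def _two_means_split(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal 1D 2-means partition: split the sorted values at the cut that
    minimizes within-group sum of squares (exhaustive over n-1 cuts)."""
    v = np.sort(values)
    n = len(v)
    best_k, best_sse = 1, np.inf
    for k in range(1, n):
        a, b = v[:k], v[k:]
        sse = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        if sse < best_sse:
            best_sse, best_k = sse, k
    return v[:best_k], v[best_k:]


def select_metaphase(kset: KinetochoreSet, max_separation_um: float = 2.0) -> bool:
    """Decide whether a cell shows a metaphase plate.

    The signed perpendicular distances to the fitted equator are split by
    1D 2-means; the cell qualifies if the two group means are separated by
    less than ``max_separation_um`` (the "two nearly parallel rows separated
    by less than ~2 µm" rule) and each group's spread (population SD) is
    smaller than that separation (the rows are *distinct* rows, not one
    diffuse cloud).
    """
    line = fit_equator(kset)
    d, _, _ = kinetochore_distances(kset, line)
    if len(d) < 4:
        return False
    a, b = _two_means_split(d)
    if len(a) == 0 or len(b) == 0:
        return False
    sep = abs(float(a.mean()) - float(b.mean()))
    spread = max(float(np.std(a)), float(np.std(b)))
    return sep < max_separation_um and spread < sep


def read_kinetochore_csv(path) -> list[KinetochoreSet]:
    """Read kinetochore sets from CSV with columns cell_id, kt_id, x_um, y_um."""
    df = pd.read_csv(path)
    required = {"cell_id", "x_um", "y_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"kinetochore CSV must have columns {sorted(required)}")
    sets = []
    for cell_id, g in df.groupby("cell_id", sort=True):
        stage = g["stage"].iloc[0] if "stage" in g.columns else "metaphase"
        sets.append(
            KinetochoreSet(
                cell_id=str(cell_id),
                points=g[["x_um", "y_um"]].to_numpy(),
                stage=str(stage),
            )
        )
    return sets


def write_kinetochore_csv(sets: list[KinetochoreSet], path) -> None:
    rows = []
    for kset in sets:
        for i, (x, y) in enumerate(kset.points):
            rows.append(
                {"cell_id": kset.cell_id, "kt_id": i, "x_um": x, "y_um": y,
                 "stage": kset.stage}
            )
    pd.DataFrame(rows).to_csv(path, index=False)
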