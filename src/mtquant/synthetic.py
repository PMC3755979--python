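"""Synthetic fluorescence-microscopy scenes with known ground truth.

Four generators emulate the data each analysis stage consumes:

* :func:`render_filament_field` — fields of rhodamine-labeled microtubules,
  optionally cross-linked into bundles, over a 65×65 µm² field with six
  0.25 µm z-sections (the bundling-assay acquisition geometry).  The sampled
  z-range is thin, so every z-section shares the same in-focus rendering
  and differs only in its shot noise.
* :func:`render_depoly_movie` — time-lapse movies of shrinking filaments,
  both ends retracting at half the total shrinkage rate.
* :func:`simulate_spindle_cells` — metaphase kinetochore position sets:
  two near-parallel rows at ±separation/2 with Gaussian scatter, randomly
  rotated and translated per cell.
* :func:`render_flux_movie` — a GFP-tubulin spindle band with photobleached
  stripes on each half-spindle translating poleward at a known rate.

Rendering model: filaments are straight segments of uniform linear photon
density; the per-slice image is the Gaussian-PSF-blurred photon map plus a
uniform background, Poisson-sampled per pixel (shot noise only — no camera
read-noise term).  ``photons_per_um`` is therefore the expected photon
count per µm of filament *per z-section*.  Every generator is
deterministic for a fixed seed and returns a :class:`SceneGroundTruth`
in bijection with the rendered objects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .stack import ImageStack
from .spindle import KinetochoreSet, EquatorLine

__all__ = [
    "FilamentFieldParams",
    "DepolyMovieParams",
    "SpindleSimParams",
    "FluxMovieParams",
    "FilamentSegment",
    "CellTruth",
    "SceneGroundTruth",
    "PlacementError",
    "render_filament_field",
    "render_depoly_movie",
    "simulate_spindle_cells",
    "render_flux_movie",
]


class PlacementError(ValueError):
    """A filament cannot be placed fully inside the field."""


# --------------------------------------------------------------------------
# parameter blocks
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FilamentFieldParams:
    """Parameters of one synthetic filament field.

    Defaults reproduce the bundling-assay acquisition: a 65×65 µm² confocal
    field with 6 z-sections of 0.25 µm.  ``photons_per_um`` is the expected
    photon count emitted per µm of a *single* filament per z-section; a
    bundle of k overlapping filaments renders at ≈k× the single-filament
    intensity.  ``min_separation_um`` optionally enforces a minimum distance
    between placed filaments (bundle members excepted), emulating a
    well-diluted preparation where filaments rarely cross; ``None`` places
    filaments independently.  ``bundle_fraction`` is the fraction of
    filaments that are members of bundles of ``bundle_size``.
    """

    field_size_um: tuple[float, float] = (65.0, 65.0)
    pixel_size_um: float = 0.13
    n_filaments: int = 60
    length_range_um: tuple[float, float] = (2.0, 10.0)
    bundle_fraction: float = 0.0
    bundle_size: int = 4
    bundle_lateral_jitter_um: float = 0.02
    psf_sigma_um: float = 0.13
    photons_per_um: float = 400.0
    background_photons: float = 2.0
    n_z: int = 6
    z_step_um: float = 0.25
    min_separation_um: float | None = None
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.bundle_fraction <= 1.0):
            raise ValueError("bundle_fraction must lie in [0, 1]")
        if self.bundle_size < 2:
            raise ValueError("bundle_size must be >= 2")
        if self.n_filaments < 1:
            raise ValueError("n_filaments must be >= 1")
        for name in ("pixel_size_um", "psf_sigma_um", "z_step_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if min(self.field_size_um) <= 0 or min(self.length_range_um) <= 0:
            raise ValueError("physical lengths must be > 0")


@dataclass(frozen=True)
class DepolyMovieParams:
    """Depolymerization movie: a filament field shrinking over time.

    Each filament loses length at ``shrink_rate_um_per_min`` total, split
    equally between its two ends, until it vanishes.  Defaults follow the
    depolymerization-assay acquisition cadence (10 s frame interval over
    400 s) on a reduced field.
    """

    field: FilamentFieldParams = field(
        default_factory=lambda: FilamentFieldParams(
            field_size_um=(65.0, 65.0), length_range_um=(8.0, 14.0), n_z=3,
            z_step_um=0.25, n_filaments=50, min_separation_um=1.0,
        )
    )
    shrink_rate_um_per_min: float = 0.6
    duration_s: float = 400.0
    frame_interval_s: float = 10.0

    def __post_init__(self) -> None:
        if self.shrink_rate_um_per_min < 0:
            raise ValueError("shrink_rate_um_per_min must be >= 0")
        if self.frame_interval_s <= 0 or self.duration_s < 0:
            raise ValueError("invalid timing")


@dataclass(frozen=True)
class SpindleSimParams:
    """Metaphase kinetochore-distribution simulation.

    Kinetochores sit at ±``plate_separation_um``/2 perpendicular to a
    per-cell equator line with Gaussian scatter ``sigma_perp_um`` across and
    ``sigma_par_um`` along the plate, then each cell is randomly rotated and
    translated.  The default separation of 1 µm satisfies the metaphase
    selection rule (rows separated by less than ~2 µm).
    """

    n_cells: int = 31
    kinetochores_per_cell: int = 20
    plate_separation_um: float = 1.0
    sigma_perp_um: float = 0.5
    sigma_par_um: float = 2.0
    rotation_range_rad: float = math.pi
    translation_range_um: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_perp_um < 0 or self.sigma_par_um < 0:
            raise ValueError("sigmas must be >= 0")
        if self.plate_separation_um < 0:
            raise ValueError("plate_separation_um must be >= 0")


@dataclass(frozen=True)
class FluxMovieParams:
    """Photobleach flux movie: a spindle band with moving bleach stripes.

    The tubulin intensity along the spindle axis is a Gaussian band of
    half-width ``spindle_sigma_um`` centered between the poles, extruded
    across the short image axis.  At t=0, multiplicative Gaussian bleach
    stripes of fractional depth ``bleach_depth`` are stamped at
    ``bleach_positions_um`` (signed offsets from the spindle center, one per
    half-spindle); each stripe center then translates toward its nearer pole
    at ``flux_rate_um_per_min``.  Bleach contrast optionally recovers with
    halftime ``recovery_halftime_s`` (``inf`` = no recovery).  Defaults
    follow the flux acquisition cadence: 5 s frame interval.
    """

    spindle_length_um: float = 10.0
    spindle_sigma_um: float = 3.0
    flux_rate_um_per_min: float = 0.9
    bleach_positions_um: tuple[float, ...] = (-2.0, 2.0)
    bleach_width_um: float = 0.8
    bleach_depth: float = 0.7
    recovery_halftime_s: float = math.inf
    frame_interval_s: float = 5.0
    n_frames: int = 13
    pixel_size_um: float = 0.13
    peak_photons: float = 400.0
    background_photons: float = 2.0
    field_height_px: int = 25
    margin_um: float = 2.0
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.bleach_depth <= 1.0):
            raise ValueError("bleach_depth must lie in (0, 1]")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.n_frames < 3:
            raise ValueError("n_frames must be >= 3")
        half = self.spindle_length_um / 2
        for c in self.bleach_positions_um:
            if abs(c) >= half + self.margin_um:
                raise ValueError(f"bleach stripe at {c} µm lies outside the field")


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FilamentSegment:
    """Endpoints of one rendered filament (µm) and its bundle membership."""

    filament_id: int
    x0: float
    y0: float
    x1: float
    y1: float
    bundle_id: int | None = None

    @property
    def length_um(self) -> float:
        return math.hypot(self.x1 - self.x0, self.y1 - self.y0)

    @property
    def midpoint(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2, (self.y0 + self.y1) / 2)


@dataclass(frozen=True)
class CellTruth:
    """Generative truth for one simulated cell."""

    cell_id: str
    equator: EquatorLine
    perp_offsets_um: np.ndarray  # signed true perpendicular offsets, per kinetochore


@dataclass
class SceneGroundTruth:
    """Generative parameters of a synthetic scene, one record per rendered object."""

    filament_segments: list[FilamentSegment] = field(default_factory=list)
    shrink_rate_um_per_min: float | None = None
    frame_times_s: list[float] | None = None
    kinetochore_truth: list[CellTruth] | None = None
    flux_rate_um_per_min: float | None = None

    def to_json_dict(self) -> dict:
        """Plain-JSON representation (for sidecar ground-truth files)."""
        out: dict = {}
        if self.filament_segments:
            out["filament_segments"] = [
                {
                    "filament_id": s.filament_id,
                    "x0": s.x0, "y0": s.y0, "x1": s.x1, "y1": s.y1,
                    "bundle_id": s.bundle_id,
                }
                for s in self.filament_segments
            ]
        if self.shrink_rate_um_per_min is not None:
            out["shrink_rate_um_per_min"] = self.shrink_rate_um_per_min
        if self.frame_times_s is not None:
            out["frame_times_s"] = list(self.frame_times_s)
        if self.kinetochore_truth is not None:
            out["kinetochore_truth"] = [
                {
                    "cell_id": c.cell_id,
                    "centroid": list(map(float, c.equator.centroid)),
                    "direction": list(map(float, c.equator.direction)),
                    "perp_offsets_um": list(map(float, c.perp_offsets_um)),
                }
                for c in self.kinetochore_truth
            ]
        if self.flux_rate_um_per_min is not None:
            out["flux_rate_um_per_min"] = self.flux_rate_um_per_min
        return out

    def segments_at(self, t_s: float) -> list[FilamentSegment]:
        """Shrunken segments at elapsed time t (depolymerization scenes only).

        Both ends retract at rate/2, so the midpoint is fixed; filaments
        whose length has reached zero are omitted.
        """
        if self.shrink_rate_um_per_min is None:
            raise ValueError("not a depolymerization scene")
        loss = self.shrink_rate_um_per_min * t_s / 60.0
        out = []
        for seg in self.filament_segments:
            new_len = seg.length_um - loss
            if new_len <= 0:
                continue
            mx, my = seg.midpoint
            ux = (seg.x1 - seg.x0) / seg.length_um
            uy = (seg.y1 - seg.y0) / seg.length_um
            h = new_len / 2
            out.append(
                replace(seg, x0=mx - ux * h, y0=my - uy * h, x1=mx + ux * h, y1=my + uy * h)
            )
        return out


# --------------------------------------------------------------------------
# rendering primitives
# --------------------------------------------------------------------------


def _rasterize_segments(
    segments: list[FilamentSegment],
    shape: tuple[int, int],
    pixel_size_um: float,
    photons_per_um: float,
    oversample: int = 5,
) -> np.ndarray:
    """Deposit segment photons onto a pixel grid (nearest-pixel splatting at
    ``oversample`` samples per pixel length; the PSF blur that follows is much
    wider than the splat quantization)."""
    photon_map = np.zeros(shape, dtype=float)
    step = pixel_size_um / oversample
    for seg in segments:
        n = max(1, int(math.ceil(seg.length_um / step)))
        ts = (np.arange(n) + 0.5) / n
        xs = seg.x0 + ts * (seg.x1 - seg.x0)
        ys = seg.y0 + ts * (seg.y1 - seg.y0)
        # physical -> pixel index, pixel centers at (i + 0.5) * px
        cols = np.clip((xs / pixel_size_um - 0.5).round().astype(int), 0, shape[1] - 1)
        rows = np.clip((ys / pixel_size_um - 0.5).round().astype(int), 0, shape[0] - 1)
        np.add.at(photon_map, (rows, cols), photons_per_um * seg.length_um / n)
    return photon_map


def _render_field_stack(
    segments: list[FilamentSegment],
    p: FilamentFieldParams,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Render one (z, y, x) stack: blurred photon map split across z-slices,
    plus background, Poisson-sampled when a generator is given."""
    shape = (
        int(round(p.field_size_um[1] / p.pixel_size_um)),
        int(round(p.field_size_um[0] / p.pixel_size_um)),
    )
    photon_map = _rasterize_segments(segments, shape, p.pixel_size_um, p.photons_per_um)
    blurred = gaussian_filter(photon_map, p.psf_sigma_um / p.pixel_size_um, mode="constant")
    # thin sampling: every z-section shares the in-focus rendering
    per_slice = blurred + p.background_photons
    stack = np.broadcast_to(per_slice, (p.n_z, *shape)).copy()
    if rng is not None and p.shot_noise:
        stack = rng.poisson(stack).astype(float)
    return stack


def _segment_distance(a: tuple, b: tuple) -> float:
    """Minimum distance between two 2D segments ((x0,y0,x1,y1) each)."""
    from shapely.geometry import LineString

    return LineString([(a[0], a[1]), (a[2], a[3])]).distance(
        LineString([(b[0], b[1]), (b[2], b[3])])
    )


def _place_segments(p: FilamentFieldParams, rng: np.random.Generator) -> list[FilamentSegment]:
    """Uniform random position/orientation, rejection-sampled until the whole
    segment lies inside the field inset by 2·psf_sigma (keeps ROIs unclipped)
    and, when ``min_separation_um`` is set, clear of previously placed
    filaments."""
    inset = 2.0 * p.psf_sigma_um
    w, h = p.field_size_um
    max_len = math.hypot(w - 2 * inset, h - 2 * inset)

    n_bundled = int(round(p.bundle_fraction * p.n_filaments))
    n_bundles = n_bundled // p.bundle_size
    n_in_bundles = n_bundles * p.bundle_size
    n_single = p.n_filaments - n_in_bundles

    placed: list[tuple] = []  # base segments, for the separation check

    def place_one(length: float) -> tuple[float, float, float]:
        if length > max_len:
            raise PlacementError(
                f"filament of length {length:.2f} µm cannot fit in a "
                f"{w}×{h} µm field inset by {inset:.2f} µm"
            )
        for _ in range(10_000):
            cx = rng.uniform(inset, w - inset)
            cy = rng.uniform(inset, h - inset)
            theta = rng.uniform(0, math.pi)
            dx, dy = math.cos(theta) * length / 2, math.sin(theta) * length / 2
            if not (
                inset <= cx - dx <= w - inset and inset <= cx + dx <= w - inset
                and inset <= cy - dy <= h - inset and inset <= cy + dy <= h - inset
            ):
                continue
            cand = (cx - dx, cy - dy, cx + dx, cy + dy)
            if p.min_separation_um is not None and any(
                _segment_distance(cand, q) < p.min_separation_um for q in placed
            ):
                continue
            placed.append(cand)
            return cx, cy, theta
        raise PlacementError(
            f"could not place filament of length {length:.2f} µm after 10000 tries"
        )

    segments: list[FilamentSegment] = []
    fid = 0
    for b in range(n_bundles):
        length = rng.uniform(*p.length_range_um)
        cx, cy, theta = place_one(length)
        ux, uy = math.cos(theta), math.sin(theta)
        nx, ny = -uy, ux
        for _ in range(p.bundle_size):
            off = rng.uniform(-p.bundle_lateral_jitter_um, p.bundle_lateral_jitter_um)
            mx, my = cx + nx * off, cy + ny * off
            segments.append(
                FilamentSegment(
                    filament_id=fid, bundle_id=b,
                    x0=mx - ux * length / 2, y0=my - uy * length / 2,
                    x1=mx + ux * length / 2, y1=my + uy * length / 2,
                )
            )
            fid += 1
    for _ in range(n_single):
        length = rng.uniform(*p.length_range_um)
        cx, cy, theta = place_one(length)
        ux, uy = math.cos(theta), math.sin(theta)
        segments.append(
            FilamentSegment(
                filament_id=fid, bundle_id=None,
                x0=cx - ux * length / 2, y0=cy - uy * length / 2,
                x1=cx + ux * length / 2, y1=cy + uy * length / 2,
            )
        )
        fid += 1
    return segments


# --------------------------------------------------------------------------
# public generators
# --------------------------------------------------------------------------


def render_filament_field(
    p: FilamentFieldParams,
) -> tuple[ImageStack, SceneGroundTruth]:
    """Render one filament field as a (z, y, x) stack with ground truth."""
    rng = np.random.default_rng(p.seed)
    segments = _place_segments(p, rng)
    pixels = _render_field_stack(segments, p, rng)
    stack = ImageStack(
        pixels=pixels, axes="zyx", pixel_size_um=p.pixel_size_um, z_step_um=p.z_step_um
    )
    return stack, SceneGroundTruth(filament_segments=segments)


def render_depoly_movie(
    p: DepolyMovieParams,
) -> tuple[ImageStack, SceneGroundTruth]:
    """Render a shrinking-filament movie as a (t, z, y, x) stack.

    Placement is fixed at t=0; each frame re-renders the retracted segments
    (both ends retract at shrink_rate/2).  Fully depolymerized filaments are
    absent from later frames.
    """
    rng = np.random.default_rng(p.field.seed)
    segments = _place_segments(p.field, rng)
    truth = SceneGroundTruth(
        filament_segments=segments,
        shrink_rate_um_per_min=p.shrink_rate_um_per_min,
    )
    times = [k * p.frame_interval_s for k in range(int(p.duration_s // p.frame_interval_s) + 1)]
    truth.frame_times_s = times
    frames = [
        _render_field_stack(truth.segments_at(t), p.field, rng) for t in times
    ]
    stack = ImageStack(
        pixels=np.stack(frames),
        axes="tzyx",
        pixel_size_um=p.field.pixel_size_um,
        z_step_um=p.field.z_step_um,
        frame_interval_s=p.frame_interval_s,
    )
    return stack, truth


def simulate_spindle_cells(
    p: SpindleSimParams,
) -> tuple[list[KinetochoreSet], SceneGroundTruth]:
    """Simulate metaphase kinetochore sets for many cells, with per-cell truth."""
    rng = np.random.default_rng(p.seed)
    sets: list[KinetochoreSet] = []
    truths: list[CellTruth] = []
    n = p.kinetochores_per_cell
    for c in range(p.n_cells):
        row_sign = np.where(np.arange(n) < n // 2, 1.0, -1.0)
        perp = row_sign * p.plate_separation_um / 2 + rng.normal(0, p.sigma_perp_um, n)
        par = rng.normal(0, p.sigma_par_um, n)
        theta = rng.uniform(0, p.rotation_range_rad) if p.rotation_range_rad > 0 else 0.0
        shift = (
            rng.uniform(-p.translation_range_um, p.translation_range_um, 2)
            if p.translation_range_um > 0
            else np.zeros(2)
        )
        direction = np.array([math.cos(theta), math.sin(theta)])
        normal = np.array([-direction[1], direction[0]])
        pts = shift + np.outer(par, direction) + np.outer(perp, normal)
        cell_id = f"cell{c:03d}"
        sets.append(KinetochoreSet(cell_id=cell_id, points=pts))
        truths.append(
            CellTruth(
                cell_id=cell_id,
                equator=EquatorLine(centroid=shift, direction=direction, normal=normal),
                perp_offsets_um=perp,
            )
        )
    return sets, SceneGroundTruth(kinetochore_truth=truths)


def flux_profile(p: FluxMovieParams, x_um: np.ndarray | float, t_s: float) -> np.ndarray:
    """Noise-free spindle-axis intensity at positions ``x_um`` (offsets from
    the spindle center) and elapsed time ``t_s``, background excluded.

    The bleach factor at a stripe center is exactly ``1 - depth(t)`` — so a
    stripe of depth 1 with no recovery is exactly zero at its center.
    """
    x = np.asarray(x_um, dtype=float)
    band = p.peak_photons * np.exp(-(x**2) / (2 * p.spindle_sigma_um**2))
    factor = np.ones_like(x)
    if math.isinf(p.recovery_halftime_s):
        depth = p.bleach_depth
    else:
        depth = p.bleach_depth * 2.0 ** (-t_s / p.recovery_halftime_s)
    sigma_b = p.bleach_width_um / 2
    for c0 in p.bleach_positions_um:
        sign = 1.0 if c0 >= 0 else -1.0  # toward the nearer pole
        c = c0 + sign * p.flux_rate_um_per_min * t_s / 60.0
        factor = factor * (1.0 - depth * np.exp(-((x - c) ** 2) / (2 * sigma_b**2)))
    return band * np.clip(factor, 0.0, None)


def render_flux_movie(p: FluxMovieParams) -> tuple[ImageStack, SceneGroundTruth]:
    """Render a photobleach flux movie as a (t, y, x) stack with ground truth."""
    rng = np.random.default_rng(p.seed)
    half_w = p.spindle_length_um / 2 + p.margin_um
    n_cols = int(round(2 * half_w / p.pixel_size_um))
    # pixel-center x coordinates, offset from the spindle center
    x = (np.arange(n_cols) + 0.5) * p.pixel_size_um - half_w
    frames = []
    for k in range(p.n_frames):
        prof = flux_profile(p, x, k * p.frame_interval_s) + p.background_photons
        frame = np.broadcast_to(prof, (p.field_height_px, n_cols)).copy()
        if p.shot_noise:
            frame = rng.poisson(frame).astype(float)
        frames.append(frame)
    stack = ImageStack(
        pixels=np.stack(frames),
        axes="tyx",
        pixel_size_um=p.pixel_size_um,
        frame_interval_s=p.frame_interval_s,
    )
    return stack, SceneGroundTruth(flux_rate_um_per_min=p.flux_rate_um_per_min)
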