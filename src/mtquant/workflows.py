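"""End-to-end workflows tying the simulator to each analysis stage.

These functions are what the command-line interface and the demo run call:
each one generates (or accepts) data, runs the corresponding measurement,
and returns plain results suitable for CSV/JSON output.  They are also the
natural entry points for recovery experiments, where the measured quantity
is compared against the simulator's ground truth.
"""

from __future__ import annotations

import numpy as np

from .bundling import bundling_fraction, compare_bundling
from .depolymerization import (
    RateSummary,
    match_filaments,
    measure_lengths,
    shrinkage_rate,
)
from .imaging import (
    max_project,
    pooled_percentile_scale,
    robust_normalize,
    segment_filaments,
)
from .kymograph import FluxEstimate, estimate_flux
from .spindle import fit_equator, kinetochore_distances
from .stack import ImageStack
from .stats import GroupStats, group_stats
from .synthetic import (
    DepolyMovieParams,
    FilamentFieldParams,
    FluxMovieParams,
    SpindleSimParams,
    render_depoly_movie,
    render_filament_field,
    render_flux_movie,
    simulate_spindle_cells,
)

__all__ = [
    "image_bundling_fraction",
    "bundling_experiment",
    "depoly_recovery",
    "spindle_sd_experiment",
    "flux_recovery",
    "demo_report",
]


def image_bundling_fraction(
    stack: ImageStack,
    scale: tuple[float, float] | None = None,
    threshold: float = 0.4,
    min_area_px: int = 5,
) -> float:
    """Bundling fraction of one image stack: project, normalize, segment, score."""
    proj = max_project(stack, "z") if "z" in stack.axes else stack
    norm = robust_normalize(proj.pixels, scale=scale)
    rois = segment_filaments(norm, min_area_px=min_area_px)
    return bundling_fraction(rois, threshold=threshold)


def bundling_experiment(
    conditions: dict[str, tuple[float, int]],
    base: FilamentFieldParams | None = None,
    threshold: float = 0.4,
    segmentation_threshold: float = 0.12,
    seed: int = 0,
) -> tuple[dict[str, list[float]], GroupStats]:
    """Simulate a bundling assay and score it.

    ``conditions`` maps condition name to (bundle_fraction, n_images).  All
    images share one normalization scale (pooled percentiles), mirroring an
    acquisition at fixed settings, and are segmented with one fixed
    threshold on that scale (``segmentation_threshold``) so the mask
    criterion is identical in every image — per-image Otsu can flip between
    separating background/filaments and filaments/bundles on strongly
    bimodal bundled fields.  Returns per-image fractions per condition and
    the cross-condition Welch statistics.
    """
    from dataclasses import replace

    base = base or FilamentFieldParams()
    rng = np.random.default_rng(seed)
    projections: list[np.ndarray] = []
    labels: list[str] = []
    for name, (bundle_fraction, n_images) in conditions.items():
        for _ in range(n_images):
            p = replace(
                base,
                bundle_fraction=bundle_fraction,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            stack, _ = render_filament_field(p)
            projections.append(max_project(stack, "z").pixels)
            labels.append(name)
    scale = pooled_percentile_scale(projections)
    fractions: dict[str, list[float]] = {name: [] for name in conditions}
    for img, name in zip(projections, labels):
        norm = robust_normalize(img, scale=scale)
        rois = segment_filaments(
            norm, threshold_method="fixed", threshold_value=segmentation_threshold
        )
        fractions[name].append(bundling_fraction(rois, threshold=threshold))
    return fractions, compare_bundling(fractions)


def depoly_recovery(
    params: DepolyMovieParams | None = None,
    t0_s: float = 0.0,
    t1_s: float = 400.0,
    seed: int = 0,
) -> tuple[RateSummary, float]:
    """Render a depolymerization movie, measure it, return (estimate, truth).

    Lengths are measured on the frames nearest t0 and t1, filaments matched
    by midpoint, and the per-filament rate summarized.
    """
    from dataclasses import replace

    params = params or DepolyMovieParams()
    params = replace(params, field=replace(params.field, seed=seed))
    movie, truth = render_depoly_movie(params)
    times = np.array(truth.frame_times_s)
    i0 = int(np.argmin(np.abs(times - t0_s)))
    i1 = int(np.argmin(np.abs(times - t1_s)))
    px = movie.pixel_size_um

    def projection(i: int) -> np.ndarray:
        frame = movie.frame(t=i)
        proj = max_project(frame, "z") if "z" in frame.axes else frame
        return proj.pixels

    # one shared scale and one shared Otsu threshold for both time points:
    # the mask (and the blur-driven extension of each filament's ends) must
    # mean the same thing at t0 and t1 so the extension cancels in the
    # length difference
    from skimage.filters import threshold_otsu

    imgs = [projection(i0), projection(i1)]
    scale = pooled_percentile_scale(imgs)
    normed = [robust_normalize(img, scale=scale) for img in imgs]
    thr = float(threshold_otsu(np.concatenate([n.ravel() for n in normed])))
    rec0, rec1 = (
        measure_lengths(n, px, threshold_method="fixed", threshold_value=thr)
        for n in normed
    )
    measurements, n_censored = match_filaments(
        rec0, rec1, t0_s=times[i0], t1_s=times[i1]
    )
    return shrinkage_rate(measurements, n_censored), params.shrink_rate_um_per_min


def spindle_sd_experiment(
    params: SpindleSimParams | None = None, seed: int = 0
) -> dict:
    """Simulate metaphase cells and measure their kinetochore distributions.

    Returns per-cell SD and AvgDist (µm) of perpendicular kinetochore
    distances to the fitted equator, their means, and the closed-form SD of
    the generative two-row mixture, √(sep²/4 + σ_perp²).
    """
    from dataclasses import replace

    params = params or SpindleSimParams()
    params = replace(params, seed=seed)
    sets, truth = simulate_spindle_cells(params)
    sds, avg_dists = [], []
    for kset in sets:
        line = fit_equator(kset)
        _, sd, avg = kinetochore_distances(kset, line)
        sds.append(sd)
        avg_dists.append(avg)
    expected_sd = float(
        np.sqrt(params.plate_separation_um**2 / 4 + params.sigma_perp_um**2)
    )
    return {
        "per_cell_sd_um": sds,
        "per_cell_avg_dist_um": avg_dists,
        "mean_sd_um": float(np.mean(sds)),
        "mean_avg_dist_um": float(np.mean(avg_dists)),
        "closed_form_sd_um": expected_sd,
        "n_cells": params.n_cells,
    }


def flux_recovery(
    params: FluxMovieParams | None = None, seed: int = 0
) -> tuple[FluxEstimate, float]:
    """Render a photobleach flux movie, estimate the rate, return truth too."""
    from dataclasses import replace

    params = params or FluxMovieParams()
    params = replace(params, seed=seed)
    movie, truth = render_flux_movie(params)
    h, w = movie.shape[-2], movie.shape[-1]
    px = movie.pixel_size_um
    y_mid = (h / 2) * px
    line = ((0.5 * px, y_mid), ((w - 0.5) * px, y_mid))
    est = estimate_flux(movie, line)
    return est, truth.flux_rate_um_per_min


def demo_report(seed: int = 0, scaled: bool = True) -> dict:
    """Run every stage on synthetic wild-type-like vs mutant-like groups.

    Produces the five metric families of the full study in one report:
    bundling fraction, shrinkage rate, kinetochore SD/AvgDist, SL/SW/KW,
    and poleward flux rate.  ``scaled`` uses reduced problem sizes for a
    fast run.
    """
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    report: dict = {"seed": seed}

    # 1. bundling: no-enzyme-like vs bundler-like conditions
    n_img = (3, 5) if scaled else (9, 24)
    base = FilamentFieldParams(
        field_size_um=(30.0, 30.0) if scaled else (65.0, 65.0), n_filaments=30
    )
    fractions, stats = bundling_experiment(
        {"MT-only": (0.0, n_img[0]), "bundler": (0.5, n_img[1])},
        base=base,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    report["bundling"] = {"per_image_fractions": fractions, "stats": stats.to_dict()}

    # 2. depolymerization rate recovery
    dp = DepolyMovieParams(
        field=FilamentFieldParams(
            field_size_um=(30.0, 30.0),
            length_range_um=(8.0, 12.0),
            n_filaments=12 if scaled else 50,
            n_z=1,
            z_step_um=0.25,
            min_separation_um=1.0,
        ),
        shrink_rate_um_per_min=0.6,
        duration_s=400.0,
        frame_interval_s=400.0,
    )
    summary, true_rate = depoly_recovery(dp, seed=int(rng.integers(0, 2**31 - 1)))
    report["depolymerization"] = {
        "mean_rate_um_per_min": summary.mean_rate_um_per_min,
        "sem_um_per_min": summary.sem_um_per_min,
        "n": summary.n,
        "n_censored": summary.n_censored,
        "true_rate_um_per_min": true_rate,
    }

    # 3. spindle geometry: control-like vs mutant-like kinetochore scatter
    n_cells = 8 if scaled else 31
    wt = spindle_sd_experiment(
        SpindleSimParams(n_cells=n_cells, sigma_perp_um=0.5),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    mut = spindle_sd_experiment(
        SpindleSimParams(n_cells=n_cells, sigma_perp_um=0.9),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    sd_stats = group_stats(
        {"WT-like": wt["per_cell_sd_um"], "mutant-like": mut["per_cell_sd_um"]}
    )
    report["spindle"] = {
        "WT-like": {k: wt[k] for k in ("mean_sd_um", "mean_avg_dist_um", "closed_form_sd_um")},
        "mutant-like": {k: mut[k] for k in ("mean_sd_um", "mean_avg_dist_um", "closed_form_sd_um")},
        "sd_stats": sd_stats.to_dict(),
    }

    # 4. spindle dimension metrics on one simulated cell with known poles
    from .spindle import KinetochoreSet, spindle_metrics

    cells, _ = simulate_spindle_cells(
        SpindleSimParams(
            n_cells=1, rotation_range_rad=0.0, translation_range_um=0.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    )
    poles = np.array([[0.0, -5.0], [0.0, 5.0]])
    m = spindle_metrics(cells[0], poles=poles)
    report["spindle_metrics_example"] = {
        "SL_um": m.SL, "KW_um": m.KW, "SD_um": m.SD, "AvgDist_um": m.AvgDist,
    }

    # 5. poleward flux recovery
    est, truth = flux_recovery(
        FluxMovieParams(flux_rate_um_per_min=0.9),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    report["flux"] = {
        "mean_rate_um_per_min": est.mean_rate_um_per_min,
        "per_mark_rates_um_per_min": list(est.rates_um_per_min),
        "true_rate_um_per_min": truth,
    }
    return report
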