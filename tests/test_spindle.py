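import math

import numpy as np
import pytest

from mtquant.spindle import (
    KinetochoreSet,
    fit_equator,
    kinetochore_distances,
    align_cells,
    spindle_metrics,
    score_lagging,
    select_metaphase,
)
from mtquant.synthetic import SpindleSimParams, simulate_spindle_cells


def rotate(points, theta, shift=(0.0, 0.0)):
    R = np.array([[math.cos(theta), -math.sin(theta)],
                  [math.sin(theta), math.cos(theta)]])
    return points @ R.T + np.asarray(shift)


def brute_force_tls_angle(points, step=1e-4):
    """Oracle: scan line angles, minimize Σ squared perpendicular distances."""
    pts = points - points.mean(axis=0)
    angles = np.arange(0.0, math.pi, step)
    normals = np.column_stack([-np.sin(angles), np.cos(angles)])
    cost = ((pts @ normals.T) ** 2).sum(axis=0)
    return angles[int(np.argmin(cost))]


# ------------------------------------------------------------ equator fit


def test_horizontal_points_give_x_axis_equator():
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [5.0, 0.0]])
    line = fit_equator(KinetochoreSet("c", pts))
    assert np.allclose(np.abs(line.direction), [1.0, 0.0])
    assert line.centroid[1] == pytest.approx(0.0)


def test_equator_fit_is_rotation_equivariant(rng):
    pts = rng.normal(0, 1, (30, 2)) * [3.0, 0.5]
    base = fit_equator(KinetochoreSet("c", pts))
    theta = 0.7
    rot = fit_equator(KinetochoreSet("c", rotate(pts, theta)))
    base_angle = math.atan2(base.direction[1], base.direction[0])
    rot_angle = math.atan2(rot.direction[1], rot.direction[0])
    assert (rot_angle - base_angle) % math.pi == pytest.approx(theta % math.pi, abs=1e-9)


def test_tls_fit_matches_brute_force_oracle(rng):
    for _ in range(100):
        pts = rng.normal(0, 1, (200, 2)) * rng.uniform(0.5, 4.0, 2)
        pts = rotate(pts, rng.uniform(0, math.pi))
        line = fit_equator(KinetochoreSet("c", pts))
        fitted = math.atan2(line.direction[1], line.direction[0]) % math.pi
        oracle = brute_force_tls_angle(pts)
        diff = min(abs(fitted - oracle), math.pi - abs(fitted - oracle))
        assert diff <= 1e-4 + 1e-9


def test_coincident_points_rejected():
    pts = np.tile([1.0, 2.0], (5, 1))
    with pytest.raises(ValueError):
        fit_equator(KinetochoreSet("c", pts))


# -------------------------------------------------------------- distances


def test_signed_distance_and_symmetric_pair():
    pts = np.array([[0.0, 1.0], [0.0, -1.0], [8.0, 1.0], [8.0, -1.0]])
    kset = KinetochoreSet("c", pts)
    line = fit_equator(kset)
    d, sd, avg = kinetochore_distances(kset, line)
    assert np.allclose(np.abs(d), 1.0)
    assert sd == pytest.approx(1.0)
    assert avg == pytest.approx(1.0)
    assert d.mean() == pytest.approx(0.0, abs=1e-12)


def test_per_cell_sd_matches_two_row_mixture_closed_form():
    """Mean per-cell SD ≈ √(sep²/4 + σ_perp²) for the two-row mixture.

    The population SD is taken about the *fitted* equator (a two-parameter
    line), so the closed-form mixture SD carries the finite-sample factor
    √((n−2)/n) for the two degrees of freedom the fit absorbs.
    """
    p = SpindleSimParams(n_cells=31, kinetochores_per_cell=20,
                         plate_separation_um=1.0, sigma_perp_um=0.5, seed=21)
    sets, _ = simulate_spindle_cells(p)
    sds = []
    for kset in sets:
        line = fit_equator(kset)
        _, sd, _ = kinetochore_distances(kset, line)
        sds.append(sd)
    sds = np.asarray(sds)
    n = p.kinetochores_per_cell
    closed_form = math.sqrt(p.plate_separation_um**2 / 4 + p.sigma_perp_um**2)
    expected = closed_form * math.sqrt((n - 2) / n)
    se = sds.std(ddof=1) / math.sqrt(len(sds))
    assert sds.mean() == pytest.approx(expected, abs=3 * se)


# -------------------------------------------------------------- alignment


def test_alignment_is_rigid_to_1e9():
    rng = np.random.default_rng(5)
    pts = rng.normal(0, 1, (20, 2)) * [3.0, 0.5] + [4.0, -2.0]
    pooled = align_cells([KinetochoreSet("c0", pts)])
    aligned = pooled[["x_um", "y_um"]].to_numpy()
    d_before = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    d_after = np.linalg.norm(aligned[:, None] - aligned[None, :], axis=-1)
    assert np.allclose(d_before, d_after, atol=1e-9)
    # centroid at origin, refitted equator along x
    assert np.allclose(aligned.mean(axis=0), 0.0, atol=1e-9)
    line = fit_equator(KinetochoreSet("c0", aligned))
    assert abs(line.direction[0]) == pytest.approx(1.0, abs=1e-9)


def test_rigid_copies_align_to_identical_clouds():
    rng = np.random.default_rng(6)
    pts = rng.normal(0, 1, (15, 2)) * [2.5, 0.4]
    moved = rotate(pts, 1.1, shift=(7.0, -3.0))
    pooled = align_cells(
        [KinetochoreSet("a", pts), KinetochoreSet("b", moved)]
    )
    a = pooled[pooled.cell_id == "a"][["x_um", "y_um"]].to_numpy()
    b = pooled[pooled.cell_id == "b"][["x_um", "y_um"]].to_numpy()
    # identical up to the ± direction convention
    assert np.allclose(a, b, atol=1e-9) or np.allclose(a, -b, atol=1e-9)


def test_isotropic_cell_skipped_with_warning():
    square = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    with pytest.warns(UserWarning, match="ambiguous"):
        pooled = align_cells([KinetochoreSet("iso", square)])
    assert pooled.empty


# ---------------------------------------------------------------- metrics


def test_spindle_length_from_poles():
    pts = np.array([[4.0, 0.5], [5.0, -0.5], [6.0, 0.5], [5.0, 0.4]])
    m = spindle_metrics(KinetochoreSet("c", pts),
                        poles=np.array([[0.0, 0.0], [10.0, 0.0]]))
    assert m.SL == pytest.approx(10.0)


def test_kw_matches_uniform_order_statistics_oracle(rng):
    """KW of U(−2, 2) projections approaches the 96% central range."""
    kws = []
    oracle = []
    for _ in range(20):
        x = rng.uniform(-2, 2, 200)
        pts = np.column_stack([x, rng.normal(0, 0.2, 200)])
        m = spindle_metrics(KinetochoreSet("c", pts),
                            poles=np.array([[-3.0, 0.0], [3.0, 0.0]]))
        kws.append(m.KW)
        lo, hi = np.percentile(rng.uniform(-2, 2, 200), [2, 98])
        oracle.append(hi - lo)
    se_diff = math.sqrt(
        np.var(kws, ddof=1) / len(kws) + np.var(oracle, ddof=1) / len(oracle)
    )
    assert np.mean(kws) == pytest.approx(np.mean(oracle), abs=3 * se_diff)
    assert np.mean(kws) == pytest.approx(3.84, abs=0.1)


def test_sw_matches_numeric_mask_oracle():
    """SW of a Gaussian tubulin band equals the rendered mask's own extent."""
    from mtquant.stack import ImageStack

    px = 0.1
    h = w = 200
    yy = (np.arange(h) + 0.5) * px
    sigma_s = 1.5
    band = np.exp(-((yy - 10.0) ** 2) / (2 * sigma_s**2))
    img = np.tile(band[:, None], (1, w)) * 100.0
    stack = ImageStack(pixels=img, axes="yx", pixel_size_um=px)
    pts = np.column_stack([np.linspace(5, 15, 10), np.full(10, 10.0)])
    poles = np.array([[2.0, 10.0], [18.0, 10.0]])
    m = spindle_metrics(KinetochoreSet("c", pts), poles=poles, tubulin=stack)
    # numeric oracle on the same half-max criterion
    mask_rows = yy[band >= 0.5 * band.max()]
    expected = mask_rows.max() - mask_rows.min()
    assert m.SW == pytest.approx(expected, abs=2 * px)
    # and the analytic FWHM for reference
    assert m.SW == pytest.approx(2 * sigma_s * math.sqrt(2 * math.log(2)), abs=0.15)


def test_metrics_invariant_under_rigid_motion(rng):
    pts = np.column_stack([rng.uniform(-2, 2, 50), rng.normal(0, 0.3, 50)])
    poles = np.array([[-4.0, 0.0], [4.0, 0.0]])
    m0 = spindle_metrics(KinetochoreSet("c", pts), poles=poles)
    theta, shift = 0.9, (5.0, -7.0)
    m1 = spindle_metrics(KinetochoreSet("c", rotate(pts, theta, shift)),
                         poles=rotate(poles, theta, shift))
    for attr in ("SL", "KW", "SD", "AvgDist"):
        assert getattr(m0, attr) == pytest.approx(getattr(m1, attr), abs=1e-9)


# ---------------------------------------------------------------- lagging


def test_lagging_scoring_boundary_conventions():
    poles = np.array([[0.0, 0.0], [10.0, 0.0]])
    near_poles = KinetochoreSet(
        "a", np.array([[0.3, 0.0], [9.6, 0.1]]), stage="anaphase")
    assert not score_lagging(near_poles, poles)
    midpoint = KinetochoreSet(
        "b", np.array([[0.3, 0.0], [5.0, 0.0]]), stage="anaphase")
    assert score_lagging(midpoint, poles)
    exactly_at = KinetochoreSet(
        "c", np.array([[2.0, 0.0]]), stage="anaphase")  # = 0.2·SL exactly
    assert not score_lagging(exactly_at, poles)
    with pytest.raises(ValueError):
        score_lagging(near_poles, None)


# -------------------------------------------------------------- metaphase


def _plate(separation, sigma=0.05, n=16, seed=0):
    rng = np.random.default_rng(seed)
    sign = np.where(np.arange(n) < n // 2, 1.0, -1.0)
    y = sign * separation / 2 + rng.normal(0, sigma, n)
    return KinetochoreSet("c", np.column_stack([rng.uniform(-3, 3, n), y]))


def test_tight_plate_is_metaphase():
    assert select_metaphase(_plate(1.0))


def test_wide_separation_is_not_metaphase():
    assert not select_metaphase(_plate(4.0))


def test_metaphase_classifier_accuracy_on_labeled_cells():
    """≥95% agreement with generative labels: 1.5 µm plates vs 6 µm
    anaphase-like separations, 100 cells each."""
    correct = 0
    for seed in range(100):
        meta_sets, _ = simulate_spindle_cells(SpindleSimParams(
            n_cells=1, plate_separation_um=1.5, sigma_perp_um=0.3, seed=seed))
        ana_sets, _ = simulate_spindle_cells(SpindleSimParams(
            n_cells=1, plate_separation_um=6.0, sigma_perp_um=0.3,
            seed=10_000 + seed))
        correct += select_metaphase(meta_sets[0])
        correct += not select_metaphase(ana_sets[0])
    assert correct >= 190
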