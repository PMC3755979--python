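import numpy as np
import pytest

from conftest import horizontal_segment, render_segments
from mtquant.spindle import fit_equator
from mtquant.synthetic import (
    DepolyMovieParams,
    FilamentFieldParams,
    FluxMovieParams,
    PlacementError,
    SpindleSimParams,
    flux_profile,
    render_depoly_movie,
    render_filament_field,
    render_flux_movie,
    simulate_spindle_cells,
)


# --------------------------------------------------------- filament fields


def test_fixed_seed_is_bit_identical():
    p = FilamentFieldParams(field_size_um=(20.0, 20.0), n_filaments=5, seed=42)
    s1, g1 = render_filament_field(p)
    s2, g2 = render_filament_field(p)
    assert np.array_equal(s1.pixels, s2.pixels)
    assert [s.x0 for s in g1.filament_segments] == [s.x0 for s in g2.filament_segments]


def test_no_emitters_renders_zero_stack():
    p = FilamentFieldParams(
        field_size_um=(10.0, 10.0), n_filaments=1, photons_per_um=0.0,
        background_photons=0.0, shot_noise=False,
    )
    stack, _ = render_filament_field(p)
    assert np.all(stack.pixels == 0)


def test_noise_free_peak_lies_on_centerline(small_field_params):
    p = small_field_params
    stack, truth = render_filament_field(p)
    seg = truth.filament_segments[0]
    img = stack.pixels[0]
    r, c = np.unravel_index(np.argmax(img), img.shape)
    # distance from the argmax pixel center to the segment's line
    x = (c + 0.5) * p.pixel_size_um
    y = (r + 0.5) * p.pixel_size_um
    d = np.abs(
        (seg.x1 - seg.x0) * (seg.y0 - y) - (seg.x0 - x) * (seg.y1 - seg.y0)
    ) / seg.length_um
    assert d <= p.pixel_size_um


def test_rendering_is_linear_in_coincident_filaments():
    p = FilamentFieldParams(field_size_um=(20.0, 20.0), n_filaments=1, n_z=1,
                            background_photons=0.0, shot_noise=False)
    one = render_segments([horizontal_segment(6.0)], p, None)
    two = render_segments([horizontal_segment(6.0), horizontal_segment(6.0, filament_id=1)], p, None)
    assert np.allclose(two, 2 * one, atol=1e-12)


def test_photon_conservation_noise_free():
    """Per-slice photon total = background·n_pixels + photons_per_um·Σ lengths."""
    p = FilamentFieldParams(field_size_um=(30.0, 30.0), n_filaments=10,
                            shot_noise=False, seed=5)
    stack, truth = render_filament_field(p)
    total_len = sum(s.length_um for s in truth.filament_segments)
    one_slice = stack.pixels[0]
    expected = p.background_photons * one_slice.size + p.photons_per_um * total_len
    assert one_slice.sum() == pytest.approx(expected, rel=1e-3)


def test_ground_truth_bijection():
    p = FilamentFieldParams(field_size_um=(40.0, 40.0), n_filaments=12,
                            bundle_fraction=0.5, bundle_size=4, seed=2)
    _, truth = render_filament_field(p)
    segs = truth.filament_segments
    assert len(segs) == p.n_filaments
    assert len({s.filament_id for s in segs}) == p.n_filaments
    n_bundled = sum(1 for s in segs if s.bundle_id is not None)
    assert n_bundled == 4  # round(0.5·12) // 4 bundles × 4 members
    for s in segs:
        assert s.length_um == pytest.approx(
            np.hypot(s.x1 - s.x0, s.y1 - s.y0)
        )


def test_oversized_filament_raises_placement_error():
    p = FilamentFieldParams(field_size_um=(10.0, 10.0), n_filaments=1,
                            length_range_um=(50.0, 50.0))
    with pytest.raises(PlacementError, match="50"):
        render_filament_field(p)


def test_min_separation_respected():
    from shapely.geometry import LineString

    p = FilamentFieldParams(field_size_um=(40.0, 40.0), n_filaments=10,
                            min_separation_um=1.5, seed=3)
    _, truth = render_filament_field(p)
    lines = [LineString([(s.x0, s.y0), (s.x1, s.y1)]) for s in truth.filament_segments]
    for i in range(len(lines)):
        for j in range(i + 1, len(lines)):
            assert lines[i].distance(lines[j]) >= 1.5


# ------------------------------------------------------------ depoly movie


def _tiny_depoly(rate, duration_s=400.0, frame_interval_s=100.0, **field_kw):
    field = FilamentFieldParams(
        field_size_um=(20.0, 20.0), n_filaments=2, n_z=1, shot_noise=False,
        length_range_um=(8.0, 10.0), min_separation_um=1.0, **field_kw,
    )
    return DepolyMovieParams(field=field, shrink_rate_um_per_min=rate,
                             duration_s=duration_s, frame_interval_s=frame_interval_s)


def test_zero_shrink_rate_gives_static_movie():
    movie, _ = render_depoly_movie(_tiny_depoly(0.0))
    for k in range(1, movie.shape[0]):
        assert np.array_equal(movie.pixels[k], movie.pixels[0])


def test_true_length_follows_linear_retraction():
    _, truth = render_depoly_movie(_tiny_depoly(0.6))
    seg0 = truth.filament_segments[0]
    seg_at_400 = [s for s in truth.segments_at(400.0) if s.filament_id == seg0.filament_id][0]
    assert seg_at_400.length_um == pytest.approx(seg0.length_um - 0.6 * 400 / 60)
    # midpoint is preserved (both ends retract symmetrically)
    assert seg_at_400.midpoint == pytest.approx(seg0.midpoint)


def test_fully_depolymerized_filament_vanishes():
    # 2 µm/min × (400/60) min = 13.3 µm loss > any initial length
    p = _tiny_depoly(2.0)
    movie, truth = render_depoly_movie(p)
    assert truth.segments_at(400.0) == []
    last = movie.pixels[-1]
    assert last.sum() == pytest.approx(
        p.field.background_photons * last.size
    )


# ------------------------------------------------------------ spindle sim


def test_zero_scatter_puts_kinetochores_on_two_rows():
    p = SpindleSimParams(n_cells=3, sigma_perp_um=0.0, sigma_par_um=1.0,
                         plate_separation_um=1.0, rotation_range_rad=0.0,
                         translation_range_um=0.0, seed=0)
    sets, truth = simulate_spindle_cells(p)
    for kset, cell in zip(sets, truth.kinetochore_truth):
        # equator is the x-axis; perpendicular offsets exactly ±0.5
        assert np.allclose(np.abs(kset.points[:, 1]), 0.5)
        assert np.allclose(cell.equator.direction, [1.0, 0.0])


def test_pooled_sd_matches_generative_sigma():
    """Pooled perpendicular scatter about the true rows ~ N(0, σ_perp)."""
    p = SpindleSimParams(n_cells=31, kinetochores_per_cell=20,
                         sigma_perp_um=0.5, seed=11)
    sets, truth = simulate_spindle_cells(p)
    n_kt = p.kinetochores_per_cell
    row_sign = np.where(np.arange(n_kt) < n_kt // 2, 1.0, -1.0)
    resid = []
    for cell in truth.kinetochore_truth:
        resid.extend(cell.perp_offsets_um - row_sign * p.plate_separation_um / 2)
    resid = np.asarray(resid)
    n = resid.size
    se = p.sigma_perp_um / np.sqrt(2 * (n - 1))
    assert resid.std() == pytest.approx(p.sigma_perp_um, abs=3 * se)


def test_ground_truth_line_matches_fitted_line():
    p = SpindleSimParams(n_cells=5, sigma_perp_um=0.1, sigma_par_um=3.0, seed=4)
    sets, truth = simulate_spindle_cells(p)
    for kset, cell in zip(sets, truth.kinetochore_truth):
        line = fit_equator(kset)
        cosang = abs(float(line.direction @ cell.equator.direction))
        assert cosang > 0.999


# ------------------------------------------------------------- flux movie


def test_zero_flux_movie_is_static():
    p = FluxMovieParams(flux_rate_um_per_min=0.0, shot_noise=False)
    movie, _ = render_flux_movie(p)
    for k in range(1, p.n_frames):
        assert np.array_equal(movie.pixels[k], movie.pixels[0])


def test_mark_center_moves_at_flux_rate():
    p = FluxMovieParams(flux_rate_um_per_min=1.2, frame_interval_s=5.0,
                        shot_noise=False)
    # 1.2 µm/min over 5 s = 0.1 µm per frame, toward the nearer pole
    x = np.linspace(-4, 4, 2001)
    for t, expected_shift in ((0.0, 0.0), (5.0, 0.1), (10.0, 0.2)):
        prof = flux_profile(p, x, t)
        band = p.peak_photons * np.exp(-(x**2) / (2 * p.spindle_sigma_um**2))
        dip = prof / band
        right = x[x > 0]
        c = right[np.argmin(dip[x > 0])]
        assert c == pytest.approx(2.0 + expected_shift, abs=0.005)


def test_full_depth_bleach_is_exactly_zero_at_center():
    p = FluxMovieParams(bleach_depth=1.0, shot_noise=False)
    assert flux_profile(p, p.bleach_positions_um[0], 0.0) == pytest.approx(0.0)


def test_bleach_outside_field_rejected():
    with pytest.raises(ValueError, match="outside"):
        FluxMovieParams(bleach_positions_um=(-30.0, 2.0))
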