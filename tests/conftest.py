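import numpy as np
import pytest

from mtquant.synthetic import FilamentFieldParams, FilamentSegment, _render_field_stack


@pytest.fixture
def small_field_params():
    """Small noise-free field parameters for fast rendering tests."""
    return FilamentFieldParams(
        field_size_um=(20.0, 20.0), n_filaments=1, n_z=1, shot_noise=False
    )


def render_segments(segments, params, rng=None):
    """Render explicit segments through the field renderer (test helper)."""
    return _render_field_stack(list(segments), params, rng)


def horizontal_segment(length_um, cx=10.0, cy=10.0, filament_id=0):
    return FilamentSegment(
        filament_id=filament_id,
        x0=cx - length_um / 2, y0=cy, x1=cx + length_um / 2, y1=cy,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
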