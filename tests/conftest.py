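"""Shared fixtures: a scaled-down phantom everything fast runs on.

The mini phantom keeps the real sheet/grid proportions (15 mm pitch,
7.6 mm sheets, 9 mm gaps, 2 mm bars) but only 3 sheets of 5x5 points in a
12 cm box, so a full volume rasterizes and processes in about a second.
The matching mini distortion model scales the study field's amplitude with
the lattice extent, preserving the field gradients of the full-size study.
"""

import logging

import numpy as np
import pytest

from mrdistcorr import (
    DistortionModel,
    PhantomGeometry,
    add_noise_and_bubbles,
    apply_bias_field,
    extract_control_points,
    rasterize_phantom,
    warp_volume,
)

logging.getLogger("mrdistcorr").setLevel(logging.ERROR)

MINI_NOISE = 45.0  # 5% of the oil-grid intensity difference


@pytest.fixture(scope="session")
def mini_geo():
    return PhantomGeometry(n_sheets=3, points_per_row=5, box_inner_mm=(120.0, 120.0, 100.0))


@pytest.fixture(scope="session")
def mini_lattice_half(mini_geo):
    g = mini_geo
    return (
        (g.points_per_row - 1) / 2 * g.point_pitch_mm,
        (g.points_per_row - 1) / 2 * g.point_pitch_mm,
        (g.n_sheets - 1) / 2 * g.sheet_pitch_mm,
    )


@pytest.fixture(scope="session")
def mini_model():
    # normalized over the box (not just the small lattice) so the field
    # stays tame everywhere the mini phantom's images have structure; the
    # harmonic is dropped — three sheets cannot sample it
    m = DistortionModel.default_study(
        scale=0.35, with_b0=False, half_extents=(60.0, 60.0, 50.0)
    )
    m.harmonics = ()
    return m


@pytest.fixture(scope="session")
def mini_nominal(mini_geo):
    return mini_geo.nominal_lattice()


@pytest.fixture(scope="session")
def mini_mr(mini_geo):
    return rasterize_phantom(mini_geo, (1.0, 1.0, 1.0), "MR")


@pytest.fixture(scope="session")
def mini_ct(mini_geo):
    return rasterize_phantom(mini_geo, (1.0, 1.0, 1.0), "CT")


@pytest.fixture(scope="session")
def mini_mr_degraded(mini_geo, mini_mr):
    v = apply_bias_field(mini_mr, 0.3, seed=5)
    return add_noise_and_bubbles(v, MINI_NOISE, 5, seed=7, geometry=mini_geo)


@pytest.fixture(scope="session")
def mini_mr_points(mini_mr):
    return extract_control_points(mini_mr)


@pytest.fixture(scope="session")
def mini_ct_points(mini_ct):
    return extract_control_points(mini_ct)


@pytest.fixture(scope="session")
def mini_warped(mini_mr, mini_model):
    return warp_volume(mini_mr, mini_model)


def nearest_errors(found: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Distance from each found point to its nearest reference point."""
    from scipy.spatial import cKDTree

    d, _ = cKDTree(reference).query(found)
    return d
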