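"""Shared fixtures: small analytic flow domains and generated boundaries."""

from __future__ import annotations

import numpy as np
import pytest

from trabflow.geometry import (GeometryParams, MotionModel,
                               generate_groove, generate_ventricle)


def rect_shell(length: float, height: float, dx: float) -> np.ndarray:
    """Counter-clockwise rectangle boundary with node spacing ~dx."""
    nx = max(3, int(round(length / dx)))
    ny = max(3, int(round(height / dx)))
    xs = np.linspace(0, length, nx + 1)
    ys = np.linspace(0, height, ny + 1)
    bottom = np.column_stack([xs[:-1], np.zeros(nx)])
    right = np.column_stack([np.full(ny, length), ys[:-1]])
    top = np.column_stack([xs[::-1][:-1], np.full(nx, height)])
    left = np.column_stack([np.zeros(ny), ys[::-1][:-1]])
    return np.vstack([bottom, right, top, left])


@pytest.fixture(scope="session")
def ventricle():
    return generate_ventricle(seed=1)


@pytest.fixture(scope="session")
def groove():
    return generate_groove(seed=0)


@pytest.fixture(scope="session")
def coarse_motion():
    """Fast 8-frame cycle for solver-level tests."""
    return MotionModel(n_frames=8)


@pytest.fixture(scope="session")
def coarse_groove(coarse_motion):
    return generate_groove(GeometryParams(), coarse_motion, seed=0,
                           node_spacing=0.9)
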