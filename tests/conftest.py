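import numpy as np
import pytest

import axonstrain as ax


@pytest.fixture
def unit_cube_mesh():
    """One unit-cube element, [0,1]^3."""
    return ax.make_box_mesh(1, 1, 1, 1.0)


@pytest.fixture
def box_mesh():
    """3x3x3 box at 1 mm spacing."""
    return ax.make_box_mesh(3, 3, 3, 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def random_affine_matrix(rng, scale=0.3):
    """A well-conditioned affine deformation matrix near identity."""
    return np.eye(3) + rng.uniform(-scale, scale, (3, 3))


def affine_history(mesh, A, times=(0.0, 1.0)):
    """Displacement history applying u = (A - I) X ramped linearly in time."""
    times = np.asarray(times, dtype=float)
    X = mesh.node_coords
    disp = np.stack([t / times[-1] * (X @ (A - np.eye(3)).T) for t in times])
    return ax.DisplacementHistory(times=times, displacements=disp)


def rigid_history(mesh, rng, times=(0.0, 0.5, 1.0)):
    """Random rigid rotation + translation ramped over time."""
    from axonstrain.synth import _rotation_matrix

    axis = rng.normal(size=3)
    angle = rng.uniform(0.2, 1.2)
    trans = rng.uniform(-3, 3, 3)
    times = np.asarray(times, dtype=float)
    X = mesh.node_coords
    disp = []
    for t in times:
        f = t / times[-1]
        R = _rotation_matrix(axis, f * angle)
        disp.append(X @ R.T + f * trans - X)
    return ax.DisplacementHistory(times=times, displacements=np.stack(disp))
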