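import numpy as np
import pytest

from microglia3d import AcquisitionGeometry
from microglia3d.synthetic import control_params, generate_scene, render_stack


@pytest.fixture(scope="session")
def small_geometry():
    """A fast desk-scale field (50 x 50 x 28 um) at the default pitch."""
    return AcquisitionGeometry(nx=160, ny=160, nz=28, dx=319.45 / 1024, dy=319.45 / 1024, dz=1.0)


@pytest.fixture(scope="session")
def small_scene(small_geometry):
    params = control_params(geometry=small_geometry, n_cells=6, n_vessels=1)
    return generate_scene(params, seed=3)


@pytest.fixture(scope="session")
def small_rendered(small_scene):
    return render_stack(small_scene)


@pytest.fixture(scope="session")
def trained_classifier(small_rendered):
    """A classifier trained on the small scene with the annotation protocol."""
    from microglia3d.classify import train_classifier
    from microglia3d.synthetic import annotate_scene

    stack, truth = small_rendered
    labels = annotate_scene(truth, n_per_class=200, seed=5)
    return train_classifier(stack.channel(0), labels, seed=0)


def digitized_ball(radius_vox, shape=None, spacing=(1.0, 1.0, 1.0), center=None):
    """Binary ball: voxel centres within radius (index units per axis)."""
    if shape is None:
        n = int(2 * radius_vox + 5)
        shape = (n, n, n)
    if center is None:
        center = tuple((s - 1) / 2 for s in shape)
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    return d2 <= radius_vox**2


def digitized_disk(radius_px, shape=None, center=None):
    if shape is None:
        n = int(2 * radius_px + 5)
        shape = (n, n)
    if center is None:
        center = tuple((s - 1) / 2 for s in shape)
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px**2
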