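import numpy as np
import pytest

from calfluct.geometry import LabelVolume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_phase_volume():
    """Random astrocyte blob in ECS on a small anisotropic grid."""
    gen = np.random.default_rng(7)
    labels = np.zeros((14, 14, 8), dtype=np.int16)
    # connected blob grown from the center
    blob = {(7, 7, 4)}
    frontier = [(7, 7, 4)]
    while len(blob) < 120 and frontier:
        x, y, z = frontier[gen.integers(len(frontier))]
        dx, dy, dz = gen.choice([(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)])
        nx, ny, nz = x + dx, y + dy, z + dz
        if 0 <= nx < 14 and 0 <= ny < 14 and 0 <= nz < 8:
            blob.add((nx, ny, nz))
            frontier.append((nx, ny, nz))
    for x, y, z in blob:
        labels[x, y, z] = 1
    return LabelVolume(labels, (6.0, 6.0, 30.0), {0: "ecs", 1: "astro"})


@pytest.fixture
def wrapped_bouton_volume():
    """Bouton sphere fully wrapped by an astrocyte shell exactly one ECS
    voxel away (face-dilation rings), on an isotropic grid."""
    from scipy import ndimage

    n = 31
    pitch = 10.0
    labels = np.zeros((n, n, n), dtype=np.int16)
    c = (n // 2 + 0.5) * pitch
    x = (np.arange(n) + 0.5) * pitch
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    r = np.sqrt((X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2)
    bouton = r <= 60
    cross = ndimage.generate_binary_structure(3, 1)
    d1 = ndimage.binary_dilation(bouton, cross)
    d3 = ndimage.binary_dilation(bouton, cross, iterations=3)
    labels[d3 & ~d1] = 1  # astro shell starting 1 face-voxel away
    labels[bouton] = 2
    return LabelVolume(labels, (pitch,) * 3, {0: "ecs", 1: "astro", 2: "bouton"})
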