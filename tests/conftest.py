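"""Shared fixtures: phantom volumes, oracle meshes, and a trained toy model.

Everything is generated programmatically and seeded; the trained network is
session-scoped because CPU training dominates the suite's runtime.
"""

from __future__ import annotations

import numpy as np
import pytest

from aaastress.nema import LoadCase
from aaastress.phantom import (FusiformSpec, make_cylinder_mesh,
                               make_sphere_mesh, make_volume,
                               normalize_images)


@pytest.fixture(scope="session")
def disk_mask():
    """64x64 binary disk of radius 20 px centred at (32, 32)."""
    yy, xx = np.mgrid[0:64, 0:64]
    return (np.hypot(xx - 32, yy - 32) <= 20).astype(np.uint8)


@pytest.fixture(scope="session")
def fusiform_spec():
    return FusiformSpec(noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def fusiform_volume(fusiform_spec):
    return make_volume(fusiform_spec)


@pytest.fixture(scope="session")
def load_case():
    return LoadCase(pressure_mmHg=93.3, thickness_mm=1.5)


@pytest.fixture(scope="session")
def cylinder_mesh():
    """R = 1.5 cm, L = 6 cm open tube, ~4.6k elements."""
    return make_cylinder_mesh(1.5, 6.0, n_theta=48, n_z=49)


@pytest.fixture(scope="session")
def sphere_mesh():
    return make_sphere_mesh(1.5, subdivisions=3)


@pytest.fixture(scope="session")
def overfit_run():
    """Train the toy-scale network to overfit 10 noiseless-ish phantom
    slices; shared across the smoke tests (training dominates runtime)."""
    from aaastress.segmentation import TOY_CONFIG, train

    spec = FusiformSpec(n_slices=10, grid=64, pixel_size=1.6, z0=5,
                        noise_sd=10.0, seed=42)
    images, masks, _ = make_volume(spec)
    images = normalize_images(images)
    dataset = [(images[i], masks[i]) for i in range(len(images))]
    model, history = train(TOY_CONFIG, dataset)
    return {"model": model, "history": history, "images": images,
            "masks": masks, "dataset": dataset}
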