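"""Shared fixtures: calibrated geometries and small rendered phantom samples.

Unit tests run on reduced problem sizes (64x64 detectors, 48^3 phantoms) so
the whole suite stays fast; the end-to-end tests use the full desk-scale
configuration.
"""

from __future__ import annotations

import numpy as np
import pytest

from spinepose.geometry import CameraGeometry, build_projection
from spinepose.phantom import (AcquisitionConfig, DatasetConfig, PhantomConfig,
                               _render_sample, make_phantom)

LUMBAR_DETECTOR = dict(detector_size_mm=(450.0, 300.0), detector_pixels=(1536, 1024))


@pytest.fixture(scope="session")
def lumbar_ap():
    return CameraGeometry("AP", 2000.0, 1000.0, 0.0, **LUMBAR_DETECTOR)


@pytest.fixture(scope="session")
def lumbar_lat():
    return CameraGeometry("LAT", 2000.0, 1000.0, 0.0, **LUMBAR_DETECTOR)


@pytest.fixture(scope="session")
def lumbar_pair(lumbar_ap, lumbar_lat):
    return build_projection(lumbar_ap), build_projection(lumbar_lat)


@pytest.fixture(scope="session")
def tiny_config() -> DatasetConfig:
    """Reduced rendering configuration for fast unit tests."""
    return DatasetConfig(
        phantom=PhantomConfig(grid_shape=(48, 48, 48), voxel_spacing_mm=4.0),
        acquisition=AcquisitionConfig(detector_pixels=(64, 64)),
        phantoms_per_split=(2, 1, 1),
        pairs_per_phantom=1,
        n_vertebrae=3,
        drr_step_mm=2.0,
    )


@pytest.fixture(scope="session")
def tiny_sample(tiny_config):
    """One rendered biplanar sample at the reduced scale."""
    phantom = make_phantom(3, seed=7, config=tiny_config.phantom)
    return _render_sample(phantom, pose_seed=11, sample_id="tiny0", cfg=tiny_config)


@pytest.fixture(scope="session")
def tiny_samples(tiny_config):
    """Four reduced-scale samples drawn from two phantoms."""
    out = []
    for pid, phantom_seed in enumerate((7, 8)):
        phantom = make_phantom(3, seed=phantom_seed, config=tiny_config.phantom)
        for j in range(2):
            out.append(_render_sample(phantom, pose_seed=20 + 10 * pid + j,
                                      sample_id=f"p{pid}s{j}", cfg=tiny_config))
    return out
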