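"""Shared fixtures: configurations, phantoms, and the expensive shared scans."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cbctmotion as cm

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cfg() -> cm.PhantomConfig:
    return cm.default_config()


@pytest.fixture(scope="session")
def static_volume(default_cfg) -> cm.VoxelVolume:
    return cm.build_phantom(default_cfg)


@pytest.fixture(scope="session")
def small_cube_volume() -> cm.VoxelVolume:
    """A 30 mm attenuating cube centered in a 48^3 grid (2 mm voxels)."""
    values = np.zeros((48, 48, 48))
    values[17:32, 17:32, 17:32] = 0.02
    origin = tuple(-(48 - 1) / 2.0 * 2.0 for _ in range(3))
    return cm.VoxelVolume(values=values, spacing=2.0, origin=origin)


@pytest.fixture(scope="session")
def small_protocol() -> cm.ScanProtocol:
    """A quick full-fan short scan matched to the small cube volume."""
    return cm.ScanProtocol(
        mode="full_fan", arc_deg=220.0, duration_s=30.0, n_projections=100,
        nu=64, nv=64, pitch=3.0,
    )


@pytest.fixture(scope="session")
def static_fullfan_recon(default_cfg, static_volume) -> cm.VoxelVolume:
    """Static-phantom full-fan acquisition and FDK reconstruction (default protocol)."""
    protocol = cm.ScanProtocol.full_fan()
    projections = cm.forward_project(static_volume, cm.static(), protocol)
    return cm.fdk_reconstruct(projections, grid=default_cfg)


@pytest.fixture(scope="session")
def static_fullfan_desk_recon(default_cfg, static_volume) -> cm.VoxelVolume:
    """Desk-scale static full-fan reconstruction (shared by motion cross-checks)."""
    protocol = cm.ScanProtocol.full_fan(desk_scale=True)
    projections = cm.forward_project(static_volume, cm.static(), protocol)
    return cm.fdk_reconstruct(projections, grid=default_cfg)
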