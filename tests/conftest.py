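"""Shared fixtures: the two frozen reference cases, tracked and solved once."""

import numpy as np
import pytest

import clotfield as cf
from clotfield import pipeline
from clotfield.config import (
    build_case,
    default_aneurysm_config,
    default_control_config,
)


@pytest.fixture(scope="session")
def control_cfg():
    return default_control_config()


@pytest.fixture(scope="session")
def aneurysm_cfg():
    return default_aneurysm_config()


@pytest.fixture(scope="session")
def control_case(control_cfg):
    return build_case(control_cfg)


@pytest.fixture(scope="session")
def aneurysm_case(aneurysm_cfg):
    return build_case(aneurysm_cfg)


@pytest.fixture(scope="session")
def control_tracking(control_cfg, control_case):
    return pipeline.track(control_cfg, control_case)


@pytest.fixture(scope="session")
def aneurysm_tracking(aneurysm_cfg, aneurysm_case):
    return pipeline.track(aneurysm_cfg, aneurysm_case)


@pytest.fixture(scope="session")
def control_result(control_cfg):
    return pipeline.run_case(control_cfg)


@pytest.fixture(scope="session")
def aneurysm_result(aneurysm_cfg):
    return pipeline.run_case(aneurysm_cfg)


@pytest.fixture()
def channel_mesh():
    return cf.build_channel_mesh(2.0, 0.15, 0.05)


@pytest.fixture()
def steady_poiseuille(channel_mesh):
    """Steady (zero-pulsatility) Poiseuille flow, U = 10 cm/s, T = 0.8 s."""
    return cf.make_pulsatile_poiseuille(channel_mesh, 10.0, 0.0, 0.8, 20)


def make_constant_field(mesh, u=(1.0, 0.0), period=1.0, n_frames=4):
    """Uniform steady velocity field (not physical at walls; test scaffolding)."""
    frames = np.tile(np.asarray(u, float), (n_frames, len(mesh.nodes), 1))
    times = np.arange(n_frames) * period / n_frames
    return cf.TimePeriodicVelocityField(mesh, frames, period, times)
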