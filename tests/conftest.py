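"""Shared fixtures: light-ligand toy systems sized for fast sampling.

Simulation fixtures use a 10 amu ligand and 5-10 fs time steps so that
diffusion across the ~20 Å toy box takes hundreds of ps instead of the
tens of ns a fragment-mass ligand would need; the physics under test
(supervision logic, thermostat statistics, bias deposition) is
unchanged by the mass.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sumdkit.dynamics import DynamicsConfig, State
from sumdkit.toy_system import (
    Confinement,
    GaussianBarrier,
    GaussianWell,
    ToySystem,
    build_scenario,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

LIGHT = {"ligand_mass": 10.0}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def binder_2d():
    return build_scenario("binder", {**LIGHT, "confinement.half_length": 18.0}, dims=2)


@pytest.fixture
def pam_2d():
    return build_scenario("pam", {**LIGHT, "confinement.half_length": 20.0}, dims=2)


@pytest.fixture
def flat_2d():
    """Flat potential inside the box (zero-depth well)."""
    return build_scenario(
        "diffusive", {**LIGHT, "wells.*.depth": 0.0, "confinement.half_length": 15.0},
        dims=2,
    )


@pytest.fixture
def harmonic_1d():
    """Pure harmonic trap via a zero-half-length confinement."""
    return ToySystem(
        dims=1,
        wells=[],
        barriers=[],
        orthosteric_center=[0.0],
        ligand_mass=10.0,
        confinement=Confinement(half_length=0.0, spring_constant=5.0),
    )


@pytest.fixture
def double_well_1d():
    """Symmetric 1-D double well with a ~1 kcal/mol central barrier."""
    return ToySystem(
        dims=1,
        wells=[
            GaussianWell((-1.5,), 1.8, 0.8),
            GaussianWell((1.5,), 1.8, 0.8),
        ],
        barriers=[],
        orthosteric_center=(-1.5,),
        ligand_mass=10.0,
        confinement=Confinement(half_length=4.0, spring_constant=10.0),
    )


@pytest.fixture
def fast_dyn():
    return DynamicsConfig(dt=0.01, temperature=310.0, friction=1.0, sample_stride=20)


def shell_start(system, distance, rng, temperature=310.0):
    """Random start on a shell around the orthosteric center."""
    from sumdkit.dynamics import sample_velocities

    direction = rng.normal(size=system.dims)
    direction /= np.linalg.norm(direction)
    return State(
        position=system.orthosteric_center + distance * direction,
        velocity=sample_velocities(system, temperature, rng),
    )
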