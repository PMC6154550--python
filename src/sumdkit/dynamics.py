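"""Langevin dynamics for the ligand pseudo-particle.

Integration uses the BAOAB splitting of the Langevin equation, which
gives accurate configurational sampling at comparatively large time
steps.  In the zero-friction, zero-temperature limit the scheme reduces
to velocity Verlet, so ballistic and energy-conservation checks are
exact limits of the same code path.

Default thermostat settings mirror a typical membrane-protein MD
production setup: 310 K, 2 fs time step, 1 ps^-1 friction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .constants import DEFAULT_TEMPERATURE, KB
from .toy_system import ToySystem

__all__ = [
    "DynamicsConfig",
    "State",
    "TrajectorySegment",
    "sample_velocities",
    "run_segment",
]


@dataclass(frozen=True)
class DynamicsConfig:
    """Integrator and thermostat settings.

    Parameters
    ----------
    dt
        Integration time step, ps (default 0.002 ps = 2 fs).
    temperature
        Thermostat temperature, K.
    friction
        Langevin friction (collision) rate, ps^-1.
    sample_stride
        Record a frame (and the ligand-site distance) every this many
        steps; the segment's first and last steps are always recorded.
    rng_seed
        Seed used when no explicit random generator is passed.
    """

    dt: float = 0.002
    temperature: float = DEFAULT_TEMPERATURE
    friction: float = 1.0
    sample_stride: int = 50
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.friction < 0:
            raise ValueError("friction must be >= 0")
        if self.sample_stride < 1:
            raise ValueError("sample_stride must be >= 1")


@dataclass(frozen=True)
class State:
    """Instantaneous ligand state: position (Å), velocity (Å/ps), time (ps)."""

    position: np.ndarray
    velocity: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "velocity", np.asarray(self.velocity, dtype=float))
        if self.position.shape != self.velocity.shape:
            raise ValueError("position and velocity must have the same shape")
        if self.time < 0:
            raise ValueError("time must be >= 0")


@dataclass
class TrajectorySegment:
    """Sampled frames of one simulation window.

    ``distances`` holds the ligand distance to the system's orthosteric
    center at each recorded frame; ``cv_values`` is populated only by
    metadynamics runs.
    """

    times: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    potential_energies: np.ndarray
    distances: np.ndarray
    cv_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.times)
        if n < 1:
            raise ValueError("segment must contain at least one frame")
        for name in ("positions", "velocities", "potential_energies", "distances"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match times")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def final_state(self) -> State:
        return State(
            position=self.positions[-1].copy(),
            velocity=self.velocities[-1].copy(),
            time=float(self.times[-1]),
        )

    def first_arrival_time(self, threshold: float) -> float | None:
        """Time of the first recorded frame with distance < threshold."""
        below = np.nonzero(self.distances < threshold)[0]
        if below.size == 0:
            return None
        return float(self.times[below[0]])


class IntegrationError(RuntimeError):
    """Raised when the integrator encounters a non-finite energy."""


def _resolve_rng(rng, config: DynamicsConfig) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(config.rng_seed)


def sample_velocities(
    system: ToySystem, temperature: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw a Maxwell-Boltzmann velocity vector for the ligand.

    Each Cartesian component is an independent normal with variance
    ``kB * T / m``; at T = 0 the result is the zero vector.
    """
    if temperature < 0:
        raise ValueError("temperature must be >= 0")
    if temperature == 0:
        return np.zeros(system.dims)
    sigma = math.sqrt(KB * temperature / system.ligand_mass)
    return rng.normal(0.0, sigma, size=system.dims)


def run_segment(
    system: ToySystem,
    start: State,
    duration: float,
    config: DynamicsConfig,
    rng: np.random.Generator | None = None,
    *,
    extra_force: Callable[[np.ndarray, float], np.ndarray] | None = None,
    step_hook: Callable[[int, np.ndarray], None] | None = None,
) -> TrajectorySegment:
    """Integrate Langevin dynamics for ``round(duration/dt)`` steps.

    The first recorded frame equals ``start``.  ``extra_force(position,
    time)`` adds a time-dependent force on top of the system force (used
    by metadynamics); ``step_hook(step_index, position)`` is called
    after every completed step.

    Raises
    ------
    IntegrationError
        If a non-finite potential energy is encountered; the message
        carries the offending step index.
    """
    if start.position.shape != (system.dims,):
        raise ValueError("start state does not match system dimensionality")
    n_steps = int(round(duration / config.dt))
    if n_steps < 1:
        raise ValueError("duration must be at least one time step")

    rng = _resolve_rng(rng, config)
    dt = config.dt
    m = system.ligand_mass
    half_dt_over_m = 0.5 * dt / m
    c1 = math.exp(-config.friction * dt)
    c2 = math.sqrt(KB * config.temperature / m * (1.0 - c1 * c1))
    stochastic = c2 > 0.0
    stride = config.sample_stride

    x = start.position.astype(float).copy()
    v = start.velocity.astype(float).copy()
    t = float(start.time)

    def total_force(pos: np.ndarray, time: float) -> np.ndarray:
        f = system.force(pos)
        if extra_force is not None:
            f = f + extra_force(pos, time)
        return f

    times = [t]
    positions = [x.copy()]
    velocities = [v.copy()]
    energies = [system.potential_energy(x)]
    distances = [system.distance_to_site(x)]
    if not math.isfinite(energies[0]):
        raise IntegrationError("non-finite potential energy at step 0")

    f = total_force(x, t)
    for step in range(1, n_steps + 1):
        # BAOAB: half kick, half drift, friction/noise, half drift, half kick
        v += half_dt_over_m * f
        x += 0.5 * dt * v
        if stochastic:
            v = c1 * v + c2 * rng.standard_normal(system.dims)
        else:
            v = c1 * v
        x += 0.5 * dt * v
        t = start.time + step * dt
        f = total_force(x, t)
        v += half_dt_over_m * f

        if step_hook is not None:
            step_hook(step, x)

        if step % stride == 0 or step == n_steps:
            pe = system.potential_energy(x)
            if not math.isfinite(pe):
                raise IntegrationError(f"non-finite potential energy at step {step}")
            times.append(t)
            positions.append(x.copy())
            velocities.append(v.copy())
            energies.append(pe)
            distances.append(system.distance_to_site(x))

    return TrajectorySegment(
        times=np.asarray(times),
        positions=np.asarray(positions),
        velocities=np.asarray(velocities),
        potential_energies=np.asarray(energies),
        distances=np.asarray(distances),
    )
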