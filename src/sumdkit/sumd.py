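"""Supervised molecular dynamics (SuMD): tabu-like adaptive sampling.

The method runs consecutive short unbiased MD windows while monitoring
the distance between the ligand and binding-site centers of mass.
After each window the collected distance points are fitted with a
linear function; a negative slope (ligand approaching) means the next
window continues from the final coordinates and velocities, otherwise
the window is discarded: coordinates are restored to the window's start
and velocities are re-drawn from the Maxwell-Boltzmann distribution.
Supervision repeats until the distance drops below the arrival
threshold (default 5 Å), after which it is disabled and a classical
(unsupervised) tail is simulated.

The per-window dynamics is ordinary unbiased Langevin dynamics — the
supervision never alters forces, it only selects which windows survive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .dynamics import DynamicsConfig, State, TrajectorySegment, run_segment, sample_velocities
from .toy_system import ToySystem

__all__ = [
    "SupervisionConfig",
    "WindowRecord",
    "SuMDRun",
    "com_distance",
    "window_slope",
    "supervise_window",
    "run_sumd",
    "run_unbiased",
]

FitMode = Literal["affine", "through_origin"]
Decision = Literal["accept", "reject", "arrival"]


@dataclass(frozen=True)
class SupervisionConfig:
    """Settings of the supervision loop.

    ``window_duration`` defaults to 600 ps and ``arrival_threshold`` to
    5 Å, the standard supervision settings at all-atom scale; tests and
    toy runs scale the window down.  A window is accepted iff its
    distance-vs-time slope is strictly below ``slope_threshold`` (fixed
    at 0: "negative slope" is read strictly, slope exactly 0 rejects).
    """

    window_duration: float = 600.0
    arrival_threshold: float = 5.0
    slope_threshold: float = 0.0
    fit_mode: FitMode = "affine"
    max_windows: int = 2000
    post_arrival_duration: float | None = None
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.window_duration <= 0:
            raise ValueError("window_duration must be > 0")
        if self.arrival_threshold <= 0:
            raise ValueError("arrival_threshold must be > 0")
        if self.max_windows < 1:
            raise ValueError("max_windows must be >= 1")

    @property
    def tail_duration(self) -> float:
        """Classical-tail length: defaults to 10x the window duration."""
        if self.post_arrival_duration is not None:
            return self.post_arrival_duration
        return 10.0 * self.window_duration


@dataclass(frozen=True)
class WindowRecord:
    """Outcome of supervising one window."""

    window_index: int
    slope_m: float
    decision: Decision
    end_distance: float
    start_time: float


@dataclass
class SuMDRun:
    """Result of a supervised run.

    ``segments`` holds only the accepted windows, in order; rejected
    windows appear in ``log`` but contribute no frames.  ``productive``
    means the arrival threshold was crossed and a classical tail was
    simulated.
    """

    segments: list[TrajectorySegment]
    log: list[WindowRecord]
    productive: bool
    total_windows_attempted: int
    classical_tail: TrajectorySegment | None
    arrival_simulated_time: float | None = None
    window_duration: float = 0.0

    @property
    def total_simulated_time(self) -> float:
        """Wall-model simulated time: all attempted windows plus the tail."""
        t = self.total_windows_attempted * self.window_duration
        if self.classical_tail is not None:
            t += self.classical_tail.duration
        return t

    def concatenated(self) -> TrajectorySegment:
        """Accepted windows (plus tail) merged into one segment.

        Consecutive segments share their boundary frame; the duplicate
        first frame of each follow-on segment is dropped.
        """
        parts = list(self.segments)
        if self.classical_tail is not None:
            parts.append(self.classical_tail)
        if not parts:
            raise ValueError("run contains no trajectory frames")
        arrays = {
            name: [getattr(parts[0], name)]
            for name in ("times", "positions", "velocities", "potential_energies", "distances")
        }
        for seg in parts[1:]:
            for name, chunks in arrays.items():
                chunks.append(getattr(seg, name)[1:])
        return TrajectorySegment(
            **{name: np.concatenate(chunks) for name, chunks in arrays.items()}
        )

    def final_state(self) -> State | None:
        if self.classical_tail is not None:
            return self.classical_tail.final_state()
        if self.segments:
            return self.segments[-1].final_state()
        return None

    @property
    def final_distance(self) -> float | None:
        if self.classical_tail is not None:
            return float(self.classical_tail.distances[-1])
        if self.segments:
            return float(self.segments[-1].distances[-1])
        return None


def com_distance(
    coords_a: Sequence[Sequence[float]],
    masses_a: Sequence[float],
    coords_b: Sequence[Sequence[float]],
    masses_b: Sequence[float],
) -> float:
    """Distance between the mass-weighted centroids of two atom sets (Å)."""

    def com(coords, masses):
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        masses = np.asarray(masses, dtype=float)
        if coords.shape[0] == 0 or masses.size == 0:
            raise ValueError("atom set must be non-empty")
        if coords.shape[0] != masses.size:
            raise ValueError("coordinates and masses must have matching lengths")
        if np.any(masses <= 0):
            raise ValueError("masses must be positive")
        return masses @ coords / masses.sum()

    return float(np.linalg.norm(com(coords_a, masses_a) - com(coords_b, masses_b)))


def window_slope(
    times: Sequence[float],
    distances: Sequence[float],
    fit_mode: FitMode = "affine",
) -> float:
    """Slope m (Å/ps) of the distance-vs-time fit over one window.

    ``affine`` is the ordinary least-squares slope of d(t) = m t + q.
    ``through_origin`` is the literal f(x) = m x reading: times are
    shifted to start at 0 and m = sum(t d) / sum(t^2); it is exposed for
    completeness but models series that start far from zero poorly.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(distances, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 points to fit a slope")
    if t.size != d.size:
        raise ValueError("times and distances must have equal length")
    if np.ptp(t) == 0:
        raise ValueError("times are constant; slope undefined")
    if fit_mode == "affine":
        tc = t - t.mean()
        return float(tc @ (d - d.mean()) / (tc @ tc))
    if fit_mode == "through_origin":
        ts = t - t[0]
        denom = ts @ ts
        if denom == 0:
            raise ValueError("times are constant; slope undefined")
        return float(ts @ d / denom)
    raise ValueError(f"unknown fit_mode '{fit_mode}'")


def supervise_window(
    segment: TrajectorySegment,
    config: SupervisionConfig,
    window_index: int = 0,
) -> WindowRecord:
    """Classify one window: arrival, accept, or reject.

    Arrival is a first-passage condition: it fires if *any* recorded
    distance in the window drops below the threshold, not only the
    endpoint.  Otherwise the window is accepted iff the fitted slope is
    strictly below the threshold (strictly negative by default).
    """
    if segment.n_frames == 0:
        raise ValueError("empty segment")
    slope = window_slope(segment.times, segment.distances, config.fit_mode)
    if float(np.min(segment.distances)) < config.arrival_threshold:
        decision: Decision = "arrival"
    elif slope < config.slope_threshold:
        decision = "accept"
    else:
        decision = "reject"
    return WindowRecord(
        window_index=window_index,
        slope_m=slope,
        decision=decision,
        end_distance=float(segment.distances[-1]),
        start_time=float(segment.times[0]),
    )


def run_sumd(
    system: ToySystem,
    start: State,
    dyn: DynamicsConfig,
    sup: SupervisionConfig,
    rng: np.random.Generator | None = None,
) -> SuMDRun:
    """Run the full supervision loop from ``start`` until arrival or budget.

    On accept the next window continues from the window's final state;
    on reject the window's initial coordinates (and start time) are
    restored bit-identically and velocities are resampled.  On arrival
    the supervision is disabled and a classical tail of
    ``sup.tail_duration`` ps is simulated.  ``arrival_simulated_time``
    on the result counts all simulated effort (accepted *and* rejected
    windows) up to the first sub-threshold frame.
    """
    if rng is None:
        rng = np.random.default_rng(sup.rng_seed)

    segments: list[TrajectorySegment] = []
    log: list[WindowRecord] = []
    productive = False
    tail: TrajectorySegment | None = None
    arrival_time: float | None = None
    attempted = 0
    state = start

    if system.distance_to_site(start.position) < sup.arrival_threshold:
        productive = True
        arrival_time = 0.0
        tail = run_segment(system, state, sup.tail_duration, dyn, rng)
        return SuMDRun(
            segments, log, productive, 0, tail, arrival_time, sup.window_duration
        )

    while attempted < sup.max_windows:
        seg = run_segment(system, state, sup.window_duration, dyn, rng)
        record = supervise_window(seg, sup, window_index=attempted)
        log.append(record)
        attempted += 1
        if record.decision == "arrival":
            segments.append(seg)
            productive = True
            in_window = seg.first_arrival_time(sup.arrival_threshold)
            offset = 0.0 if in_window is None else in_window - seg.times[0]
            arrival_time = (attempted - 1) * sup.window_duration + offset
            tail = run_segment(system, seg.final_state(), sup.tail_duration, dyn, rng)
            break
        if record.decision == "accept":
            segments.append(seg)
            state = seg.final_state()
        else:  # reject: restore coordinates and time, resample velocities
            state = State(
                position=state.position.copy(),
                velocity=sample_velocities(system, dyn.temperature, rng),
                time=state.time,
            )

    return SuMDRun(
        segments, log, productive, attempted, tail, arrival_time, sup.window_duration
    )


def run_unbiased(
    system: ToySystem,
    start: State,
    duration: float,
    dyn: DynamicsConfig,
    rng: np.random.Generator | None = None,
) -> TrajectorySegment:
    """One long classical segment with no supervision."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    return run_segment(system, start, duration, dyn, rng)
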