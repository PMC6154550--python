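"""Trajectory analyses of ligand recognition events.

Summaries mirror the usual post-processing of adaptive-sampling binding
trajectories: a (distance, interaction-energy) recognition landscape,
detection of metastable states (plateaus of the distance series),
poorly-populated distance gaps between them (putative transition-state
regions), and a residence-weighted path summary in which each visited
region carries the simulated time the ligand spent there (rendered as
spheres whose diameter is proportional to residence time).

Interaction energies follow the stabilisation-is-negative convention:
a frame bound in a well has a negative energy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "LandscapeGrid",
    "MetastableState",
    "PathNode",
    "recognition_landscape",
    "find_metastable_states",
    "occupancy_gaps",
    "path_summary",
]


@dataclass
class LandscapeGrid:
    """2-D frame-count histogram over (distance, energy)."""

    distance_bin_edges: np.ndarray
    energy_bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def n_frames(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetastableState:
    """A time-contiguous plateau of the distance series."""

    mean_distance: float
    distance_span: float
    dwell_time: float
    mean_energy: float
    frame_indices: np.ndarray
    start_time: float


@dataclass
class PathNode:
    """A visited spatial cell with its total residence time."""

    position: np.ndarray
    residence_time: float
    replica_id: int


def recognition_landscape(
    distances: Sequence[float],
    energies: Sequence[float],
    n_distance_bins: int = 40,
    n_energy_bins: int = 40,
    *,
    distance_range: tuple[float, float] | None = None,
    energy_range: tuple[float, float] | None = None,
) -> LandscapeGrid:
    """Histogram trajectory frames on the (distance, energy) plane."""
    d = np.asarray(distances, dtype=float)
    e = np.asarray(energies, dtype=float)
    if d.size == 0:
        raise ValueError("empty input series")
    if d.size != e.size:
        raise ValueError("distances and energies must have equal length")
    rng = None
    if distance_range is not None or energy_range is not None:
        rng = [
            distance_range or (d.min(), d.max()),
            energy_range or (e.min(), e.max()),
        ]
    counts, d_edges, e_edges = np.histogram2d(
        d, e, bins=[n_distance_bins, n_energy_bins], range=rng
    )
    return LandscapeGrid(d_edges, e_edges, counts)


def find_metastable_states(
    distances: Sequence[float],
    energies: Sequence[float],
    times: Sequence[float],
    min_dwell: float,
    distance_tolerance: float,
) -> list[MetastableState]:
    """Detect distance plateaus lasting at least ``min_dwell`` ps.

    A plateau is a maximal time-contiguous run of frames whose distance
    stays within ``distance_tolerance`` of the run's running mean; when
    a frame breaks the band the run is closed (kept if long enough) and
    a new run starts at the breaking frame.  States are returned in
    start-time order.
    """
    d = np.asarray(distances, dtype=float)
    e = np.asarray(energies, dtype=float)
    t = np.asarray(times, dtype=float)
    if not (d.size == e.size == t.size):
        raise ValueError("distances, energies and times must be aligned")
    if d.size == 0:
        raise ValueError("empty input series")
    if min_dwell <= 0:
        raise ValueError("min_dwell must be > 0")

    states: list[MetastableState] = []

    def close(i: int, j: int) -> None:
        """Close the run covering frames i..j inclusive."""
        dwell = float(t[j] - t[i])
        if dwell >= min_dwell:
            idx = np.arange(i, j + 1)
            states.append(
                MetastableState(
                    mean_distance=float(d[idx].mean()),
                    distance_span=float(d[idx].max() - d[idx].min()),
                    dwell_time=dwell,
                    mean_energy=float(e[idx].mean()),
                    frame_indices=idx,
                    start_time=float(t[i]),
                )
            )

    run_start = 0
    run_sum = d[0]
    for j in range(1, d.size):
        n = j - run_start
        running_mean = run_sum / n
        if abs(d[j] - running_mean) <= distance_tolerance:
            run_sum += d[j]
        else:
            close(run_start, j - 1)
            run_start = j
            run_sum = d[j]
    close(run_start, d.size - 1)
    return states


def occupancy_gaps(
    distances: Sequence[float],
    bin_width: float,
    occupancy_threshold: float = 0.005,
) -> list[tuple[float, float]]:
    """Poorly-populated distance intervals between populated regions.

    The distance axis is binned at ``bin_width``; contiguous bins whose
    occupancy fraction falls below ``occupancy_threshold`` are merged
    into intervals, and only intervals strictly flanked by populated
    bins on both sides are reported (sparse tails at the range edges
    are not gaps).
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty input series")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if not (0 <= occupancy_threshold < 1):
        raise ValueError("occupancy_threshold must be in [0, 1)")

    lo, hi = float(d.min()), float(d.max())
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width))) if hi > lo else 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, edges = np.histogram(d, bins=edges) if hi > lo else (np.array([d.size]), np.array([lo, lo + bin_width]))
    frac = counts / d.size
    populated = frac >= max(occupancy_threshold, np.finfo(float).tiny)

    gaps: list[tuple[float, float]] = []
    i = 0
    n = len(counts)
    while i < n:
        if not populated[i]:
            j = i
            while j < n and not populated[j]:
                j += 1
            if i > 0 and j < n:  # flanked by populated bins on both sides
                gaps.append((float(edges[i]), float(edges[j])))
            i = j
        else:
            i += 1
    return gaps


def path_summary(
    positions: Sequence[Sequence[float]],
    times: Sequence[float],
    cell_size: float,
    replica_id: int = 0,
) -> list[PathNode]:
    """Bin a trajectory into cubic cells and accumulate residence time.

    Each frame carries a trapezoidal time weight (half the interval to
    each neighbour; end frames carry a half interval), so residence
    times over all nodes sum exactly to the trajectory duration.  Nodes
    are ordered by first visit; positions are time-weighted means.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    t = np.asarray(times, dtype=float)
    if pos.shape[0] != t.size:
        raise ValueError("positions and times must be aligned")
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    n = t.size
    if n == 0:
        raise ValueError("empty trajectory")

    if n == 1:
        weights = np.array([0.0])
    else:
        dt = np.diff(t)
        weights = np.empty(n)
        weights[0] = 0.5 * dt[0]
        weights[-1] = 0.5 * dt[-1]
        weights[1:-1] = 0.5 * (dt[:-1] + dt[1:])

    cells = np.floor(pos / cell_size).astype(np.int64)
    order: list[tuple] = []
    acc: dict[tuple, list] = {}
    for i in range(n):
        key = tuple(cells[i])
        if key not in acc:
            acc[key] = [0.0, np.zeros(pos.shape[1])]
            order.append(key)
        entry = acc[key]
        entry[0] += weights[i]
        entry[1] += weights[i] * pos[i]

    nodes = []
    for key in order:
        w, wx = acc[key]
        if w > 0:
            mean_pos = wx / w
        else:  # degenerate single-frame trajectory: zero weight, plain mean
            mask = np.all(cells == np.asarray(key), axis=1)
            mean_pos = pos[mask].mean(axis=0)
        nodes.append(PathNode(position=mean_pos, residence_time=float(w), replica_id=replica_id))
    return nodes
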