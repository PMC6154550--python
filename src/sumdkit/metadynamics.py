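"""Well-tempered metadynamics on 1-2 toy collective variables.

Gaussian hills of geometrically damped height are deposited along the
collective variables (CVs) at a fixed stride; the accumulated bias
V(s) yields the free-energy estimate

    F(s) = -(gamma / (gamma - 1)) * V(s),

shifted so that min F = 0.  The hill height follows the well-tempered
rule  w = w0 * exp(-V(s) / (kB * (gamma - 1) * T)).

Defaults reproduce a standard salt-bridge protocol: initial height
0.3 kcal/mol, widths 0.04 Å (distance CV) and 0.3 rad (dihedral-like
CV), deposition stride 0.5 ps, bias factor gamma = 6, 298 K, 10 ns of
production.  Toy runs and tests scale the duration down.

The bias force on the ligand is evaluated analytically from the hill
parameters through the CV gradients; a gridded-bias evaluation mode is
available for long runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np

from .constants import KB
from .dynamics import DynamicsConfig, State, TrajectorySegment, run_segment
from .toy_system import ToySystem

__all__ = [
    "CollectiveVariable",
    "coordinate_cv",
    "distance_cv",
    "polar_angle_cv",
    "Hill",
    "MetadConfig",
    "BiasState",
    "FreeEnergySurface",
    "bias_potential",
    "next_hill_height",
    "run_metadynamics",
    "estimate_fes",
    "closed_state_fraction",
    "basin_delta_f",
    "reweighted_basin_delta_f",
    "write_hills",
    "read_hills",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class CollectiveVariable:
    """A scalar function of the ligand position with an analytic gradient.

    ``periodic`` CVs live on [-pi, pi) and hill distances are wrapped by
    minimum image.  Use the factory helpers below rather than building
    instances by hand.
    """

    name: str
    kind: Literal["coordinate_distance", "angle_like"]
    value_fn: Callable[[np.ndarray], float]
    grad_fn: Callable[[np.ndarray], np.ndarray]

    @property
    def periodic(self) -> bool:
        return self.kind == "angle_like"

    def value(self, position: np.ndarray) -> float:
        return self.value_fn(position)

    def gradient(self, position: np.ndarray) -> np.ndarray:
        return self.grad_fn(position)


def coordinate_cv(axis: int = 0, name: str | None = None) -> CollectiveVariable:
    """A Cartesian coordinate of the ligand as a distance-like CV."""

    def grad(r: np.ndarray) -> np.ndarray:
        g = np.zeros_like(r)
        g[axis] = 1.0
        return g

    return CollectiveVariable(
        name=name or f"x{axis}",
        kind="coordinate_distance",
        value_fn=lambda r: float(r[axis]),
        grad_fn=grad,
    )


def distance_cv(reference: Sequence[float], name: str = "dist") -> CollectiveVariable:
    """Euclidean distance of the ligand to a fixed reference point."""
    ref = np.asarray(reference, dtype=float)

    def value(r: np.ndarray) -> float:
        return float(np.linalg.norm(r - ref))

    def grad(r: np.ndarray) -> np.ndarray:
        diff = r - ref
        norm = np.linalg.norm(diff)
        if norm == 0:
            return np.zeros_like(diff)
        return diff / norm

    return CollectiveVariable(name, "coordinate_distance", value, grad)


def polar_angle_cv(name: str = "theta") -> CollectiveVariable:
    """Polar angle atan2(y, x) in the first two coordinates; periodic."""

    def value(r: np.ndarray) -> float:
        return math.atan2(r[1], r[0])

    def grad(r: np.ndarray) -> np.ndarray:
        g = np.zeros_like(r)
        r2 = r[0] * r[0] + r[1] * r[1]
        if r2 == 0:
            return g
        g[0] = -r[1] / r2
        g[1] = r[0] / r2
        return g

    return CollectiveVariable(name, "angle_like", value, grad)


@dataclass(frozen=True)
class Hill:
    """One deposited Gaussian: center in CV space, per-CV sigma, height."""

    center: tuple[float, ...]
    widths: tuple[float, ...]
    height: float
    deposit_time: float

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.widths):
            raise ValueError("hill widths must be > 0")
        if self.height <= 0:
            raise ValueError("hill height must be > 0")


@dataclass(frozen=True)
class MetadConfig:
    """Well-tempered metadynamics settings (see module docstring)."""

    cvs: tuple[CollectiveVariable, ...]
    w0: float = 0.3
    sigmas: tuple[float, ...] = (0.04,)
    stride: float = 0.5
    bias_factor: float = 6.0
    temperature: float = 298.0
    duration: float = 10000.0
    bias_eval: Literal["analytic", "grid"] = "analytic"
    grid_bounds: tuple[tuple[float, float], ...] | None = None
    grid_points: int = 2048

    def __post_init__(self) -> None:
        if not 1 <= len(self.cvs) <= 2:
            raise ValueError("1 or 2 collective variables required")
        if len(self.sigmas) != len(self.cvs):
            raise ValueError("one sigma per CV required")
        if self.bias_factor <= 1:
            raise ValueError("bias_factor must be > 1")
        if self.w0 <= 0:
            raise ValueError("initial hill height must be > 0")
        if self.stride <= 0:
            raise ValueError("stride must be > 0")


class BiasState:
    """Accumulated hills plus the parameters needed to interpret them."""

    def __init__(
        self,
        cvs: Sequence[CollectiveVariable],
        bias_factor: float,
        temperature: float,
    ) -> None:
        self.cvs = tuple(cvs)
        self.bias_factor = float(bias_factor)
        self.temperature = float(temperature)
        self.hills: list[Hill] = []
        self._centers = np.empty((0, len(self.cvs)))
        self._inv_w2 = np.empty((0, len(self.cvs)))
        self._heights = np.empty(0)
        self._periodic = np.array([cv.periodic for cv in self.cvs])

    @property
    def n_cvs(self) -> int:
        return len(self.cvs)

    def add_hill(self, hill: Hill) -> None:
        if len(hill.center) != self.n_cvs:
            raise ValueError("hill dimensionality does not match CVs")
        if self.hills and hill.deposit_time < self.hills[-1].deposit_time:
            raise ValueError("hills must be added in deposit-time order")
        self.hills.append(hill)
        self._centers = np.vstack([self._centers, np.asarray(hill.center)])
        self._inv_w2 = np.vstack(
            [self._inv_w2, 1.0 / np.square(np.asarray(hill.widths))]
        )
        self._heights = np.append(self._heights, hill.height)

    def _deltas(self, point: np.ndarray) -> np.ndarray:
        delta = point - self._centers
        if self._periodic.any():
            p = self._periodic
            delta[:, p] = (delta[:, p] + math.pi) % TWO_PI - math.pi
        return delta

    def potential(self, point) -> float:
        """Accumulated bias V(s) at a CV-space point (kcal/mol)."""
        s = np.asarray(point, dtype=float).reshape(-1)
        if s.size != self.n_cvs:
            raise ValueError(f"cv point must have {self.n_cvs} components")
        if self._heights.size == 0:
            return 0.0
        delta = self._deltas(s)
        expo = -0.5 * np.einsum("ij,ij->i", delta * delta, self._inv_w2)
        return float(self._heights @ np.exp(expo))

    def gradient(self, point) -> np.ndarray:
        """dV/ds at a CV-space point."""
        s = np.asarray(point, dtype=float).reshape(-1)
        if s.size != self.n_cvs:
            raise ValueError(f"cv point must have {self.n_cvs} components")
        if self._heights.size == 0:
            return np.zeros(self.n_cvs)
        delta = self._deltas(s)
        expo = np.exp(-0.5 * np.einsum("ij,ij->i", delta * delta, self._inv_w2))
        terms = (self._heights * expo)[:, None] * delta * self._inv_w2
        return -terms.sum(axis=0)


@dataclass
class FreeEnergySurface:
    """Free energy on a regular CV grid, shifted so min F = 0."""

    grids: tuple[np.ndarray, ...]
    values: np.ndarray

    @property
    def grid(self) -> np.ndarray:
        if len(self.grids) != 1:
            raise ValueError("scalar grid only defined for 1-D surfaces")
        return self.grids[0]


def bias_potential(bias: BiasState, cv_point) -> float:
    """Accumulated bias V(s), a sum of Gaussians over deposited hills."""
    return bias.potential(cv_point)


def next_hill_height(bias: BiasState, cv_point, config: MetadConfig) -> float:
    """Well-tempered height: w0 * exp(-V(s) / (kB (gamma-1) T))."""
    if config.bias_factor <= 1:
        raise ValueError("bias_factor must be > 1")
    v = bias.potential(cv_point)
    delta_t_energy = KB * (config.bias_factor - 1.0) * config.temperature
    return config.w0 * math.exp(-v / delta_t_energy)


class _GridBias:
    """Incrementally gridded 1-D bias for O(1) per-step force evaluation."""

    def __init__(self, bounds: tuple[float, float], n: int) -> None:
        self.x = np.linspace(bounds[0], bounds[1], n)
        self.v = np.zeros(n)
        self.dv = np.zeros(n)
        self._dx = self.x[1] - self.x[0]

    def add_hill(self, center: float, sigma: float, height: float) -> None:
        d = self.x - center
        g = height * np.exp(-0.5 * (d / sigma) ** 2)
        self.v += g
        self.dv += -g * d / sigma**2

    def _interp(self, arr: np.ndarray, s: float) -> float:
        i = (s - self.x[0]) / self._dx
        i0 = int(np.clip(math.floor(i), 0, len(self.x) - 2))
        frac = i - i0
        return float(arr[i0] * (1 - frac) + arr[i0 + 1] * frac)

    def potential(self, s: float) -> float:
        return self._interp(self.v, s)

    def gradient(self, s: float) -> float:
        return self._interp(self.dv, s)


def run_metadynamics(
    system: ToySystem,
    start: State,
    dyn: DynamicsConfig,
    config: MetadConfig,
    rng: np.random.Generator | None = None,
) -> tuple[BiasState, TrajectorySegment]:
    """Biased Langevin run depositing one hill every ``config.stride`` ps.

    The total force is the system force plus the analytic bias force
    mapped through the CV gradients.  Exactly ``floor(duration/stride)``
    hills are deposited (none at t = 0).  The returned segment carries
    the CV values of the recorded frames in ``cv_values``.
    """
    if rng is None:
        rng = np.random.default_rng(dyn.rng_seed)
    bias = BiasState(config.cvs, config.bias_factor, config.temperature)

    steps_per_stride = max(1, int(round(config.stride / dyn.dt)))
    n_steps = int(round(config.duration / dyn.dt))
    n_hills_expected = int(math.floor(config.duration / config.stride))

    use_grid = config.bias_eval == "grid"
    grid: _GridBias | None = None
    if use_grid:
        if bias.n_cvs != 1:
            raise ValueError("gridded bias evaluation supports 1-D CVs only")
        if config.grid_bounds is None:
            L = system.confinement.half_length + 5.0
            bounds = (-L, L)
        else:
            bounds = config.grid_bounds[0]
        grid = _GridBias(bounds, config.grid_points)

    cv_values_fn = lambda r: np.array([cv.value(r) for cv in config.cvs])

    def extra_force(r: np.ndarray, t: float) -> np.ndarray:
        f = np.zeros_like(r)
        if use_grid:
            s = config.cvs[0].value(r)
            dvds = grid.gradient(s)
            if dvds != 0.0:
                f -= dvds * config.cvs[0].gradient(r)
        else:
            s = cv_values_fn(r)
            dvds = bias.gradient(s)
            for k, cv in enumerate(config.cvs):
                if dvds[k] != 0.0:
                    f -= dvds[k] * cv.gradient(r)
        return f

    deposited = 0

    def step_hook(step: int, r: np.ndarray) -> None:
        nonlocal deposited
        if step % steps_per_stride == 0 and deposited < n_hills_expected:
            s = cv_values_fn(r)
            if use_grid:
                v = grid.potential(float(s[0]))
                h = config.w0 * math.exp(
                    -v / (KB * (config.bias_factor - 1.0) * config.temperature)
                )
            else:
                h = next_hill_height(bias, s, config)
            hill = Hill(
                center=tuple(s),
                widths=tuple(config.sigmas),
                height=h,
                deposit_time=start.time + step * dyn.dt,
            )
            bias.add_hill(hill)
            if use_grid:
                grid.add_hill(float(s[0]), config.sigmas[0], h)
            deposited += 1

    segment = run_segment(
        system,
        start,
        config.duration,
        dyn,
        rng,
        extra_force=extra_force,
        step_hook=step_hook,
    )
    segment.cv_values = np.array([cv_values_fn(r) for r in segment.positions])
    return bias, segment


def _hill_grid_matrix(
    centers: np.ndarray,
    inv_w2: np.ndarray,
    heights: np.ndarray,
    periodic: np.ndarray,
    pts: np.ndarray,
) -> np.ndarray:
    """(n_hills, n_points) matrix of per-hill bias contributions."""
    delta = pts[None, :, :] - centers[:, None, :]  # (H, P, C)
    if periodic.any():
        delta[:, :, periodic] = (delta[:, :, periodic] + math.pi) % TWO_PI - math.pi
    expo = -0.5 * np.einsum("hpc,hc->hp", delta * delta, inv_w2)
    return heights[:, None] * np.exp(expo)


def estimate_fes(
    bias: BiasState,
    bounds: Sequence[tuple[float, float]] | None = None,
    n_points: int = 400,
    time_average: float = 0.5,
) -> FreeEnergySurface:
    """Well-tempered free-energy estimate F(s) = -(g/(g-1)) V(s), min-shifted.

    ``bounds`` default to the hill-center range padded by 3 sigma per CV.
    With ``time_average`` > 0 the estimate is the time average of
    -(g/(g-1)) V(s, t) over the last ``time_average`` fraction of the
    deposition history, which suppresses the late-time fluctuations of
    the instantaneous bias around the converged profile; set it to 0
    for the plain final-bias estimate.
    """
    if not bias.hills:
        raise ValueError("bias contains no hills")
    if not 0 <= time_average < 1:
        raise ValueError("time_average must be in [0, 1)")
    prefactor = bias.bias_factor / (bias.bias_factor - 1.0)
    if bounds is None:
        centers = np.array([h.center for h in bias.hills])
        widths = np.array([h.widths for h in bias.hills])
        pad = 3.0 * widths.max(axis=0)
        bounds = [
            (-math.pi, math.pi)
            if cv.periodic
            else (centers[:, k].min() - pad[k], centers[:, k].max() + pad[k])
            for k, cv in enumerate(bias.cvs)
        ]
    grids = tuple(np.linspace(lo, hi, n_points) for lo, hi in bounds)
    mesh = np.meshgrid(*grids, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)

    n_hills = len(bias.hills)
    n_avg = int(time_average * n_hills)
    if n_avg < 2:
        weights = np.ones(n_hills)
    else:
        # average of V(s, t) over the last n_avg deposition checkpoints:
        # hills deposited before the averaging window carry weight 1,
        # later hills the fraction of checkpoints that include them.
        first = n_hills - n_avg
        weights = np.ones(n_hills)
        idx = np.arange(first, n_hills)
        weights[idx] = (n_hills - idx) / n_avg
    v = np.zeros(pts.shape[0])
    chunk = max(1, 2_000_000 // pts.shape[0])
    for h0 in range(0, n_hills, chunk):
        h1 = min(n_hills, h0 + chunk)
        v += weights[h0:h1] @ _hill_grid_matrix(
            bias._centers[h0:h1],
            bias._inv_w2[h0:h1],
            bias._heights[h0:h1],
            bias._periodic,
            pts,
        )
    f = -prefactor * v.reshape(mesh[0].shape)
    f -= f.min()
    return FreeEnergySurface(grids=grids, values=f)


def closed_state_fraction(
    cv_series: Sequence[float],
    closed_threshold: float,
    bias: BiasState | None = None,
) -> tuple[float, float | None]:
    """Fraction of frames with CV below ``closed_threshold``.

    When a 1-D ``bias`` is supplied, additionally returns the free-energy
    difference F(open) - F(closed) from the estimated surface, where
    each basin free energy is the Boltzmann integral of F over its side
    of the threshold at the bias temperature (positive values mean the
    closed state is more stable).
    """
    s = np.asarray(cv_series, dtype=float)
    if s.size == 0:
        raise ValueError("empty CV series")
    if closed_threshold <= 0:
        raise ValueError("closed_threshold must be > 0")
    fraction = float(np.mean(s < closed_threshold))

    delta_f = None
    if bias is not None:
        if bias.n_cvs != 1:
            raise ValueError("basin free energies require a 1-D bias")
        fes = estimate_fes(bias)
        delta_f = basin_delta_f(fes, closed_threshold, bias.temperature)
    return fraction, delta_f


def reweighted_basin_delta_f(
    bias: BiasState,
    cv_series,
    threshold: float,
    last_fraction: float = 0.5,
) -> float:
    """F(closed) - F(open) by reweighting late biased samples.

    Frames from the last ``last_fraction`` of the trajectory (where the
    well-tempered bias is quasi-static) are reweighted by
    ``exp(V(s)/kB T)`` to recover unbiased basin populations, and the
    basin free-energy difference is ``-kB T ln(p_closed / p_open)``.
    Because whole-basin populations are integrated, this estimator is
    limited by the number of inter-basin crossings rather than by the
    pointwise roughness of the deposited bias.
    """
    if bias.n_cvs != 1:
        raise ValueError("basin reweighting requires a 1-D bias")
    s = np.asarray(cv_series, dtype=float).reshape(-1)
    if s.size == 0:
        raise ValueError("empty CV series")
    if not 0 < last_fraction <= 1:
        raise ValueError("last_fraction must be in (0, 1]")
    s = s[int((1.0 - last_fraction) * s.size):]
    kt = KB * bias.temperature
    pts = s[:, None]
    v = np.zeros(s.size)
    n_hills = len(bias.hills)
    chunk = max(1, 2_000_000 // s.size)
    for h0 in range(0, n_hills, chunk):
        h1 = min(n_hills, h0 + chunk)
        v += _hill_grid_matrix(
            bias._centers[h0:h1],
            bias._inv_w2[h0:h1],
            bias._heights[h0:h1],
            bias._periodic,
            pts,
        ).sum(axis=0)
    w = np.exp((v - v.max()) / kt)
    closed = s < threshold
    p_closed = w[closed].sum()
    p_open = w[~closed].sum()
    if p_closed == 0 or p_open == 0:
        raise ValueError("one basin was never sampled in the reweighting window")
    return float(-kt * math.log(p_closed / p_open))


def basin_delta_f(
    fes: FreeEnergySurface, threshold: float, temperature: float
) -> float:
    """F(open) - F(closed) from a 1-D surface split at ``threshold``.

    Basin free energies are -kB T log of the Boltzmann-weighted measure
    of each side, so broad shallow basins are handled sensibly.
    """
    x = fes.grid
    f = fes.values
    kt = KB * temperature
    w = np.exp(-f / kt)
    closed = x < threshold
    if not closed.any() or closed.all():
        raise ValueError("threshold does not split the FES grid into two basins")
    f_closed = -kt * math.log(np.trapezoid(w[closed], x[closed]))
    f_open = -kt * math.log(np.trapezoid(w[~closed], x[~closed]))
    return f_open - f_closed


# -- HILLS text interchange ------------------------------------------


def write_hills(bias: BiasState, path: str | Path) -> None:
    """Write hills in a PLUMED-style whitespace-delimited text layout."""
    names = [cv.name for cv in bias.cvs]
    header = (
        "#! FIELDS time "
        + " ".join(names)
        + " "
        + " ".join(f"sigma_{n}" for n in names)
        + " height biasf\n"
    )
    lines = [header]
    for h in bias.hills:
        vals = (
            [h.deposit_time]
            + list(h.center)
            + list(h.widths)
            + [h.height, bias.bias_factor]
        )
        lines.append(" ".join(f"{v:.9f}" for v in vals) + "\n")
    Path(path).write_text("".join(lines))


def read_hills(
    path: str | Path,
    cvs: Sequence[CollectiveVariable],
    temperature: float = 298.0,
) -> BiasState:
    """Read a HILLS file written by :func:`write_hills`."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#!"):
        raise ValueError("missing HILLS header line")
    n_cv = len(cvs)
    bias: BiasState | None = None
    for line in lines[1:]:
        if not line.strip() or line.startswith("#"):
            continue
        vals = [float(x) for x in line.split()]
        if len(vals) != 2 * n_cv + 3:
            raise ValueError(f"malformed HILLS row: '{line}'")
        time, rest = vals[0], vals[1:]
        center = tuple(rest[:n_cv])
        widths = tuple(rest[n_cv : 2 * n_cv])
        height, biasf = rest[2 * n_cv], rest[2 * n_cv + 1]
        if bias is None:
            bias = BiasState(cvs, biasf, temperature)
        bias.add_hill(Hill(center, widths, height, time))
    if bias is None:
        raise ValueError("HILLS file contains no hills")
    return bias
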