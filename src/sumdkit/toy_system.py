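"""Analytic toy receptor-ligand energy landscapes.

A :class:`ToySystem` is a sum of attractive Gaussian wells (stable or
metastable ligand sites), repulsive Gaussian barriers (e.g. an
electrostatically repulsive patch on the recognition pathway) and a
harmonic confining wall that bounds ligand diffusion.  Positions are in
Å, energies in kcal/mol, masses in amu.

Scenario presets emulate the qualitative phenomenology of ligand
recognition at a GPCR extracellular vestibule:

``binder``
    an orthosteric binder (caffeine-like): the orthosteric well is the
    global minimum, with a shallow metastable stop-over and a weak
    unfavourable region on the way in.
``pam``
    a fragment-like positive allosteric modulator: a metastable
    extracellular site ~15 Å from the orthosteric center is *deeper*
    than the orthosteric well and a repulsive barrier sits between
    them, so the ligand stalls in the vestibule.
``diffusive``
    a nearly flat landscape (free diffusion inside the box).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "GaussianWell",
    "GaussianBarrier",
    "Confinement",
    "ToySystem",
    "PRESETS",
    "build_scenario",
    "load_scenario",
    "save_scenario",
]


@dataclass(frozen=True)
class GaussianWell:
    """Attractive Gaussian well: contributes ``-depth * exp(-|r-c|^2 / 2w^2)``."""

    center: tuple[float, ...]
    depth: float
    width: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.depth):
            raise ValueError("well depth must be finite")
        if self.width <= 0:
            raise ValueError("well width must be > 0")


@dataclass(frozen=True)
class GaussianBarrier:
    """Repulsive Gaussian bump: contributes ``+height * exp(-|r-c|^2 / 2w^2)``."""

    center: tuple[float, ...]
    height: float
    width: float

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError("barrier height must be >= 0")
        if self.width <= 0:
            raise ValueError("barrier width must be > 0")


@dataclass(frozen=True)
class Confinement:
    """Harmonic wall outside a box of half-length ``half_length``.

    ``U = 0.5 * k * sum_i max(|x_i| - L, 0)^2``.  Setting ``half_length``
    to 0 turns the confinement into a plain isotropic harmonic trap,
    which is convenient for integrator checks.
    """

    half_length: float = 25.0
    spring_constant: float = 10.0

    def __post_init__(self) -> None:
        if self.half_length < 0:
            raise ValueError("confinement half_length must be >= 0")
        if self.spring_constant < 0:
            raise ValueError("confinement spring_constant must be >= 0")


class ToySystem:
    """Analytic ligand-receptor potential: wells + barriers + confinement.

    Parameters
    ----------
    dims
        Spatial dimensionality (1, 2 or 3; 3 matches a simulation box,
        lower dimensions keep tests and pedagogical runs cheap).
    wells, barriers
        Gaussian terms of the landscape.
    orthosteric_center
        Center of the designated orthosteric site; must coincide with
        the center of exactly one well unless the landscape is flat.
    ligand_mass
        Mass of the ligand pseudo-particle, amu.
    confinement
        Harmonic wall parameters.
    """

    def __init__(
        self,
        dims: int,
        wells: Sequence[GaussianWell],
        barriers: Sequence[GaussianBarrier],
        orthosteric_center: Sequence[float],
        ligand_mass: float,
        confinement: Confinement | None = None,
    ) -> None:
        if dims not in (1, 2, 3):
            raise ValueError(f"dims must be 1, 2 or 3, got {dims}")
        if ligand_mass <= 0:
            raise ValueError("ligand_mass must be > 0")
        self.dims = int(dims)
        self.wells = tuple(wells)
        self.barriers = tuple(barriers)
        self.orthosteric_center = np.asarray(orthosteric_center, dtype=float)
        if self.orthosteric_center.shape != (self.dims,):
            raise ValueError(
                f"orthosteric_center must have {self.dims} components, "
                f"got shape {self.orthosteric_center.shape}"
            )
        self.ligand_mass = float(ligand_mass)
        self.confinement = confinement if confinement is not None else Confinement()

        for term in (*self.wells, *self.barriers):
            if len(term.center) != self.dims:
                raise ValueError(
                    f"term center {term.center} does not match dims={self.dims}"
                )
        active_wells = [w for w in self.wells if w.depth != 0.0]
        if active_wells:
            hits = sum(
                np.allclose(w.center, self.orthosteric_center) for w in active_wells
            )
            if hits != 1:
                raise ValueError(
                    "orthosteric_center must coincide with the center of exactly "
                    f"one (non-flat) well; it matches {hits}"
                )

        # Precompute stacked arrays for vectorised energy/force evaluation.
        amps, centers, widths = [], [], []
        for w in self.wells:
            amps.append(-w.depth)
            centers.append(w.center)
            widths.append(w.width)
        for b in self.barriers:
            amps.append(b.height)
            centers.append(b.center)
            widths.append(b.width)
        n = len(amps)
        self._amps = np.asarray(amps, dtype=float)
        self._centers = (
            np.asarray(centers, dtype=float).reshape(n, self.dims)
            if n
            else np.empty((0, self.dims))
        )
        w = np.asarray(widths, dtype=float)
        self._inv_w2 = 1.0 / (w * w) if n else w
        self._n_interaction_wells = len(self.wells)

    # -- energies -----------------------------------------------------

    def _check_position(self, position: np.ndarray) -> np.ndarray:
        r = np.asarray(position, dtype=float)
        if r.shape != (self.dims,):
            raise ValueError(
                f"position must have {self.dims} components, got shape {r.shape}"
            )
        return r

    def _gaussian_terms(self, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-term energies and displacement vectors at ``r``."""
        diff = r - self._centers
        r2 = np.einsum("ij,ij->i", diff, diff)
        e = self._amps * np.exp(-0.5 * r2 * self._inv_w2)
        return e, diff

    def interaction_energy(self, position) -> float:
        """Ligand-receptor interaction energy: wells + barriers, no wall.

        This is the per-frame energy used by the landscape analyses (it
        stands in for a force-field ligand-receptor interaction energy;
        the confining wall is an artefact of the toy box, not an
        interaction).
        """
        r = self._check_position(position)
        if self._amps.size == 0:
            return 0.0
        e, _ = self._gaussian_terms(r)
        return float(e.sum())

    def wall_energy(self, position) -> float:
        r = self._check_position(position)
        over = np.maximum(np.abs(r) - self.confinement.half_length, 0.0)
        return float(0.5 * self.confinement.spring_constant * np.dot(over, over))

    def potential_energy(self, position) -> float:
        """Total potential: interaction terms plus the confining wall."""
        return self.interaction_energy(position) + self.wall_energy(position)

    def force(self, position) -> np.ndarray:
        """Analytic force ``-dU/dr`` (kcal/mol/Å)."""
        r = self._check_position(position)
        f = np.zeros(self.dims)
        if self._amps.size:
            e, diff = self._gaussian_terms(r)
            # d/dr [a exp(-|d|^2/2w^2)] = -a exp(..) d / w^2 ; force = -grad
            f += (e * self._inv_w2) @ diff
        over = np.maximum(np.abs(r) - self.confinement.half_length, 0.0)
        f -= self.confinement.spring_constant * np.sign(r) * over
        return f

    # -- convenience --------------------------------------------------

    def distance_to_site(self, position) -> float:
        """Euclidean distance from ``position`` to the orthosteric center."""
        r = self._check_position(position)
        return float(np.linalg.norm(r - self.orthosteric_center))

    def to_dict(self) -> dict:
        return {
            "dims": self.dims,
            "wells": [
                {"center": list(w.center), "depth": w.depth, "width": w.width}
                for w in self.wells
            ],
            "barriers": [
                {"center": list(b.center), "height": b.height, "width": b.width}
                for b in self.barriers
            ],
            "orthosteric_center": list(map(float, self.orthosteric_center)),
            "ligand_mass": self.ligand_mass,
            "confinement": {
                "half_length": self.confinement.half_length,
                "spring_constant": self.confinement.spring_constant,
            },
        }

    @classmethod
    def from_dict(cls, spec: Mapping[str, Any]) -> "ToySystem":
        _validate_scenario_dict(spec)
        conf = spec.get("confinement", {})
        return cls(
            dims=int(spec["dims"]),
            wells=[
                GaussianWell(tuple(w["center"]), float(w["depth"]), float(w["width"]))
                for w in spec.get("wells", [])
            ],
            barriers=[
                GaussianBarrier(
                    tuple(b["center"]), float(b["height"]), float(b["width"])
                )
                for b in spec.get("barriers", [])
            ],
            orthosteric_center=spec["orthosteric_center"],
            ligand_mass=float(spec["ligand_mass"]),
            confinement=Confinement(
                half_length=float(conf.get("half_length", 25.0)),
                spring_constant=float(conf.get("spring_constant", 10.0)),
            ),
        )


_SCENARIO_KEYS = {
    "dims",
    "wells",
    "barriers",
    "orthosteric_center",
    "ligand_mass",
    "confinement",
}


def _validate_scenario_dict(spec: Mapping[str, Any]) -> None:
    unknown = set(spec) - _SCENARIO_KEYS
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    for key in ("dims", "orthosteric_center", "ligand_mass"):
        if key not in spec:
            raise ValueError(f"scenario missing required key '{key}'")
    for w in spec.get("wells", []):
        if set(w) != {"center", "depth", "width"}:
            raise ValueError(f"well entry must have center/depth/width, got {sorted(w)}")
    for b in spec.get("barriers", []):
        if set(b) != {"center", "height", "width"}:
            raise ValueError(
                f"barrier entry must have center/height/width, got {sorted(b)}"
            )


def _pad(coords: Sequence[float], dims: int) -> list[float]:
    out = list(coords)[:dims]
    return out + [0.0] * (dims - len(out))


def _shell_points(radius: float, dims: int, n: int) -> list[list[float]]:
    """Roughly equidistant points on the sphere/circle of given radius.

    Used to lay metastable sites and repulsive patches on a
    site-distance shell, so that a ligand approaching from any direction
    encounters them — the toy analogue of a receptor vestibule that
    funnels every approach path.
    """
    if dims == 1:
        return [[radius], [-radius]]
    if dims == 2:
        angles = 2.0 * np.pi * np.arange(n) / n
        return [[radius * np.cos(a), radius * np.sin(a)] for a in angles]
    # Fibonacci sphere
    golden = np.pi * (3.0 - np.sqrt(5.0))
    pts = []
    for i in range(n):
        z = 1.0 - 2.0 * (i + 0.5) / n
        rho = np.sqrt(max(0.0, 1.0 - z * z))
        phi = golden * i
        pts.append(
            [radius * rho * np.cos(phi), radius * rho * np.sin(phi), radius * z]
        )
    return pts


def _preset_dict(name: str, dims: int) -> dict:
    """Scenario dictionaries for the built-in presets.

    Geometry: orthosteric site at the origin, metastable vestibule site
    15 Å out along the first axis, repulsive patch at 10 Å between them.
    Magnitudes are chosen so the binder landscape has its global minimum
    at the orthosteric site while the pam landscape has the metastable
    site deeper than the orthosteric one behind a barrier; none of the
    magnitudes come from experiment and all are overridable.
    """
    origin = _pad([0.0], dims)
    if name == "binder":
        return {
            "dims": dims,
            "wells": [
                {"center": origin, "depth": 8.0, "width": 2.5},
                {"center": _pad([15.0], dims), "depth": 3.0, "width": 2.0},
            ],
            "barriers": [{"center": _pad([10.0], dims), "height": 1.5, "width": 1.5}],
            "orthosteric_center": origin,
            "ligand_mass": 194.19,  # caffeine-like
            "confinement": {"half_length": 25.0, "spring_constant": 10.0},
        }
    if name == "pam":
        # The metastable vestibule is a *shell* of deep sites 15 Å from
        # the orthosteric center (a center-of-mass distance of 15 Å is a
        # radius, not a point), with repulsive patches on the 10 Å shell
        # between vestibule and orthosteric site.  Every approach
        # direction therefore meets a vestibule site that is deeper than
        # the orthosteric well.
        n_meta = {1: 2, 2: 16, 3: 150}[dims]
        n_barrier = {1: 2, 2: 12, 3: 60}[dims]
        return {
            "dims": dims,
            "wells": [{"center": origin, "depth": 3.0, "width": 2.0}]
            + [
                {"center": c, "depth": 7.0, "width": 2.0}
                for c in _shell_points(15.0, dims, n_meta)
            ],
            "barriers": [
                {"center": c, "height": 5.0, "width": 2.0}
                for c in _shell_points(11.0, dims, n_barrier)
            ],
            "orthosteric_center": origin,
            "ligand_mass": 230.0,  # fragment-like acid
            "confinement": {"half_length": 25.0, "spring_constant": 10.0},
        }
    if name == "diffusive":
        return {
            "dims": dims,
            "wells": [{"center": origin, "depth": 0.5, "width": 3.0}],
            "barriers": [],
            "orthosteric_center": origin,
            "ligand_mass": 100.0,
            "confinement": {"half_length": 25.0, "spring_constant": 10.0},
        }
    raise KeyError(f"unknown preset '{name}' (expected binder, pam or diffusive)")


PRESETS = ("binder", "pam", "diffusive")


def _apply_override(spec: dict, path: str, value: Any) -> None:
    """Assign ``value`` at a dotted ``path`` into the scenario dict.

    List indices are numeric path components; ``*`` fans out over every
    element of a list.  Unknown fields raise ``KeyError``.
    """
    parts = path.split(".")
    targets: list[Any] = [spec]
    for part in parts[:-1]:
        nxt: list[Any] = []
        for t in targets:
            if part == "*":
                if not isinstance(t, list):
                    raise KeyError(f"'*' in '{path}' does not address a list")
                nxt.extend(t)
            elif isinstance(t, list):
                nxt.append(t[int(part)])
            else:
                if part not in t:
                    raise KeyError(f"override path '{path}': no field '{part}'")
                nxt.append(t[part])
        targets = nxt
    leaf = parts[-1]
    for t in targets:
        if isinstance(t, list):
            t[int(leaf)] = value
        else:
            if leaf not in t:
                raise KeyError(f"override path '{path}': no field '{leaf}'")
            t[leaf] = value


def build_scenario(
    preset: str,
    overrides: Mapping[str, Any] | None = None,
    *,
    dims: int = 3,
) -> ToySystem:
    """Resolve a named preset (plus optional overrides) into a ToySystem.

    ``overrides`` maps dotted field paths into the scenario dictionary,
    e.g. ``{"ligand_mass": 10.0, "wells.*.depth": 0.0}``.
    """
    spec = _preset_dict(preset, dims)
    for path, value in (overrides or {}).items():
        _apply_override(spec, path, value)
    return ToySystem.from_dict(spec)


def load_scenario(path: str | Path) -> ToySystem:
    """Load a scenario from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        spec = json.loads(text)
    else:
        spec = yaml.safe_load(text)
    if not isinstance(spec, Mapping):
        raise ValueError(f"scenario file {path} does not contain a mapping")
    return ToySystem.from_dict(spec)


def save_scenario(system: ToySystem, path: str | Path) -> None:
    path = Path(path)
    spec = system.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(spec, indent=2))
    else:
        path.write_text(yaml.safe_dump(spec, sort_keys=False))
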