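"""File formats: XYZ trajectories, CSV logs, PDB coordinates, manifests.

The trajectory format is plain XYZ with one pseudo-atom per frame; the
comment line carries the frame time in ps (``t= <ps>``).  Supervision
logs, distance/energy series and free-energy curves are CSV with fixed
six-decimal formatting so repeated runs are byte-identical.  PDB
reading (for center-of-mass computations on real structures) is
delegated to Biopython.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .dynamics import TrajectorySegment
from .landscape import PathNode
from .sumd import SuMDRun

__all__ = [
    "write_xyz",
    "read_xyz",
    "read_pdb_coords",
    "write_supervision_log",
    "write_series_csv",
    "write_path_pdb",
    "RunManifest",
]

_ATOM_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.99, "K": 39.098, "MG": 24.305, "CA": 40.078, "ZN": 65.38,
    "FE": 55.845,
}


def _frame_xyz(position: np.ndarray) -> np.ndarray:
    out = np.zeros(3)
    out[: min(3, position.size)] = position[:3]
    return out


def write_xyz(segment: TrajectorySegment, path: str | Path, element: str = "L") -> None:
    """Write a segment as XYZ, one pseudo-atom per frame block.

    Lower-dimensional positions are padded with zeros to three columns.
    """
    lines = []
    for t, pos in zip(segment.times, segment.positions):
        x, y, z = _frame_xyz(np.asarray(pos))
        lines.append(f"1\nt= {t:.6f}\n{element} {x:.6f} {y:.6f} {z:.6f}\n")
    Path(path).write_text("".join(lines))


def read_xyz(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read an XYZ trajectory; returns (positions (n,3), times (n,)).

    Times default to the frame index when the comment line carries no
    ``t=`` tag.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError("empty XYZ file")
    positions: list[list[float]] = []
    times: list[float] = []
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"malformed XYZ header at line {i + 1}") from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        t = float(frame)
        if "t=" in comment:
            try:
                t = float(comment.split("t=")[1].split()[0])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"malformed time comment at line {i + 2}") from exc
        block = lines[i + 2 : i + 2 + n_atoms]
        if len(block) != n_atoms:
            raise ValueError(f"inconsistent atom count at line {i + 1}")
        for atom_line in block:
            parts = atom_line.split()
            if len(parts) < 4:
                raise ValueError(f"malformed atom line: '{atom_line}'")
            positions.append([float(parts[1]), float(parts[2]), float(parts[3])])
        times.append(t)
        frame += 1
        i += 2 + n_atoms
    return np.asarray(positions), np.asarray(times)


def read_pdb_coords(
    path: str | Path,
    chain: str | None = None,
    residues: Sequence[str | int] | None = None,
    atom_names: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract coordinates (Å) and masses (amu) of selected PDB atoms.

    ``residues`` entries may be residue names ("TRP") or residue
    sequence numbers.  Raises ``ValueError`` when nothing matches.
    """
    import warnings

    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("s", str(path))

    res_names = {str(r).upper() for r in residues} if residues is not None else None
    wanted_atoms = {a.upper() for a in atom_names} if atom_names is not None else None

    coords, masses = [], []
    for model in structure:
        for ch in model:
            if chain is not None and ch.id != chain:
                continue
            for res in ch:
                if res_names is not None:
                    resname = res.get_resname().strip().upper()
                    resseq = str(res.get_id()[1])
                    if resname not in res_names and resseq not in res_names:
                        continue
                for atom in res:
                    if wanted_atoms is not None and atom.get_name().upper() not in wanted_atoms:
                        continue
                    element = (atom.element or "").strip().upper()
                    mass = _ATOM_MASSES.get(element)
                    if mass is None:
                        mass = float(atom.mass) if atom.mass == atom.mass else None
                    if mass is None:
                        raise ValueError(
                            f"cannot infer mass for atom '{atom.get_name()}'"
                        )
                    coords.append(atom.coord.tolist())
                    masses.append(mass)
        break  # first model only
    if not coords:
        raise ValueError("selection matched no atoms")
    return np.asarray(coords, dtype=float), np.asarray(masses, dtype=float)


def write_supervision_log(run: SuMDRun, path: str | Path) -> None:
    """Supervision decisions as CSV (fixed precision, reproducible bytes)."""
    lines = ["window_index,start_time_ps,slope_A_per_ps,decision,end_distance_A\n"]
    for rec in run.log:
        lines.append(
            f"{rec.window_index},{rec.start_time:.6f},{rec.slope_m:.6f},"
            f"{rec.decision},{rec.end_distance:.6f}\n"
        )
    Path(path).write_text("".join(lines))


def write_series_csv(
    path: str | Path, columns: Mapping[str, Sequence[float]]
) -> None:
    """Aligned numeric columns as CSV with fixed six-decimal formatting."""
    names = list(columns)
    arrays = [np.asarray(columns[n], dtype=float) for n in names]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("columns must have equal length")
    lines = [",".join(names) + "\n"]
    for i in range(n):
        lines.append(",".join(f"{a[i]:.6f}" for a in arrays) + "\n")
    Path(path).write_text("".join(lines))


def write_path_pdb(nodes: Sequence[PathNode], path: str | Path) -> None:
    """Path nodes as HETATM pseudo-atoms with B-factor ∝ residence time.

    B-factors are scaled so the longest residence maps to 99.99, which
    molecular viewers render as the largest sphere.
    """
    if not nodes:
        raise ValueError("no path nodes to write")
    max_res = max(n.residence_time for n in nodes) or 1.0
    lines = []
    for i, node in enumerate(nodes, start=1):
        x, y, z = _frame_xyz(np.asarray(node.position))
        b = 99.99 * node.residence_time / max_res
        lines.append(
            f"HETATM{i:5d}  C   PTH A{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}           C\n"
        )
    lines.append("END\n")
    Path(path).write_text("".join(lines))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record for one CLI run: configs, seed, output checksums."""

    command: str
    seed: int | None
    configs: dict
    outputs: dict = field(default_factory=dict)
    version: str = ""

    def record_outputs(self, paths: Sequence[str | Path]) -> None:
        for p in paths:
            p = Path(p)
            self.outputs[p.name] = _sha256(p)

    def write(self, path: str | Path) -> None:
        payload = {
            "command": self.command,
            "seed": self.seed,
            "configs": self.configs,
            "software_version": self.version,
            "outputs": self.outputs,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        payload = json.loads(Path(path).read_text())
        m = cls(
            command=payload["command"],
            seed=payload["seed"],
            configs=payload["configs"],
            version=payload.get("software_version", ""),
        )
        m.outputs = payload["outputs"]
        return m
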