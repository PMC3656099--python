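"""Multi-frame coordinate containers, PDB/XYZ I/O, and frame/time bookkeeping.

A trajectory is an ordered stack of frames with a fixed recording interval
(default 200 ps per frame).  Frame indices are 0-based; a span's duration is
``(end - start) * interval`` (the paper-anchored difference convention:
frames 6544-6635 at 200 ps give 18.2 ns).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AtomKey",
    "Frame",
    "Trajectory",
    "TrajectoryFormatError",
    "read_trajectory",
    "write_trajectory",
    "frame_to_time",
    "span_duration",
    "export_timeseries",
]

AtomKey = tuple[int, str]  # (hybrid residue id, atom name)

DEFAULT_INTERVAL_PS = 200.0


class TrajectoryFormatError(ValueError):
    """Raised for unreadable or inconsistent trajectory files."""


def frame_to_time(index: int, interval_ps: float = DEFAULT_INTERVAL_PS) -> float:
    """Time of a frame in nanoseconds (``index * interval``); linear in index."""
    if index < 0:
        raise ValueError(f"frame index must be >= 0, got {index}")
    return index * interval_ps / 1000.0


def span_duration(f_start: int, f_end: int,
                  interval_ps: float = DEFAULT_INTERVAL_PS) -> float:
    """Duration of a frame span in nanoseconds, end-minus-start convention."""
    if f_end < f_start:
        raise ValueError(f"span end {f_end} precedes start {f_start}")
    return (f_end - f_start) * interval_ps / 1000.0


class Trajectory:
    """Ordered coordinate frames over a fixed atom inventory.

    Parameters
    ----------
    atoms:
        Atom keys ``(residue id, atom name)`` defining the column order.
    xyz:
        Array of shape ``(n_frames, n_atoms, 3)`` in Angstrom.
    resnames:
        Residue-id to residue-name map used when writing PDB.
    recording_interval_ps:
        Picoseconds of simulated time per stored frame.
    """

    def __init__(self, atoms: Sequence[AtomKey], xyz: np.ndarray,
                 resnames: Mapping[int, str] | None = None,
                 recording_interval_ps: float = DEFAULT_INTERVAL_PS,
                 ligand_present: bool = True, label: str = ""):
        xyz = np.asarray(xyz, dtype=float)
        if xyz.ndim != 3 or xyz.shape[1] != len(atoms) or xyz.shape[2] != 3:
            raise ValueError(f"xyz shape {xyz.shape} does not match {len(atoms)} atoms")
        if not np.isfinite(xyz).all():
            raise ValueError("trajectory coordinates must be finite")
        if recording_interval_ps <= 0:
            raise ValueError("recording interval must be positive")
        if len(set(atoms)) != len(atoms):
            raise ValueError("duplicate atom keys")
        self.atoms: list[AtomKey] = [tuple(a) for a in atoms]
        self.xyz = xyz
        self.resnames = dict(resnames or {})
        self.recording_interval_ps = float(recording_interval_ps)
        self.ligand_present = ligand_present
        self.label = label
        self._index = {a: i for i, a in enumerate(self.atoms)}

    # -- basic access ---------------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.xyz.shape[1]

    def column(self, key: AtomKey) -> int:
        try:
            return self._index[tuple(key)]
        except KeyError:
            raise KeyError(f"atom {key} not in trajectory") from None

    def has_atom(self, key: AtomKey) -> bool:
        return tuple(key) in self._index

    def atom_series(self, key: AtomKey) -> np.ndarray:
        """(n_frames, 3) coordinate series of one atom."""
        return self.xyz[:, self.column(key), :]

    def frame(self, i: int) -> "Frame":
        if not 0 <= i < self.n_frames:
            raise IndexError(f"frame {i} out of range")
        return Frame(self, i)

    def frames(self) -> Iterator["Frame"]:
        return (Frame(self, i) for i in range(self.n_frames))

    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.recording_interval_ps / 1000.0

    def residue_ids(self) -> list[int]:
        return sorted({rid for rid, _ in self.atoms})


@dataclass(frozen=True)
class Frame:
    """A single coordinate snapshot; behaves as a (resid, atom) -> xyz map."""

    trajectory: Trajectory
    index: int

    def __getitem__(self, key: AtomKey) -> np.ndarray:
        return self.trajectory.xyz[self.index, self.trajectory.column(key), :]

    def get(self, key: AtomKey, default=None):
        if self.trajectory.has_atom(key):
            return self[key]
        return default

    def __contains__(self, key: AtomKey) -> bool:
        return self.trajectory.has_atom(key)

    @property
    def coords(self) -> dict[AtomKey, np.ndarray]:
        xyz = self.trajectory.xyz[self.index]
        return {a: xyz[i] for i, a in enumerate(self.trajectory.atoms)}

    @property
    def time_ns(self) -> float:
        return frame_to_time(self.index, self.trajectory.recording_interval_ps)

    def residue_atoms(self, resid: int) -> dict[str, np.ndarray]:
        xyz = self.trajectory.xyz[self.index]
        return {name: xyz[i] for i, (rid, name) in enumerate(self.trajectory.atoms)
                if rid == resid}


# ---------------------------------------------------------------------------
# Multi-model PDB (canonical dialect) and XYZ-per-frame fallback.
# ---------------------------------------------------------------------------

def _pdb_fullname(name: str) -> str:
    # Single-letter elements start in column 14, two-letter (MG) in column 13.
    if len(name) >= 4 or name[:2] in ("MG", "FE", "ZN", "CL", "BR", "NA"):
        return f"{name:<4}"
    return f" {name:<3}"


def write_trajectory(traj: Trajectory, path: str | Path, format: str = "pdb") -> None:
    """Write a trajectory as multi-model PDB (default) or XYZ-per-frame."""
    path = Path(path)
    if format == "pdb":
        _write_pdb(traj, path)
    elif format == "xyz":
        _write_xyz(traj, path)
    else:
        raise TrajectoryFormatError(f"unknown trajectory format {format!r}")


def _element_of(name: str) -> str:
    if name[:2] in ("MG",):
        return "MG"
    stripped = name.strip("0123456789'\"*")
    return stripped[:1].upper() if stripped else "X"


def _write_pdb(traj: Trajectory, path: Path) -> None:
    lines: list[str] = []
    multi = traj.n_frames > 1
    for f in range(traj.n_frames):
        if multi:
            lines.append(f"MODEL     {f + 1:4d}")
        serial = 1
        for i, (rid, name) in enumerate(traj.atoms):
            x, y, z = traj.xyz[f, i]
            resname = traj.resnames.get(rid, "UNK")
            elem = _element_of(name)
            lines.append(
                f"ATOM  {serial:5d} {_pdb_fullname(name)} {resname:>3s} A"
                f"{rid:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {elem:>2s}"
            )
            serial += 1
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _parse_pdb(path: Path) -> tuple[list[AtomKey], dict[int, str], list[np.ndarray]]:
    """Parse a multi-model PDB via Bio.PDB, preserving model order."""
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure("traj", str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise TrajectoryFormatError(f"{path}: bad PDB record: {exc}") from exc

    models = list(structure)
    if not models:
        raise TrajectoryFormatError(f"{path}: no MODEL/ATOM records found")

    atoms: list[AtomKey] = []
    resnames: dict[int, str] = {}
    frames: list[np.ndarray] = []
    for m_i, model in enumerate(models):
        keys: list[AtomKey] = []
        coords: list[np.ndarray] = []
        for chain in model:
            for residue in chain:
                rid = residue.id[1]
                resnames.setdefault(rid, residue.get_resname().strip())
                for atom in residue:
                    keys.append((rid, atom.get_name()))
                    coords.append(atom.get_coord().astype(float))
        if m_i == 0:
            atoms = keys
        elif keys != atoms:
            raise TrajectoryFormatError(
                f"{path}: model {m_i + 1} atom inventory differs from model 1")
        frames.append(np.array(coords))
    if not atoms:
        raise TrajectoryFormatError(f"{path}: no ATOM records found")
    return atoms, resnames, frames


def read_trajectory(path: str | Path, format: str = "pdb",
                    recording_interval_ps: float = DEFAULT_INTERVAL_PS,
                    ligand_present: bool = True, label: str = "") -> Trajectory:
    """Read a multi-model PDB (one frame per MODEL) or XYZ-per-frame file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise TrajectoryFormatError(f"{path}: empty trajectory file")
    if format == "pdb":
        atoms, resnames, frames = _parse_pdb(path)
    elif format == "xyz":
        atoms, resnames, frames = _parse_xyz(path)
    else:
        raise TrajectoryFormatError(f"unknown trajectory format {format!r}")
    xyz = np.stack(frames)
    return Trajectory(atoms, xyz, resnames, recording_interval_ps,
                      ligand_present, label or path.stem)


def _write_xyz(traj: Trajectory, path: Path) -> None:
    """Documented fallback: per frame, a count line, a comment line, then one
    ``resname resid atomname x y z`` line per atom (free-format whitespace)."""
    lines = []
    for f in range(traj.n_frames):
        lines.append(str(traj.n_atoms))
        lines.append(f"frame {f}")
        for i, (rid, name) in enumerate(traj.atoms):
            x, y, z = traj.xyz[f, i]
            resname = traj.resnames.get(rid, "UNK")
            lines.append(f"{resname} {rid} {name} {x:.3f} {y:.3f} {z:.3f}")
    path.write_text("\n".join(lines) + "\n")


def _parse_xyz(path: Path) -> tuple[list[AtomKey], dict[int, str], list[np.ndarray]]:
    raw = path.read_text().splitlines()
    pos = 0
    atoms: list[AtomKey] = []
    resnames: dict[int, str] = {}
    frames: list[np.ndarray] = []
    while pos < len(raw):
        if not raw[pos].strip():
            pos += 1
            continue
        try:
            n = int(raw[pos].split()[0])
        except ValueError:
            raise TrajectoryFormatError(
                f"{path}: line {pos + 1}: expected atom count, got {raw[pos]!r}")
        block = raw[pos + 2: pos + 2 + n]
        if len(block) < n:
            raise TrajectoryFormatError(f"{path}: truncated frame at line {pos + 1}")
        keys, coords = [], []
        for j, line in enumerate(block):
            parts = line.split()
            try:
                resname, rid, name = parts[0], int(parts[1]), parts[2]
                xyz = [float(v) for v in parts[3:6]]
            except (IndexError, ValueError):
                raise TrajectoryFormatError(
                    f"{path}: line {pos + 3 + j}: bad atom record {line!r}")
            resnames.setdefault(rid, resname)
            keys.append((rid, name))
            coords.append(xyz)
        if not frames:
            atoms = keys
        elif keys != atoms:
            raise TrajectoryFormatError(
                f"{path}: frame {len(frames) + 1} atom inventory differs")
        frames.append(np.array(coords))
        pos += 2 + n
    if not frames:
        raise TrajectoryFormatError(f"{path}: no frames found")
    return atoms, resnames, frames


def export_timeseries(values: Mapping[str, np.ndarray] | pd.DataFrame,
                      path: str | Path,
                      interval_ps: float = DEFAULT_INTERVAL_PS) -> pd.DataFrame:
    """Write a per-frame quantity table as CSV with frame and time_ns columns."""
    df = pd.DataFrame(values)
    df.insert(0, "frame", np.arange(len(df)))
    df.insert(1, "time_ns", df["frame"] * interval_ps / 1000.0)
    df.to_csv(path, index=False)
    return df
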