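"""Trajectory and tabular I/O.

Conventions used throughout the package: lengths in Å, times in ns, angles
in degrees.  Residue numbering is kept 1-based exactly as found in the
source PDB (residues are cited by PDB number); frame indices are 0-based.

Topologies are plain PDB files.  Frame data is either a multi-model PDB or
a whitespace-delimited XYZ table (three floats per atom line, frames
separated by blank lines, or a flat block that is reshaped against the
topology atom count).  Binary trajectory formats are out of scope.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

__all__ = [
    "Atom",
    "Trajectory",
    "FeatureDescriptor",
    "FeatureTable",
    "read_trajectory",
    "write_trajectory",
    "write_representatives",
    "read_feature_table",
    "write_feature_table",
    "write_matrix",
    "read_matrix",
]


@dataclass(frozen=True)
class Atom:
    """One atom of the (frame-invariant) topology."""

    name: str
    res_name: str
    res_id: int  # 1-based, as in the source PDB
    chain_id: str
    element: str = ""


@dataclass
class Trajectory:
    """Topology plus per-frame coordinates.

    coords has shape (n_frames, n_atoms, 3) in Å; frame_interval is the
    sampling interval in ns (0.1 ns for the reference systems).
    """

    atoms: list[Atom]
    coords: np.ndarray
    frame_interval: float = 0.1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"coords has {self.coords.shape[1]} atoms but topology has "
                f"{len(self.atoms)}"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def slice_frames(self, indices: Sequence[int]) -> "Trajectory":
        return Trajectory(self.atoms, self.coords[list(indices)], self.frame_interval)


@dataclass(frozen=True)
class FeatureDescriptor:
    """Descriptor of one feature column: its kind, the selection it was
    computed from and its unit."""

    kind: str  # chi1 | helix_distance | ligand_distance | sasa | generic
    selection: str
    units: str

    def __str__(self) -> str:  # header token, must not contain tabs
        return f"{self.kind}|{self.selection}|{self.units}"

    @staticmethod
    def parse(token: str) -> "FeatureDescriptor":
        parts = token.split("|")
        if len(parts) != 3:
            raise ValueError(f"malformed feature descriptor {token!r}")
        return FeatureDescriptor(*parts)


@dataclass
class FeatureTable:
    """frames x features values with per-feature descriptors."""

    values: np.ndarray
    descriptors: list[FeatureDescriptor]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.descriptors):
            raise ValueError("descriptor count does not match feature count")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def hstack(self, other: "FeatureTable") -> "FeatureTable":
        if other.n_frames != self.n_frames:
            raise ValueError("frame counts differ")
        return FeatureTable(
            np.hstack([self.values, other.values]),
            self.descriptors + other.descriptors,
        )


# ---------------------------------------------------------------------------
# PDB <-> Trajectory


def _atoms_from_array(array: struc.AtomArray) -> list[Atom]:
    return [
        Atom(
            name=str(array.atom_name[i]),
            res_name=str(array.res_name[i]),
            res_id=int(array.res_id[i]),
            chain_id=str(array.chain_id[i]),
            element=str(array.element[i]) if "element" in array.get_annotation_categories() else "",
        )
        for i in range(array.array_length())
    ]


def _check_model_atom_counts(path: Path, n_expected: int) -> None:
    """Pre-scan a multi-model PDB so an atom-count mismatch can be reported
    with the offending frame index."""
    counts: list[int] = []
    current = 0
    in_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "MODEL ":
                in_model = True
                current = 0
            elif rec == "ENDMDL":
                counts.append(current)
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                current += 1
        if in_model:
            counts.append(current)
    for frame, c in enumerate(counts):
        if c != n_expected:
            raise ValueError(
                f"frame {frame} has {c} atoms but topology has {n_expected}"
            )


def _parse_xyz_frames(path: Path, n_atoms: int) -> np.ndarray:
    """Whitespace-delimited XYZ frames; blank lines separate frames.  A flat
    stream without blank lines is reshaped against the topology."""
    blocks: list[list[list[float]]] = [[]]
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                if blocks[-1]:
                    blocks.append([])
                continue
            blocks[-1].append([float(x) for x in stripped.split()[:3]])
    if blocks and not blocks[-1]:
        blocks.pop()
    if not blocks:
        raise ValueError("no coordinate frames found")
    if len(blocks) == 1 and len(blocks[0]) % n_atoms == 0 and len(blocks[0]) != n_atoms:
        flat = np.asarray(blocks[0], dtype=float)
        return flat.reshape(-1, n_atoms, 3)
    for frame, block in enumerate(blocks):
        if len(block) != n_atoms:
            raise ValueError(
                f"frame {frame} has {len(block)} atoms but topology has {n_atoms}"
            )
    return np.asarray(blocks, dtype=float)


def read_trajectory(
    topology_path: str | Path,
    frames_path: str | Path | None = None,
    frame_interval: float = 0.1,
) -> Trajectory:
    """Read a topology PDB plus frames (multi-model PDB or XYZ table).

    With ``frames_path=None`` the models of the topology file itself are the
    frames.
    """
    topology_path = Path(topology_path)
    pdb_file = pdbio.PDBFile.read(str(topology_path))
    template = pdb_file.get_structure(model=1)
    atoms = _atoms_from_array(template)
    n_atoms = len(atoms)

    if frames_path is None:
        _check_model_atom_counts(topology_path, n_atoms)
        stack = pdb_file.get_structure()
        coords = np.asarray(stack.coord, dtype=float).reshape(-1, n_atoms, 3)
        return Trajectory(atoms, coords, frame_interval)

    frames_path = Path(frames_path)
    if frames_path.suffix.lower() in (".pdb", ".ent"):
        _check_model_atom_counts(frames_path, n_atoms)
        stack = pdbio.PDBFile.read(str(frames_path)).get_structure()
        coords = np.asarray(stack.coord, dtype=float).reshape(-1, n_atoms, 3)
    else:
        coords = _parse_xyz_frames(frames_path, n_atoms)
    return Trajectory(atoms, coords, frame_interval)


def _to_atom_array(traj: Trajectory, frame: int) -> struc.AtomArray:
    n = traj.n_atoms
    array = struc.AtomArray(n)
    array.coord = traj.coords[frame].astype(np.float32)
    array.atom_name = np.array([a.name for a in traj.atoms])
    array.res_name = np.array([a.res_name for a in traj.atoms])
    array.res_id = np.array([a.res_id for a in traj.atoms])
    array.chain_id = np.array([a.chain_id for a in traj.atoms])
    array.element = np.array([a.element or _guess_element(a.name) for a in traj.atoms])
    array.hetero = np.zeros(n, dtype=bool)
    return array


def _guess_element(atom_name: str) -> str:
    # PDB protein atom names start with the element letter (CA is C-alpha,
    # not calcium); two-letter elements only for a few common ions.
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[:2].upper() in ("CL", "BR", "MG", "ZN", "FE", "MN"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


def write_trajectory(traj: Trajectory, frames_path: str | Path) -> None:
    """Write frames as multi-model PDB (.pdb) or XYZ table (anything else)."""
    frames_path = Path(frames_path)
    if frames_path.suffix.lower() == ".pdb":
        stack = struc.stack([_to_atom_array(traj, f) for f in range(traj.n_frames)])
        out = pdbio.PDBFile()
        out.set_structure(stack)
        out.write(str(frames_path))
    else:
        with open(frames_path, "w") as fh:
            fh.write(f"# xyz frames, {traj.n_atoms} atoms, interval {traj.frame_interval} ns\n")
            for f in range(traj.n_frames):
                for x, y, z in traj.coords[f]:
                    fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
                fh.write("\n")


def write_representatives(
    traj: Trajectory,
    frame_indices: Sequence[int],
    out_dir: str | Path,
    prefix: str = "rep",
) -> list[Path]:
    """Write one single-model PDB per frame index.

    Duplicate indices produce distinct files via an ordinal suffix.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seen: dict[int, int] = {}
    paths: list[Path] = []
    for idx in frame_indices:
        idx = int(idx)
        if not 0 <= idx < traj.n_frames:
            raise IndexError(f"frame index {idx} out of range (n_frames={traj.n_frames})")
        ordinal = seen.get(idx, 0)
        seen[idx] = ordinal + 1
        suffix = f"_{ordinal}" if ordinal else ""
        path = out_dir / f"{prefix}_frame{idx}{suffix}.pdb"
        out = pdbio.PDBFile()
        out.set_structure(_to_atom_array(traj, idx))
        out.write(str(path))
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# tabular artifacts (TSV)


def write_feature_table(table: FeatureTable, path: str | Path, header_meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, val in (header_meta or {}).items():
            fh.write(f"# {key}={val}\n")
        fh.write("\t".join(str(d) for d in table.descriptors) + "\n")
        np.savetxt(fh, table.values, fmt="%.8g", delimiter="\t")


def read_feature_table(path: str | Path) -> FeatureTable:
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    header = lines[0].rstrip("\n").split("\t")
    descriptors = [FeatureDescriptor.parse(tok) for tok in header]
    values = np.loadtxt(io.StringIO("".join(lines[1:])), delimiter="\t", ndmin=2)
    return FeatureTable(values, descriptors)


def write_matrix(matrix: np.ndarray, path: str | Path, header_meta: dict | None = None) -> None:
    """Write a matrix (e.g. a TPM with its lag) as TSV with '#' metadata."""
    with open(path, "w") as fh:
        for key, val in (header_meta or {}).items():
            fh.write(f"# {key}={val}\n")
        np.savetxt(fh, np.atleast_2d(matrix), fmt="%.12g", delimiter="\t")


def read_matrix(path: str | Path) -> tuple[np.ndarray, dict]:
    meta: dict[str, str] = {}
    rows: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
            else:
                rows.append(line)
    return np.loadtxt(io.StringIO("".join(rows)), delimiter="\t", ndmin=2), meta
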