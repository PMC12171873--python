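"""Geometric observables used to characterise transporter states.

The observables are the ones the gating analysis is built on: first
side-chain dihedrals (chi1) with their rotamer classes, inter-helix
centre-of-geometry distances, minimum ligand-residue distances capped at a
fixed radius, contact residence (occupancy) with the 4 Å / 50% convention,
and per-selection solvent accessible surface area (Shrake-Rupley).

Selections are strings of the form ``"A:388"``, ``"A:5-30"`` (chain and
1-based residue range), ``"resname:URA"`` or ``"name:CA"``; conjunctions
are written with ``&`` (e.g. ``"A:5-30&name:CA"``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .trajectory_io import FeatureDescriptor, FeatureTable, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "RotamerClass",
    "ResidenceReport",
    "select_atoms",
    "compute_chi1",
    "classify_rotamer",
    "compute_helix_distance",
    "compute_ligand_distances",
    "residence_time",
    "compute_sasa",
]

#: gamma atom completing the chi1 quadruplet (N, CA, CB, gamma), by residue.
CHI1_GAMMA_ATOM = {
    "SER": "OG",
    "THR": "OG1",
    "CYS": "SG",
    "ILE": "CG1",
    "VAL": "CG1",
}
_DEFAULT_GAMMA = "CG"
_NO_CHI1 = {"GLY", "ALA"}

#: van der Waals radii (Å) keyed by element; unknown elements fall back to
#: 1.5 Å with a warning.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
}
_FALLBACK_RADIUS = 1.5


@dataclass(frozen=True)
class RotamerClass:
    """trans (180°), gauche_plus (−60°) or gauche_minus (+60°)."""

    label: str

    def __post_init__(self) -> None:
        if self.label not in ("trans", "gauche_plus", "gauche_minus"):
            raise ValueError(f"unknown rotamer label {self.label!r}")


TRANS = RotamerClass("trans")
GAUCHE_PLUS = RotamerClass("gauche_plus")
GAUCHE_MINUS = RotamerClass("gauche_minus")


@dataclass(frozen=True)
class ResidenceReport:
    """Contact occupancy of a selection pair under a distance cutoff."""

    pair: str
    cutoff: float
    occupancy: float
    consistent: bool  # strictly above 50% occupancy


# ---------------------------------------------------------------------------
# selections


def _match_clause(traj: Trajectory, clause: str) -> np.ndarray:
    clause = clause.strip()
    key, _, rest = clause.partition(":")
    mask = np.zeros(traj.n_atoms, dtype=bool)
    if key == "resname":
        for i, a in enumerate(traj.atoms):
            mask[i] = a.res_name == rest
    elif key == "name":
        for i, a in enumerate(traj.atoms):
            mask[i] = a.name == rest
    elif key == "index":
        for tok in rest.split(","):
            mask[int(tok)] = True
    else:  # chain:resid or chain:lo-hi
        chain = key
        if "-" in rest:
            lo, hi = (int(x) for x in rest.split("-"))
        else:
            lo = hi = int(rest)
        for i, a in enumerate(traj.atoms):
            mask[i] = a.chain_id == chain and lo <= a.res_id <= hi
    return mask


def select_atoms(traj: Trajectory, selection: str | list) -> np.ndarray:
    """Resolve a selection expression to atom indices."""
    if isinstance(selection, (int, np.integer)):  # bare 1-based residue number
        return np.array(
            [i for i, a in enumerate(traj.atoms) if a.res_id == int(selection)], dtype=int
        )
    if isinstance(selection, (list, tuple, np.ndarray)):
        parts = [select_atoms(traj, s) for s in selection]
        return np.unique(np.concatenate(parts)) if parts else np.array([], dtype=int)
    mask = np.ones(traj.n_atoms, dtype=bool)
    for clause in str(selection).split("&"):
        mask &= _match_clause(traj, clause)
    return np.nonzero(mask)[0]


def _residue_groups(traj: Trajectory, atom_idx: np.ndarray):
    """Group selected atom indices by (chain, resid); preserves order."""
    groups: dict[tuple[str, int], list[int]] = {}
    for i in atom_idx:
        a = traj.atoms[i]
        groups.setdefault((a.chain_id, a.res_id), []).append(int(i))
    return groups


# ---------------------------------------------------------------------------
# dihedrals and rotamers


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Signed dihedral in degrees in (−180, 180], vectorised over frames."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    m1 = np.cross(n1, b1n)
    x = np.einsum("...i,...i", n1, n2)
    y = np.einsum("...i,...i", m1, n2)
    ang = np.degrees(np.arctan2(y, x))
    # map the closed branch point −180° to +180°
    return np.where(ang <= -180.0 + 1e-12, ang + 360.0, ang)


def compute_chi1(traj: Trajectory, residues: str | list) -> FeatureTable:
    """chi1 (N-CA-CB-gamma) per frame for each selected residue.

    Residues without a gamma atom (GLY/ALA or incomplete side chains) are
    skipped with a warning.
    """
    idx = select_atoms(traj, residues)
    groups = _residue_groups(traj, idx)
    cols, descs = [], []
    for (chain, resid), atom_ids in groups.items():
        res_name = traj.atoms[atom_ids[0]].res_name
        if res_name in _NO_CHI1:
            logger.warning("residue %s:%d (%s) has no chi1; skipped", chain, resid, res_name)
            continue
        gamma = CHI1_GAMMA_ATOM.get(res_name, _DEFAULT_GAMMA)
        by_name = {traj.atoms[i].name: i for i in atom_ids}
        quad = [by_name.get(n) for n in ("N", "CA", "CB", gamma)]
        if any(q is None for q in quad):
            logger.warning(
                "residue %s:%d (%s) missing chi1 atoms; skipped", chain, resid, res_name
            )
            continue
        p = [traj.coords[:, q, :] for q in quad]
        cols.append(dihedral(*p))
        descs.append(FeatureDescriptor("chi1", f"{chain}:{resid}", "deg"))
    if not cols:
        raise ValueError("no residue in the selection has a computable chi1")
    return FeatureTable(np.column_stack(cols), descs)


def classify_rotamer(chi1: float) -> RotamerClass:
    """Rotamer class of a chi1 angle in (−180, 180].

    trans for \\|chi1\\| ≥ 120, gauche(+) (the −60° well) for −120 < chi1 < 0,
    gauche(−) (the +60° well) for 0 ≤ chi1 < 120.
    """
    if not -180.0 < chi1 <= 180.0:
        raise ValueError("chi1 must lie in (-180, 180]")
    if abs(chi1) >= 120.0:
        return TRANS
    if chi1 < 0.0:
        return GAUCHE_PLUS
    return GAUCHE_MINUS


# ---------------------------------------------------------------------------
# distances


def compute_helix_distance(traj: Trajectory, range_a: str, range_b: str) -> FeatureTable:
    """Distance between CA centres of geometry of two residue spans (Å)."""
    out_cols = []
    for rng in (range_a, range_b):
        idx = select_atoms(traj, rng)
        ca = [i for i in idx if traj.atoms[i].name == "CA"]
        if not ca:
            raise ValueError(f"selection {rng!r} contains no CA atoms")
        out_cols.append(traj.coords[:, ca, :].mean(axis=1))
    dist = np.linalg.norm(out_cols[0] - out_cols[1], axis=1)
    desc = FeatureDescriptor("helix_distance", f"{range_a} vs {range_b}", "angstrom")
    return FeatureTable(dist[:, None], [desc])


def _min_dist_per_frame(coords_a: np.ndarray, coords_b: np.ndarray) -> np.ndarray:
    """Minimum atom-pair distance per frame; coords_* are (F, n, 3)."""
    diff = coords_a[:, :, None, :] - coords_b[:, None, :, :]
    return np.sqrt((diff**2).sum(-1)).reshape(coords_a.shape[0], -1).min(axis=1)


def compute_ligand_distances(
    traj: Trajectory,
    ligand: str | list,
    residues: str | list,
    cap: float = 12.0,
) -> FeatureTable:
    """Capped minimum ligand-residue distance per frame and residue.

    Distances above ``cap`` (default 12 Å) are replaced by the cap value,
    matching the capped-input convention of the pathway detector.
    """
    lig_idx = select_atoms(traj, ligand)
    if lig_idx.size == 0:
        raise ValueError("empty ligand selection")
    res_idx = select_atoms(traj, residues)
    if res_idx.size == 0:
        raise ValueError("empty residue selection")
    lig = traj.coords[:, lig_idx, :]
    cols, descs = [], []
    for (chain, resid), atom_ids in _residue_groups(traj, res_idx).items():
        d = _min_dist_per_frame(lig, traj.coords[:, atom_ids, :])
        cols.append(np.minimum(d, cap))
        descs.append(FeatureDescriptor("ligand_distance", f"{chain}:{resid}", "angstrom"))
    return FeatureTable(np.column_stack(cols), descs)


def residence_time(
    traj: Trajectory,
    selection_a: str | list,
    selection_b: str | list,
    cutoff: float = 4.0,
) -> ResidenceReport:
    """Fraction of frames with min inter-selection distance below cutoff.

    A contact is called consistent when its occupancy is strictly above 50%.
    """
    if traj.n_frames == 0:
        raise ValueError("trajectory has no frames")
    ia = select_atoms(traj, selection_a)
    ib = select_atoms(traj, selection_b)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("empty selection")
    d = _min_dist_per_frame(traj.coords[:, ia, :], traj.coords[:, ib, :])
    occupancy = float((d < cutoff).mean())
    return ResidenceReport(
        pair=f"{selection_a} -- {selection_b}",
        cutoff=cutoff,
        occupancy=occupancy,
        consistent=occupancy > 0.5,
    )


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _atom_radii(traj: Trajectory) -> np.ndarray:
    radii = np.empty(traj.n_atoms)
    warned: set[str] = set()
    for i, a in enumerate(traj.atoms):
        element = (a.element or a.name.strip().lstrip("0123456789")[:1]).upper()
        if element in VDW_RADII:
            radii[i] = VDW_RADII[element]
        elif element[:2] in VDW_RADII:
            radii[i] = VDW_RADII[element[:2]]
        else:
            if element not in warned:
                logger.warning("unknown element %r: using %.1f Å radius", element, _FALLBACK_RADIUS)
                warned.add(element)
            radii[i] = _FALLBACK_RADIUS
    return radii


def compute_sasa(
    traj: Trajectory,
    residues: str | list,
    probe: float = 1.4,
    n_points: int = 960,
) -> FeatureTable:
    """Shrake-Rupley SASA (Å²) summed over the selection, per frame.

    Test points are placed on each selected atom's solvent-expanded sphere
    and counted as accessible when outside every neighbouring expanded
    sphere; all atoms of the trajectory occlude, so the value is the
    selection's surface in the context of the full structure.
    """
    sel = select_atoms(traj, residues)
    if sel.size == 0:
        raise ValueError("empty selection")
    radii = _atom_radii(traj) + probe
    unit = _sphere_points(n_points)
    out = np.zeros(traj.n_frames)
    max_r = radii.max()
    for f in range(traj.n_frames):
        pos = traj.coords[f]
        tree = cKDTree(pos)
        total = 0.0
        for i in sel:
            pts = pos[i] + radii[i] * unit
            neighbors = [j for j in tree.query_ball_point(pos[i], radii[i] + max_r) if j != i]
            if neighbors:
                npos = pos[neighbors]
                nrad = radii[neighbors]
                d2 = ((pts[:, None, :] - npos[None, :, :]) ** 2).sum(-1)
                accessible = (d2 >= (nrad**2)[None, :]).all(axis=1)
                frac = accessible.mean()
            else:
                frac = 1.0
            total += 4.0 * np.pi * radii[i] ** 2 * frac
        out[f] = total
    desc = FeatureDescriptor("sasa", str(residues), "angstrom^2")
    return FeatureTable(out[:, None], [desc])
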