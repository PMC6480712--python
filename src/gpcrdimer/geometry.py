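"""Geometric kernels: Kabsch superposition, RMSD traces, dihedrals, distances.

Angle convention
----------------
Dihedrals are computed with the usual two-plane-normal (IUPAC sign)
construction and then mapped from (-180, 180] degrees onto [0, 360) by
adding 360 to negative values.  The sidechain chi1 pseudo-states used
downstream (trans near 180 deg, "cis" near 300 deg, split at 240 deg) are
only representable on this wrapped range, which is why no operation in the
package ever exposes a signed angle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import SelectionError, TopologyError
from .model_io import BWMap, Structure, Trajectory
from .selections import select

__all__ = [
    "RmsdTrace",
    "kabsch_superpose",
    "rmsd_trace",
    "dihedral",
    "min_pair_distance",
    "tmd_backbone_selection",
]

_EQ_TOL = 1e-6  # Angstrom; package-wide float-equality tolerance


@dataclass
class RmsdTrace:
    """Per-frame RMSD (Angstrom) of a selection against a fixed reference."""

    times: np.ndarray  # ns
    values: np.ndarray  # Angstrom, >= 0
    selection: str
    reference: str  # "frame:<i>" | "final" | "external"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(self.values < -_EQ_TOL):
            raise ValueError("RMSD values must be non-negative")


def _check_point_set(points: np.ndarray, label: str) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"{label} must be an (M, 3) array")
    if pts.shape[0] < 3:
        raise ValueError(f"{label}: need at least 3 points, got {pts.shape[0]}")
    return pts


def _is_collinear(points: np.ndarray) -> bool:
    centered = points - points.mean(axis=0)
    # rank < 2 => all points on one line (or a single point)
    return np.linalg.matrix_rank(centered, tol=1e-8) < 2


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd_after)`` such that
    ``mobile @ rotation.T + translation`` minimizes RMSD to ``reference``
    over all proper rigid motions (SVD solution with determinant repair).
    """
    mob = _check_point_set(mobile, "mobile")
    ref = _check_point_set(reference, "reference")
    if mob.shape != ref.shape:
        raise ValueError("mobile and reference must have the same shape")
    if _is_collinear(ref):
        raise ValueError("reference point set is degenerate (collinear)")
    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    h = (mob - mob_c).T @ (ref - ref_c)
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ref_c - rot @ mob_c
    moved = mob @ rot.T + trans
    rmsd_after = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return rot, trans, rmsd_after


def _plain_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _resolve_reference_coords(
    traj: Trajectory, reference, atom_idx: np.ndarray
) -> tuple[np.ndarray, str]:
    if isinstance(reference, Structure):
        if reference.n_atoms == traj.n_atoms:
            return reference.xyz[atom_idx], "external"
        if reference.n_atoms == atom_idx.size:
            return reference.xyz, "external"
        raise TopologyError(
            "external reference must carry either the full topology or "
            "exactly the selected atoms"
        )
    if reference == "final":
        return traj.coords[-1, atom_idx], "final"
    if reference == "first":
        return traj.coords[0, atom_idx], "frame:0"
    i = int(reference)
    return traj.coords[i, atom_idx], f"frame:{i}"


def rmsd_trace(
    traj: Trajectory,
    selection: str,
    reference: int | str | Structure = 0,
    superpose: bool = True,
    fit_selection: str | None = None,
    bw_map: BWMap | None = None,
) -> RmsdTrace:
    """Per-frame RMSD of ``selection`` against a reference frame.

    With ``superpose=True`` every frame is first rigidly fitted to the
    reference.  ``fit_selection`` lets the fit run on a different atom set
    than the one measured -- the ligand-drift convention: superpose on the
    receptor TMD backbone, then measure the ligand without re-fitting it.
    """
    atom_idx = select(traj.topology, selection, bw_map)
    if atom_idx.size == 0:
        raise SelectionError(f"selection {selection!r} matched no atoms")
    ref_xyz, ref_desc = _resolve_reference_coords(traj, reference, atom_idx)

    if fit_selection is not None:
        fit_idx = select(traj.topology, fit_selection, bw_map)
        if fit_idx.size < 3:
            raise SelectionError(
                f"fit selection {fit_selection!r} needs >= 3 atoms"
            )
        fit_ref, _ = _resolve_reference_coords(traj, reference, fit_idx)
    else:
        fit_idx = atom_idx
        fit_ref = ref_xyz

    values = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        frame_sel = traj.coords[t, atom_idx]
        if superpose:
            rot, trans, _ = kabsch_superpose(traj.coords[t, fit_idx], fit_ref)
            frame_sel = frame_sel @ rot.T + trans
        values[t] = _plain_rmsd(frame_sel, ref_xyz)
    return RmsdTrace(traj.times.copy(), values, selection, ref_desc)


def tmd_backbone_selection(ca_only: bool = False) -> str:
    """Backbone selection string for the transmembrane domain.

    The TMD is every residue labeled TM1-TM7 in the BW map; "backbone"
    defaults to N, CA, C, O.  Whether a published backbone RMSD used CA-only
    or the full backbone is often unstated, so both variants are exposed.
    """
    names = "name CA" if ca_only else "backbone"
    return f"segment TM1 TM2 TM3 TM4 TM5 TM6 TM7 and {names}"


def dihedral(p1, p2, p3, p4) -> float | np.ndarray:
    """Torsion angle p1-p2-p3-p4 in degrees on [0, 360).

    Accepts single points (shape (3,)) or stacked frames (shape (T, 3));
    stacked inputs return a (T,) array.  Raises on collinear triples, where
    the torsion is undefined.
    """
    a1 = np.asarray(p1, dtype=float)
    a2 = np.asarray(p2, dtype=float)
    a3 = np.asarray(p3, dtype=float)
    a4 = np.asarray(p4, dtype=float)
    scalar = a1.ndim == 1
    a1, a2, a3, a4 = (np.atleast_2d(a) for a in (a1, a2, a3, a4))
    b1 = a2 - a1
    b2 = a3 - a2
    b3 = a4 - a3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1_norm = np.linalg.norm(n1, axis=1)
    n2_norm = np.linalg.norm(n2, axis=1)
    b2_len = np.linalg.norm(b2, axis=1)
    if np.any(b2_len < 1e-10) or np.any(np.linalg.norm(b1, axis=1) < 1e-10) \
            or np.any(np.linalg.norm(b3, axis=1) < 1e-10):
        raise ValueError("consecutive dihedral points must be distinct")
    if np.any(n1_norm < 1e-8) or np.any(n2_norm < 1e-8):
        raise ValueError("collinear triple: dihedral angle undefined")
    m = np.cross(n1, b2 / b2_len[:, None])
    x = np.sum(n1 * n2, axis=1)
    y = np.sum(m * n2, axis=1)
    ang = np.degrees(np.arctan2(-y, x))  # sign fixed so 270 deg example holds
    ang = np.mod(ang, 360.0)
    return float(ang[0]) if scalar else ang


def min_pair_distance(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Minimum distance over all cross pairs of two coordinate sets (Angstrom)."""
    a = np.asarray(group_a, dtype=float).reshape(-1, 3)
    b = np.asarray(group_b, dtype=float).reshape(-1, 3)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("min_pair_distance: both groups must be non-empty")
    return float(cdist(a, b).min())
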