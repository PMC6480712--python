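"""Homodimer interface characterization.

Covers four report surfaces for a two-protomer (two-chain) receptor dimer:

* inter-protomer distance traces (center-of-geometry and minimum heavy-atom
  distance between helix selections);
* geometric hydrogen-bond occupancy between chosen donor/acceptor atoms;
* a simplified pairwise interaction energy across the interface;
* computational alanine scanning (sidechain truncation to C-beta on fixed
  backbone coordinates, then energy re-evaluation).

Energy model
------------
The interface energy is a deliberately simple surrogate, not a force field:

    E = sum over inter-protomer heavy-atom pairs with r < 12 A of
        q_i q_j * 332.0636 / (eps(r) * r)  +  4 eps_ij [ (s_ij/r)^12 - (s_ij/r)^6 ]

with a distance-dependent dielectric eps(r) = 4r (a common implicit-screening
choice), Lorentz-Berthelot combination of the packaged per-element LJ
parameters, and formal charges on ionizable sidechains only.  Its contract is
self-consistency -- rigid-motion invariance, protomer-swap symmetry, exact
additivity over pair terms -- which is what alanine-scan bookkeeping
(contribution = E_wt - E_mut) needs.  Absolute values are not comparable to
any particular published force-field or empirical energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ParameterError, SelectionError, TopologyError
from .geometry import min_pair_distance
from .model_io import Structure, Trajectory

__all__ = [
    "HBondCriterion",
    "InterfaceEnergyReport",
    "AlaScanResult",
    "EnergyModel",
    "load_energy_params",
    "interface_distance_trace",
    "residue_pair_min_distance",
    "hbond_occupancy",
    "interface_energy",
    "mutate_to_alanine",
    "alanine_scan",
    "energy_contribution",
    "COULOMB_CONSTANT",
    "ENERGY_CUTOFF",
]

COULOMB_CONSTANT = 332.0636  # kcal mol^-1 A e^-2
ENERGY_CUTOFF = 12.0  # Angstrom

_BACKBONE = {"N", "CA", "C", "O"}
_ALA_ATOMS = {"N", "CA", "C", "O", "CB"}


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class EnergyModel:
    """LJ + screened-Coulomb parameter set with cutoff, as loaded from TSV."""

    lj_sigma: dict[str, float]  # element -> Angstrom
    lj_epsilon: dict[str, float]  # element -> kcal/mol
    charges: dict[tuple[str, str], float]  # (resName, atomName) -> e
    cutoff: float = ENERGY_CUTOFF
    source: str = "packaged"

    def describe(self) -> str:
        return (
            f"LJ+Coulomb/eps(r)=4r, cutoff {self.cutoff:g} A, "
            f"params: {self.source}"
        )

    def atom_params(self, structure: Structure):
        """Per-atom (sigma, epsilon, charge) arrays; errors name the element."""
        n = structure.n_atoms
        sigma = np.empty(n)
        eps = np.empty(n)
        charge = np.zeros(n)
        for i in range(n):
            el = str(structure.element[i]).upper()
            if el not in self.lj_sigma:
                raise ParameterError(
                    f"no LJ parameters for element {el!r} "
                    f"(atom {structure.name[i]} of "
                    f"{structure.res_name[i]}{structure.res_seq[i]})"
                )
            sigma[i] = self.lj_sigma[el]
            eps[i] = self.lj_epsilon[el]
            charge[i] = self.charges.get(
                (str(structure.res_name[i]).upper(), str(structure.name[i]).upper()),
                0.0,
            )
        return sigma, eps, charge


def load_energy_params(path: str | Path | None = None,
                       cutoff: float = ENERGY_CUTOFF) -> EnergyModel:
    """Load the packaged (or a user-supplied) energy parameter TSV."""
    if path is None:
        ref = resources.files("gpcrdimer.data").joinpath("energy_params.tsv")
        text = ref.read_text()
        source = "packaged energy_params.tsv"
    else:
        text = Path(path).read_text()
        source = str(path)
    lj_sigma: dict[str, float] = {}
    lj_eps: dict[str, float] = {}
    charges: dict[tuple[str, str], float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "LJ" and len(parts) == 4:
            lj_sigma[parts[1].upper()] = float(parts[2])
            lj_eps[parts[1].upper()] = float(parts[3])
        elif parts[0] == "CHARGE" and len(parts) == 4:
            charges[(parts[1].upper(), parts[2].upper())] = float(parts[3])
        else:
            raise ValueError(f"bad parameter line: {line!r}")
    return EnergyModel(lj_sigma, lj_eps, charges, cutoff, source)


# ---------------------------------------------------------------------------
# Distances and H-bonds
# ---------------------------------------------------------------------------

def _split_protomers(structure: Structure, chain_a: str, chain_b: str):
    idx_a = np.flatnonzero(structure.chain_id == chain_a)
    idx_b = np.flatnonzero(structure.chain_id == chain_b)
    if idx_a.size == 0 or idx_b.size == 0:
        raise TopologyError(
            f"dimer must contain chains {chain_a!r} and {chain_b!r}"
        )
    return idx_a, idx_b


def interface_distance_trace(
    traj: Trajectory,
    sel_a: np.ndarray,
    sel_b: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame (center-of-geometry distance, minimum heavy-atom distance)
    between two interface selections on distinct chains."""
    sel_a = np.asarray(sel_a, dtype=int)
    sel_b = np.asarray(sel_b, dtype=int)
    if sel_a.size == 0 or sel_b.size == 0:
        raise SelectionError("interface selections must be non-empty")
    top = traj.topology
    chains_a = set(top.chain_id[sel_a])
    chains_b = set(top.chain_id[sel_b])
    if chains_a & chains_b:
        raise SelectionError(
            f"interface selections share chains {sorted(chains_a & chains_b)}"
        )
    heavy_a = sel_a[[str(top.element[i]).upper() != "H" for i in sel_a]]
    heavy_b = sel_b[[str(top.element[i]).upper() != "H" for i in sel_b]]
    cog = np.empty(traj.n_frames)
    dmin = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        a = traj.coords[t, heavy_a]
        b = traj.coords[t, heavy_b]
        cog[t] = np.linalg.norm(a.mean(axis=0) - b.mean(axis=0))
        dmin[t] = cdist(a, b).min()
    return cog, dmin


def residue_pair_min_distance(
    traj: Trajectory,
    residues_a: list[tuple[str, int]],
    residues_b: list[tuple[str, int]],
    window: tuple[float, float] | None = None,
) -> tuple[float, float, np.ndarray]:
    """Per-frame minimum heavy-atom distance between two residue groups on
    opposite protomers, summarized as (mean, population SD, trace)."""
    top = traj.topology
    idx_a = np.concatenate([top.residue_atoms(c, r) for c, r in residues_a])
    idx_b = np.concatenate([top.residue_atoms(c, r) for c, r in residues_b])
    idx_a = idx_a[[str(top.element[i]).upper() != "H" for i in idx_a]]
    idx_b = idx_b[[str(top.element[i]).upper() != "H" for i in idx_b]]
    mask = traj.window_mask(window)
    frames = np.flatnonzero(mask)
    trace = np.empty(frames.size)
    for k, t in enumerate(frames):
        trace[k] = min_pair_distance(traj.coords[t, idx_a], traj.coords[t, idx_b])
    return float(trace.mean()), float(trace.std()), trace


@dataclass
class HBondCriterion:
    """Geometric hydrogen-bond definition.

    Donor-acceptor heavy-atom distance <= ``distance_cutoff`` (Angstrom);
    the D-H...A angle condition (>= ``angle_cutoff`` degrees) applies only
    when an explicit hydrogen on the donor is available, so heavy-atom-only
    structures fall back to the pure distance criterion.
    """

    distance_cutoff: float = 3.5
    angle_cutoff: float = 150.0

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.angle_cutoff <= 180:
            raise ValueError("angle cutoff must lie in (0, 180]")

    def describe(self) -> str:
        return (
            f"D..A<={self.distance_cutoff:g}A"
            f"+D-H..A>={self.angle_cutoff:g}deg(if H present)"
        )


def _donor_hydrogens(structure: Structure, donor_idx: int) -> np.ndarray:
    """Indices of hydrogens bonded to the donor heavy atom (<= 1.3 A)."""
    h_idx = np.flatnonzero(
        np.array([str(e).upper() == "H" for e in structure.element])
    )
    if h_idx.size == 0:
        return h_idx
    d = np.linalg.norm(structure.xyz[h_idx] - structure.xyz[donor_idx], axis=1)
    return h_idx[d <= 1.3]


def hbond_occupancy(
    traj: Trajectory,
    donor: tuple[str, int, str],
    acceptor: tuple[str, int, str],
    criterion: HBondCriterion | None = None,
    window: tuple[float, float] | None = None,
    symmetric: bool = False,
) -> float:
    """Fraction of window frames satisfying the H-bond criterion.

    ``donor``/``acceptor`` are (chain, resSeq, atomName) triples of heavy
    atoms.  ``symmetric=True`` accepts the bond with either side donating
    (the Tyr-Tyr hydroxyl pair across a dimer interface); with heavy atoms
    only the two directions coincide.
    """
    criterion = criterion or HBondCriterion()
    top = traj.topology
    d_idx = top.atom_index(*donor)
    a_idx = top.atom_index(*acceptor)
    mask = traj.window_mask(window)
    frames = np.flatnonzero(mask)
    dist = np.linalg.norm(
        traj.coords[frames, d_idx] - traj.coords[frames, a_idx], axis=1
    )
    ok = dist <= criterion.distance_cutoff

    h_near = _donor_hydrogens(top.with_coords(traj.coords[frames[0]]), d_idx)
    if h_near.size and not symmetric:
        # apply the angle condition with the closest donor hydrogen per frame
        ang_ok = np.zeros_like(ok)
        for k, t in enumerate(frames):
            if not ok[k]:
                continue
            hv = traj.coords[t, h_near]
            dh = hv - traj.coords[t, d_idx][None]
            best = h_near[np.argmin(np.linalg.norm(dh, axis=1))]
            v1 = traj.coords[t, d_idx] - traj.coords[t, best]
            v2 = traj.coords[t, a_idx] - traj.coords[t, best]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            ang_ok[k] = ang >= criterion.angle_cutoff
        ok &= ang_ok
    return float(np.count_nonzero(ok) / frames.size)


# ---------------------------------------------------------------------------
# Interface energy and alanine scanning
# ---------------------------------------------------------------------------

@dataclass
class InterfaceEnergyReport:
    """Per-frame inter-protomer energies with their summary statistics."""

    per_frame: np.ndarray  # kcal/mol
    times: np.ndarray  # ns
    model: str  # term weights / cutoff descriptor, always embedded
    chains: tuple[str, str] = ("A", "B")

    @property
    def mean(self) -> float:
        return float(self.per_frame.mean())

    @property
    def sd(self) -> float:
        return float(self.per_frame.std())


def _pair_energy(
    xyz_a: np.ndarray, xyz_b: np.ndarray,
    par_a: tuple[np.ndarray, np.ndarray, np.ndarray],
    par_b: tuple[np.ndarray, np.ndarray, np.ndarray],
    cutoff: float,
) -> float:
    sig_a, eps_a, q_a = par_a
    sig_b, eps_b, q_b = par_b
    r = cdist(xyz_a, xyz_b)
    within = r < cutoff
    if not within.any():
        return 0.0
    ia, ib = np.nonzero(within)
    rr = r[ia, ib]
    sig = 0.5 * (sig_a[ia] + sig_b[ib])
    eps = np.sqrt(eps_a[ia] * eps_b[ib])
    sr6 = (sig / rr) ** 6
    lj = 4.0 * eps * (sr6 * sr6 - sr6)
    coul = q_a[ia] * q_b[ib] * COULOMB_CONSTANT / (4.0 * rr * rr)  # eps(r)=4r
    return float(np.sum(lj + coul))


def _heavy_subset(structure: Structure, idx: np.ndarray) -> np.ndarray:
    return idx[[str(structure.element[i]).upper() != "H" for i in idx]]


def interface_energy(
    obj: Structure | Trajectory,
    model: EnergyModel | None = None,
    chains: tuple[str, str] = ("A", "B"),
) -> InterfaceEnergyReport:
    """Simplified inter-protomer interaction energy (kcal/mol).

    Only heavy-atom pairs crossing the two named chains and closer than the
    model cutoff contribute; intra-protomer terms are excluded by
    construction.
    """
    model = model or load_energy_params()
    if isinstance(obj, Structure):
        traj = Trajectory(obj, obj.xyz[None], np.zeros(1))
    else:
        traj = obj
    top = traj.topology
    idx_a, idx_b = _split_protomers(top, *chains)
    idx_a = _heavy_subset(top, idx_a)
    idx_b = _heavy_subset(top, idx_b)
    sub_a = top.subset(idx_a)
    sub_b = top.subset(idx_b)
    par_a = model.atom_params(sub_a)
    par_b = model.atom_params(sub_b)
    energies = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        energies[t] = _pair_energy(
            traj.coords[t, idx_a], traj.coords[t, idx_b], par_a, par_b,
            model.cutoff,
        )
    return InterfaceEnergyReport(energies, traj.times.copy(),
                                 model.describe(), chains)


def mutate_to_alanine(structure: Structure,
                      residues: list[tuple[str, int]]) -> Structure:
    """Truncate the listed residues to alanine on fixed coordinates.

    Sidechain atoms beyond C-beta are removed, C-beta and the backbone are
    kept untouched, and the residue is renamed ALA.  Mutating an alanine is
    the identity; glycine (no C-beta) is an error.
    """
    keep = np.ones(structure.n_atoms, dtype=bool)
    new_res_name = structure.res_name.copy()
    for chain_id, res_seq in residues:
        idx = structure.residue_atoms(chain_id, res_seq)
        names = {str(structure.name[i]) for i in idx}
        if "CB" not in names:
            raise TopologyError(
                f"residue {chain_id}:{res_seq} has no CB (glycine?) -- "
                "cannot truncate to alanine"
            )
        for i in idx:
            name = str(structure.name[i])
            el = str(structure.element[i]).upper()
            if name not in _ALA_ATOMS and el != "H":
                keep[i] = False
            if el == "H":  # sidechain hydrogens beyond CB also go
                if name not in ("H", "HA", "HB1", "HB2", "HB3"):
                    keep[i] = False
            new_res_name[i] = "ALA"
    out = structure.subset(np.flatnonzero(keep))
    # apply renames on the surviving atoms
    renames = new_res_name[keep]
    return Structure(out.serial, out.name, out.element, renames,
                     out.res_seq, out.chain_id, out.xyz, out.hetero)


@dataclass
class AlaScanResult:
    """Energy bookkeeping of one (possibly multiple-residue) alanine scan."""

    mutated: list[tuple[str, int]]
    e_wt: float  # kcal/mol, mean interface energy of the wild type
    e_mut: float  # kcal/mol, mean interface energy of the mutant
    model: str = ""

    @property
    def contribution(self) -> float:
        """E_wt - E_mut: the energy the scanned sidechains contributed."""
        return energy_contribution(self.e_wt, self.e_mut)


def energy_contribution(e_wt: float, e_mut: float) -> float:
    """Contribution of the removed interactions: E_wt - E_mut (kcal/mol).

    A negative value means the wild-type interface was more favorable than
    the truncated one, i.e. the scanned sidechains stabilized the dimer.
    """
    return e_wt - e_mut


def _mutate_trajectory(traj: Trajectory,
                       residues: list[tuple[str, int]]) -> Trajectory:
    mut_top_full = mutate_to_alanine(traj.topology, residues)
    # figure out which original atom columns survived
    keep = np.ones(traj.topology.n_atoms, dtype=bool)
    for chain_id, res_seq in residues:
        idx = traj.topology.residue_atoms(chain_id, res_seq)
        for i in idx:
            name = str(traj.topology.name[i])
            el = str(traj.topology.element[i]).upper()
            if el == "H" and name not in ("H", "HA", "HB1", "HB2", "HB3"):
                keep[i] = False
            elif el != "H" and name not in _ALA_ATOMS:
                keep[i] = False
    coords = traj.coords[:, keep]
    return Trajectory(mut_top_full, coords, traj.times.copy())


def alanine_scan(
    obj: Structure | Trajectory,
    residues: list[tuple[str, int]],
    model: EnergyModel | None = None,
    chains: tuple[str, str] = ("A", "B"),
) -> AlaScanResult:
    """Single-point alanine scan on wild-type coordinates.

    No repacking or minimization is performed: the mutant reuses the
    wild-type backbone frames with the listed sidechains truncated, keeping
    the scan deterministic and the contribution exactly equal to minus the
    sum of the removed inter-protomer pair terms.
    """
    model = model or load_energy_params()
    wt = interface_energy(obj, model, chains)
    if isinstance(obj, Structure):
        mut_obj: Structure | Trajectory = mutate_to_alanine(obj, residues)
    else:
        mut_obj = _mutate_trajectory(obj, residues)
    mut = interface_energy(mut_obj, model, chains)
    return AlaScanResult(list(residues), wt.mean, mut.mean, model.describe())
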