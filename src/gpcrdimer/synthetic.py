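"""Ground-truthed synthetic structures and trajectories.

Every analysis stage in this package can be exercised without external data:
this module builds toy GPCR-like protomers (ideal alpha-helices carrying
full-atom Tyr/Phe sidechains and an Asp pocket residue), then writes
trajectories in which the quantities of interest are *scripted*:

* chi1 rotamer states follow a two-state Markov chain with a requested
  stationary P(trans) and persistence; angles are the state's center
  (180 deg trans / 300 deg "cis") plus wrapped-Gaussian noise;
* a rigid 5-atom pseudo-ligand is placed so its minimum heavy-atom distance
  to the pocket residue is exactly the scripted value, frame by frame
  (inside the cutoff on scripted contact frames, outside otherwise), with an
  optional pose switch that delays the stability onset to a chosen frame;
* a second protomer faces the first across the TM5/TM6 side so the
  cross-protomer Tyr/Phe minimum distance follows a scripted series exactly,
  and the two Tyr hydroxyl oxygens are posed to satisfy the H-bond distance
  criterion in exactly the requested fraction of frames.

A global rigid-body jitter (rotation + translation per frame) is applied to
exercise superposition; all scripted quantities are invariant under it.
The emitted :class:`GroundTruth` records, by construction, exactly what each
analysis operation should recover.

What this generator does NOT emulate: force-field dynamics, membrane
environment, correlated backbone motion, or realistic sidechain packing.
Passing recovery tests therefore validates the analysis bookkeeping, not
conformational sampling of real receptors.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .model_io import BWMap, Structure, Trajectory

__all__ = [
    "RotamerModel",
    "LigandPlan",
    "DimerPlan",
    "SyntheticSpec",
    "GroundTruth",
    "generate_rotamer_sequence",
    "build_ideal_helix",
    "build_toy_protomer",
    "generate_monomer_trajectory",
    "generate_dimer_trajectory",
    "clozapine_like_monomer_spec",
    "spiperone_like_monomer_spec",
    "dimer_interface_spec",
]

TRANS_CENTER = 180.0
CIS_CENTER = 300.0

# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass
class RotamerModel:
    """Two-state Markov chi1 model for one tracked residue.

    ``p_trans`` is the stationary probability of the trans well;
    ``p_stay`` is P(trans -> trans) (defaults to 1 - (1 - p_trans)/2, which
    is reachable for every stationary value and gives a lag-1 state
    autocorrelation of 0.5).  ``sigma`` is the angular noise SD in degrees;
    the default 15 deg keeps 3 sigma inside each side of the 240 deg
    classification boundary, so state labels are unambiguous.
    """

    p_trans: float
    p_stay: float | None = None
    center_trans: float = TRANS_CENTER
    center_cis: float = CIS_CENTER
    sigma: float = 15.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_trans <= 1.0:
            raise ConfigError(f"p_trans {self.p_trans} outside [0, 1]")
        if self.sigma <= 0:
            raise ConfigError("sigma must be positive")
        if self.p_stay is None:
            self.p_stay = 1.0 - (1.0 - self.p_trans) / 2.0

    def transition_probs(self) -> tuple[float, float]:
        """(P(trans->trans), P(cis->trans)) solved from stationarity."""
        p, stay = self.p_trans, float(self.p_stay)
        if not 0.0 <= stay <= 1.0:
            raise ConfigError(f"p_stay {stay} outside [0, 1]")
        if p in (0.0, 1.0):
            return (1.0, 1.0) if p == 1.0 else (0.0, 0.0)
        b = p * (1.0 - stay) / (1.0 - p)
        if not 0.0 <= b <= 1.0:
            raise ConfigError(
                f"unreachable combination p_trans={p}, p_stay={stay}: "
                f"implied P(cis->trans)={b:.3f} outside [0, 1]"
            )
        return stay, b


@dataclass
class LigandPlan:
    """Placement script for the rigid pseudo-ligand.

    The ligand's nearest heavy atom sits ``target_distance - 0.3`` Angstrom
    from the pocket residue on scripted contact frames and
    ``target_distance + 2.0`` otherwise.  Before ``pose_switch_frame`` the
    whole ligand is additionally displaced by ``switch_displacement``, so
    the pose-stability onset lands exactly on that frame.  Contact frames
    are drawn (exact count) from the stable window only.
    """

    residue_label: str = "3.32"
    target_distance: float = 3.5
    contact_fraction: float = 0.3
    pose_switch_frame: int = 0
    switch_displacement: float = 6.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.contact_fraction <= 1.0:
            raise ConfigError("contact_fraction outside [0, 1]")
        if self.pose_switch_frame < 0:
            raise ConfigError("pose_switch_frame must be >= 0")


@dataclass
class DimerPlan:
    """Interface script for the two-protomer trajectory.

    ``separations`` (if given) is the exact per-frame cross-protomer
    Tyr/Phe minimum heavy-atom distance in Angstrom; otherwise it is drawn
    as Normal(``separation_mean``, ``separation_sd``) clipped at
    ``separation_min`` (kept above the H-bond cutoff so non-scripted frames
    never satisfy the criterion).  On ``hbond_fraction`` of frames (exact
    count) the two Tyr OH oxygens are posed ``hbond_distance`` apart.
    """

    separations: np.ndarray | None = None
    separation_mean: float = 5.5
    separation_sd: float = 1.5
    separation_min: float = 3.6
    hbond_fraction: float = 0.04
    hbond_distance: float = 2.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.hbond_fraction <= 1.0:
            raise ConfigError("hbond_fraction outside [0, 1]")


@dataclass
class SyntheticSpec:
    """Full generator configuration with one explicit random seed."""

    n_frames: int = 600
    dt: float = 5.0  # ns per frame
    seed: int = 0
    rotamers: dict[str, RotamerModel] = field(default_factory=dict)  # BW label ->
    ligand: LigandPlan | None = None
    dimer: DimerPlan | None = None
    jitter_translation: float = 0.5  # Angstrom SD per frame
    jitter_rotation_deg: float = 4.0  # max random rotation per frame

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        if self.dt <= 0:
            raise ConfigError("dt must be positive")


@dataclass
class GroundTruth:
    """Exact expected outputs for every analysis stage, by construction."""

    seed: int
    states: dict[str, list[str]] = field(default_factory=dict)
    angles: dict[str, list[float]] = field(default_factory=dict)
    occupancy_trans: dict[str, float] = field(default_factory=dict)
    contact_frames: list[int] = field(default_factory=list)
    contact_fraction: float | None = None
    stable_onset_ns: float | None = None
    hbond_frames: list[int] = field(default_factory=list)
    hbond_fraction: float | None = None
    separations: list[float] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @staticmethod
    def from_json(path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return GroundTruth(**json.load(fh))


# ---------------------------------------------------------------------------
# Rotamer sequences
# ---------------------------------------------------------------------------


def generate_rotamer_sequence(
    model: RotamerModel, n_frames: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate (states, angles) for one residue.

    States follow the model's Markov chain started from its stationary
    distribution; angles are the state center plus wrapped-Gaussian noise,
    reduced to [0, 360).
    """
    stay_t, to_t = model.transition_probs()
    u = rng.random(n_frames)
    trans = np.empty(n_frames, dtype=bool)
    trans[0] = u[0] < model.p_trans
    for i in range(1, n_frames):
        p = stay_t if trans[i - 1] else to_t
        trans[i] = u[i] < p
    centers = np.where(trans, model.center_trans, model.center_cis)
    angles = np.mod(centers + rng.normal(0.0, model.sigma, n_frames), 360.0)
    states = np.where(trans, "trans", "cis")
    return states, angles


# ---------------------------------------------------------------------------
# Geometry construction
# ---------------------------------------------------------------------------

_HELIX_RISE = 1.5  # Angstrom per residue
_HELIX_TWIST = 100.0  # degrees per residue
_CA_RADIUS = 2.28  # gives CA(i)-CA(i+1) ~ 3.8 A


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle: float, torsion) -> np.ndarray:
    """Internal-coordinate (NeRF) placement of atom D after chain A-B-C.

    ``|CD| = bond``, ``angle(B, C, D) = angle`` (degrees) and
    ``dihedral(A, B, C, D) = torsion`` (degrees) under this package's
    dihedral convention.  Inputs broadcast over leading frame axes.
    """
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    c = np.atleast_2d(np.asarray(c, float))
    torsion = np.broadcast_to(np.asarray(torsion, float), (a.shape[0],))
    th = np.radians(angle)
    phi = np.radians(torsion)
    u_cb = c - b
    u_cb /= np.linalg.norm(u_cb, axis=1, keepdims=True)
    u_ba = b - a
    u_ba /= np.linalg.norm(u_ba, axis=1, keepdims=True)
    n = np.cross(u_ba, u_cb)
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    m = np.cross(n, u_cb)
    d = (
        -np.cos(th)[..., None] * u_cb
        + (np.sin(th) * np.cos(phi))[..., None] * m
        + (np.sin(th) * np.sin(phi))[..., None] * n
    )
    return c + bond * d


def build_ideal_helix(
    res_seqs: range,
    axis_xy: tuple[float, float],
    phase_ref: int,
    phase_deg: float,
    z_ref: int | None = None,
) -> dict[int, dict[str, np.ndarray]]:
    """Backbone (N, CA, C, O) of an ideal alpha-helix along z.

    Rise 1.5 A and twist 100 deg per residue; CA radius chosen so
    consecutive CA atoms sit ~3.8 A apart.  ``phase_ref`` is the residue
    whose CA azimuth equals ``phase_deg``.
    """
    x0, y0 = axis_xy
    z_ref = phase_ref if z_ref is None else z_ref
    out: dict[int, dict[str, np.ndarray]] = {}
    for r in res_seqs:
        az = np.radians(phase_deg + _HELIX_TWIST * (r - phase_ref))
        z = _HELIX_RISE * (r - z_ref)
        ca = np.array([x0 + _CA_RADIUS * np.cos(az), y0 + _CA_RADIUS * np.sin(az), z])
        az_n = az - np.radians(28.0)
        n = np.array([x0 + 1.60 * np.cos(az_n), y0 + 1.60 * np.sin(az_n), z - 0.95])
        az_c = az + np.radians(30.0)
        c = np.array([x0 + 1.66 * np.cos(az_c), y0 + 1.66 * np.sin(az_c), z + 0.80])
        o = c + np.array([0.0, 0.0, 1.23])
        out[r] = {"N": n, "CA": ca, "C": c, "O": o}
    return out


# chi-dependent sidechain internal coordinates: atom -> (parents, bond, angle,
# torsion or "chi1"/"chi2" placeholders); ring closure is approximate, which
# is irrelevant here -- only the chi1 torsion must be exact.
_RING = [
    ("CG", ("N", "CA", "CB"), 1.51, 114.0, "chi1"),
    ("CD1", ("CA", "CB", "CG"), 1.39, 120.0, 90.0),
    ("CD2", ("CA", "CB", "CG"), 1.39, 120.0, 270.0),
    ("CE1", ("CB", "CG", "CD1"), 1.39, 120.0, 180.0),
    ("CE2", ("CB", "CG", "CD2"), 1.39, 120.0, 180.0),
    ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
]
_TYR_EXTRA = [("OH", ("CD1", "CE1", "CZ"), 1.37, 120.0, 180.0)]
_ASP_SIDE = [
    ("CG", ("N", "CA", "CB"), 1.52, 113.0, "chi1"),
    ("OD1", ("CA", "CB", "CG"), 1.25, 118.0, 0.0),
    ("OD2", ("CA", "CB", "CG"), 1.25, 118.0, 180.0),
]

_SIDECHAIN_DEFS = {
    "TYR": _RING + _TYR_EXTRA,
    "PHE": _RING,
    "ASP": _ASP_SIDE,
}


def _sidechain_atoms(res_name: str) -> list[str]:
    return ["CB"] + [entry[0] for entry in _SIDECHAIN_DEFS[res_name]]


def _pose_sidechain(
    bb_n: np.ndarray, bb_ca: np.ndarray, bb_c: np.ndarray,
    res_name: str, chi1,
) -> dict[str, np.ndarray]:
    """Coordinates of CB + sidechain for given chi1 (scalar or per-frame)."""
    single = np.asarray(chi1, float).ndim == 0 and bb_n.ndim == 1
    n = np.atleast_2d(bb_n)
    ca = np.atleast_2d(bb_ca)
    c = np.atleast_2d(bb_c)
    t = max(n.shape[0], np.atleast_1d(np.asarray(chi1, float)).shape[0])
    n, ca, c = (np.broadcast_to(x, (t, 3)) for x in (n, ca, c))
    cb = _place_atom(c, n, ca, 1.53, 110.5, np.full(t, 238.0))
    coords: dict[str, np.ndarray] = {"N": n, "CA": ca, "CB": np.atleast_2d(cb)}
    chi_arr = np.broadcast_to(np.asarray(chi1, float), (t,))
    for name, parents, bond, angle, torsion in _SIDECHAIN_DEFS[res_name]:
        tor = chi_arr if torsion == "chi1" else np.full(t, float(torsion))
        p1, p2, p3 = (coords[p] for p in parents)
        coords[name] = np.atleast_2d(_place_atom(p1, p2, p3, bond, angle, tor))
    out = {k: v for k, v in coords.items() if k not in ("N", "CA")}
    if single:
        out = {k: v[0] for k, v in out.items()}
    return out


_ELEMENT_FROM_NAME = {"OH": "O", "OD1": "O", "OD2": "O"}


def _element_of(atom_name: str) -> str:
    return _ELEMENT_FROM_NAME.get(atom_name, atom_name[0])


def build_toy_protomer(
    chain_id: str = "A",
    chi1: dict[str, float] | None = None,
    include_pocket: bool = False,
) -> tuple[Structure, BWMap]:
    """Two facing ideal helices (TM5/TM6) with full-atom Tyr199 and Phe390.

    TM5 carries residues 193-206 (Tyr at 199 = BW 5.48), TM6 carries
    383-396 (Phe at 390 = BW 6.52); both aromatic sidechains point toward
    +y, the interface side.  With ``include_pocket=True`` a third short
    helix (TM3, residues 110-120 with Asp114 = BW 3.32) sits on the -y
    side as the ligand-binding anchor.  ``chi1`` maps BW labels to initial
    chi1 angles (degrees), default 300 (the "cis" well, as in an
    antagonist-free crystal pose).
    """
    chi1 = {"5.48": CIS_CENTER, "6.52": CIS_CENTER, "3.32": 180.0, **(chi1 or {})}
    records: list[tuple] = []  # (name, element, res_name, res_seq)
    coords: list[np.ndarray] = []
    bw_entries: dict[tuple[str, int], tuple[str, str]] = {}

    def add_residue(res_seq: int, res_name: str, bb: dict[str, np.ndarray],
                    label: str, segment: str, chi: float | None) -> None:
        for atom in ("N", "CA", "C", "O"):
            records.append((atom, atom[0], res_name, res_seq))
            coords.append(bb[atom])
        if res_name in _SIDECHAIN_DEFS:
            side = _pose_sidechain(bb["N"], bb["CA"], bb["C"], res_name, chi)
            for atom in _sidechain_atoms(res_name):
                records.append((atom, _element_of(atom), res_name, res_seq))
                coords.append(side[atom])
        bw_entries[(chain_id, res_seq)] = (label, segment)

    helices = [
        ("TM5", range(193, 207), (0.0, 0.0), 199, 90.0, "5", 48, "TYR", 199),
        ("TM6", range(383, 397), (9.5, 0.0), 390, 90.0, "6", 52, "PHE", 390),
    ]
    if include_pocket:
        helices.append(
            ("TM3", range(110, 121), (4.75, -7.0), 114, -90.0, "3", 32, "ASP", 114)
        )
    for segment, seqs, axis, ref, phase, helix_no, ref_pos, aa, aa_seq in helices:
        bb = build_ideal_helix(seqs, axis, ref, phase)
        for r in seqs:
            label = f"{helix_no}.{ref_pos + (r - aa_seq)}"
            if r == aa_seq:
                add_residue(r, aa, bb[r], label, segment, chi1[f"{helix_no}.{ref_pos}"])
            else:
                add_residue(r, "GLY", bb[r], label, segment, None)

    n = len(records)
    structure = Structure(
        serial=np.arange(1, n + 1),
        name=np.array([r[0] for r in records], dtype=object),
        element=np.array([r[1] for r in records], dtype=object),
        res_name=np.array([r[2] for r in records], dtype=object),
        res_seq=np.array([r[3] for r in records]),
        chain_id=np.array([chain_id] * n, dtype=object),
        xyz=np.array(coords),
    )
    return structure, BWMap(bw_entries)


_LIGAND_OFFSETS = np.array(
    [[0.0, 0.0, 0.0], [0.8, 0.0, 0.0], [-0.8, 0.0, 0.0],
     [0.0, 0.0, 0.8], [0.0, 0.0, -0.8]]
)


def _ligand_records(chain_id: str = "L", res_seq: int = 900):
    return [(f"C{i + 1}", "C", "LIG", res_seq, chain_id, True) for i in range(5)]


def _exact_min_shift(anchor_pts: np.ndarray, probe_pts: np.ndarray,
                     direction: np.ndarray, target: float) -> float:
    """Shift of ``probe_pts`` along ``direction`` (unit) so that the minimum
    cross distance to ``anchor_pts`` equals ``target`` exactly.

    Each pair distance is monotone in the shift once the probe is on the
    far side, so the solution is the max over pairs of the per-pair shift.
    """
    rel = probe_pts[None, :, :] - anchor_pts[:, None, :]  # (na, np, 3)
    along = rel @ direction
    perp2 = np.sum(rel * rel, axis=2) - along**2
    need = np.sqrt(np.clip(target**2 - perp2, 0.0, None)) - along
    need[perp2 > target**2] = -np.inf  # pair can never reach the target
    return float(need.max())


def _random_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.radians(rng.uniform(-max_deg, max_deg))
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(ang) * k + (1 - np.cos(ang)) * (k @ k)


def _apply_jitter(coords: np.ndarray, spec: SyntheticSpec,
                  rng: np.random.Generator) -> np.ndarray:
    """Rigid rotation about the frame centroid plus a random translation."""
    out = np.empty_like(coords)
    for t in range(coords.shape[0]):
        rot = _random_rotation(rng, spec.jitter_rotation_deg)
        shift = rng.normal(0.0, spec.jitter_translation, 3)
        center = coords[t].mean(axis=0)
        out[t] = (coords[t] - center) @ rot.T + center + shift
    return out


def _posed_protomer_frames(
    base: Structure, bw_map: BWMap, chain_id: str, spec: SyntheticSpec,
    rng: np.random.Generator, truth: GroundTruth, key_prefix: str = "",
) -> np.ndarray:
    """Per-frame coordinates of one protomer with scripted chi1 dynamics.

    Rotamer-model keys are BW labels, optionally chain-qualified
    ("B:5.48"); unqualified keys apply to every protomer, qualified ones
    only to the named chain.
    """
    coords = np.broadcast_to(base.xyz, (spec.n_frames, base.n_atoms, 3)).copy()
    for raw_key, model in spec.rotamers.items():
        if ":" in raw_key:
            key_chain, label = raw_key.split(":", 1)
            if key_chain != chain_id:
                continue
        else:
            label = raw_key
        try:
            chain, res_seq = bw_map.lookup(label, chain_id)
        except KeyError:
            continue
        states, angles = generate_rotamer_sequence(model, spec.n_frames, rng)
        key = key_prefix + label
        truth.states[key] = states.tolist()
        truth.angles[key] = [round(a, 6) for a in angles]
        truth.occupancy_trans[key] = float(np.mean(states == "trans"))
        res_name = str(base.res_name[base.residue_atoms(chain, res_seq)[0]])
        n_i = base.atom_index(chain, res_seq, "N")
        ca_i = base.atom_index(chain, res_seq, "CA")
        c_i = base.atom_index(chain, res_seq, "C")
        side = _pose_sidechain(
            base.xyz[n_i], base.xyz[ca_i], base.xyz[c_i], res_name, angles
        )
        for atom, xyz in side.items():
            coords[:, base.atom_index(chain, res_seq, atom)] = xyz
    return coords


def generate_monomer_trajectory(
    spec: SyntheticSpec,
) -> tuple[Trajectory, BWMap, GroundTruth]:
    """Monomeric receptor with bound pseudo-ligand, plus exact ground truth."""
    spec = spec if spec.ligand is not None else _with_default_ligand(spec)
    plan = spec.ligand
    assert plan is not None
    rng = np.random.default_rng(spec.seed)
    truth = GroundTruth(seed=spec.seed)
    base, bw_map = build_toy_protomer("A", include_pocket=True)
    coords = _posed_protomer_frames(base, bw_map, "A", spec, rng, truth)

    # pocket anchor: the plan residue's heavy atoms (static across frames)
    chain, res_seq = bw_map.lookup(plan.residue_label, "A")
    anchor_idx = base.residue_atoms(chain, res_seq)
    direction = np.array([0.0, -1.0, 0.0])  # away from the dimerization side

    k = min(plan.pose_switch_frame, spec.n_frames)
    stable_frames = np.arange(k, spec.n_frames)
    n_contact = int(round(plan.contact_fraction * stable_frames.size))
    contact = np.zeros(spec.n_frames, dtype=bool)
    if n_contact:
        chosen = rng.choice(stable_frames, size=n_contact, replace=False)
        contact[np.sort(chosen)] = True
    # final frame defines the reference pose; keep its placement scripted too
    truth.contact_frames = np.flatnonzero(contact).tolist()
    truth.contact_fraction = n_contact / stable_frames.size if stable_frames.size else None
    truth.stable_onset_ns = float(k * spec.dt) if k < spec.n_frames else None

    lig_records = _ligand_records()
    lig_base = _LIGAND_OFFSETS + np.array([4.75, -12.0, 0.0])
    lig_coords = np.empty((spec.n_frames, 5, 3))
    for t in range(spec.n_frames):
        d = plan.target_distance - 0.3 if contact[t] else plan.target_distance + 2.0
        shift = _exact_min_shift(
            coords[t, anchor_idx], lig_base, direction, d
        )
        pose = lig_base + shift * direction
        if t < k:
            pose = pose + np.array([0.0, 0.0, plan.switch_displacement])
        lig_coords[t] = pose

    # assemble combined topology
    n0 = base.n_atoms
    topology = Structure(
        serial=np.concatenate([base.serial, np.arange(n0 + 1, n0 + 6)]),
        name=np.concatenate([base.name, [r[0] for r in lig_records]]),
        element=np.concatenate([base.element, [r[1] for r in lig_records]]),
        res_name=np.concatenate([base.res_name, [r[2] for r in lig_records]]),
        res_seq=np.concatenate([base.res_seq, [r[3] for r in lig_records]]),
        chain_id=np.concatenate([base.chain_id, [r[4] for r in lig_records]]),
        xyz=np.vstack([base.xyz, lig_base]),
        hetero=np.concatenate([base.hetero, np.ones(5, dtype=bool)]),
    )
    all_coords = np.concatenate([coords, lig_coords], axis=1)
    all_coords = _apply_jitter(all_coords, spec, rng)
    times = np.arange(spec.n_frames) * spec.dt
    return Trajectory(topology, all_coords, times), bw_map, truth


def generate_dimer_trajectory(
    spec: SyntheticSpec,
) -> tuple[Trajectory, BWMap, GroundTruth]:
    """Antagonist-free homodimer with scripted interface geometry.

    Protomer B is protomer A rotated 180 deg about the TM5 axis (so the
    Tyr/Phe interface sides face each other) and shifted along +y, frame by
    frame, so the cross-protomer Tyr199/Phe390 minimum heavy-atom distance
    equals the scripted separation exactly.  Tyr OH oxygens are re-posed on
    scripted H-bond frames.
    """
    plan = spec.dimer or DimerPlan()
    rng = np.random.default_rng(spec.seed)
    truth = GroundTruth(seed=spec.seed)
    base_a, bw_a = build_toy_protomer("A")
    base_b, bw_b = build_toy_protomer("B")

    coords_a = _posed_protomer_frames(base_a, bw_a, "A", spec, rng, truth, "A:")
    coords_b = _posed_protomer_frames(base_b, bw_b, "B", spec, rng, truth, "B:")

    # rotate protomer B: 180 deg about the z axis through TM5 (x=0, y=0)
    rot = np.diag([-1.0, -1.0, 1.0])
    coords_b = coords_b @ rot.T

    if plan.separations is not None:
        seps = np.asarray(plan.separations, dtype=float)
        if seps.shape != (spec.n_frames,):
            raise ConfigError("separations must have length n_frames")
    else:
        seps = np.clip(
            rng.normal(plan.separation_mean, plan.separation_sd, spec.n_frames),
            plan.separation_min, None,
        )

    n_hb = int(round(plan.hbond_fraction * spec.n_frames))
    hb = np.zeros(spec.n_frames, dtype=bool)
    if n_hb:
        hb[np.sort(rng.choice(spec.n_frames, size=n_hb, replace=False))] = True
    truth.hbond_frames = np.flatnonzero(hb).tolist()
    truth.hbond_fraction = n_hb / spec.n_frames

    cluster_a = np.concatenate([
        base_a.residue_atoms("A", 199), base_a.residue_atoms("A", 390)
    ])
    cluster_b = np.concatenate([
        base_b.residue_atoms("B", 199), base_b.residue_atoms("B", 390)
    ])
    oh_a = base_a.atom_index("A", 199, "OH")
    oh_b = base_b.atom_index("B", 199, "OH")
    direction = np.array([0.0, 1.0, 0.0])

    for t in range(spec.n_frames):
        shift = _exact_min_shift(
            coords_a[t, cluster_a], coords_b[t, cluster_b], direction, seps[t]
        )
        coords_b[t] += shift * direction
        if hb[t]:
            pa = coords_a[t, oh_a]
            pb = coords_b[t, oh_b]
            mid = 0.5 * (pa + pb)
            u = pb - pa
            u /= np.linalg.norm(u)
            coords_a[t, oh_a] = mid - 0.5 * plan.hbond_distance * u
            coords_b[t, oh_b] = mid + 0.5 * plan.hbond_distance * u
    truth.separations = [round(float(s), 6) for s in seps]

    # merge topologies and BW maps
    topology = Structure(
        serial=np.concatenate([base_a.serial, base_a.n_atoms + base_b.serial]),
        name=np.concatenate([base_a.name, base_b.name]),
        element=np.concatenate([base_a.element, base_b.element]),
        res_name=np.concatenate([base_a.res_name, base_b.res_name]),
        res_seq=np.concatenate([base_a.res_seq, base_b.res_seq]),
        chain_id=np.concatenate([base_a.chain_id, base_b.chain_id]),
        xyz=np.vstack([base_a.xyz, base_b.xyz @ rot.T]),
        hetero=np.concatenate([base_a.hetero, base_b.hetero]),
    )
    coords = np.concatenate([coords_a, coords_b], axis=1)
    coords = _apply_jitter(coords, spec, rng)
    bw_map = BWMap({**bw_a.entries, **bw_b.entries})
    times = np.arange(spec.n_frames) * spec.dt
    return Trajectory(topology, coords, times), bw_map, truth


# ---------------------------------------------------------------------------
# Study-condition presets
# ---------------------------------------------------------------------------


def _with_default_ligand(spec: SyntheticSpec) -> SyntheticSpec:
    return SyntheticSpec(
        n_frames=spec.n_frames, dt=spec.dt, seed=spec.seed,
        rotamers=spec.rotamers, ligand=LigandPlan(), dimer=spec.dimer,
        jitter_translation=spec.jitter_translation,
        jitter_rotation_deg=spec.jitter_rotation_deg,
    )


def clozapine_like_monomer_spec(seed: int = 0, n_frames: int = 600) -> SyntheticSpec:
    """Monomer whose tracked residues strongly prefer trans (99%) and whose
    ligand settles at 0.4 us of a 3 us run -- the clozapine-like condition."""
    k = int(round(n_frames * 0.4 / 3.0))
    return SyntheticSpec(
        n_frames=n_frames,
        dt=3000.0 / n_frames,
        seed=seed,
        rotamers={
            "5.48": RotamerModel(p_trans=0.99),
            "6.52": RotamerModel(p_trans=0.99),
        },
        ligand=LigandPlan(pose_switch_frame=k),
    )


def spiperone_like_monomer_spec(seed: int = 0, n_frames: int = 600) -> SyntheticSpec:
    """Monomer with Tyr cis 25% of the time, Phe locked cis, late (1.8 us)
    pose stabilization -- the spiperone-like condition.

    The Tyr well hopping is modeled as memoryless (p_stay equal to the
    stationary probability), reflecting the rapid cis/trans fluctuation this
    condition is characterized by.
    """
    k = int(round(n_frames * 1.8 / 3.0))
    return SyntheticSpec(
        n_frames=n_frames,
        dt=3000.0 / n_frames,
        seed=seed,
        rotamers={
            "5.48": RotamerModel(p_trans=0.75, p_stay=0.75),
            "6.52": RotamerModel(p_trans=0.0),
        },
        ligand=LigandPlan(pose_switch_frame=k),
    )


def dimer_interface_spec(seed: int = 0, n_frames: int = 1000) -> SyntheticSpec:
    """Homodimer study condition: protomer A trans occupancies 94%/90%
    (Tyr/Phe), protomer B Phe 93% trans with Tyr locked cis; Tyr-Tyr H-bond
    in 4% of frames; Tyr/Phe minimum distance around 5.5 +/- 1.5 A."""
    return SyntheticSpec(
        n_frames=n_frames,
        dt=3000.0 / n_frames,
        seed=seed,
        rotamers={
            "A:5.48": RotamerModel(p_trans=0.94),
            "A:6.52": RotamerModel(p_trans=0.90),
            "B:5.48": RotamerModel(p_trans=0.0),  # locked cis
            "B:6.52": RotamerModel(p_trans=0.93),
        },
        dimer=DimerPlan(),
    )
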