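"""Structure/trajectory containers, fixed-column PDB I/O and residue-label maps.

Coordinates are carried in Angstrom and times in nanoseconds throughout the
package (reports may additionally print microseconds).  Structures are
column-oriented: per-atom fields live in numpy arrays so downstream geometry
kernels can vectorize over atoms and frames.

Conventions
-----------
* Hydrogens are optional; every default selection downstream is heavy-atom
  only, because crystal-derived inputs usually lack them.
* Chain identity defines protomer identity in dimers (protomer 1 = chain A,
  protomer 2 = chain B by convention).
* Residue numbering is author/PDB numbering; nothing is renumbered.
* Ligands travel as HETATM records with their own chain id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from .errors import PDBFormatError, TopologyError

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "BWMap",
    "read_pdb",
    "write_pdb",
    "load_bw_map",
]


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure, in PDB terms."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    xyz: np.ndarray  # shape (3,), Angstrom
    hetero: bool = False

    def __post_init__(self) -> None:
        if not self.element:
            raise TopologyError(f"atom serial {self.serial}: empty element symbol")
        xyz = np.asarray(self.xyz, dtype=float)
        if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
            raise TopologyError(f"atom serial {self.serial}: non-finite coordinates")
        object.__setattr__(self, "xyz", xyz)


class Structure:
    """An ordered collection of atoms with a residue index.

    Parameters are parallel per-atom arrays; ``xyz`` has shape (N, 3).
    ``(chain_id, res_seq, name)`` must be unique across atoms.
    """

    def __init__(
        self,
        serial: np.ndarray,
        name: np.ndarray,
        element: np.ndarray,
        res_name: np.ndarray,
        res_seq: np.ndarray,
        chain_id: np.ndarray,
        xyz: np.ndarray,
        hetero: np.ndarray | None = None,
    ) -> None:
        n = len(serial)
        self.serial = np.asarray(serial, dtype=int)
        self.name = np.asarray(name, dtype=object)
        self.element = np.asarray(element, dtype=object)
        self.res_name = np.asarray(res_name, dtype=object)
        self.res_seq = np.asarray(res_seq, dtype=int)
        self.chain_id = np.asarray(chain_id, dtype=object)
        self.xyz = np.asarray(xyz, dtype=float).reshape(n, 3)
        self.hetero = (
            np.zeros(n, dtype=bool) if hetero is None else np.asarray(hetero, dtype=bool)
        )
        for arr, label in [
            (self.name, "name"),
            (self.element, "element"),
            (self.res_name, "res_name"),
            (self.res_seq, "res_seq"),
            (self.chain_id, "chain_id"),
            (self.hetero, "hetero"),
        ]:
            if len(arr) != n:
                raise TopologyError(f"field '{label}' length {len(arr)} != n_atoms {n}")
        if not np.all(np.isfinite(self.xyz)):
            raise TopologyError("non-finite coordinates in structure")
        keys = list(zip(self.chain_id, self.res_seq, self.name))
        if len(set(keys)) != n:
            seen: set[tuple] = set()
            for k in keys:
                if k in seen:
                    raise TopologyError(f"duplicate atom key (chain,resSeq,name) = {k}")
                seen.add(k)
        self._residue_index: dict[tuple[str, int], np.ndarray] = {}
        for i, key in enumerate(zip(self.chain_id, self.res_seq)):
            self._residue_index.setdefault(key, []).append(i)  # type: ignore[arg-type]
        self._residue_index = {
            k: np.asarray(v, dtype=int) for k, v in self._residue_index.items()
        }

    # -- container protocol -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    def __len__(self) -> int:
        return self.n_atoms

    def atoms(self) -> Iterator[AtomRecord]:
        for i in range(self.n_atoms):
            yield AtomRecord(
                serial=int(self.serial[i]),
                name=str(self.name[i]),
                element=str(self.element[i]),
                res_name=str(self.res_name[i]),
                res_seq=int(self.res_seq[i]),
                chain_id=str(self.chain_id[i]),
                xyz=self.xyz[i].copy(),
                hetero=bool(self.hetero[i]),
            )

    # -- residue access ------------------------------------------------------
    @property
    def residues(self) -> list[tuple[str, int]]:
        return list(self._residue_index)

    def residue_atoms(self, chain_id: str, res_seq: int) -> np.ndarray:
        """Indices of the atoms of residue ``(chain_id, res_seq)``."""
        try:
            return self._residue_index[(chain_id, res_seq)]
        except KeyError:
            raise TopologyError(f"no residue {res_seq} in chain {chain_id!r}") from None

    def atom_index(self, chain_id: str, res_seq: int, name: str) -> int:
        idx = self.residue_atoms(chain_id, res_seq)
        for i in idx:
            if self.name[i] == name:
                return int(i)
        raise TopologyError(
            f"residue {chain_id}:{res_seq} has no atom named {name!r}"
        )

    def subset(self, indices: np.ndarray) -> "Structure":
        indices = np.asarray(indices, dtype=int)
        return Structure(
            self.serial[indices],
            self.name[indices],
            self.element[indices],
            self.res_name[indices],
            self.res_seq[indices],
            self.chain_id[indices],
            self.xyz[indices],
            self.hetero[indices],
        )

    def with_coords(self, xyz: np.ndarray) -> "Structure":
        return Structure(
            self.serial, self.name, self.element, self.res_name,
            self.res_seq, self.chain_id, xyz, self.hetero,
        )

    @staticmethod
    def from_records(records: list[AtomRecord]) -> "Structure":
        if not records:
            return Structure(
                np.empty(0, int), np.empty(0, object), np.empty(0, object),
                np.empty(0, object), np.empty(0, int), np.empty(0, object),
                np.empty((0, 3), float), np.empty(0, bool),
            )
        return Structure(
            np.array([r.serial for r in records]),
            np.array([r.name for r in records], dtype=object),
            np.array([r.element for r in records], dtype=object),
            np.array([r.res_name for r in records], dtype=object),
            np.array([r.res_seq for r in records]),
            np.array([r.chain_id for r in records], dtype=object),
            np.array([r.xyz for r in records], dtype=float),
            np.array([r.hetero for r in records], dtype=bool),
        )


@dataclass
class Trajectory:
    """Topology plus T coordinate frames (Angstrom) and timestamps (ns)."""

    topology: Structure
    coords: np.ndarray  # (T, N, 3)
    times: np.ndarray  # (T,), ns, strictly increasing

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TopologyError("trajectory coords must have shape (T, N, 3)")
        t, n, _ = self.coords.shape
        if n != self.topology.n_atoms:
            raise TopologyError(
                f"frames carry {n} atoms but topology has {self.topology.n_atoms}"
            )
        if self.times.shape != (t,):
            raise TopologyError("times length must equal number of frames")
        if t > 1 and not np.all(np.diff(self.times) > 0):
            raise TopologyError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.coords[i])

    def window_mask(self, window: tuple[float, float] | None) -> np.ndarray:
        """Boolean frame mask for an inclusive (t_start, t_end) ns window."""
        if window is None:
            return np.ones(self.n_frames, dtype=bool)
        t0, t1 = window
        mask = (self.times >= t0) & (self.times <= t1)
        if not mask.any():
            raise TopologyError(f"window {window} ns overlaps no frame")
        return mask


# ---------------------------------------------------------------------------
# Ballesteros-Weinstein residue-label map
# ---------------------------------------------------------------------------

_SEGMENTS = (
    {"TM1", "TM2", "TM3", "TM4", "TM5", "TM6", "TM7"}
    | {"ECL1", "ECL2", "ECL3", "ICL1", "ICL2", "ICL3", "other"}
)


@dataclass
class BWMap:
    """Two-way map between (chain, resSeq) and generic residue labels.

    Class-A GPCR positions carry Ballesteros-Weinstein labels such as
    ``"5.48"`` (helix 5, position 48); loop residues carry their segment
    (e.g. ``ECL2``) as the label surrogate.
    """

    entries: dict[tuple[str, int], tuple[str, str]] = field(default_factory=dict)
    # (chain, resSeq) -> (label, segment)

    def __post_init__(self) -> None:
        by_chain: dict[str, set[str]] = {}
        for (chain, _res), (label, segment) in self.entries.items():
            if segment not in _SEGMENTS:
                raise ValueError(f"unknown segment {segment!r} in BW map")
            seen = by_chain.setdefault(chain, set())
            if label in seen:
                raise ValueError(f"duplicate BW label {label!r} in chain {chain!r}")
            seen.add(label)

    def label(self, chain_id: str, res_seq: int) -> str:
        return self.entries[(chain_id, res_seq)][0]

    def segment(self, chain_id: str, res_seq: int) -> str:
        return self.entries[(chain_id, res_seq)][1]

    def label_or_none(self, chain_id: str, res_seq: int) -> str | None:
        entry = self.entries.get((chain_id, res_seq))
        return entry[0] if entry else None

    def lookup(self, label: str, chain_id: str | None = None) -> tuple[str, int]:
        """Resolve a BW label back to (chain, resSeq).

        Without an explicit chain the label must be unique across chains.
        """
        hits = [
            key
            for key, (lab, _seg) in self.entries.items()
            if lab == label and (chain_id is None or key[0] == chain_id)
        ]
        if not hits:
            raise KeyError(f"BW label {label!r} not in map"
                           + (f" for chain {chain_id!r}" if chain_id else ""))
        if len(hits) > 1:
            raise KeyError(
                f"BW label {label!r} is ambiguous across chains "
                f"{sorted(h[0] for h in hits)}; pass chain_id"
            )
        return hits[0]

    def residues_in_segment(self, segment: str, chain_id: str | None = None):
        return [
            key
            for key, (_lab, seg) in self.entries.items()
            if seg == segment and (chain_id is None or key[0] == chain_id)
        ]

    def chains(self) -> list[str]:
        return sorted({chain for chain, _ in self.entries})


def load_bw_map(path: str | Path) -> BWMap:
    """Read a tab-separated residue-label table: chain, resSeq, label, segment."""
    entries: dict[tuple[str, int], tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, got {len(parts)}"
                )
            chain, res_seq_s, label, segment = parts
            try:
                res_seq = int(res_seq_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: bad resSeq {res_seq_s!r}") from None
            key = (chain, res_seq)
            if key in entries:
                raise ValueError(f"{path}:{lineno}: duplicate residue {key}")
            entries[key] = (label, segment)
    return BWMap(entries)


def save_bw_map(bw_map: BWMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for (chain, res_seq), (label, segment) in sorted(bw_map.entries.items()):
            fh.write(f"{chain}\t{res_seq}\t{label}\t{segment}\n")


# ---------------------------------------------------------------------------
# PDB fixed-column I/O
# ---------------------------------------------------------------------------

_COORD_MAX = 1e4  # %8.3f column limit


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21].strip() or " "
        res_seq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError):
        raise PDBFormatError(
            f"line {lineno}: unparsable ATOM/HETATM record: {line.rstrip()!r}"
        ) from None
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # PDB v2-style files: fall back on the first letter of the atom name.
        stripped = name.lstrip("0123456789")
        element = stripped[:1].upper()
    return AtomRecord(
        serial=serial,
        name=name,
        element=element,
        res_name=res_name,
        res_seq=res_seq,
        chain_id=chain_id,
        xyz=np.array([x, y, z]),
        hetero=line.startswith("HETATM"),
    )


def read_pdb(path: str | Path, dt: float = 1.0) -> Structure | Trajectory:
    """Read a PDB file into a Structure (no MODEL records) or Trajectory.

    MODEL/ENDMDL blocks delimit frames; atom ordering must be identical in
    every model.  Times are ``arange(T) * dt`` ns unless the file carries a
    ``REMARK   3 DT_NS`` header written by :func:`write_pdb`.

    Raises
    ------
    PDBFormatError
        On unparsable records (with line number) or MODEL blocks whose atom
        count differs from the first model (naming the model index).
    """
    frames: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    saw_model = False
    model_index = 0
    file_dt: float | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model = True
                model_index += 1
                current = []
            elif rec == "ENDMDL":
                frames.append(current)
                current = []
            elif rec in ("ATOM  ", "HETATM"):
                current.append(_parse_atom_line(line, lineno))
            elif line.startswith("REMARK   3 DT_NS"):
                try:
                    file_dt = float(line.split()[-1])
                except ValueError:
                    raise PDBFormatError(f"line {lineno}: bad DT_NS remark") from None
            # TER / END / other records are ignored
    if current:
        frames.append(current)

    if not saw_model:
        records = frames[0] if frames else []
        return Structure.from_records(records)

    frames = [f for f in frames if f] or [[]]
    n0 = len(frames[0])
    for i, f in enumerate(frames[1:], start=2):
        if len(f) != n0:
            raise PDBFormatError(
                f"MODEL {i} has {len(f)} atoms but MODEL 1 has {n0}"
            )
    topology = Structure.from_records(frames[0])
    coords = np.array([[r.xyz for r in f] for f in frames], dtype=float)
    step = file_dt if file_dt is not None else dt
    times = np.arange(len(frames), dtype=float) * step
    return Trajectory(topology, coords, times)


def _format_atom_line(
    serial: int, name: str, res_name: str, chain_id: str, res_seq: int,
    xyz: np.ndarray, element: str, hetero: bool,
) -> str:
    if np.any(np.abs(xyz) >= _COORD_MAX):
        raise ValueError(
            f"atom serial {serial}: |coordinate| >= {_COORD_MAX:g} A does not fit "
            "%8.3f PDB columns"
        )
    record = "HETATM" if hetero else "ATOM  "
    # Atom-name column convention: 1-3 char names start at column 14.
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (
        f"{record}{serial:>5d} {name_field}{'':1s}{res_name:>3s} {chain_id:1s}"
        f"{res_seq:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.0:6.2f}{0.0:6.2f}          {element:>2s}\n"
    )


def _write_frame(fh, structure: Structure, coords: np.ndarray) -> None:
    for i in range(structure.n_atoms):
        fh.write(
            _format_atom_line(
                int(structure.serial[i]), str(structure.name[i]),
                str(structure.res_name[i]), str(structure.chain_id[i]),
                int(structure.res_seq[i]), coords[i], str(structure.element[i]),
                bool(structure.hetero[i]),
            )
        )


def write_pdb(obj: Structure | Trajectory, path: str | Path) -> None:
    """Write a Structure or Trajectory as a fixed-column PDB file.

    Trajectories are emitted as MODEL/ENDMDL blocks; a uniform time step is
    preserved in a ``REMARK   3 DT_NS`` header so a round trip keeps times.
    """
    with open(path, "w") as fh:
        if isinstance(obj, Trajectory):
            steps = np.diff(obj.times)
            if obj.n_frames > 1 and np.allclose(steps, steps[0]):
                fh.write(f"REMARK   3 DT_NS {steps[0]:.9g}\n")
            for t in range(obj.n_frames):
                fh.write(f"MODEL {t + 1:>8d}\n")
                _write_frame(fh, obj.topology, obj.coords[t])
                fh.write("ENDMDL\n")
        else:
            _write_frame(fh, obj, obj.xyz)
        fh.write("END\n")
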