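"""Protein-ligand close-contact fingerprints and their cross-ligand partition.

A residue is "in contact" with the ligand in a frame when any heavy-atom
pair sits strictly below the cutoff (default 3.5 Angstrom).  Fingerprints
can be taken from a single frame (crystal convention) or as per-residue
contact frequencies over a trajectory window, thresholded into a set.

Given named fingerprints for several ligands, :func:`partition_contacts`
splits the union into the familiar report categories: residues common to
all ligands (I), residues shared by exactly one pair (II/III/IV in input
order), and per-ligand unique remainders.  The categories form a true set
partition of the union.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping

import numpy as np
from scipy.spatial.distance import cdist

from .errors import SelectionError
from .model_io import BWMap, Structure, Trajectory

__all__ = [
    "ResidueTag",
    "ContactSet",
    "ContactPartition",
    "close_contacts",
    "contact_frequency",
    "frequent_contacts",
    "partition_contacts",
    "CONTACT_CUTOFF",
]

#: Default protein-ligand close-contact cutoff (strict "<"), Angstrom.
CONTACT_CUTOFF = 3.5


@dataclass(frozen=True, order=True)
class ResidueTag:
    """Identity of one receptor residue in a fingerprint."""

    chain_id: str
    res_seq: int
    res_name: str = ""
    label: str = ""  # BW label, or segment name for loop residues

    def display(self) -> str:
        name = f"{self.res_name}{self.res_seq}" if self.res_name else str(self.res_seq)
        return f"{name}^{self.label}" if self.label else name


@dataclass
class ContactSet:
    """Residues in close contact with one ligand, plus how the set was made."""

    ligand: str
    residues: frozenset[Hashable]
    basis: str  # e.g. "frame:0" or "frequency>=0.50 over (0,100) ns"

    def __contains__(self, item: Hashable) -> bool:
        return item in self.residues


def _heavy_mask(structure: Structure, indices: np.ndarray) -> np.ndarray:
    els = np.array([str(e).upper() for e in structure.element], dtype=object)
    return indices[els[indices] != "H"]


def _tag(structure: Structure, chain_id: str, res_seq: int,
         bw_map: BWMap | None) -> ResidueTag:
    idx = structure.residue_atoms(chain_id, res_seq)
    res_name = str(structure.res_name[idx[0]])
    label = ""
    if bw_map is not None:
        entry = bw_map.entries.get((chain_id, res_seq))
        if entry:
            lab, seg = entry
            # loop residues display their segment (e.g. "ECL2"), helix
            # residues their BW position (e.g. "5.48")
            label = lab if seg.upper().startswith("TM") else seg
    return ResidueTag(chain_id, res_seq, res_name, label)


def _contact_matrix(frame_xyz: np.ndarray, ligand_idx: np.ndarray,
                    receptor_idx: np.ndarray, cutoff: float) -> np.ndarray:
    d = cdist(frame_xyz[receptor_idx], frame_xyz[ligand_idx])
    return d.min(axis=1) < cutoff  # per-receptor-atom flag, strict


def close_contacts(
    frame: Structure,
    ligand_idx: np.ndarray,
    receptor_idx: np.ndarray,
    cutoff: float = CONTACT_CUTOFF,
    bw_map: BWMap | None = None,
    ligand_name: str = "ligand",
) -> ContactSet:
    """Residues of the receptor with any heavy atom < cutoff from the ligand."""
    ligand_idx = np.asarray(ligand_idx, dtype=int)
    receptor_idx = np.asarray(receptor_idx, dtype=int)
    if ligand_idx.size == 0 or receptor_idx.size == 0:
        raise SelectionError("ligand and receptor selections must be non-empty")
    if np.intersect1d(ligand_idx, receptor_idx).size:
        raise SelectionError("ligand and receptor selections overlap")
    ligand_idx = _heavy_mask(frame, ligand_idx)
    receptor_idx = _heavy_mask(frame, receptor_idx)
    atom_flags = _contact_matrix(frame.xyz, ligand_idx, receptor_idx, cutoff)
    tags = set()
    for i in receptor_idx[atom_flags]:
        tags.add(_tag(frame, str(frame.chain_id[i]), int(frame.res_seq[i]), bw_map))
    return ContactSet(ligand_name, frozenset(tags), basis="single-frame")


def contact_frequency(
    traj: Trajectory,
    ligand_idx: np.ndarray,
    receptor_idx: np.ndarray,
    window: tuple[float, float] | None = None,
    cutoff: float = CONTACT_CUTOFF,
    bw_map: BWMap | None = None,
) -> dict[ResidueTag, float]:
    """Per-residue fraction of window frames in which the residue contacts
    the ligand.  Residues never in contact are absent from the result."""
    ligand_idx = np.asarray(ligand_idx, dtype=int)
    receptor_idx = np.asarray(receptor_idx, dtype=int)
    if ligand_idx.size == 0 or receptor_idx.size == 0:
        raise SelectionError("ligand and receptor selections must be non-empty")
    if np.intersect1d(ligand_idx, receptor_idx).size:
        raise SelectionError("ligand and receptor selections overlap")
    top = traj.topology
    ligand_idx = _heavy_mask(top, ligand_idx)
    receptor_idx = _heavy_mask(top, receptor_idx)
    mask = traj.window_mask(window)
    frames = np.flatnonzero(mask)
    res_keys = [(str(top.chain_id[i]), int(top.res_seq[i])) for i in receptor_idx]
    counts: dict[tuple[str, int], int] = {}
    for t in frames:
        flags = _contact_matrix(traj.coords[t], ligand_idx, receptor_idx, cutoff)
        hit_res = {res_keys[j] for j in np.flatnonzero(flags)}
        for key in hit_res:
            counts[key] = counts.get(key, 0) + 1
    n = len(frames)
    return {
        _tag(top, chain, res, bw_map): c / n
        for (chain, res), c in sorted(counts.items())
    }


def frequent_contacts(
    frequencies: Mapping[ResidueTag, float],
    min_fraction: float = 0.5,
    ligand_name: str = "ligand",
    window_desc: str = "",
) -> ContactSet:
    """Threshold a frequency fingerprint into a contact set (>= min_fraction)."""
    residues = frozenset(
        tag for tag, f in frequencies.items() if f >= min_fraction
    )
    basis = f"frequency>={min_fraction:g}"
    if window_desc:
        basis += f" over {window_desc}"
    return ContactSet(ligand_name, residues, basis)


def reference_antipsychotic_fingerprints() -> tuple[
    dict[str, frozenset[tuple[str, int]]],
    dict[tuple[str, tuple[str, int]], str],
    dict[tuple[str, int], str],
]:
    """Packaged D2-receptor pocket fingerprints of three antipsychotics.

    Returns ``(sets, expected_tags, labels)`` where ``sets`` maps ligand
    name to its residue set keyed by (res_name, res_seq), ``expected_tags``
    maps (ligand, residue) to the published category tag and ``labels``
    carries the BW/segment annotations for rendering.  Input order is
    risperidone, clozapine, spiperone, which pins the pair-category names
    II (risperidone+clozapine), III (risperidone+spiperone) and IV
    (clozapine+spiperone).
    """
    from importlib import resources

    text = resources.files("gpcrdimer.data").joinpath(
        "d2r_ligand_contacts.tsv"
    ).read_text()
    sets: dict[str, set[tuple[str, int]]] = {
        "risperidone": set(), "clozapine": set(), "spiperone": set(),
    }
    expected: dict[tuple[str, tuple[str, int]], str] = {}
    labels: dict[tuple[str, int], str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        ligand, res_name, res_seq_s, label, tag = line.split("\t")
        key = (res_name, int(res_seq_s))
        sets[ligand].add(key)
        expected[(ligand, key)] = tag
        labels[key] = label
    return {k: frozenset(v) for k, v in sets.items()}, expected, labels


@dataclass
class ContactPartition:
    """Disjoint categories of a multi-ligand contact comparison.

    ``common_all`` is category (I); ``pairwise`` maps each unordered ligand
    pair to its exclusive shared residues (categories II, III, IV in the
    input pair order); ``unique`` holds each ligand's remainder.
    """

    ligands: tuple[str, ...]
    common_all: frozenset[Hashable]
    pairwise: dict[tuple[str, str], frozenset[Hashable]]
    unique: dict[str, frozenset[Hashable]]
    category_names: dict[tuple[str, str], str] = field(default_factory=dict)

    def category_of(self, ligand: str, residue: Hashable) -> str:
        """Roman-numeral tag ("I".."IV") or "unique" for one membership."""
        if residue in self.common_all:
            return "I"
        for pair, members in self.pairwise.items():
            if ligand in pair and residue in members:
                return self.category_names[pair]
        if residue in self.unique[ligand]:
            return "unique"
        raise KeyError(f"{residue!r} is not a contact of {ligand!r}")


_ROMAN = ["II", "III", "IV", "V", "VI", "VII"]


def partition_contacts(
    sets: Mapping[str, Iterable[Hashable]] | Iterable[ContactSet],
) -> ContactPartition:
    """Partition named contact sets into common/pairwise/unique categories.

    Categories: (I) residues present in every set; one category per ligand
    pair (II, III, ... following the order of pair enumeration) holding
    residues of exactly that pair; "unique" for single-set residues.  With k
    input sets the pair categories cover only pairwise-exclusive residues,
    so the result is always a true partition of the union.
    """
    if isinstance(sets, Mapping):
        named = [(name, frozenset(res)) for name, res in sets.items()]
    else:
        named = []
        for cs in sets:
            named.append((cs.ligand, frozenset(cs.residues)))
    names = [n for n, _ in named]
    if len(names) != len(set(names)):
        raise ValueError(f"duplicate ligand names in {names}")
    if not 2 <= len(named) <= 3:
        # with more sets, residues shared by exactly three of four ligands
        # would fall in no category; the I-IV scheme is a 2/3-ligand report
        raise ValueError("need two or three named contact sets")
    mapping = dict(named)
    common_all = frozenset.intersection(*(mapping[n] for n in names))
    pairwise: dict[tuple[str, str], frozenset] = {}
    category_names: dict[tuple[str, str], str] = {}
    pair_idx = 0
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            shared = mapping[a] & mapping[b]
            # exclusively this pair: drop residues in any third set
            for other in names:
                if other not in (a, b):
                    shared -= mapping[other]
            shared -= common_all
            pairwise[(a, b)] = frozenset(shared)
            category_names[(a, b)] = _ROMAN[pair_idx]
            pair_idx += 1
    unique: dict[str, frozenset] = {}
    for n in names:
        others = frozenset.union(*(mapping[m] for m in names if m != n)) \
            if len(names) > 1 else frozenset()
        unique[n] = frozenset(mapping[n] - others)
    return ContactPartition(tuple(names), common_all, pairwise, unique,
                            category_names)
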