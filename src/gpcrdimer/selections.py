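"""Tiny atom-selection language over :class:`~gpcrdimer.model_io.Structure`.

Grammar (case-insensitive)::

    selection := clause ( "and" clause )*
    clause    := [ "not" ] term
    term      := "chain"   id+        # chain identifiers
               | "resid"   spec+      # integers or inclusive ranges "193-206"
               | "name"    name+      # atom names
               | "resname" name+      # residue names
               | "element" sym+       # element symbols
               | "bw"      label+     # Ballesteros-Weinstein labels (needs map)
               | "segment" seg+       # TM1..TM7 / ECL* / ICL* (needs map)
               | "backbone"           # atom name in {N, CA, C, O}
               | "heavy"              # element != H
               | "protein"            # ATOM records (not HETATM)
               | "hetero"             # HETATM records (ligands)
               | "all"

Multiple values inside one term are OR-ed; clauses are AND-ed.  Example:
``"chain A and segment TM5 TM6 and backbone"``.
"""

from __future__ import annotations

import numpy as np

from .errors import SelectionError
from .model_io import BWMap, Structure

__all__ = ["select", "select_atoms"]

_BACKBONE_NAMES = {"N", "CA", "C", "O"}


def _term_mask(structure: Structure, keyword: str, values: list[str],
               bw_map: BWMap | None) -> np.ndarray:
    n = structure.n_atoms
    if keyword == "all":
        return np.ones(n, dtype=bool)
    if keyword == "backbone":
        return np.isin(structure.name.astype(str), list(_BACKBONE_NAMES))
    if keyword == "heavy":
        return np.array([e.upper() != "H" for e in structure.element], dtype=bool)
    if keyword == "protein":
        return ~structure.hetero
    if keyword == "hetero":
        return structure.hetero
    if not values:
        raise SelectionError(f"selection term {keyword!r} needs at least one value")
    if keyword == "chain":
        return np.isin([c.upper() for c in structure.chain_id],
                       [v.upper() for v in values])
    if keyword == "name":
        return np.isin([s.upper() for s in structure.name],
                       [v.upper() for v in values])
    if keyword == "resname":
        return np.isin([s.upper() for s in structure.res_name],
                       [v.upper() for v in values])
    if keyword == "element":
        return np.isin([s.upper() for s in structure.element],
                       [v.upper() for v in values])
    if keyword == "resid":
        mask = np.zeros(n, dtype=bool)
        for v in values:
            if "-" in v[1:]:  # allow leading minus, though resSeq is positive here
                lo_s, hi_s = v.rsplit("-", 1)
                try:
                    lo, hi = int(lo_s), int(hi_s)
                except ValueError:
                    raise SelectionError(f"bad resid range {v!r}") from None
                mask |= (structure.res_seq >= lo) & (structure.res_seq <= hi)
            else:
                try:
                    mask |= structure.res_seq == int(v)
                except ValueError:
                    raise SelectionError(f"bad resid {v!r}") from None
        return mask
    if keyword in ("bw", "segment"):
        if bw_map is None:
            raise SelectionError(f"term {keyword!r} requires a BW map")
        mask = np.zeros(n, dtype=bool)
        if keyword == "bw":
            wanted = set(values)
            for i in range(n):
                label = bw_map.label_or_none(str(structure.chain_id[i]),
                                             int(structure.res_seq[i]))
                if label in wanted:
                    mask[i] = True
        else:
            wanted = {v.upper() for v in values}
            for i in range(n):
                entry = bw_map.entries.get(
                    (str(structure.chain_id[i]), int(structure.res_seq[i]))
                )
                if entry and entry[1].upper() in wanted:
                    mask[i] = True
        return mask
    raise SelectionError(f"unknown selection keyword {keyword!r}")


_KEYWORDS = {
    "chain", "resid", "name", "resname", "element", "bw", "segment",
    "backbone", "heavy", "protein", "hetero", "all",
}


def select(structure: Structure, query: str, bw_map: BWMap | None = None) -> np.ndarray:
    """Return the sorted indices of atoms matching ``query``."""
    tokens = query.split()
    if not tokens:
        raise SelectionError("empty selection string")
    # Split on "and" into clauses.
    clauses: list[list[str]] = [[]]
    for tok in tokens:
        if tok.lower() == "and":
            if not clauses[-1]:
                raise SelectionError(f"misplaced 'and' in {query!r}")
            clauses.append([])
        else:
            clauses[-1].append(tok)
    mask = np.ones(structure.n_atoms, dtype=bool)
    for clause in clauses:
        if not clause:
            raise SelectionError(f"empty clause in {query!r}")
        negate = clause[0].lower() == "not"
        if negate:
            clause = clause[1:]
            if not clause:
                raise SelectionError(f"dangling 'not' in {query!r}")
        keyword = clause[0].lower()
        if keyword not in _KEYWORDS:
            raise SelectionError(f"unknown selection keyword {clause[0]!r}")
        m = _term_mask(structure, keyword, clause[1:], bw_map)
        mask &= ~m if negate else m
    return np.flatnonzero(mask)


def select_atoms(structure: Structure, query: str,
                 bw_map: BWMap | None = None) -> Structure:
    """Like :func:`select` but returns the matching sub-structure."""
    idx = select(structure, query, bw_map)
    if idx.size == 0:
        raise SelectionError(f"selection {query!r} matched no atoms")
    return structure.subset(idx)
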