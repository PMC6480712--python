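"""Sidechain chi1 rotamer analysis and ligand-pose stability windows.

The chi1 torsion (N-CA-CB-CG) of the aromatic residues tracked here hops
between two pseudo-stable wells: "trans" near 180 deg and (in the
nomenclature kept by this package) "cis" near 300 deg.  Frames are labeled
by a hard threshold at 240 deg -- cis for angles strictly above it, trans
otherwise.  Note that "cis" here is rotamer-chemistry gauche-minus; the
nonstandard naming is retained because it is how the wells are referred to
in the GPCR literature this package serves.

Occupancies are kept as frame counts (the fractions always sum to one
exactly).  Angle summaries use circular statistics; naive means would be
wrong near the 0/360 seam.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import circmean, circstd

from .errors import TopologyError
from .geometry import RmsdTrace, dihedral
from .model_io import BWMap, Trajectory

__all__ = [
    "CHI1_CIS_THRESHOLD",
    "Chi1Trace",
    "RotamerStates",
    "OccupancyReport",
    "StabilityWindow",
    "chi1_trace",
    "classify_rotamer",
    "state_occupancy",
    "stability_onset",
    "summarize_trace",
]

#: Classification threshold in degrees: chi1 > threshold is "cis" (well at
#: 300 deg), otherwise "trans" (well at 180 deg).  The boundary value itself
#: is trans, following the strict ">" convention.
CHI1_CIS_THRESHOLD = 240.0

_CHI1_ATOMS = ("N", "CA", "CB", "CG")


@dataclass
class Chi1Trace:
    """Per-frame chi1 angle series for one residue, degrees on [0, 360)."""

    chain_id: str
    res_seq: int
    label: str | None  # BW label if known
    times: np.ndarray
    angles: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.times.shape != self.angles.shape:
            raise ValueError("times and angles must have equal length")
        if np.any((self.angles < 0) | (self.angles >= 360)):
            raise ValueError("chi1 angles must lie in [0, 360)")


@dataclass
class RotamerStates:
    """Cis/trans labeling of a chi1 trace at a fixed threshold."""

    trace: Chi1Trace
    threshold: float = CHI1_CIS_THRESHOLD
    states: np.ndarray = field(init=False)  # "cis" / "trans" per frame

    def __post_init__(self) -> None:
        self.states = np.where(
            self.trace.angles > self.threshold, "cis", "trans"
        )


@dataclass
class OccupancyReport:
    """Cis/trans frame-count occupancies of one residue over a window."""

    chain_id: str
    res_seq: int
    label: str | None
    window: tuple[float, float]
    n_frames: int
    n_cis: int

    @property
    def n_trans(self) -> int:
        return self.n_frames - self.n_cis

    @property
    def fraction_cis(self) -> float:
        return self.n_cis / self.n_frames

    @property
    def fraction_trans(self) -> float:
        return self.n_trans / self.n_frames


@dataclass
class StabilityWindow:
    """Trailing window in which RMSD-to-final stays below a threshold."""

    onset: float  # ns
    threshold: float  # Angstrom
    reference: str = "final"


def chi1_trace(traj: Trajectory, chain_id: str, res_seq: int,
               bw_map: BWMap | None = None) -> Chi1Trace:
    """Chi1 (N-CA-CB-CG) angle of one residue across all frames."""
    top = traj.topology
    idx = []
    for atom in _CHI1_ATOMS:
        try:
            idx.append(top.atom_index(chain_id, res_seq, atom))
        except TopologyError:
            raise TopologyError(
                f"residue {chain_id}:{res_seq} lacks atom {atom!r} "
                "required for chi1"
            ) from None
    n, ca, cb, cg = idx
    angles = dihedral(
        traj.coords[:, n], traj.coords[:, ca], traj.coords[:, cb], traj.coords[:, cg]
    )
    label = bw_map.label_or_none(chain_id, res_seq) if bw_map else None
    return Chi1Trace(chain_id, res_seq, label, traj.times.copy(),
                     np.atleast_1d(angles))


def classify_rotamer(angle: float, threshold: float = CHI1_CIS_THRESHOLD) -> str:
    """Label a wrapped chi1 angle: "cis" iff angle > threshold, else "trans"."""
    if not 0.0 <= angle < 360.0:
        raise ValueError(
            f"angle {angle!r} outside [0, 360); wrap before classifying"
        )
    return "cis" if angle > threshold else "trans"


def state_occupancy(states: RotamerStates,
                    window: tuple[float, float] | None = None) -> OccupancyReport:
    """Cis/trans occupancy of a labeled trace within an inclusive time window."""
    trace = states.trace
    if window is None:
        window = (float(trace.times[0]), float(trace.times[-1]))
    mask = (trace.times >= window[0]) & (trace.times <= window[1])
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"window {window} ns overlaps no frame")
    n_cis = int(np.count_nonzero(states.states[mask] == "cis"))
    return OccupancyReport(trace.chain_id, trace.res_seq, trace.label,
                           window, n, n_cis)


def stability_onset(trace: RmsdTrace, threshold: float = 3.0) -> StabilityWindow:
    """Earliest time from which RMSD-to-final stays strictly below threshold.

    The final frame has RMSD 0 against itself, so an onset always exists
    (the final-frame time in the worst case).
    """
    if trace.values.size == 0:
        raise ValueError("empty RMSD trace")
    above = np.flatnonzero(trace.values >= threshold)
    onset_idx = 0 if above.size == 0 else int(above[-1]) + 1
    if onset_idx >= trace.values.size:
        onset_idx = trace.values.size - 1  # last frame trivially qualifies
    return StabilityWindow(onset=float(trace.times[onset_idx]),
                           threshold=threshold, reference=trace.reference)


def summarize_trace(times: np.ndarray, values: np.ndarray,
                    window: tuple[float, float] | None = None,
                    circular: bool = False) -> tuple[float, float]:
    """Mean and population SD of a per-frame series over a window.

    ``circular=True`` treats values as angles in degrees and returns the
    circular mean (mapped to [0, 360)) and circular SD.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if window is not None:
        mask = (times >= window[0]) & (times <= window[1])
        values = values[mask]
    if values.size < 2:
        raise ValueError("summary window must contain at least 2 frames")
    if circular:
        mean = float(circmean(values, high=360.0, low=0.0))
        sd = float(circstd(values, high=360.0, low=0.0))
        return mean % 360.0, sd
    return float(values.mean()), float(values.std())
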