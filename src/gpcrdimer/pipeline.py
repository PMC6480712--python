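"""End-to-end monomer/dimer/partition analyses driven by a config file.

Each run reads standard inputs (multi-MODEL PDB trajectory, BW-map TSV,
fingerprint TSVs), executes the relevant operations with the configured
cutoffs, and emits a deterministic report: a JSON file holding every number
plus TSV side-products (occupancy tables, fingerprints, partition table).
Every threshold that affected a number is echoed into the report, and all
floats are formatted to fixed precision (3 decimals; percentages to 1), so
reruns on identical inputs are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .contacts import (CONTACT_CUTOFF, contact_frequency, frequent_contacts,
                       partition_contacts)
from .errors import ConfigError, GpcrDimerError
from .geometry import rmsd_trace, tmd_backbone_selection
from .interface import (ENERGY_CUTOFF, HBondCriterion, alanine_scan,
                        hbond_occupancy, interface_distance_trace,
                        interface_energy, load_energy_params,
                        residue_pair_min_distance)
from .model_io import Trajectory, load_bw_map, read_pdb
from .rotamers import (CHI1_CIS_THRESHOLD, RotamerStates, chi1_trace,
                       stability_onset, state_occupancy, summarize_trace)
from .selections import select

__all__ = ["AnalysisConfig", "RunReport", "run_monomer", "run_dimer",
           "run_partition", "run_from_config"]


@dataclass
class AnalysisConfig:
    """Pipeline configuration (YAML-loadable) with the standard cutoffs."""

    mode: str  # monomer | dimer | partition
    trajectory: str | None = None
    bw_map: str | None = None
    ligand_chain: str = "L"
    chains: tuple[str, str] = ("A", "B")
    fingerprints: dict[str, str] = field(default_factory=dict)
    tracked_bw: list[str] = field(default_factory=lambda: ["5.48", "6.52"])
    contact_cutoff: float = CONTACT_CUTOFF
    rotamer_threshold: float = CHI1_CIS_THRESHOLD
    stability_threshold: float = 3.0
    energy_cutoff: float = ENERGY_CUTOFF
    hbond_distance: float = 3.5
    hbond_angle: float = 150.0
    min_contact_fraction: float = 0.5
    ca_only_backbone: bool = False
    outdir: str = "."

    def __post_init__(self) -> None:
        if self.mode not in ("monomer", "dimer", "partition"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        for name in ("contact_cutoff", "rotamer_threshold",
                     "stability_threshold", "energy_cutoff", "hbond_distance"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.mode in ("monomer", "dimer"):
            if not self.trajectory or not self.bw_map:
                raise ConfigError(
                    f"mode {self.mode!r} requires 'trajectory' and 'bw_map' paths"
                )
        if self.mode == "partition" and len(self.fingerprints) < 2:
            raise ConfigError("partition mode needs >= 2 named fingerprint files")
        self.chains = tuple(self.chains)  # type: ignore[assignment]

    @staticmethod
    def from_yaml(path: str | Path, **overrides: Any) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} must be a YAML mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        try:
            return AnalysisConfig(**data)
        except TypeError as exc:
            raise ConfigError(f"bad config key: {exc}") from None


def _fmt(x: float, nd: int = 3) -> float:
    return float(f"{x:.{nd}f}")


def _pct(x: float) -> float:
    return float(f"{100.0 * x:.1f}")


@dataclass
class RunReport:
    """Provenance plus all numeric outputs of one pipeline run."""

    mode: str
    provenance: dict[str, Any]
    results: dict[str, Any]
    tables: dict[str, str] = field(default_factory=dict)  # filename -> text

    def to_json(self) -> str:
        return json.dumps(
            {"mode": self.mode, "provenance": self.provenance,
             "results": self.results},
            indent=1, sort_keys=True,
        ) + "\n"

    def write(self, outdir: str | Path) -> list[Path]:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        written = [out / f"{self.mode}_report.json"]
        written[0].write_text(self.to_json())
        for name, text in self.tables.items():
            p = out / name
            p.write_text(text)
            written.append(p)
        return written


def _provenance(config: AnalysisConfig, extra: dict[str, Any] | None = None):
    prov: dict[str, Any] = {
        "package_version": __version__,
        "mode": config.mode,
        "cutoffs": {
            "contact_cutoff_A": config.contact_cutoff,
            "rotamer_threshold_deg": config.rotamer_threshold,
            "stability_threshold_A": config.stability_threshold,
            "energy_cutoff_A": config.energy_cutoff,
            "hbond_distance_A": config.hbond_distance,
            "hbond_angle_deg": config.hbond_angle,
            "min_contact_fraction": config.min_contact_fraction,
        },
        "tracked_bw": list(config.tracked_bw),
    }
    if extra:
        prov.update(extra)
    return prov


def _load_traj(config: AnalysisConfig) -> Trajectory:
    obj = read_pdb(config.trajectory)
    if not isinstance(obj, Trajectory):
        obj = Trajectory(obj, obj.xyz[None], [0.0])
    return obj


def _window_desc(window: tuple[float, float]) -> str:
    return f"({window[0]:g},{window[1]:g}) ns"


def _occupancy_rows(traj, bw_map, config, residues, window):
    rows = []
    for chain, res_seq in residues:
        trace = chi1_trace(traj, chain, res_seq, bw_map)
        states = RotamerStates(trace, threshold=config.rotamer_threshold)
        occ = state_occupancy(states, window)
        rows.append(occ)
    return rows


def _occupancy_table(rows, window_name: str) -> str:
    lines = ["residue\tlabel\twindow_ns\tn_frames\tfraction_cis\tfraction_trans"]
    for occ in rows:
        lines.append(
            f"{occ.chain_id}:{occ.res_seq}\t{occ.label or '-'}\t"
            f"{occ.window[0]:g}-{occ.window[1]:g}\t{occ.n_frames}\t"
            f"{occ.fraction_cis:.3f}\t{occ.fraction_trans:.3f}"
        )
    return "\n".join(lines) + "\n"


def _tracked_residues(bw_map, config, chain):
    out = []
    for label in config.tracked_bw:
        try:
            out.append(bw_map.lookup(label, chain))
        except KeyError:
            raise ConfigError(
                f"tracked BW label {label!r} not present for chain {chain!r}"
            ) from None
    return out


class _Stage:
    """Context manager that renames any error with its pipeline stage."""

    def __init__(self, name: str) -> None:
        self.name = name

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and isinstance(exc, GpcrDimerError):
            raise type(exc)(f"stage {self.name!r}: {exc}") from None
        return False


def run_monomer(config: AnalysisConfig) -> RunReport:
    """Ligand-bound monomer analysis: RMSD traces, pose-stability window,
    contact fingerprint over the stable window, chi1 occupancies."""
    if config.mode != "monomer":
        raise ConfigError("config mode must be 'monomer'")
    with _Stage("load"):
        traj = _load_traj(config)
        bw_map = load_bw_map(config.bw_map)
        lig_idx = select(traj.topology, f"chain {config.ligand_chain}")
        if lig_idx.size == 0:
            raise ConfigError(
                f"ligand chain {config.ligand_chain!r} absent from trajectory"
            )
        rec_idx = select(traj.topology, f"not chain {config.ligand_chain}")
    backbone_sel = tmd_backbone_selection(config.ca_only_backbone)
    with _Stage("rmsd"):
        bb_rmsd = rmsd_trace(traj, backbone_sel, reference=0, superpose=True,
                             bw_map=bw_map)
        lig_rmsd = rmsd_trace(traj, f"chain {config.ligand_chain}",
                              reference="final", superpose=True,
                              fit_selection=backbone_sel, bw_map=bw_map)
    with _Stage("stability"):
        window_obj = stability_onset(lig_rmsd, config.stability_threshold)
        stable = (window_obj.onset, float(traj.times[-1]))
        full = (float(traj.times[0]), float(traj.times[-1]))
        lig_mean, lig_sd = summarize_trace(lig_rmsd.times, lig_rmsd.values, stable) \
            if ((lig_rmsd.times >= stable[0]).sum() >= 2) else (0.0, 0.0)
    with _Stage("contacts"):
        freq = contact_frequency(traj, lig_idx, rec_idx, window=stable,
                                 cutoff=config.contact_cutoff, bw_map=bw_map)
        pocket = frequent_contacts(freq, config.min_contact_fraction,
                                   ligand_name=config.ligand_chain,
                                   window_desc=_window_desc(stable))
    with _Stage("rotamers"):
        residues = _tracked_residues(bw_map, config, "A")
        occ_stable = _occupancy_rows(traj, bw_map, config, residues, stable)
        occ_full = _occupancy_rows(traj, bw_map, config, residues, full)

    results = {
        "backbone_rmsd_final_A": _fmt(bb_rmsd.values[-1]),
        "ligand_rmsd_stable_mean_A": _fmt(lig_mean),
        "ligand_rmsd_stable_sd_A": _fmt(lig_sd),
        "stable_onset_ns": _fmt(window_obj.onset),
        "stable_onset_us": _fmt(window_obj.onset / 1000.0),
        "pocket_residues": sorted(t.display() for t in pocket.residues),
        "contact_frequencies": {
            t.display(): _fmt(f) for t, f in freq.items()
        },
        "occupancy_stable_window": {
            f"{o.chain_id}:{o.res_seq}": {"cis_pct": _pct(o.fraction_cis),
                                          "trans_pct": _pct(o.fraction_trans)}
            for o in occ_stable
        },
        "occupancy_full_run": {
            f"{o.chain_id}:{o.res_seq}": {"cis_pct": _pct(o.fraction_cis),
                                          "trans_pct": _pct(o.fraction_trans)}
            for o in occ_full
        },
    }
    tables = {
        "occupancy_stable.tsv": _occupancy_table(occ_stable, "stable"),
        "occupancy_full.tsv": _occupancy_table(occ_full, "full"),
        "fingerprint.tsv": "residue\tlabel\tfraction\n" + "".join(
            f"{t.res_name}{t.res_seq}\t{t.label or '-'}\t{f:.3f}\n"
            for t, f in sorted(freq.items())
        ),
    }
    prov = _provenance(config, {
        "trajectory": str(config.trajectory), "bw_map": str(config.bw_map),
        "n_frames": traj.n_frames,
        "stable_window_ns": [stable[0], stable[1]],
        "backbone_selection": backbone_sel,
    })
    return RunReport("monomer", prov, results, tables)


def run_dimer(config: AnalysisConfig) -> RunReport:
    """Homodimer interface analysis: distance traces, Tyr-Tyr H-bond
    occupancy, interface energy and alanine scan of the tracked residues."""
    if config.mode != "dimer":
        raise ConfigError("config mode must be 'dimer'")
    chain_a, chain_b = config.chains
    with _Stage("load"):
        traj = _load_traj(config)
        bw_map = load_bw_map(config.bw_map)
        chains_present = set(traj.topology.chain_id)
        if not {chain_a, chain_b} <= chains_present:
            raise ConfigError(
                f"dimer mode needs chains {chain_a}/{chain_b}; trajectory has "
                f"{sorted(chains_present)}"
            )
    with _Stage("distances"):
        sel_a = select(traj.topology, f"chain {chain_a} and segment TM5 TM6",
                       bw_map)
        sel_b = select(traj.topology, f"chain {chain_b} and segment TM5 TM6",
                       bw_map)
        cog, dmin = interface_distance_trace(traj, sel_a, sel_b)
        res_a = _tracked_residues(bw_map, config, chain_a)
        res_b = _tracked_residues(bw_map, config, chain_b)
        pair_mean, pair_sd, _tr = residue_pair_min_distance(traj, res_a, res_b)
    with _Stage("hbond"):
        criterion = HBondCriterion(config.hbond_distance, config.hbond_angle)
        tyr_a = res_a[0]
        tyr_b = res_b[0]
        hb_occ = hbond_occupancy(
            traj, (*tyr_a, "OH"), (*tyr_b, "OH"), criterion, symmetric=True,
        )
    with _Stage("energy"):
        model = load_energy_params(cutoff=config.energy_cutoff)
        energy = interface_energy(traj, model, (chain_a, chain_b))
        scan = alanine_scan(traj, res_a + res_b, model, (chain_a, chain_b))
    with _Stage("rotamers"):
        occ = _occupancy_rows(traj, bw_map, config, res_a + res_b,
                              (float(traj.times[0]), float(traj.times[-1])))

    results = {
        "interface_cog_distance_mean_A": _fmt(cog.mean()),
        "interface_min_distance_mean_A": _fmt(dmin.mean()),
        "tracked_pair_min_distance_mean_A": _fmt(pair_mean),
        "tracked_pair_min_distance_sd_A": _fmt(pair_sd),
        "hbond_occupancy_pct": _pct(hb_occ),
        "hbond_criterion": criterion.describe(),
        "interface_energy_mean_kcal_mol": _fmt(energy.mean),
        "interface_energy_sd_kcal_mol": _fmt(energy.sd),
        "energy_model": energy.model,
        "alascan": {
            "mutated": [f"{c}:{r}" for c, r in scan.mutated],
            "e_wt_kcal_mol": _fmt(scan.e_wt),
            "e_mut_kcal_mol": _fmt(scan.e_mut),
            "contribution_kcal_mol": _fmt(scan.contribution),
        },
        "occupancy_full_run": {
            f"{o.chain_id}:{o.res_seq}": {"cis_pct": _pct(o.fraction_cis),
                                          "trans_pct": _pct(o.fraction_trans)}
            for o in occ
        },
    }
    tables = {"occupancy_full.tsv": _occupancy_table(occ, "full")}
    prov = _provenance(config, {
        "trajectory": str(config.trajectory), "bw_map": str(config.bw_map),
        "n_frames": traj.n_frames, "chains": [chain_a, chain_b],
    })
    return RunReport("dimer", prov, results, tables)


def _read_fingerprint_tsv(path: str | Path) -> set[tuple[str, int]]:
    residues: set[tuple[str, int]] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "residue\t")):
                continue
            fields = line.split("\t")
            name_seq = fields[0]
            res_name = name_seq.rstrip("0123456789")
            res_seq = int(name_seq[len(res_name):])
            residues.add((res_name, res_seq))
    return residues


def run_partition(config: AnalysisConfig) -> RunReport:
    """Cross-ligand contact partition rendered as a two-column table."""
    if config.mode != "partition":
        raise ConfigError("config mode must be 'partition'")
    with _Stage("load"):
        sets = {name: _read_fingerprint_tsv(path)
                for name, path in config.fingerprints.items()}
    with _Stage("partition"):
        part = partition_contacts(sets)

    def disp(res: tuple[str, int]) -> str:
        return f"{res[0]}{res[1]}"

    lines = ["ligand\tunique_interactions\tcommon_interactions\tcategory"]
    results: dict[str, Any] = {"ligands": list(part.ligands), "categories": {}}
    for ligand in part.ligands:
        uniques = sorted(part.unique[ligand])
        commons = [(res, part.category_of(ligand, res))
                   for res in sorted(sets[ligand] - part.unique[ligand])]
        commons.sort(key=lambda rc: ({"I": 0, "II": 1, "III": 2, "IV": 3}
                                     .get(rc[1], 9), rc[0]))
        results["categories"][ligand] = {
            "unique": [disp(r) for r in uniques],
            "common": {disp(r): tag for r, tag in commons},
        }
        n = max(len(uniques), len(commons))
        for i in range(n):
            u = disp(uniques[i]) if i < len(uniques) else ""
            c, tag = (disp(commons[i][0]), commons[i][1]) if i < len(commons) \
                else ("", "")
            lines.append(f"{ligand if i == 0 else ''}\t{u}\t{c}\t{tag}")
    prov = _provenance(config, {"fingerprints": dict(config.fingerprints)})
    return RunReport("partition", prov, results,
                     {"partition_table.tsv": "\n".join(lines) + "\n"})


def run_from_config(config: AnalysisConfig) -> RunReport:
    runner = {"monomer": run_monomer, "dimer": run_dimer,
              "partition": run_partition}[config.mode]
    return runner(config)
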