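# gpcrdimer

Analysis toolkit for molecular-dynamics trajectories of class-A GPCRs that
asks a specific structural question: **how does a bound antagonist select
sidechain rotamer states on transmembrane helices 5 and 6, and how do those
states shape a TM5/TM6 homodimer interface?**  It was built around the
dopamine D2 receptor case — Tyr199 at Ballesteros–Weinstein position 5.48
and Phe390 at 6.52 — but every operation works on any receptor given a
residue-numbering map.

It is a library first (plus a thin `gpcrdimer` CLI over the pipeline), aimed
at computational structural biologists who have trajectories (or want
fully ground-truthed synthetic ones) and need the following report surfaces:

* **Ligand-pose stability**: per-frame RMSD of the ligand to its *final*
  conformation after superposing each frame on the receptor TMD backbone;
  the stable window starts at the earliest time *t*\* such that
  RMSD(t) < 3.0 Å for all t ≥ t\*.
* **χ1 rotamer occupancy**: χ1 = dihedral(N, CA, CB, CG) on [0°, 360°),
  classified **cis** (well at 300°) iff χ1 > 240°, else **trans** (well at
  180°) — the nomenclature of the GPCR literature this serves (chemists
  would say gauche− / anti).  Occupancies are frame counts, summarized over
  explicit windows; angle means are circular.
* **Contact fingerprints**: residue *r* contacts the ligand in a frame iff
  any heavy-atom pair distance < 3.5 Å (strict).  Frequencies over the
  stable window, thresholded at 50%, define the orthosteric pocket; named
  fingerprints for 2–3 ligands are partitioned into categories
  (I) common to all, (II)–(IV) exclusive pairwise, and unique.
* **Dimer interface**: inter-protomer center-of-geometry and minimum
  heavy-atom distances, geometric H-bond occupancy (donor–acceptor ≤ 3.5 Å,
  D–H···A ≥ 150° when hydrogens exist), a simplified interface energy

  E = Σ_{i∈A, j∈B, r_ij<12 Å} [ q_i q_j·332.0636/(4 r_ij²) + 4ε_ij((σ_ij/r_ij)¹² − (σ_ij/r_ij)⁶) ]

  (distance-dependent dielectric ε(r) = 4r, Lorentz–Berthelot mixing), and
  **computational alanine scanning**: truncate sidechains to Cβ on fixed
  coordinates and report the contribution ΔE = E_wt − E_mut.
* **Synthetic trajectories with exact ground truth**: two-state Markov χ1
  dynamics (stationary P(trans), persistence, wrapped-Gaussian noise
  σ = 15°), scripted ligand contact distances, scripted inter-protomer
  separations and H-bond frames — so every analysis stage is testable
  without external data.

## Worked example

```bash
python examples/dimer_interface.py
```

prints (seed 3, 500 frames):

```
TM5/TM6 center-of-geometry distance: 18.8 A
Tyr199/Phe390 cross-protomer min distance: 5.43 +/- 1.43 A
Tyr199-Tyr199 H-bond occupancy: 4.0% (scripted 4.0%)
interface energy (surrogate model): -0.59 +/- 0.63 kcal/mol
alanine scan Y199A+F390A (both protomers): E_wt -0.59, E_mut -0.01, contribution -0.58 kcal/mol
```

Read this as: the two protomers hold a tight aromatic interface (average
Tyr/Phe minimum distance ≈ 5.4 Å) with a transient Tyr–Tyr hydrogen bond in
4% of frames, and truncating the four interface aromatics to alanine wipes
out essentially the whole attractive interface energy — the aromatics *are*
the interface in this geometry.  Other examples cover pose stability
(`pose_stability.py`), rotamer occupancies under two antagonist conditions
(`rotamer_occupancy.py`), pocket fingerprints (`contact_fingerprint.py`)
and the cross-ligand contact partition (`contact_partition.py`).

The same analyses run from the shell:

```bash
gpcrdimer simulate --kind dimer --seed 3 --frames 500 --outdir run/
gpcrdimer analyze-dimer --trajectory run/dimer.pdb --bw-map run/dimer_bw.tsv --outdir run/
```

## Layout

```
src/gpcrdimer/
  model_io.py    PDB (multi-MODEL) I/O, Structure/Trajectory, BW-label maps
  selections.py  "chain A and segment TM5 TM6 and backbone" mini-language
  geometry.py    Kabsch superposition, RMSD traces, dihedrals, distances
  rotamers.py    chi1 traces, cis/trans classification, stability windows
  contacts.py    contact fingerprints and the cross-ligand partition
  interface.py   dimer distances, H-bonds, interface energy, alanine scan
  synthetic.py   ground-truthed toy protomers and trajectories
  pipeline.py    config-driven monomer/dimer/partition runs
  cli.py         thin click front end (simulate / analyze-* / partition)
```

See `docs/methods.md` for the model definitions, parameter choices and
limitations.
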