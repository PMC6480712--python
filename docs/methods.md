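# Methods

This note defines the quantities the package computes, the conventions and
parameters behind them, what the synthetic generator does and does not
emulate, and the design choices made where the design was genuinely open.

## Coordinates, units, conventions

Coordinates are in Å, times in ns (reports also print µs).  Hydrogens are
optional everywhere; all default selections are heavy-atom-only, because
crystal-derived inputs lack hydrogens and mixing H-bearing and H-free
frames would make fingerprints incomparable.  Chain identity defines
protomer identity (protomer 1 = chain A, protomer 2 = chain B by default);
residue numbering is the author/PDB numbering, never renumbered.  Ligands
travel as HETATM records under their own chain id.  A tab-separated
residue-label table (chain, resSeq, label, segment) supplies
Ballesteros–Weinstein positions ("5.48") and segment assignments
(TM1–TM7, ECL/ICL loops); lookups work in both directions.

## Dihedral angles

Torsions use the two-plane-normal construction with the field-standard
sign (verified against MDAnalysis and mdtraj on random quadruples), then
map (−180°, 180°] to [0°, 360°) by adding 360° to negatives.  The wrapped
range is load-bearing: the χ1 wells at 300° ("cis") and 180° (trans) and
the 240° classification threshold are only representable there.  Signed
angles are never exposed.  Note that a genuine torsion is invariant under
reversing the atom order (the IUPAC sign does not depend on the viewing
direction); the property tests assert exactly that invariance.

## χ1 classification and occupancy

χ1 = dihedral(N, CA, CB, CG).  A frame is **cis** iff χ1 > 240° (strict),
otherwise **trans**; the boundary value 240.0° is trans.  The "cis/trans"
naming follows the GPCR-pharmacology usage for these wells (rotamer
chemistry would call them gauche− and anti); the package keeps the field's
names rather than correcting them.  Occupancies are stored as frame counts
over an explicit window, so fraction_cis + fraction_trans = 1 exactly.  Two
window presets matter because published numbers mix them: the ligand's
stable window (monomer analyses) and the full run (dimer analyses); the
operation always takes the window as an argument.  No smoothing or
debouncing is applied to state sequences — a frame above the threshold is
cis, full stop.  Angle means/SDs are circular (naïve means are wrong near
the 0°/360° seam).

## Ligand-pose stability

Every frame is rigidly superposed (Kabsch, SVD with determinant repair) on
the receptor TMD backbone — N, CA, C, O atoms of residues labeled TM1–TM7;
a CA-only variant is exposed since published backbone RMSDs often do not
state the atom set.  The ligand RMSD to the **final** frame is then
computed without re-fitting the ligand, so it measures pose drift in the
receptor frame.  The stable window starts at the earliest frame from which
the trace stays strictly below the threshold (default 3.0 Å); the final
frame qualifies trivially, so an onset always exists.

## Contacts and the cross-ligand partition

Residue–ligand contact: any heavy-atom pair distance < cutoff (default
3.5 Å, strict, so exactly 3.5 Å is *not* a contact).  Frequencies are
fractions of window frames; "frequently contacted" defaults to ≥ 0.5
(a median-occupancy convention — the threshold is echoed into report
metadata because it is a choice, not a standard).  Both a
frequency-threshold mode and single-frame/union modes exist, since
published tables rarely state which was used.

The partition of 2–3 named contact sets: category I = residues in every
set; one category per ligand pair (II, III, IV in pair-enumeration order) =
residues in exactly that pair; unique = the remainder.  These blocks always
form a true partition of the union.  With four or more sets a residue
shared by exactly three would fall into no category, so the operation
rejects > 3 sets rather than silently mislabeling.

## Dimer interface

Distance traces report both the center-of-geometry distance and the
minimum heavy-atom distance between interface selections on distinct
chains.  The residue-pair statistic used for the aromatic cluster is the
per-frame minimum heavy-atom distance between {Tyr5.48, Phe6.52} of
protomer 1 and the same pair of protomer 2, summarized as mean ± population
SD.

Hydrogen bonds are geometric: donor–acceptor heavy-atom distance ≤ 3.5 Å,
plus D–H···A angle ≥ 150° *only when an explicit donor hydrogen exists*
(heavy-atom-only structures fall back to the distance criterion).  A
symmetric mode accepts either partner as donor — for hydroxyl pairs
without hydrogens the two directions coincide.  The criterion parameters
are embedded in every report.

### Interface energy (surrogate)

The interaction energy between protomers is a deliberately simple pairwise
surrogate, not a force field and not comparable to any published
FoldX/CHARMM number:

    E = Σ over inter-chain heavy-atom pairs with r < 12 Å of
        q_i q_j · 332.0636 / (4 r²)           (Coulomb, ε(r) = 4r)
      + 4 ε_ij [ (σ_ij/r)¹² − (σ_ij/r)⁶ ]     (Lennard-Jones)

with Lorentz–Berthelot mixing of a packaged per-element LJ table
(σ: H 2.00, C 3.40, N 3.25, O 2.96, S 3.56, P 3.74 Å; ε: 0.016–0.25
kcal/mol — generic values of the magnitude common to protein force fields)
and formal charges only on ionizable sidechain termini (Asp/Glu −0.5 per
carboxylate O, Lys +1 on NZ, Arg +0.5 per NH, protonated His +0.5 per ring
N).  The distance-dependent dielectric ε(r) = 4r is a standard implicit
screening choice.  The model's contract is self-consistency: exact pair
additivity, protomer-swap symmetry, rigid-motion invariance, zero beyond
the cutoff — which is what alanine-scan bookkeeping requires.

### Alanine scanning

Mutation truncates the listed residues to Cβ on *fixed* wild-type
coordinates (no repacking or minimization), renames them ALA, and
re-evaluates the interface energy on identical frames.  The contribution is
ΔE = E_wt − E_mut; by pair additivity it equals minus the sum of the
removed atoms' inter-protomer terms, and the scan is deterministic and
idempotent.  Negative ΔE means the truncated sidechains stabilized the
interface.  Externally computed docking interface scores can be annotated
against the conventional −5.0 "satisfactory" threshold but are never
computed here.

## Synthetic generator

The generator emulates the *statistical structure* of the study outputs,
with exact ground truth by construction:

* **Protomer**: ideal α-helices (rise 1.5 Å/residue, twist 100°/residue,
  CA radius 2.28 Å → CA–CA 3.80 Å) labeled TM5 (residues 193–206, Tyr199 =
  5.48) and TM6 (383–396, Phe390 = 6.52), plus an optional TM3 pocket helix
  (110–120, Asp114 = 3.32) on the opposite face.  Tyr/Phe sidechains are
  full-heavy-atom and rebuilt each frame by internal-coordinate (NeRF)
  placement, so χ1 is settable exactly; ring closure is approximate, which
  is irrelevant to every measured quantity.
* **χ1 dynamics**: a two-state Markov chain per tracked residue with
  stationary P(trans) and persistence p_stay = P(trans→trans);
  P(cis→trans) is solved from stationarity and combinations implying a
  probability outside [0, 1] are rejected.  The default persistence
  1 − (1 − P(trans))/2 is reachable for every stationary value and gives a
  lag-1 autocorrelation of exactly 0.5, hence an effective sample size of
  n/3 for occupancy standard errors.  Angles are the well center (180°/300°)
  plus wrapped-Gaussian noise, σ = 15° by default so 3σ stays clear of the
  240° boundary and state labels are unambiguous; the spiperone-like preset
  uses memoryless hopping (p_stay = stationary) to reflect that condition's
  rapid fluctuation.
* **Ligand**: a rigid 5-atom cluster placed so its minimum heavy-atom
  distance to the pocket residue is *exactly* the scripted value (solved in
  closed form along the approach direction): cutoff − 0.3 Å on scripted
  contact frames, cutoff + 2 Å otherwise; contact frames are drawn with
  exact count from the stable window.  Before the scripted pose-switch
  frame the whole ligand is displaced 6 Å, putting the stability onset
  exactly on that frame.  Anchoring on the rotamer-static pocket residue
  (not on the hopping aromatics) keeps the stable-window pose drift well
  under the 3 Å threshold by construction.
* **Dimer**: protomer B is protomer A rotated 180° about the TM5 axis and
  shifted along the interface normal so the cross-protomer Tyr/Phe minimum
  distance equals the scripted separation exactly per frame (default
  Normal(5.5, 1.5) Å clipped at 3.6 Å — the floor keeps non-scripted frames
  above the H-bond cutoff).  On an exact count of H-bond frames the two Tyr
  hydroxyl oxygens are posed 2.8 Å apart; those frames therefore undercut
  the scripted minimum distance slightly, a deliberate correlated
  fluctuation (distance-recovery checks use H-bond-free runs).
* **Jitter**: a per-frame random rigid rotation (≤ 4°) and translation
  (σ = 0.5 Å) of the whole system exercises superposition; every scripted
  quantity is invariant under it.

Scale defaults (600–10⁴ frames, ≤ ~500 atoms) keep full analyses at
seconds-to-minutes; the 3 µs study timescale is mapped onto the frame count
via dt.  What the generator does **not** emulate: force-field dynamics,
membrane environment, correlated backbone motion, realistic packing or
solvent.  Recovery tests therefore validate the analysis bookkeeping and
estimators, not conformational sampling of real receptors.

## Numerical choices

Float-equality tolerance 10⁻⁶ Å unless stated; energies compared to the
brute-force oracle at 10⁻⁸ kcal/mol on clash-free geometries.  Kabsch uses
SVD with determinant repair (rotations are always proper); degenerate
(collinear or < 3-point) references are errors, as are collinear dihedral
triples and empty selections.  χ1 = 240.0° classifies as trans (strict
">" for cis).  PDB output is fixed-column with %8.3f coordinates
(|x| ≥ 10⁴ Å is an error) and a DT_NS remark preserving uniform time steps
across round trips; multi-MODEL files must have identical atom counts per
model (the error names the offending model).  Reports format floats to 3
decimals (percentages to 1), making reruns byte-identical.

## Known limitations

The energy surrogate has no solvation, entropy or polarization; its
absolute scale on toy geometries (around −0.5 kcal/mol) is far from
published interface energies of full receptors — only differences and
bookkeeping transfer.  The H-bond criterion's angle term silently
deactivates without hydrogens.  The partition report is defined for at
most three ligands.  The selection language has AND/NOT but no OR or
parentheses.  Trajectory I/O is PDB-only by design; binary formats should
be converted upstream.
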