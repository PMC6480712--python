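"""Chi1 rotamer occupancy of Tyr199(5.48) and Phe390(6.52).

Two antagonist conditions are simulated: a clozapine-like monomer (both
residues ~99% trans) and a spiperone-like monomer (Tyr hopping with 25% cis,
Phe locked cis).  Chi1 = N-CA-CB-CG is measured per frame on [0, 360) and
classified cis (>240 deg, well at 300) vs trans (<=240 deg, well at 180).
"""

from gpcrdimer import RotamerStates, chi1_trace, state_occupancy
from gpcrdimer.synthetic import (clozapine_like_monomer_spec,
                                 generate_monomer_trajectory,
                                 spiperone_like_monomer_spec)

for name, maker in (("clozapine-like", clozapine_like_monomer_spec),
                    ("spiperone-like", spiperone_like_monomer_spec)):
    spec = maker(seed=2, n_frames=2000)
    traj, bw_map, truth = generate_monomer_trajectory(spec)
    print(f"\n{name} monomer ({traj.n_frames} frames):")
    for label in ("5.48", "6.52"):
        chain, res = bw_map.lookup(label, "A")
        states = RotamerStates(chi1_trace(traj, chain, res, bw_map))
        occ = state_occupancy(states)
        print(f"  {label} (res {res}): trans {100 * occ.fraction_trans:5.1f}% "
              f"cis {100 * occ.fraction_cis:5.1f}%  "
              f"(generator stationary P(trans) = "
              f"{spec.rotamers[label].p_trans:.2f})")
# Trans orients both aromatics outward (toward the membrane / a partner
# protomer); cis points them into the helix bundle. The occupancy split is
# what distinguishes the two antagonist conditions.
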