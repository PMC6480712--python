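import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpcrdimer.contacts import (close_contacts, contact_frequency,
                                frequent_contacts, partition_contacts,
                                reference_antipsychotic_fingerprints)
from gpcrdimer.errors import SelectionError
from gpcrdimer.model_io import Trajectory
from gpcrdimer.selections import select

from _oracles import brute_contact_residues
from conftest import make_structure


def _pocket(distances, rng=None):
    """One ligand atom at the origin plus one CA per residue at the given
    distances (random directions)."""
    rng = rng or np.random.default_rng(5)
    atoms = [("C1", "C", "LIG", 900, "L", (0.0, 0.0, 0.0), True)]
    for i, d in enumerate(distances):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        atoms.append(("CA", "C", "GLY", 10 + i, "A", tuple(d * u), False))
    return make_structure(atoms)


class TestCloseContacts:
    @pytest.mark.parametrize("d,included", [(3.4, True), (3.6, False),
                                            (3.5, False)])  # strict "<"
    def test_cutoff_is_strict(self, d, included):
        frame = _pocket([d])
        cs = close_contacts(frame, np.array([0]), np.array([1]))
        assert (len(cs.residues) == 1) == included

    def test_counts_match_brute_force_on_random_pockets(self, rng):
        for _ in range(100):
            dists = rng.uniform(2.0, 6.0, size=rng.integers(3, 12))
            frame = _pocket(dists, rng)
            lig = np.array([0])
            rec = np.arange(1, frame.n_atoms)
            cs = close_contacts(frame, lig, rec)
            keys = {i: (str(frame.chain_id[i]), int(frame.res_seq[i]))
                    for i in rec}
            want = brute_contact_residues(frame.xyz, lig, rec, keys, 3.5)
            assert {(t.chain_id, t.res_seq) for t in cs.residues} == want

    def test_cutoff_monotonicity(self, rng):
        frame = _pocket(rng.uniform(2, 8, size=10), rng)
        lig, rec = np.array([0]), np.arange(1, 11)
        prev = frozenset()
        for cutoff in (2.5, 3.5, 5.0, 8.0):
            cur = close_contacts(frame, lig, rec, cutoff=cutoff).residues
            assert prev <= cur
            prev = cur

    def test_overlapping_selections_rejected(self):
        frame = _pocket([3.0])
        with pytest.raises(SelectionError, match="overlap"):
            close_contacts(frame, np.array([0, 1]), np.array([1]))

    def test_hydrogens_ignored(self):
        atoms = [("C1", "C", "LIG", 900, "L", (0, 0, 0), True),
                 ("CA", "C", "GLY", 10, "A", (6.0, 0, 0), False),
                 ("HA", "H", "GLY", 10, "A", (3.0, 0, 0), False)]
        frame = make_structure(atoms)
        cs = close_contacts(frame, np.array([0]), np.array([1, 2]))
        assert not cs.residues  # only the H was inside the cutoff


class TestContactFrequency:
    def _traj(self, in_contact_frames, n_frames=10):
        frame = _pocket([5.0])
        coords = np.broadcast_to(frame.xyz, (n_frames, 2, 3)).copy()
        for t in in_contact_frames:
            coords[t, 1] = [3.0, 0.0, 0.0]
        return Trajectory(frame, coords, np.arange(n_frames, dtype=float))

    def test_every_frame_gives_one(self):
        traj = self._traj(range(10))
        freq = contact_frequency(traj, np.array([0]), np.array([1]))
        assert list(freq.values()) == [1.0]

    def test_never_contacting_residue_absent(self):
        freq = contact_frequency(self._traj([]), np.array([0]), np.array([1]))
        assert freq == {}

    def test_scripted_fraction_recovered_exactly(self, monomer_run):
        _spec, traj, bw, truth = monomer_run
        window = (truth.stable_onset_ns, float(traj.times[-1]))
        freq = contact_frequency(traj, select(traj.topology, "hetero"),
                                 select(traj.topology, "protein"),
                                 window=window, bw_map=bw)
        assert len(freq) == 1
        (tag, fraction), = freq.items()
        assert (tag.res_name, tag.res_seq, tag.label) == ("ASP", 114, "3.32")
        assert fraction == pytest.approx(truth.contact_fraction, abs=1e-12)


class TestFrequentContacts:
    def test_thresholding(self):
        tags = {f"r{i}": i for i in range(4)}
        freqs = {k: v for k, v in zip(tags, [1.0, 0.49, 0.5, 0.0])}
        kept = frequent_contacts(freqs).residues
        assert kept == frozenset({"r0", "r2"})

    def test_zero_threshold_keeps_every_contacting_residue(self):
        freqs = {"a": 0.01, "b": 0.99}
        assert frequent_contacts(freqs, min_fraction=0.0).residues \
            == frozenset({"a", "b"})


class TestPartition:
    def test_reference_fingerprints_reproduce_published_tags(self):
        sets, expected, _labels = reference_antipsychotic_fingerprints()
        part = partition_contacts({k: sets[k] for k in
                                   ("risperidone", "clozapine", "spiperone")})
        for (ligand, residue), tag in expected.items():
            assert part.category_of(ligand, residue) == tag, (ligand, residue)
        # spot anchors: the conserved salt-bridge aspartate is category I,
        # Val91 is spiperone-only
        assert ("ASP", 114) in part.common_all
        assert ("VAL", 91) in part.unique["spiperone"]

    def test_disjoint_sets_all_unique(self):
        part = partition_contacts({"a": {1, 2}, "b": {3}, "c": {4, 5}})
        assert not part.common_all
        assert all(not v for v in part.pairwise.values())
        assert part.unique == {"a": frozenset({1, 2}), "b": frozenset({3}),
                               "c": frozenset({4, 5})}

    def test_identical_sets_all_common(self):
        part = partition_contacts({"a": {1, 2}, "b": {1, 2}})
        assert part.common_all == frozenset({1, 2})
        assert not part.unique["a"] and not part.unique["b"]

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            partition_contacts([type("CS", (), {"ligand": "x",
                                                "residues": {1}})()] * 2)

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError, match="two"):
            partition_contacts({"only": {1}})

    @given(st.lists(st.sets(st.integers(0, 15)), min_size=2, max_size=3))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_partition_is_disjoint_and_covering(self, raw_sets):
        sets = {f"lig{i}": s for i, s in enumerate(raw_sets)}
        part = partition_contacts(sets)
        union = set().union(*sets.values())
        blocks = [part.common_all, *part.pairwise.values(),
                  *part.unique.values()]
        # disjoint
        seen = set()
        for block in blocks:
            assert not (seen & block)
            seen |= block
        # covering
        assert seen == union
        # per-ligand reconstruction
        for name, residues in sets.items():
            rebuilt = set(part.common_all & residues) | set(part.unique[name])
            for pair, members in part.pairwise.items():
                if name in pair:
                    rebuilt |= members & residues
            assert rebuilt == residues
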