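"""Contact classification, cluster populations, bound states,
representative snapshots — all checked against brute-force recomputation
on constructed scenes."""

import numpy as np
import pytest

from ionloop.binding import (BoundContactRecord, bound_ion_count,
                             bound_state_partition, cluster_populations,
                             contact_cluster_label, contact_records,
                             interacting_residues, kabsch_rotation,
                             representative_snapshot)
from ionloop.errors import AnalysisError
from ionloop.structio import (SelectionGroup, Trajectory,
                              resolve_selection)
from ionloop.synthgen import (assemble_system, ion_topology,
                              sample_ion_trajectory)


def rec(frame, ion, residues=(), cluster=(0, 0)):
    return BoundContactRecord(frame=frame, ion=ion,
                              residues=tuple(residues), cluster=cluster)


@pytest.fixture(scope="module")
def scene(pentamer):
    """Scaffold + 3 ions at hand-placed positions: ion 0 near chain A's
    E316 carboxylate, ion 1 near chain B's E320, ion 2 far in the bulk."""
    top, straj = pentamer
    frame = straj.coords[0]

    def cd_of(role, chain):
        idx = [i for i in top.roles[role]
               if str(top.chainids[i]) == chain
               and str(top.names[i]) == "CD"]
        return frame[idx[0]]

    p0 = cd_of("E316", "A") + np.array([0.0, -0.25, 0.0])
    p1 = cd_of("E320", "B") + np.array([0.0, 0.1, -0.2])
    p2 = np.array([10.0, 10.0, 10.0])
    ion_top = ion_topology(3)
    ion_traj = Trajectory(coords=np.stack([p0, p1, p2])[None],
                          temperature=315.0)
    sys_top, sys_traj = assemble_system(top, frame, ion_top, ion_traj)
    return sys_top, sys_traj


def chain_groups(top, resid):
    out = []
    for c in "ABCDE":
        out.append(resolve_selection(top, f"chain:{c} and resid:{resid}"))
    return out


class TestInteractingResidues:
    def test_constructed_contacts(self, scene):
        top, traj = scene
        protein = resolve_selection(top, "not role:ion_center")
        ion0 = int(top.roles["ion_center"][0])
        res = interacting_residues(top, traj.coords[0], ion0, protein)
        assert ("A", "GLU", 316) in res
        ion2 = int(top.roles["ion_center"][2])
        assert interacting_residues(top, traj.coords[0], ion2,
                                    protein) == []

    def test_cutoff_is_strict(self):
        top = ion_topology(2, element="MG")
        top.elements = np.array(["C", "MG"], dtype=object)
        frame = np.array([[0.0, 0, 0], [0.5, 0, 0]])
        protein = SelectionGroup("p", np.array([0]))
        assert interacting_residues(top, frame, 1, protein,
                                    cutoff=0.5) == []
        assert len(interacting_residues(top, frame, 1, protein,
                                        cutoff=0.5 + 1e-9)) == 1

    def test_matches_brute_force_on_sampled_system(self, pentamer):
        top, straj = pentamer
        field_frame = straj.coords[0]
        from ionloop.synthgen import field_from_scaffold
        field = field_from_scaffold(top, field_frame)
        itraj = sample_ion_trajectory(field, n_ions=4, n_frames=5,
                                      temperature=315.0, seed=17)
        sys_top, sys_traj = assemble_system(top, field_frame,
                                            ion_topology(4), itraj)
        protein = resolve_selection(sys_top, "not role:ion_center")
        heavy = sys_top.heavy_mask
        for f in range(5):
            frame = sys_traj.coords[f]
            for ion in sys_top.roles["ion_center"]:
                got = interacting_residues(sys_top, frame, int(ion),
                                           protein)
                # brute force with plain loops
                expect = set()
                for j in protein.indices:
                    if not heavy[j]:
                        continue
                    if np.linalg.norm(frame[int(ion)] - frame[j]) < 0.5:
                        expect.add((str(sys_top.chainids[j]),
                                    str(sys_top.resnames[j]),
                                    int(sys_top.resids[j])))
                assert set(got) == expect


class TestClusterLabels:
    def test_constructed_labels(self, scene):
        top, traj = scene
        e316 = chain_groups(top, 316)
        e320 = chain_groups(top, 320)
        ions = top.roles["ion_center"]
        lab0 = contact_cluster_label(top, traj.coords[0], int(ions[0]),
                                     e316, e320)
        assert lab0[0] >= 1  # ion 0 touches at least chain A's E316
        lab1 = contact_cluster_label(top, traj.coords[0], int(ions[1]),
                                     e316, e320)
        assert lab1 == (0, 1)
        lab2 = contact_cluster_label(top, traj.coords[0], int(ions[2]),
                                     e316, e320)
        assert lab2 == (0, 0)

    def mini_topology(self):
        """Two E316-like carboxylate carbons (chains A, B), one E320
        (chain A), one ion — distances chosen by hand."""
        from ionloop.structio import Topology
        top = Topology(
            names=np.array(["CD", "CD", "CD", "MG"], dtype=object),
            elements=np.array(["C", "C", "C", "MG"], dtype=object),
            masses=np.array([12.011, 12.011, 12.011, 24.305]),
            resids=np.array([316, 316, 320, 1]),
            resnames=np.array(["GLU", "GLU", "GLU", "MG"], dtype=object),
            chainids=np.array(["A", "B", "A", "I"], dtype=object))
        frame = np.array([[0.0, 0.0, 0.0], [0.6, 0.0, 0.0],
                          [0.3, 0.4, 0.0], [0.0, 0.0, 0.0]])
        e316 = [SelectionGroup("A316", np.array([0])),
                SelectionGroup("B316", np.array([1]))]
        e320 = [SelectionGroup("A320", np.array([2]))]
        return top, frame, e316, e320

    def test_one_one_label_by_brute_force(self):
        top, frame, e316, e320 = self.mini_topology()
        frame[3] = [0.0, 0.3, 0.0]  # 0.30 to A316, 0.67 to B316,
        #                             0.316 to A320
        assert contact_cluster_label(top, frame, 3, e316, e320) == (1, 1)

    def test_two_one_label_by_brute_force(self):
        top, frame, e316, e320 = self.mini_topology()
        frame[3] = [0.3, 0.0, 0.0]  # 0.30 to both E316, 0.40 to A320
        assert contact_cluster_label(top, frame, 3, e316, e320) == (2, 1)

    def test_populations_hand_count(self):
        records = [rec(0, 0, cluster=(0, 1)), rec(0, 1, cluster=(0, 1)),
                   rec(1, 0, cluster=(1, 1)), rec(1, 1, cluster=(0, 0))]
        pops = cluster_populations(records)
        assert pops["0-1"] == pytest.approx(200 / 3)
        assert pops["1-1"] == pytest.approx(100 / 3)
        assert "0-0" not in pops
        assert sum(pops.values()) == pytest.approx(100.0, abs=0.1)

    def test_single_label_is_100(self):
        pops = cluster_populations([rec(0, 0, cluster=(1, 0))] * 4)
        assert pops == {"1-0": 100.0}

    def test_empty_denominator_rejected(self):
        with pytest.raises(AnalysisError):
            cluster_populations([rec(0, 0, cluster=(0, 0))])


class TestBoundCounts:
    def test_constructed_frame_counts(self):
        residues = (("A", "GLU", 316),)
        records = [rec(0, i, residues=residues) for i in range(3)] + \
                  [rec(0, i) for i in range(3, 10)]
        counts, mean, sd = bound_ion_count(records)
        assert counts.tolist() == [3]
        assert mean == 3.0

    def test_monotone_in_cutoff(self, scene):
        top, traj = scene
        protein = resolve_selection(top, "not role:ion_center")
        ions = top.roles["ion_center"]
        previous = -1
        for cutoff in [0.2, 0.4, 0.6, 1.0, 5.0]:
            n = sum(
                len(interacting_residues(top, traj.coords[0], int(i),
                                         protein, cutoff)) > 0
                for i in ions)
            assert n >= previous
            previous = n

    def test_partition_alternating_two_three(self):
        residues = (("A", "GLU", 316),)
        records = []
        for f in range(10):
            k = 2 if f % 2 == 0 else 3
            for i in range(k):
                records.append(rec(f, i, residues=residues,
                                   cluster=(1, 0)))
            for i in range(k, 5):
                records.append(rec(f, i))
        part = bound_state_partition(records)
        assert part.populations == {2: pytest.approx(0.5),
                                    3: pytest.approx(0.5)}
        assert part.mean == pytest.approx(2.5)

    def test_empty_bound_frames_reported_as_state_zero(self):
        records = [rec(0, 0), rec(0, 1),
                   rec(1, 0, (("A", "GLU", 316),), cluster=(1, 0)),
                   rec(1, 1)]
        part = bound_state_partition(records)
        assert 0 in part.populations
        assert part.populations[0] == pytest.approx(0.5)

    def test_signature_format(self):
        records = [rec(0, 0, (("A", "GLU", 316), ("C", "GLU", 320)),
                       (1, 1)),
                   rec(0, 1, (("B", "GLU", 320),), (0, 1))]
        part = bound_state_partition(records)
        assert part.signatures[2] == "GLU(A)/GLU(C), GLU(B)"


class TestRepresentativeSnapshot:
    def make_traj(self, ion_positions, n_protein=4, seed=0):
        rng = np.random.default_rng(seed)
        protein = rng.normal(size=(n_protein, 3))
        frames = [np.vstack([protein, np.atleast_2d(p)])
                  for p in ion_positions]
        return Trajectory(coords=np.stack(frames), temperature=315.0)

    def groups(self, n_protein=4):
        return (SelectionGroup("prot", np.arange(n_protein)),
                SelectionGroup("ion", np.array([n_protein])))

    def test_single_frame_returns_itself(self):
        traj = self.make_traj([[1.0, 0, 0]])
        prot, ion = self.groups()
        assert representative_snapshot(traj, prot, ion) == 0

    def test_coincident_pair_beats_outlier(self):
        traj = self.make_traj([[1.0, 0, 0], [1.0, 0, 0], [5.0, 5, 5]])
        prot, ion = self.groups()
        assert representative_snapshot(traj, prot, ion) in (0, 1)

    def test_rigid_rotations_collapse_to_one_cluster(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(5, 3))
        frames = [base]
        for _ in range(4):
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            if np.linalg.det(q) < 0:
                q[:, 0] = -q[:, 0]
            frames.append(base @ q.T + rng.normal(size=3))
        traj = Trajectory(coords=np.stack(frames), temperature=315.0)
        prot = SelectionGroup("prot", np.arange(4))
        ion = SelectionGroup("ion", np.array([4]))
        # all frames are rigid copies: RMSD ~ 0 after superposition, so
        # even a tiny linkage cutoff keeps them in a single cluster and
        # any frame is a valid medoid
        rep = representative_snapshot(traj, prot, ion, rmsd_cutoff=1e-6)
        assert rep in range(5)
        from ionloop.binding import _superpose
        ion_pos = np.stack([_superpose(f, frames[0], np.arange(4))[4]
                            for f in frames])
        assert np.linalg.norm(ion_pos - ion_pos[0], axis=1).max() < 1e-9

    def test_matches_brute_force_medoid(self):
        rng = np.random.default_rng(9)
        ions = np.vstack([rng.normal(0, 0.02, size=(6, 3)),
                          rng.normal(3, 0.02, size=(3, 3))])
        traj = self.make_traj(ions, seed=1)
        prot, ion = self.groups()
        got = representative_snapshot(traj, prot, ion, rmsd_cutoff=0.5)
        # brute force: largest cluster is the 6-frame blob; medoid is
        # the frame minimizing summed distance to the others
        pos = traj.coords[:6, 4]
        summed = [np.linalg.norm(pos - p, axis=1).sum() for p in pos]
        assert got == int(np.argmin(summed))

    def test_kabsch_is_proper_rotation(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            P, Q = rng.normal(size=(2, 7, 3))
            P -= P.mean(0)
            Q -= Q.mean(0)
            R = kabsch_rotation(P, Q)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
            assert np.allclose(R @ R.T, np.eye(3), atol=1e-9)


class TestOracleEquivalence:
    def test_records_match_brute_force(self, scene):
        """Full pipeline records equal naive recomputation."""
        top, traj = scene
        protein = resolve_selection(top, "not role:ion_center")
        e316, e320 = chain_groups(top, 316), chain_groups(top, 320)
        records = contact_records(top, traj, top.roles["ion_center"],
                                  protein, e316, e320)
        heavy = top.heavy_mask
        for r in records:
            frame = traj.coords[r.frame]
            x, y = 0, 0
            for g, counter in ((e316, "x"), (e320, "y")):
                for grp_ in g:
                    idx = [i for i in grp_.indices if heavy[i]]
                    dmin = min(np.linalg.norm(frame[r.ion] - frame[i])
                               for i in idx)
                    if dmin < 0.5:
                        if counter == "x":
                            x += 1
                        else:
                            y += 1
            assert r.cluster == (x, y)
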