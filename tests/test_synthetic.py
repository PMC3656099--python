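"""Generator correctness: duplex geometry, schedules, noise, markers."""

import math

import numpy as np
import pytest

from strandmig import synthetic as syn
from strandmig.hbond import hbp_matrix
from strandmig.metrics import (contact_distance_series, exclusions_from_bonds,
                               steric_clash_count)
from strandmig.registry import AT, P1, UNPAIRED


def _hbond_geometry(coords, triple):
    d, h, a = (coords[k] for k in triple)
    v1, v2 = d - h, a - h
    dist = float(np.linalg.norm(v2))
    ang = math.degrees(math.acos(
        np.clip(np.dot(v1, v2) / (np.linalg.norm(v1) * dist), -1, 1)))
    return dist, ang


class TestAformDuplex:
    def test_residue_count(self, duplex):
        assert duplex.n_residues == 22

    def test_c1_step_distances_constant(self, duplex):
        for strand in (duplex.strand1, duplex.strand2):
            c1 = [duplex.coords[(r, "C1'")] for r in strand]
            d = [np.linalg.norm(b - a) for a, b in zip(c1, c1[1:])]
            assert max(d) - min(d) < 1e-6

    def test_all_scheduled_bonds_satisfy_binary_criterion(self, duplex):
        for triple in duplex.hbonds():
            dist, ang = _hbond_geometry(duplex.coords, triple)
            assert dist < 3.5 and ang > 145.0

    def test_ideal_duplex_clash_free(self, duplex):
        excl = exclusions_from_bonds(duplex.covalent_bonds())
        assert steric_clash_count(duplex.coords, 2.0, excl) == 0

    def test_backbone_chain_closes(self, duplex):
        for strand in (duplex.strand1, duplex.strand2):
            for r1, r2 in zip(strand, strand[1:]):
                gap = np.linalg.norm(duplex.coords[(r1, "O3'")]
                                     - duplex.coords[(r2, "P")])
                assert gap < 1.8

    def test_bad_sequences_rejected(self):
        with pytest.raises(ValueError):
            syn.build_aform_duplex("")
        with pytest.raises(ValueError):
            syn.build_aform_duplex("AUGX")
        with pytest.raises(ValueError):
            syn.build_aform_duplex("AUG", complement="GGG")

    def test_explicit_complement_accepted(self):
        d = syn.build_aform_duplex("AUG", complement="CAU")
        assert d.n_residues == 6


class TestMigrationSchedule:
    def test_states_before_and_after_event(self):
        sched = syn.script_migration_event(1000, 400)
        m0 = sched.map_at(0).as_dict()
        assert m0 == {108: AT, 109: AT, 110: UNPAIRED, 111: AT}
        assert sched.map_at(399).as_dict() == m0
        assert all(v == P1 for v in sched.map_at(400).as_dict().values())
        assert all(v == P1 for v in sched.map_at(999).as_dict().values())

    def test_event_frame_bounds(self):
        with pytest.raises(ValueError):
            syn.script_migration_event(100, 100)
        with pytest.raises(ValueError):
            syn.script_migration_event(100, -1)

    def test_fray_window_validation(self):
        with pytest.raises(ValueError):  # before the event
            syn.script_migration_event(100, 50, [(6, 40, 60)])
        with pytest.raises(ValueError):  # past the end
            syn.script_migration_event(100, 50, [(6, 60, 120)])
        with pytest.raises(ValueError):  # not a competing position
            syn.script_migration_event(100, 50, [(1, 60, 80)])

    def test_fray_occupancy_arithmetic(self):
        sched = syn.script_migration_event(1000, 400, [(6, 500, 600)])
        formed = sched.states[:, 0] == 1  # ordinal 6 <-> switching 108
        window = formed[400:1000]
        assert window.sum() == 500 and len(window) == 600

    def test_no_event_schedule(self):
        sched = syn.script_migration_event(50, None)
        assert not sched.full_p1_frames().any()


class TestSwitchTrajectory:
    def test_same_seed_bit_identical(self, registry, mig_schedule):
        t1, _ = syn.generate_switch_trajectory(registry, mig_schedule, 0.2, 42)
        t2, _ = syn.generate_switch_trajectory(registry, mig_schedule, 0.2, 42)
        assert np.array_equal(t1.xyz, t2.xyz)
        t3, _ = syn.generate_switch_trajectory(registry, mig_schedule, 0.2, 43)
        assert not np.array_equal(t1.xyz, t3.xyz)

    def test_frame_count_matches_schedule(self, noiseless, mig_schedule):
        traj, _ = noiseless
        assert traj.n_frames == mig_schedule.n_frames

    def test_noiseless_scheduled_bonds_all_binary_true(self, registry, noiseless):
        traj, sched = noiseless
        for helix in (P1, AT):
            got = hbp_matrix(traj, registry, helix=helix, binary=True)
            want = sched.bond_fraction(registry, helix)
            assert np.array_equal(got.mean(axis=1).to_numpy(), want)

    def test_unscheduled_bonds_all_broken(self, registry, noiseless):
        """A position paired in one helix must not satisfy the other helix's
        bonds, and an unpaired position satisfies neither."""
        traj, sched = noiseless
        for helix in (P1, AT):
            binary = hbp_matrix(traj, registry, helix=helix, binary=True)
            for pos in registry.positions(helix):
                formed = sched.position_formed(registry, helix, pos.ordinal)
                cols = [b.bond_id for b in registry.bonds(helix, pos.ordinal)]
                sub = binary[cols].to_numpy().all(axis=1)
                assert np.array_equal(sub, formed)

    def test_negative_sigma_rejected(self, registry, mig_schedule):
        with pytest.raises(ValueError):
            syn.generate_switch_trajectory(registry, mig_schedule, -0.1, 0)

    def test_atom_noise_mode(self, registry, mig_schedule):
        t1, _ = syn.generate_switch_trajectory(registry, mig_schedule, 0.05, 7,
                                               noise_mode="atom")
        t0, _ = syn.generate_switch_trajectory(registry, mig_schedule, 0.0, 7)
        dev = np.abs(t1.xyz - t0.xyz)
        assert 0 < dev.mean() < 0.2


class TestSiteMarkers:
    def test_scripted_drift_reproduced_exactly(self, registry):
        sched = syn.default_schedule(100, 40, sam_present=False)
        key = (9, "O6")
        traj, _ = syn.generate_switch_trajectory(registry, sched, 0.0, 0)
        cs = contact_distance_series(traj, syn.MG_KEY, key)
        assert np.allclose(cs.distances, sched.marker_scripts[(syn.MG_KEY, key)],
                           atol=1e-9)
        assert cs.distances[0] == pytest.approx(2.2)
        assert cs.distances[-1] == pytest.approx(6.0)

    def test_constant_script_constant_series(self):
        sched = syn.default_schedule(50, 10)
        markers = syn.place_site_markers(sched)
        i = markers.atoms.index((81, "P"))
        mg = markers.atoms.index(syn.MG_KEY)
        d = np.linalg.norm(markers.xyz[:, i] - markers.xyz[:, mg], axis=1)
        assert np.allclose(d, 2.1)

    def test_no_ligand_mode_omits_sulfur(self, registry):
        sched = syn.default_schedule(20, 5, sam_present=False)
        traj, _ = syn.generate_switch_trajectory(registry, sched, 0.0, 0)
        assert not traj.has_atom(syn.SD_KEY)
        assert traj.has_atom(syn.MG_KEY)
        assert not traj.ligand_present

    def test_triangle_violation_rejected(self):
        sched = syn.default_schedule(10, 2)
        d_ms = sched.marker_scripts[(syn.MG_KEY, syn.SD_KEY)][0]
        # anchor demanded 1 A from both centers that sit d_ms >> 2 apart
        sched.marker_scripts[(syn.SD_KEY, (9, "O6"))] = np.full(10, 1.0)
        sched.marker_scripts[(syn.MG_KEY, (9, "O6"))] = np.full(10, 1.0)
        assert d_ms > 2.0
        with pytest.raises(syn.MarkerScriptError, match="triangle"):
            syn.place_site_markers(sched)

    def test_two_center_script_solved_when_feasible(self):
        sched = syn.default_schedule(10, 2)
        d_ms = float(sched.marker_scripts[(syn.MG_KEY, syn.SD_KEY)][0])
        sched.marker_scripts[(syn.MG_KEY, (9, "O6"))] = np.full(10, 0.6 * d_ms)
        sched.marker_scripts[(syn.SD_KEY, (9, "O6"))] = np.full(10, 0.6 * d_ms)
        markers = syn.place_site_markers(sched)
        i = markers.atoms.index((9, "O6"))
        mg = markers.atoms.index(syn.MG_KEY)
        sd = markers.atoms.index(syn.SD_KEY)
        d1 = np.linalg.norm(markers.xyz[:, i] - markers.xyz[:, mg], axis=1)
        d2 = np.linalg.norm(markers.xyz[:, i] - markers.xyz[:, sd], axis=1)
        assert np.allclose(d1, 0.6 * d_ms) and np.allclose(d2, 0.6 * d_ms)

    def test_nonpositive_script_rejected(self):
        with pytest.raises(syn.MarkerScriptError):
            syn.PairingSchedule(np.ones((5, 4), dtype=np.int8),
                                marker_scripts={(syn.MG_KEY, (9, "O6")):
                                                np.zeros(5)})

    def test_schedule_csv_round_trip_files(self, tmp_path):
        sched = syn.default_schedule(10, 2)
        sched.to_csv(tmp_path / "schedule.csv")
        sched.markers_to_csv(tmp_path / "markers.csv")
        assert (tmp_path / "schedule.csv").read_text().startswith(
            "frame,position,state")
        assert "distance" in (tmp_path / "markers.csv").read_text().splitlines()[0]
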