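"""Superposition, dihedrals, energies, contacts, clashes — with independent
oracles (brute-force rotational search, MDAnalysis, closed forms)."""

import itertools
import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from strandmig import synthetic as syn
from strandmig.metrics import (DEFAULT_LJ, LJParams, backbone_rmsd,
                               base_pair_rmsd, contact_distance_series,
                               exclusions_from_bonds, ideal_pair_reference,
                               lj_pair_energy, pseudo_dihedral,
                               pseudo_dihedral_histogram,
                               screened_coulomb_energy, steric_clash_count,
                               superpose, COULOMB_KCAL)
from strandmig.registry import P1


def brute_force_min_rmsd(X, Y):
    """Quaternion-grid search plus local refinement, independent of Kabsch."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)

    def rmsd_of(R):
        return math.sqrt((((Xc @ R.T) - Yc) ** 2).sum() / len(X))

    best_val, best_q = np.inf, None
    for q in itertools.product(np.linspace(-1, 1, 7), repeat=4):
        q = np.asarray(q)
        n = np.linalg.norm(q)
        if n < 1e-9:
            continue
        val = rmsd_of(Rotation.from_quat(q / n).as_matrix())
        if val < best_val:
            best_val, best_q = val, q / n
    rv0 = Rotation.from_quat(best_q).as_rotvec()
    res = minimize(lambda v: rmsd_of(Rotation.from_rotvec(v).as_matrix()), rv0,
                   method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
    return min(best_val, res.fun)


class TestSuperpose:
    def test_identical_sets_zero(self, rng):
        X = rng.normal(size=(6, 3))
        assert superpose(X, X)[2] == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_zero(self, rng):
        X = rng.normal(size=(5, 3))
        R = Rotation.random(random_state=5).as_matrix()
        Y = X @ R.T + np.array([3.0, -1.0, 2.0])
        assert superpose(X, Y)[2] == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(5, 3))
        Y = rng.normal(size=(5, 3))
        _, _, rmsd = superpose(X, Y)
        assert abs(rmsd - brute_force_min_rmsd(X, Y)) < 1e-3

    def test_size_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            superpose(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))
        with pytest.raises(ValueError):
            superpose(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))

    def test_proper_rotation(self, rng):
        X = rng.normal(size=(5, 3))
        Y = rng.normal(size=(5, 3))
        R, _, _ = superpose(X, Y)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)


class TestBasePairRMSD:
    def test_ideal_pair_vs_own_template_zero(self, registry, noiseless):
        traj, _ = noiseless
        pos = registry.position(P1, 1)
        ref = ideal_pair_reference(registry, pos)
        assert base_pair_rmsd(traj.frame(100), pos, ref) == pytest.approx(
            0.0, abs=1e-9)

    def test_out_of_plane_base_exceeds_3A(self, registry, noiseless):
        """A competing pair whose base is flipped 90 degrees out of plane
        (the unformed state) scores far from the template."""
        traj, _ = noiseless
        pos = registry.position(P1, 4)  # boundary pair, unpaired at frame 0
        ref = ideal_pair_reference(registry, pos)
        assert base_pair_rmsd(traj.frame(0), pos, ref) > 3.0

    def test_invariant_under_global_rigid_motion(self, registry, noiseless):
        traj, _ = noiseless
        pos = registry.position(P1, 2)
        ref = ideal_pair_reference(registry, pos)
        v0 = base_pair_rmsd(traj.frame(0), pos, ref)
        R = Rotation.random(random_state=11).as_matrix()
        moved = {k: R @ v + np.array([5.0, 6.0, 7.0])
                 for k, v in traj.frame(0).coords.items()}
        v1 = base_pair_rmsd(moved, pos, ref)
        assert v1 == pytest.approx(v0, abs=1e-9)

    def test_missing_atoms_rejected(self, registry):
        pos = registry.position(P1, 1)
        ref = ideal_pair_reference(registry, pos)
        with pytest.raises(KeyError):
            base_pair_rmsd({}, pos, ref)


class TestBackboneRMSD:
    def test_self_zero(self, registry, noiseless):
        traj, _ = noiseless
        ref = traj.frame(0).coords
        assert backbone_rmsd(traj.frame(0), range(101, 114), ref) == pytest.approx(
            0.0, abs=1e-12)

    def test_noise_matches_closed_form_expectation(self, rng):
        """Monte-Carlo mean RMSD of per-atom Gaussian noise approaches
        sigma * sqrt((3N - 6) / N) after removing the 6 fitted dof."""
        sigma, n_res = 0.1, 6
        keys = [(r, a) for r in range(1, n_res + 1)
                for a in ("P", "O5'", "C5'", "C4'", "C3'", "O3'")]
        base = {k: rng.normal(scale=4.0, size=3) for k in keys}
        n_atoms = len(keys)
        vals = []
        for _ in range(300):
            noisy = {k: v + rng.normal(scale=sigma, size=3)
                     for k, v in base.items()}
            vals.append(backbone_rmsd(noisy, range(1, n_res + 1), base))
        expected = sigma * math.sqrt((3 * n_atoms - 6) / n_atoms)
        assert np.mean(vals) == pytest.approx(expected, rel=0.05)

    def test_missing_phosphate_excluded(self, rng):
        keys = [(1, a) for a in ("O5'", "C5'", "C4'", "C3'", "O3'")]  # no 5' P
        ref = {k: rng.normal(size=3) for k in keys}
        assert backbone_rmsd(dict(ref), [1], ref) == pytest.approx(0.0, abs=1e-12)

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError):
            backbone_rmsd({(1, "P"): np.zeros(3)}, [1], {(1, "P"): np.zeros(3)})


class TestPseudoDihedral:
    def test_cis_zero(self):
        assert pseudo_dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_trans_180(self):
        assert pseudo_dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0)) == \
            pytest.approx(180.0)

    def test_right_handed_quarter_turn(self):
        assert pseudo_dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)) == \
            pytest.approx(90.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_mdanalysis(self, seed):
        from MDAnalysis.lib.distances import calc_dihedrals
        q = np.random.default_rng(seed).normal(size=(4, 3))
        ref = math.degrees(float(calc_dihedrals(
            q[0][None], q[1][None], q[2][None], q[3][None])[0]))
        assert pseudo_dihedral(*q) == pytest.approx(ref, abs=1e-3)  # f32 oracle

    def test_reversal_invariant(self, rng):
        q = rng.normal(size=(4, 3))
        assert pseudo_dihedral(*q[::-1]) == pytest.approx(pseudo_dihedral(*q))

    def test_collinear_rejected(self):
        with pytest.raises(ValueError):
            pseudo_dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


class TestDihedralHistogram:
    def test_identical_angles_single_bin(self):
        counts, _ = pseudo_dihedral_histogram([42.0] * 100, 10.0)
        assert counts.max() == 100 and counts.sum() == 100

    def test_counts_conserved(self, rng):
        samples = rng.uniform(-180, 180, 5000)
        counts, _ = pseudo_dihedral_histogram(samples, 10.0)
        assert counts.sum() == 5000

    def test_uniform_samples_flat(self, rng):
        samples = rng.uniform(-180, 180, 100_000)
        counts, _ = pseudo_dihedral_histogram(samples, 10.0)
        assert counts.max() / counts.min() < 2.0

    def test_unsigned_domain(self):
        counts, edges = pseudo_dihedral_histogram([-170.0], 10.0, "unsigned")
        assert edges[0] == 0.0 and edges[-1] == 360.0
        assert counts[19] == 1  # -170 -> 190


class TestLennardJones:
    def test_symmetry(self, rng):
        a = {"C1'": rng.normal(size=3), "N9": rng.normal(size=3)}
        b = {"O2": rng.normal(size=3) + 4.0, "P": rng.normal(size=3) + 4.0}
        assert lj_pair_energy(a, b) == pytest.approx(lj_pair_energy(b, a))

    def test_analytic_minimum(self):
        sigma, eps = DEFAULT_LJ.table["C"]
        r = 2 ** (1 / 6) * sigma
        e = lj_pair_energy({"C1": np.zeros(3)}, {"C2": np.array([r, 0, 0])})
        assert e == pytest.approx(-eps, rel=1e-12)

    def test_beyond_cutoff_zero(self):
        e = lj_pair_energy({"C1": np.zeros(3)},
                           {"C2": np.array([DEFAULT_LJ.cutoff + 1, 0, 0])})
        assert e == 0.0

    def test_additivity(self, rng):
        a = {"C1": rng.normal(size=3)}
        b1 = {"N1": rng.normal(size=3) + 4}
        b2 = {"O1": rng.normal(size=3) + 5}
        assert lj_pair_energy(a, {**b1, **b2}) == pytest.approx(
            lj_pair_energy(a, b1) + lj_pair_energy(a, b2))

    def test_hydrogens_ignored(self):
        e = lj_pair_energy({"H61": np.zeros(3)}, {"C1": np.array([3.0, 0, 0])})
        assert e == 0.0

    def test_unknown_element_rejected(self):
        with pytest.raises(KeyError):
            lj_pair_energy({"XE1": np.zeros(3)}, {"C1": np.array([3.0, 0, 0])})


class TestScreenedCoulomb:
    def test_kappa_zero_is_unscreened(self):
        charges = [(np.zeros(3), 1.0), (np.array([5.0, 0, 0]), 1.0)]
        assert screened_coulomb_energy(charges, kappa=0.0) == pytest.approx(
            COULOMB_KCAL / 5.0)

    def test_single_pair_closed_form(self):
        """Two unit charges at 10 A under the default screening constant."""
        charges = [(np.zeros(3), 1.0), (np.array([10.0, 0, 0]), 1.0)]
        e = screened_coulomb_energy(charges, kappa=0.19)
        assert e == pytest.approx(COULOMB_KCAL * math.exp(-1.9) / 10.0, rel=1e-12)
        assert e == pytest.approx(4.96663, abs=1e-4)

    def test_magnitude_decreases_with_kappa(self):
        charges = [(np.zeros(3), 1.0), (np.array([6.0, 0, 0]), 1.0)]
        kappas = [0.0, 0.1, 0.19, 0.5]
        es = [screened_coulomb_energy(charges, kappa=k) for k in kappas]
        assert all(a > b > 0 for a, b in zip(es, es[1:]))

    def test_additive_over_disjoint_subsets(self, rng):
        pts = [(rng.normal(size=3) * 4, q) for q in (-1.0, -1.0, 1.0)]
        full = screened_coulomb_energy(pts)
        parts = sum(screened_coulomb_energy([pts[i], pts[j]])
                    for i, j in itertools.combinations(range(3), 2))
        assert full == pytest.approx(parts)


class TestContacts:
    def test_atom_vs_itself_zero(self, noiseless):
        traj, _ = noiseless
        cs = contact_distance_series(traj, syn.MG_KEY, syn.MG_KEY)
        assert np.all(cs.distances == 0.0)

    def test_missing_atom_reports(self, noiseless):
        traj, _ = noiseless
        with pytest.raises(KeyError, match="frames"):
            contact_distance_series(traj, (999, "ZZ"), syn.MG_KEY)

    def test_step_script_fraction_below(self, registry):
        """A scripted step drift crosses the contact cutoff at a known frame."""
        sched = syn.default_schedule(100, 40, sam_present=False)
        traj, _ = syn.generate_switch_trajectory(registry, sched, 0.0, 0)
        cs = contact_distance_series(traj, syn.MG_KEY, (8, "P"))
        # linear 2.1 -> 6.0 over 100 frames; below 4.05 for the first half
        assert cs.fraction_below(4.05) == pytest.approx(0.5, abs=0.02)
        assert cs.mean == pytest.approx((2.1 + 6.0) / 2, abs=0.05)


class TestClashCount:
    def test_two_close_atoms(self):
        coords = {(1, "C1"): np.zeros(3), (2, "C1"): np.array([1.0, 0, 0])}
        assert steric_clash_count(coords, 2.0) == 1

    def test_bonded_neighbors_excluded(self):
        coords = {(1, "C1"): np.zeros(3), (1, "O1"): np.array([1.4, 0, 0])}
        excl = exclusions_from_bonds([((1, "C1"), (1, "O1"))])
        assert steric_clash_count(coords, 2.0, excl) == 0
        assert steric_clash_count(coords, 2.0) == 1

    def test_one_three_excluded(self):
        coords = {(1, "A"): np.zeros(3), (1, "B"): np.array([1.0, 0, 0]),
                  (1, "C"): np.array([1.8, 0, 0])}
        excl = exclusions_from_bonds([((1, "A"), (1, "B")), ((1, "B"), (1, "C"))])
        assert steric_clash_count(coords, 2.0, excl) == 0

    def test_ideal_duplex_clash_free(self, duplex):
        excl = exclusions_from_bonds(duplex.covalent_bonds())
        assert steric_clash_count(duplex.coords, 2.0, excl) == 0
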