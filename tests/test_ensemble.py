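import numpy as np
import pytest
from scipy import constants
from scipy.spatial.transform import Rotation

from tunnelprof import fixtures, structio
from tunnelprof.ensemble import (binding_free_energy, born_radii_hct,
                                 cluster_medoids, gb_polar_energy,
                                 gbsa_binding, gbsa_solvation, kabsch_rmsd,
                                 mm_energy, rotational_entropy, rrho_entropy,
                                 translational_entropy, vibrational_entropy)
from tunnelprof.errors import TunnelprofError


def grid_rmsd_oracle(A, B, coarse=5.0, fine=0.5):
    """Brute-force rotation-grid RMSD: dense Euler scan (vectorized) followed
    by a sub-degree local refinement around the best coarse cell."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)

    def scan(alphas, betas, gammas):
        grid = np.array(np.meshgrid(alphas, betas, gammas,
                                    indexing="ij")).reshape(3, -1).T
        mats = Rotation.from_euler("zyz", grid, degrees=True).as_matrix()
        rotated = np.einsum("nij,kj->nki", mats, B)
        rmsd = np.sqrt(((rotated - A) ** 2).sum(axis=2).mean(axis=1))
        k = int(np.argmin(rmsd))
        return float(rmsd[k]), grid[k]

    _, (a0, b0, g0) = scan(np.arange(0, 360, coarse),
                           np.arange(0, 180 + coarse, coarse),
                           np.arange(0, 360, coarse))
    best, _ = scan(np.arange(a0 - coarse, a0 + coarse + fine / 2, fine),
                   np.arange(b0 - coarse, b0 + coarse + fine / 2, fine),
                   np.arange(g0 - coarse, g0 + coarse + fine / 2, fine))
    return best


class TestKabschRMSD:
    def test_identical_zero(self):
        A = np.random.default_rng(0).normal(size=(6, 3))
        assert kabsch_rmsd(A, A) == pytest.approx(0.0, abs=1e-9)

    def test_translation_invariant(self):
        A = np.random.default_rng(1).normal(size=(5, 3))
        assert kabsch_rmsd(A, A + np.array([3.0, -2.0, 9.0])) == \
            pytest.approx(0.0, abs=1e-9)

    def test_rotation_invariant(self):
        A = np.random.default_rng(2).normal(size=(5, 3))
        R = Rotation.from_rotvec([0.5, 1.0, -0.7]).as_matrix()
        assert kabsch_rmsd(A, A @ R.T) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_rotation_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(5, 3))
        B = A + rng.normal(0, 0.3, size=(5, 3))
        assert kabsch_rmsd(A, B) == pytest.approx(grid_rmsd_oracle(A, B),
                                                  abs=1e-3)

    def test_pseudo_metric(self):
        rng = np.random.default_rng(5)
        X, Y, Z = (rng.normal(size=(5, 3)) for _ in range(3))
        dxy, dyx = kabsch_rmsd(X, Y), kabsch_rmsd(Y, X)
        assert dxy == pytest.approx(dyx, abs=1e-9)
        assert kabsch_rmsd(X, Z) <= dxy + kabsch_rmsd(Y, Z) + 1e-9

    def test_count_mismatch(self):
        with pytest.raises(TunnelprofError):
            kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))


class TestClustering:
    def test_k1_global_minimizer(self, planted_ensemble):
        ens, _ = planted_ensemble
        sub = ens.subset(np.arange(min(30, ens.n_atoms)))
        res = cluster_medoids(sub, k=1, seed=0)
        D = np.array([[kabsch_rmsd(sub.coords[i], sub.coords[j])
                       for j in range(sub.n_snapshots)]
                      for i in range(sub.n_snapshots)])
        assert res.medoid_ids[0] == int(np.argmin(D.sum(axis=1)))

    def test_k_equals_n_singletons(self):
        base, _ = fixtures.make_channel(fixtures.ChannelSpec(
            shape="straight", centerline_length=8.0, base_radius=2.0))
        traj = fixtures.make_trajectory(base, 10, 0.1, seed=5)
        res = cluster_medoids(traj, k=10, seed=0)
        assert sorted(res.sizes()) == [1] * 10
        assert sorted(res.medoid_ids) == list(range(10))

    def test_planted_partition_recovered(self, planted_ensemble):
        ens, labels = planted_ensemble
        res = cluster_medoids(ens, k=2, seed=0)
        got = res.labels
        same = (got == got[0])
        planted = (labels == labels[0])
        assert np.array_equal(same, planted)

    def test_deterministic_for_seed(self, planted_ensemble):
        ens, _ = planted_ensemble
        a = cluster_medoids(ens, k=3, seed=7)
        b = cluster_medoids(ens, k=3, seed=7)
        assert np.array_equal(a.labels, b.labels)
        assert a.medoid_ids == b.medoid_ids

    def test_medoid_in_own_cluster(self, planted_ensemble):
        ens, _ = planted_ensemble
        res = cluster_medoids(ens, k=4, seed=1)
        for c, m in enumerate(res.medoid_ids):
            assert res.labels[m] == c

    def test_k_too_large(self, planted_ensemble):
        ens, _ = planted_ensemble
        with pytest.raises(TunnelprofError):
            cluster_medoids(ens, k=ens.n_snapshots + 1)


class TestMMEnergy:
    def test_vanishes_at_infinite_separation(self):
        e = mm_energy([[0, 0, 0]], ["C"], [[100.0, 0, 0]], ["C"])
        assert abs(e) < 1e-4

    def test_coulomb_closed_form(self):
        with_q = mm_energy([[0, 0, 0]], ["H"], [[3.32, 0, 0]], ["H"],
                           [1.0], [1.0])
        no_q = mm_energy([[0, 0, 0]], ["H"], [[3.32, 0, 0]], ["H"])
        assert with_q - no_q == pytest.approx(332.06 / 3.32, abs=1e-9)

    def test_lj_minimum_depth(self):
        from tunnelprof.ensemble import _LJ

        eps, sig = _LJ["C"]
        r = 2.0 ** (1 / 6) * sig
        e = mm_energy([[0, 0, 0]], ["C"], [[r, 0, 0]], ["C"])
        assert e == pytest.approx(-eps, abs=1e-12)

    def test_rigid_invariance(self):
        rng = np.random.default_rng(8)
        rp = rng.normal(0, 3, (6, 3))
        lp = rng.normal(0, 2, (3, 3)) + 5.0
        q = rng.normal(0, 0.2, 9)
        base = mm_energy(rp, ["C"] * 6, lp, ["O"] * 3, q[:6], q[6:])
        R = Rotation.from_rotvec([0.3, 0.3, 0.9]).as_matrix()
        t = np.array([1.0, 2.0, 3.0])
        moved = mm_energy(rp @ R.T + t, ["C"] * 6, lp @ R.T + t, ["O"] * 3,
                          q[:6], q[6:])
        assert moved == pytest.approx(base, abs=1e-6)


class TestGBSA:
    def test_born_ion_closed_form(self):
        e = gb_polar_energy(np.zeros((1, 3)), np.array([1.0]), np.array([2.0]))
        expected = -0.5 * 332.06 * (1 - 1 / 78.5) / 2.0
        assert e == pytest.approx(expected, abs=1e-6)

    def test_zero_charges_zero_polar(self):
        rng = np.random.default_rng(1)
        pos = rng.normal(0, 3, (5, 3))
        born = born_radii_hct(pos, ["C"] * 5)
        assert gb_polar_energy(pos, np.zeros(5), born) == 0.0

    def test_born_radii_bounded_below_by_intrinsic(self):
        rng = np.random.default_rng(2)
        pos = rng.normal(0, 4, (8, 3))
        born = born_radii_hct(pos, ["C"] * 8)
        assert np.all(born >= 1.70 - 0.09 - 1e-9)

    def test_descreening_grows_radii(self):
        lone = born_radii_hct(np.zeros((1, 3)), ["C"])[0]
        pair = born_radii_hct(np.array([[0, 0, 0], [3.0, 0, 0]]), ["C", "C"])
        assert pair[0] > lone  # a neighbor descreens, enlarging the radius

    def test_nonpolar_binding_negative(self):
        rng = np.random.default_rng(3)
        rec = rng.normal(0, 2.5, (12, 3))
        lig = rec.mean(axis=0) + rng.normal(0, 1.0, (4, 3))
        pos = np.vstack([rec, lig])
        els = ["C"] * 16
        q = np.zeros(16)
        dg = gbsa_binding(pos, els, q, np.arange(12), np.arange(12, 16))
        # zero charges isolate the nonpolar (SASA) part: burying surface
        # on complexation is favorable, minus the double-counted constant b
        assert dg <= -0.92 + 1e-9

    def test_rigid_invariance(self):
        rng = np.random.default_rng(4)
        pos = rng.normal(0, 3, (6, 3))
        q = rng.normal(0, 0.3, 6)
        els = ["C", "O", "N", "C", "C", "O"]
        R = Rotation.from_rotvec([1.1, -0.4, 0.2]).as_matrix()
        # polar (GB) term is analytically rigid-invariant ...
        base = gbsa_solvation(pos, els, q, sasa=False)
        moved = gbsa_solvation(pos @ R.T + 7.0, els, q, sasa=False)
        assert moved == pytest.approx(base, abs=1e-6)
        # ... the point-sampled SASA term only to quadrature accuracy
        full_base = gbsa_solvation(pos, els, q)
        full_moved = gbsa_solvation(pos @ R.T + 7.0, els, q)
        assert full_moved == pytest.approx(full_base, abs=2e-2)


class TestRRHO:
    def test_argon_sackur_tetrode(self):
        s = translational_entropy(39.948, 298.15, standard_state="1bar")
        assert s == pytest.approx(154.846, abs=0.1)

    def test_doubling_temperature(self):
        s1 = translational_entropy(39.948, 298.15)
        s2 = translational_entropy(39.948, 2 * 298.15)
        assert s2 - s1 == pytest.approx(1.5 * constants.R * np.log(2), abs=1e-9)

    def test_monoatomic_no_rotation(self):
        assert rotational_entropy(np.array([39.948]), np.zeros((1, 3))) == 0.0

    def test_linear_rotor_reduced_formula(self):
        pos = np.array([[0, 0, -1.16], [0, 0, 0.0], [0, 0, 1.16]])
        m = np.array([15.999, 12.011, 15.999])
        s = rotational_entropy(m, pos, sigma_sym=2)
        assert np.isfinite(s) and s > 0

    def test_negative_frequency_rejected(self):
        with pytest.raises(TunnelprofError):
            vibrational_entropy(np.array([-10.0]))

    def test_no_frequencies_means_no_vibrational_term(self):
        m = np.array([12.011] * 4)
        pos = np.random.default_rng(0).normal(0, 1, (4, 3))
        tds = rrho_entropy(m, pos)
        s_ext = (translational_entropy(m.sum()) + rotational_entropy(m, pos))
        assert tds == pytest.approx(298.15 * s_ext / 4184.0, abs=1e-9)

    def test_bound_fraction_scales(self):
        m = np.array([12.011] * 3)
        pos = np.array([[0, 0, 0], [1.5, 0, 0], [2.2, 1.2, 0]])
        assert rrho_entropy(m, pos, bound_fraction=0.5) == \
            pytest.approx(0.5 * rrho_entropy(m, pos), abs=1e-12)


def _complex_trajectory(n_snapshots=6, sigma=0.05, seed=3, shift=0.0):
    """Small receptor cage + 2-atom ligand inside, as one jitterable complex."""
    rng = np.random.default_rng(seed)
    rec = np.array([[4.0 * np.cos(a), 4.0 * np.sin(a), z]
                    for z in (-1.5, 1.5)
                    for a in np.linspace(0, 2 * np.pi, 6, endpoint=False)])
    lig = np.array([[0.0, 0, -0.75], [0.0, 0, 0.75]]) + shift
    base_xyz = np.vstack([rec, lig])
    atoms = [structio.Atom(i + 1, "C", "C", "REC", i + 1, "A", base_xyz[i])
             for i in range(12)]
    atoms += [structio.Atom(13 + i, "C", "C", "LIG", 1, "L", base_xyz[12 + i],
                            True) for i in range(2)]
    base = structio.StructureEnsemble(atoms, base_xyz[None])
    return fixtures.make_trajectory(base, n_snapshots, sigma, seed=seed)


class TestBindingFreeEnergy:
    def test_identity_holds_everywhere(self):
        traj = _complex_trajectory()
        q = np.concatenate([np.full(12, 0.05), [-0.3, -0.3]])
        res = binding_free_energy(traj, np.arange(12), np.array([12, 13]),
                                  q, k=3, seed=0)
        for pc in res.per_cluster:
            assert pc["dG_bind"] == pytest.approx(
                pc["dE_MM"] + pc["dG_solv"] - pc["TdS"], abs=1e-6)
        assert res.dG_bind == pytest.approx(res.dE_MM + res.dG_solv - res.TdS,
                                            abs=1e-6)

    def test_identical_snapshots_zero_spread(self):
        traj = _complex_trajectory(sigma=0.0)
        q = np.zeros(14)
        res = binding_free_energy(traj, np.arange(12), np.array([12, 13]),
                                  q, k=2, seed=0)
        vals = [pc["dG_bind"] for pc in res.per_cluster]
        assert np.ptp(vals) == pytest.approx(0.0, abs=1e-9)

    def test_weighted_average_hand_check(self):
        traj = _complex_trajectory()
        q = np.zeros(14)
        res = binding_free_energy(traj, np.arange(12), np.array([12, 13]),
                                  q, k=3, seed=1)
        hand = sum(pc["weight"] * pc["dE_MM"] for pc in res.per_cluster)
        assert res.dE_MM == pytest.approx(hand, abs=1e-9)
        assert sum(pc["weight"] for pc in res.per_cluster) == pytest.approx(1.0)

    def test_clustered_average_between_planted_geometries(self):
        """Two energy-distinct binding geometries: the clustered average lies
        between the per-geometry values."""
        tight = _complex_trajectory(3, 0.02, seed=5, shift=0.0)
        loose = _complex_trajectory(3, 0.02, seed=6, shift=1.2)
        atoms = tight.atoms
        both = structio.StructureEnsemble(
            atoms, np.concatenate([tight.coords, loose.coords]))
        q = np.zeros(14)
        res = binding_free_energy(both, np.arange(12), np.array([12, 13]),
                                  q, k=2, seed=0)
        per = [pc["dE_MM"] for pc in res.per_cluster]
        assert min(per) - 1e-9 <= res.dE_MM <= max(per) + 1e-9

    def test_empty_selection_rejected(self):
        traj = _complex_trajectory(3)
        with pytest.raises(TunnelprofError):
            binding_free_energy(traj, np.array([], int), np.array([12, 13]),
                                np.zeros(14), k=2)

    def test_per_residue_map_sums_to_dE(self):
        traj = _complex_trajectory()
        q = np.concatenate([np.full(12, 0.02), [-0.12, -0.12]])
        res = binding_free_energy(traj, np.arange(12), np.array([12, 13]),
                                  q, k=2, seed=0, per_residue=True)
        assert sum(res.per_residue_dE_MM.values()) == \
            pytest.approx(res.dE_MM, abs=1e-6)
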