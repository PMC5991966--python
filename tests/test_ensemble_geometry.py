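import numpy as np
import pytest

from allostruct import ensemble_geometry as geo
from allostruct import synthetic_data as synth
from allostruct.structures_io import ResidueFrame


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def grid_min_rmsd(P, Q, rng, n_start=400, n_local=200, levels=10):
    """Brute-force rigid-superposition minimizer: random quaternion grid
    followed by multiscale local refinement.  Independent of Kabsch."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def rmsd_for(q):
        w, x, y, z = q
        R = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        d = Pc @ R.T - Qc
        return np.sqrt(np.mean(np.sum(d * d, axis=1)))

    cands = rng.normal(size=(n_start, 4))
    cands /= np.linalg.norm(cands, axis=1, keepdims=True)
    best_q = min(cands, key=rmsd_for)
    best = rmsd_for(best_q)
    sigma = 0.4
    for _ in range(levels):
        local = best_q + rng.normal(scale=sigma, size=(n_local, 4))
        local /= np.linalg.norm(local, axis=1, keepdims=True)
        for q in local:
            r = rmsd_for(q)
            if r < best:
                best, best_q = r, q
        sigma *= 0.5
    return best


class TestKabsch:
    def test_identity_on_equal_inputs(self, rng):
        P = rng.normal(size=(10, 3)) * 5
        fit = geo.kabsch_superpose(P, P)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(fit.rotation, np.eye(3), atol=1e-10)

    def test_recovers_known_rotation(self, rng):
        P = rng.normal(size=(12, 3)) * 5
        R = random_rotation(rng)
        t = rng.normal(size=3) * 10
        Q = P @ R.T + t
        fit = geo.kabsch_superpose(P, Q)
        assert fit.rmsd < 1e-9
        np.testing.assert_allclose(fit.rotation, R, atol=1e-8)
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0)

    def test_never_returns_reflection(self, rng):
        for _ in range(20):
            P = rng.normal(size=(6, 3))
            Q = rng.normal(size=(6, 3))
            fit = geo.kabsch_superpose(P, Q)
            assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_quaternion_grid_minimizer(self, rng):
        for _ in range(15):
            P = rng.normal(size=(10, 3)) * 3
            Q = rng.normal(size=(10, 3)) * 3
            fit = geo.kabsch_superpose(P, Q)
            brute = grid_min_rmsd(P, Q, rng)
            assert fit.rmsd <= brute + 1e-9       # Kabsch is optimal
            assert abs(fit.rmsd - brute) < 1e-3   # grid search gets close

    def test_rmsd_invariant_under_common_rigid_transform(self, rng):
        P = rng.normal(size=(9, 3)) * 4
        Q = rng.normal(size=(9, 3)) * 4
        base = geo.kabsch_superpose(P, Q).rmsd
        R, t = random_rotation(rng), rng.normal(size=3) * 7
        moved = geo.kabsch_superpose(P @ R.T + t, Q @ R.T + t).rmsd
        assert moved == pytest.approx(base, abs=1e-9)

    def test_collinear_subset_rejected(self):
        P = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate"):
            geo.kabsch_superpose(P, P + 1.0)

    def test_too_few_points_rejected(self, rng):
        P = rng.normal(size=(5, 3))
        with pytest.raises(ValueError, match="at least 3"):
            geo.kabsch_superpose(P, P, subset=[0, 1])

    def test_fit_on_subset_reports_subset_rmsd(self, rng):
        P = rng.normal(size=(8, 3)) * 3
        Q = P.copy()
        Q[6:] += 20.0  # outliers excluded from the fit
        fit = geo.kabsch_superpose(P, Q, subset=list(range(6)))
        assert fit.rmsd == pytest.approx(0.0, abs=1e-9)


class TestInvariantCore:
    def test_identical_ensemble_keeps_all_residues(self):
        base = np.array([r.ca.xyz for r in synth.make_chain(20, seed=0).residues]).ravel()
        ens = geo.EnsembleMatrix(
            [f"m{i}" for i in range(5)], ResidueFrame(range(1, 21)),
            np.tile(base, (5, 1)),
        )
        assert geo.find_invariant_core(ens) == list(range(20))

    def test_noisy_tail_is_trimmed(self, rng):
        m, n = 20, 12
        base = np.array([r.ca.xyz for r in synth.make_chain(m, seed=1).residues]).ravel()
        rows = np.tile(base, (n, 1))
        rows[:, 30:] += rng.normal(0, 4.0, size=(n, 3 * m - 30))  # residues 11-20 mobile
        ens = geo.EnsembleMatrix(
            [f"m{i}" for i in range(n)], ResidueFrame(range(1, m + 1)), rows
        )
        core = geo.find_invariant_core(ens, floor=5)
        assert set(core) <= set(range(10))

    def test_floor_equals_m_short_circuits(self, three_cluster):
        ens, _ = three_cluster
        core = geo.find_invariant_core(ens, floor=ens.n_residues)
        assert core == list(range(ens.n_residues))

    def test_planted_core_recovered(self, three_cluster):
        ens, truth = three_cluster
        core = geo.find_invariant_core(ens)
        assert set(core) <= set(truth.core_positions)
        assert len(core) >= 30


class TestSuperposeEnsemble:
    def test_prealigned_unchanged(self):
        base = np.array([r.ca.xyz for r in synth.make_chain(15, seed=2).residues]).ravel()
        ens = geo.EnsembleMatrix(
            ["a", "b", "c"], ResidueFrame(range(1, 16)), np.tile(base, (3, 1))
        )
        aligned = geo.superpose_ensemble(ens, list(range(15)))
        np.testing.assert_allclose(aligned.coords, ens.coords, atol=1e-9)

    def test_rigid_copies_collapse(self, rng):
        base = np.array([r.ca.xyz for r in synth.make_chain(15, seed=3).residues])
        rows = []
        for _ in range(6):
            R, t = random_rotation(rng), rng.normal(size=3) * 30
            rows.append((base @ R.T + t).ravel())
        ens = geo.EnsembleMatrix(
            [f"m{i}" for i in range(6)], ResidueFrame(range(1, 16)), np.vstack(rows)
        )
        aligned = geo.superpose_ensemble(ens, list(range(15)))
        assert geo.pairwise_rmsd(aligned).max() < 1e-6

    def test_core_rmsd_not_increased(self, three_cluster, rng):
        ens, truth = three_cluster
        core = truth.core_positions
        stack = ens.coords.reshape(ens.n_members, ens.n_residues, 3)

        def mean_core_rmsd(stack):
            sub = stack[:, core, :]
            mean = sub.mean(axis=0)
            return np.sqrt(np.mean(np.sum((sub - mean) ** 2, axis=2)))

        before = mean_core_rmsd(stack)
        aligned = geo.superpose_ensemble(ens, core)
        after = mean_core_rmsd(aligned.coords.reshape(ens.n_members, ens.n_residues, 3))
        assert after <= before + 1e-12


class TestRmsf:
    def test_zero_for_rigid_ensemble(self):
        base = np.array([r.ca.xyz for r in synth.make_chain(10, seed=4).residues]).ravel()
        ens = geo.EnsembleMatrix(
            ["a", "b", "c"], ResidueFrame(range(1, 11)), np.tile(base, (3, 1))
        )
        np.testing.assert_allclose(geo.rmsf(ens), 0.0, atol=1e-12)

    def test_isotropic_noise_closed_form(self, rng):
        sigma, n, m = 0.7, 2000, 6
        base = np.array([r.ca.xyz for r in synth.make_chain(m, seed=5).residues]).ravel()
        rows = np.tile(base, (n, 1))
        rows[:, 0:3] += rng.normal(0, sigma, size=(n, 3))  # residue 0 fluctuates
        ens = geo.EnsembleMatrix(
            [f"m{i}" for i in range(n)], ResidueFrame(range(1, m + 1)), rows
        )
        prof = geo.rmsf(ens)
        assert prof[0] == pytest.approx(sigma * np.sqrt(3), rel=0.05)
        np.testing.assert_allclose(prof[1:], 0.0, atol=1e-12)

    def test_doubling_ensemble_preserves_rmsf(self, aligned_three_cluster):
        aligned, _ = aligned_three_cluster
        doubled = geo.EnsembleMatrix(
            aligned.ids + [f"{i}_copy" for i in aligned.ids],
            aligned.frame,
            np.vstack([aligned.coords, aligned.coords]),
        )
        np.testing.assert_allclose(geo.rmsf(doubled), geo.rmsf(aligned), atol=1e-9)


class TestPairwiseRmsd:
    def test_duplicate_members_give_zero(self):
        base = np.array([r.ca.xyz for r in synth.make_chain(8, seed=6).residues]).ravel()
        ens = geo.EnsembleMatrix(["a", "b"], ResidueFrame(range(1, 9)),
                                 np.tile(base, (2, 1)))
        mat = geo.pairwise_rmsd(ens)
        assert mat[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_zero_diagonal(self, aligned_three_cluster):
        aligned, _ = aligned_three_cluster
        mat = geo.pairwise_rmsd(aligned)
        np.testing.assert_allclose(mat, mat.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(mat), 0.0, atol=1e-12)

    def test_matches_per_pair_formula(self, aligned_three_cluster, rng):
        aligned, _ = aligned_three_cluster
        subset = sorted(rng.choice(aligned.n_residues, size=10, replace=False).tolist())
        mat = geo.pairwise_rmsd(aligned, subset)
        stack = aligned.coords.reshape(aligned.n_members, aligned.n_residues, 3)
        for a in range(0, aligned.n_members, 5):
            for b in range(0, aligned.n_members, 7):
                d = stack[a, subset, :] - stack[b, subset, :]
                expected = np.sqrt(np.mean(np.sum(d * d, axis=1)))
                assert mat[a, b] == pytest.approx(expected, abs=1e-12)

    def test_empty_subset_rejected(self, aligned_three_cluster):
        aligned, _ = aligned_three_cluster
        with pytest.raises(ValueError, match="empty"):
            geo.pairwise_rmsd(aligned, [])


class TestHierarchicalCluster:
    def test_k_equals_n_singletons(self, rng):
        X = rng.normal(size=(6, 2))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        model = geo.hierarchical_cluster(D, k=6)
        assert sorted(model.labels) == list(range(6))
        assert sorted(model.clustroid_indices) == list(range(6))

    def test_two_planted_groups_recovered(self, rng):
        X = np.vstack([rng.normal(0, 0.1, size=(5, 2)),
                       rng.normal(50, 0.1, size=(7, 2))])
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        model = geo.hierarchical_cluster(D, k=2)
        assert len(set(model.labels[:5])) == 1
        assert len(set(model.labels[5:])) == 1
        assert model.labels[0] != model.labels[5]

    def test_k1_clustroid_matches_exhaustive_scan(self, rng):
        X = rng.normal(size=(11, 3))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        model = geo.hierarchical_cluster(D, k=1)
        expected = min(range(11), key=lambda i: D[i].sum())
        assert model.clustroid_indices == [expected]

    def test_clustroid_minimizes_within_cluster_distance(self, aligned_three_cluster):
        aligned, _ = aligned_three_cluster
        D = geo.pairwise_rmsd(aligned)
        model = geo.hierarchical_cluster(D, k=3, ids=aligned.ids)
        for c, rep in enumerate(model.clustroid_indices):
            members = [i for i in range(len(model.labels)) if model.labels[i] == c]
            best = min(D[np.ix_(members, members)].sum(axis=1))
            assert D[rep, members].sum() == pytest.approx(best)

    def test_invalid_inputs_rejected(self, rng):
        D = rng.random((4, 4))  # not symmetric
        with pytest.raises(ValueError, match="symmetric"):
            geo.hierarchical_cluster(D, k=2)
        ok = np.zeros((4, 4))
        with pytest.raises(ValueError, match="out of range"):
            geo.hierarchical_cluster(ok, k=5)
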