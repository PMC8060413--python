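"""Superposition RMSD, gromos clustering, and distance-distribution prediction."""

import numpy as np
import pytest

from spintrace import (
    ConformerEnsemble,
    cluster_weighted_average,
    gromos_cluster,
    kabsch_rmsd,
    make_grid,
    make_helix_ensemble,
    read_ensemble_pdb,
    samples_to_distribution,
    site_distance_samples,
    write_ensemble_pdb,
)
from spintrace.structures import pairwise_rmsd, predict_distance_distribution
from spintrace.synthetic import helix_site_distance, make_pr


def quaternion_rmsd(a, b):
    """Independent oracle: Horn's quaternion method for optimal superposition."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    M = a.T @ b
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    N = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam_max = np.linalg.eigvalsh(N)[-1]
    msd = (np.sum(a**2) + np.sum(b**2) - 2 * lam_max) / a.shape[0]
    return float(np.sqrt(max(msd, 0.0)))


def brute_force_gromos(D, cutoff):
    """Oracle: recompute neighbor counts from scratch every round."""
    n = D.shape[0]
    active = set(range(n))
    assignments = np.full(n, -1)
    cid = 0
    while active:
        best_center, best_count = None, -1
        for i in sorted(active):
            count = sum(1 for j in active if D[i, j] <= cutoff)
            if count > best_count:
                best_center, best_count = i, count
        members = [j for j in sorted(active) if D[best_center, j] <= cutoff]
        for j in members:
            assignments[j] = cid
        active -= set(members)
        cid += 1
    return assignments


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


class TestKabsch:
    def test_identical_coordinates(self, rng):
        coords = rng.normal(size=(10, 3))
        assert kabsch_rmsd(coords, coords) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        coords = rng.normal(size=(20, 3))
        moved = coords @ random_rotation(rng).T + np.array([1.0, -2.0, 0.5])
        assert kabsch_rmsd(coords, moved) == pytest.approx(0.0, abs=1e-10)

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(5):
            a = rng.normal(size=(5, 3))
            b = rng.normal(size=(5, 3))
            assert kabsch_rmsd(a, b) == pytest.approx(quaternion_rmsd(a, b), abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError):
            kabsch_rmsd(line, line)
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


class TestGromos:
    def test_single_frame(self):
        ens = make_helix_ensemble(n_frames=1, jitter_sigma=0.0, seed=0)
        cs = gromos_cluster(ens, cutoff=0.15)
        assert cs.n_clusters == 1
        assert cs.sizes[0] == 1

    def test_huge_cutoff_single_cluster(self):
        ens = make_helix_ensemble(n_frames=15, jitter_sigma=0.1, seed=1)
        cs = gromos_cluster(ens, cutoff=100.0)
        assert cs.n_clusters == 1
        assert cs.sizes[0] == 15

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        ens = make_helix_ensemble(n_frames=20, jitter_sigma=0.12, seed=seed)
        D = pairwise_rmsd(ens)
        cutoff = float(np.median(D))
        cs = gromos_cluster(ens, cutoff, rmsd_matrix=D)
        expected = brute_force_gromos(D, cutoff)
        np.testing.assert_array_equal(cs.assignments, expected)

    def test_sizes_sum_to_frames(self):
        ens = make_helix_ensemble(n_frames=30, jitter_sigma=0.1, seed=3)
        cs = gromos_cluster(ens, cutoff=0.12)
        assert cs.sizes.sum() == 30

    def test_permutation_equivariance(self, rng):
        # tie-free construction: three well-separated shape families of
        # distinct sizes, so neighbor counts are unique in every round
        blobs = []
        for size, stretch in ((7, 1.0), (5, 1.6), (3, 2.4)):
            ref = make_helix_ensemble(n_frames=1, jitter_sigma=0.0, seed=0)
            for m in range(size):
                coords = ref.backbone[0] * stretch
                coords = coords + rng.normal(0, 0.01, size=coords.shape)
                blobs.append(coords)
        backbone = np.asarray(blobs)
        sites = {"a": backbone[:, 0], "b": backbone[:, -1]}
        ens = ConformerEnsemble(backbone, sites)
        cutoff = 0.2  # intra-blob ~0.014, inter-blob >> cutoff
        base = gromos_cluster(ens, cutoff).assignments
        perm = rng.permutation(15)
        permuted = ens.subset(perm)
        shuffled = gromos_cluster(permuted, cutoff).assignments
        # partitions agree up to cluster relabeling
        for i in range(15):
            for j in range(15):
                same_base = base[perm[i]] == base[perm[j]]
                same_perm = shuffled[i] == shuffled[j]
                assert same_base == same_perm


class TestSiteDistances:
    def test_zero_label_sigma_exact(self):
        ens = make_helix_ensemble(n_frames=5, jitter_sigma=0.0, seed=0)
        d = site_distance_samples(ens, "5", "25", label_sigma=0.0)
        expected = helix_site_distance(20)
        np.testing.assert_allclose(d, expected, atol=1e-12)

    def test_broadening_matches_monte_carlo_oracle(self):
        sigma = 0.25
        xi = np.array([[0.0, 0.0, 0.0]])
        xj = np.array([[3.0, 0.0, 0.0]])
        ens = ConformerEnsemble(np.zeros((1, 3, 3)), {"a": xi, "b": xj})
        samples = site_distance_samples(ens, "a", "b", sigma, n_draws=200_000, seed=1)
        rng = np.random.default_rng(99)
        delta = rng.normal(0, sigma, (1_000_000, 3)) - rng.normal(0, sigma, (1_000_000, 3))
        oracle = np.linalg.norm(np.array([3.0, 0, 0]) + delta, axis=1)
        assert samples.mean() == pytest.approx(oracle.mean(), abs=0.02)
        assert samples.std() == pytest.approx(oracle.std(), rel=0.05)

    def test_seed_determinism(self):
        ens = make_helix_ensemble(n_frames=3, seed=0)
        a = site_distance_samples(ens, "5", "25", seed=7)
        b = site_distance_samples(ens, "5", "25", seed=7)
        np.testing.assert_array_equal(a, b)

    def test_missing_site(self):
        ens = make_helix_ensemble(n_frames=2, seed=0)
        with pytest.raises(KeyError):
            site_distance_samples(ens, "5", "99")


class TestSamplesToDistribution:
    def test_single_sample_mode(self):
        grid = make_grid(1.5, 8.0, 256)
        d = samples_to_distribution(np.array([3.5]), grid, bandwidth=0.2)
        assert d.n_modes() == 1
        assert abs(d.mode() - 3.5) <= 0.1

    def test_unit_integral(self, rng):
        grid = make_grid(1.5, 8.0, 128)
        d = samples_to_distribution(rng.uniform(2, 6, size=500), grid)
        assert d.integral() == pytest.approx(1.0, abs=1e-9)

    def test_bimodal_equal_masses(self, rng):
        grid = make_grid(1.5, 8.0, 256)
        cloud = np.concatenate([
            rng.normal(3.0, 0.1, 20_000), rng.normal(5.0, 0.1, 20_000)
        ])
        d = samples_to_distribution(cloud, grid, bandwidth=0.1)
        assert d.n_modes() == 2
        mid = np.searchsorted(grid.r, 4.0)
        lower = np.trapezoid(d.density[:mid], grid.r[:mid])
        assert lower == pytest.approx(0.5, abs=0.02)

    def test_samples_outside_grid_rejected(self):
        grid = make_grid(1.5, 8.0, 128)
        with pytest.raises(ValueError):
            samples_to_distribution(np.array([50.0]), grid, bandwidth=0.1)


class TestClusterAverage:
    def test_single_cluster_zero_band(self, rgrid):
        p = make_pr([(3.5, 0.3, 1.0)], rgrid)
        mean, (low, high) = cluster_weighted_average([p], [100])
        np.testing.assert_allclose(mean.density, p.density)
        np.testing.assert_allclose(low, high)

    def test_two_equal_clusters_arithmetic_mean(self, rgrid):
        p1 = make_pr([(3.0, 0.3, 1.0)], rgrid)
        p2 = make_pr([(5.0, 0.3, 1.0)], rgrid)
        mean, (low, high) = cluster_weighted_average([p1, p2], [60, 60])
        np.testing.assert_allclose(
            mean.density, 0.5 * (p1.density + p2.density), atol=1e-12
        )
        assert np.all(low >= 0)
        assert np.all(low <= high)

    def test_empty_cluster_list_rejected(self):
        with pytest.raises(ValueError):
            cluster_weighted_average([], [])


class TestPrediction:
    def test_helix_fixture_peak_matches_closed_form(self):
        ens = make_helix_ensemble(
            n_residues=40, site_pair=(5, 25), n_frames=150,
            jitter_sigma=0.05, seed=1,
        )
        grid = make_grid(1.5, 8.0, 256)
        mean, (low, high), clusters = predict_distance_distribution(
            ens, "5", "25", grid, cutoff=0.15, seed=2
        )
        ideal = helix_site_distance(20)
        assert abs(mean.mode() - ideal) <= 0.2
        assert np.all(low >= 0)
        kept_sizes = clusters.sizes[clusters.kept]
        assert np.all(kept_sizes > 0.05 * ens.n_frames)

    def test_population_filter_error(self):
        ens = make_helix_ensemble(n_frames=30, jitter_sigma=0.05, seed=4)
        grid = make_grid(1.5, 8.0, 128)
        with pytest.raises(ValueError, match="min_fraction"):
            predict_distance_distribution(
                ens, "5", "25", grid, cutoff=0.001, min_fraction=0.9
            )

    def test_unfolded_control_is_broader(self):
        helical = make_helix_ensemble(site_pair=(5, 35), n_frames=200, seed=3)
        unfolded = make_helix_ensemble(
            site_pair=(5, 35), n_frames=200, unfolded=True, seed=3
        )
        dh = site_distance_samples(helical, "5", "35", label_sigma=0.0)
        du = site_distance_samples(unfolded, "5", "35", label_sigma=0.0)
        assert du.std() >= 3 * dh.std()


class TestPdbIO:
    def test_round_trip(self, tmp_path):
        ens = make_helix_ensemble(n_frames=4, jitter_sigma=0.02, seed=5)
        path = tmp_path / "ensemble.pdb"
        write_ensemble_pdb(path, ens)
        back = read_ensemble_pdb(path, [5, 25])
        assert back.n_frames == 4
        # PDB stores 3 decimals in angstrom -> 5e-5 nm rounding
        np.testing.assert_allclose(back.backbone, ens.backbone, atol=1e-4)
        np.testing.assert_allclose(back.sites["5"], ens.sites["5"], atol=1e-4)
        np.testing.assert_allclose(back.sites["25"], ens.sites["25"], atol=1e-4)
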