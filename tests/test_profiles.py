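"""Connectivity profiles, maturational connectome, embedding, groups, hubs."""

import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from matnets import (
    CohortTable,
    MaskedSeries,
    SpatialMapSet,
    connectivity_profiles,
    hub_maps,
    laplacian_embedding,
    maturational_connectome,
    ward_partition,
)
from matnets.connectome import MaturationalDense
from matnets.core import ValidationError, zscore_maps
from matnets.profiles import (
    ConnectivityProfiles,
    GroupPartition,
    MatnetConnectome,
    coupling_trajectory,
)


def _thresholded_dense(t):
    md = MaturationalDense(np.asarray(t, dtype=float), df=10, thresholded=True)
    return md


class TestConnectivityProfiles:
    def test_recovers_planted_mixture_weights(self, rng):
        n, m = 120, 3
        maps = zscore_maps(rng.standard_normal((m, n)))
        w = np.abs(rng.standard_normal((m, n)))  # planted mixing, per column
        dense = maps.T @ w + 0.5  # intercept offset per column
        prof = connectivity_profiles(
            SpatialMapSet(maps), _thresholded_dense(dense)
        )
        assert np.allclose(prof.slopes, w, atol=1e-8)

    def test_zero_column_gives_zero_slopes(self, rng):
        maps = zscore_maps(rng.standard_normal((2, 50)))
        dense = np.zeros((50, 50))
        prof = connectivity_profiles(SpatialMapSet(maps),
                                     _thresholded_dense(dense))
        assert np.allclose(prof.slopes, 0.0)

    def test_single_map_equals_simple_regression(self, rng):
        n = 60
        maps = zscore_maps(rng.standard_normal((1, n)))
        dense = np.abs(rng.standard_normal((n, n)))
        prof = connectivity_profiles(SpatialMapSet(maps),
                                     _thresholded_dense(dense))
        for v in [0, 17, 59]:
            res = stats.linregress(maps[0], dense[:, v])
            assert prof.slopes[0, v] == pytest.approx(res.slope, abs=1e-10)

    def test_requires_thresholded_input(self, rng):
        maps = zscore_maps(rng.standard_normal((2, 30)))
        md = MaturationalDense(np.zeros((30, 30)), df=5, thresholded=False)
        with pytest.raises(ValidationError, match="thresholded"):
            connectivity_profiles(SpatialMapSet(maps), md)

    def test_collinear_maps_raise_rank_error(self, rng):
        m = rng.standard_normal((1, 40))
        maps = np.vstack([m, 2 * m, rng.standard_normal((1, 40))])
        with pytest.raises(ValidationError, match="collinear"):
            connectivity_profiles(SpatialMapSet(maps),
                                  _thresholded_dense(np.zeros((40, 40))))


class TestMaturationalConnectome:
    def test_identical_and_orthogonal_rows(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([-1.0, 1.0, 1.0, -1.0])  # orthogonal to a after demeaning
        c = maturational_connectome(ConnectivityProfiles(np.stack([a, a, b])))
        assert c.corr[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert c.corr[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_matches_pairwise_pearson_oracle(self, rng):
        p = rng.standard_normal((5, 200))
        c = maturational_connectome(ConnectivityProfiles(p))
        oracle = np.corrcoef(p)
        assert np.max(np.abs(c.corr - oracle)) < 1e-12
        assert np.allclose(np.diag(c.corr), 1.0)

    def test_zero_variance_row_flagged(self, rng):
        p = rng.standard_normal((3, 50))
        p[1] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            c = maturational_connectome(ConnectivityProfiles(p))
        assert np.all(c.corr[1] == 0)
        assert list(c.zero_variance) == [1]


def _two_block_corr(strength=0.9, bridge=0.05):
    """6-network connectome: two dense triangles, weak bridge."""
    c = np.full((6, 6), bridge)
    for block in ([0, 1, 2], [3, 4, 5]):
        for i, j in itertools.combinations(block, 2):
            c[i, j] = c[j, i] = strength
    np.fill_diagonal(c, 1.0)
    return c


class TestLaplacianEmbedding:
    def test_first_coordinate_separates_two_blocks(self):
        emb = laplacian_embedding(MatnetConnectome(_two_block_corr()), dim=3)
        signs = np.sign(emb.coords[:, 0])
        assert len(set(signs[:3])) == 1
        assert len(set(signs[3:])) == 1
        assert signs[0] != signs[3]

    def test_equivariance_under_network_permutation(self, rng):
        # break the block symmetry so all retained eigenvalues are simple
        pert = rng.normal(0, 0.02, size=(6, 6))
        c = _two_block_corr(0.8, 0.1) + (pert + pert.T) / 2
        np.fill_diagonal(c, 1.0)
        perm = rng.permutation(6)
        e1 = laplacian_embedding(MatnetConnectome(c), dim=3)
        e2 = laplacian_embedding(MatnetConnectome(c[np.ix_(perm, perm)]), dim=3)
        for d in range(3):
            dots = e1.coords[perm, d] @ e2.coords[:, d]
            assert abs(abs(dots) - np.linalg.norm(e1.coords[perm, d]) *
                       np.linalg.norm(e2.coords[:, d])) < 1e-8

    def test_complete_graph_closed_form(self):
        """K_6 with equal weights: all nontrivial normalised-Laplacian
        eigenvalues equal M/(M-1); eigenvector coordinates orthonormal."""
        m = 6
        c = np.ones((m, m))
        emb = laplacian_embedding(MatnetConnectome(c), dim=3)
        assert np.allclose(emb.eigenvalues, m / (m - 1), atol=1e-12)
        assert np.allclose(emb.coords.T @ emb.coords, np.eye(3), atol=1e-10)

    def test_eigenvalues_in_laplacian_range(self):
        emb = laplacian_embedding(MatnetConnectome(_two_block_corr()), dim=3)
        assert np.all(emb.eigenvalues >= 0) and np.all(emb.eigenvalues <= 2)

    def test_disconnected_graph_rejected(self):
        c = np.zeros((10, 10))
        for block in range(5):  # 5 components > dim + 1
            i, j = 2 * block, 2 * block + 1
            c[i, j] = c[j, i] = 0.9
        np.fill_diagonal(c, 1.0)
        with pytest.raises(ValidationError, match="connected components"):
            laplacian_embedding(MatnetConnectome(c), dim=3)

    def test_isolated_node_rejected(self):
        c = _two_block_corr()
        c[5, :] = c[:, 5] = -0.5
        c[5, 5] = 1.0
        with pytest.raises(ValidationError, match="isolated"):
            laplacian_embedding(MatnetConnectome(c), dim=3)

    def test_needs_more_networks_than_dims(self):
        with pytest.raises(ValidationError):
            laplacian_embedding(MatnetConnectome(np.eye(3)), dim=3)


class TestWardPartition:
    def test_two_planted_clouds_recovered_at_g2(self, rng):
        a = rng.normal(0, 0.1, size=(5, 3))
        b = rng.normal(5, 0.1, size=(5, 3)) * np.array([1, -1, 1])
        coords = np.vstack([a, b])
        part = ward_partition(coords)
        cut2 = fcluster(part.linkage, t=2, criterion="maxclust")
        assert len(set(cut2[:5])) == 1 and len(set(cut2[5:])) == 1
        assert cut2[0] != cut2[5]

    @pytest.mark.parametrize("m", [4, 6, 8])
    def test_finest_no_singleton_rule_matches_brute_force(self, rng, m):
        coords = rng.standard_normal((m, 3))
        part = ward_partition(coords)
        link = linkage(coords, method="ward")
        best = 1
        for g in range(2, m + 1):
            lab = fcluster(link, t=g, criterion="maxclust")
            if len(np.unique(lab)) == g and np.bincount(lab)[1:].min() >= 2:
                best = max(best, g)
        assert part.n_groups == best
        if best > 1:
            assert np.bincount(part.labels)[1:].min() >= 2

    def test_two_networks_fall_back_to_one_group(self):
        part = ward_partition(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        assert part.n_groups == 1
        assert np.all(part.labels == 1)


class TestHubMaps:
    def test_identical_maps_group(self, rng):
        h = rng.standard_normal(80)
        prof = ConnectivityProfiles(np.stack([h, h, h]))
        part = GroupPartition(np.array([1, 1, 1]), 1, np.zeros((0, 4)))
        hubs = hub_maps(prof, part)
        r = np.corrcoef(hubs.maps[0], h)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)
        assert r > 0  # sign aligned with the group mean
        assert hubs.explained_variance[0] == pytest.approx(1.0)

    def test_planted_one_factor_model(self, rng):
        h = rng.standard_normal(200)
        rows = np.stack(
            [w * h + 0.05 * rng.standard_normal(200) for w in (0.5, 1.0, 2.0)]
        )
        prof = ConnectivityProfiles(rows)
        part = GroupPartition(np.array([1, 1, 1]), 1, np.zeros((0, 4)))
        hubs = hub_maps(prof, part)
        assert abs(np.corrcoef(hubs.maps[0], h)[0, 1]) >= 0.99

    def test_matches_full_svd_oracle(self, rng):
        rows = rng.standard_normal((4, 100))
        prof = ConnectivityProfiles(rows)
        part = GroupPartition(np.array([1, 1, 1, 1]), 1, np.zeros((0, 4)))
        hubs = hub_maps(prof, part)
        centred = rows - rows.mean(axis=1, keepdims=True)
        vt = np.linalg.svd(centred, full_matrices=False)[2]
        dot = abs(hubs.maps[0] @ vt[0])
        assert dot == pytest.approx(np.linalg.norm(hubs.maps[0]) *
                                    np.linalg.norm(vt[0]), abs=1e-10)

    def test_single_map_group_flagged(self, rng):
        rows = rng.standard_normal((3, 50))
        prof = ConnectivityProfiles(rows)
        part = GroupPartition(np.array([1, 1, 2]), 2, np.zeros((0, 4)))
        with pytest.warns(UserWarning, match="single map"):
            hubs = hub_maps(prof, part)
        assert np.array_equal(hubs.maps[1], rows[2])


class TestPipelineDualism:
    """The dual view: grouping matnets by the similarity of their
    emerging-connectivity targets recovers planted target structure."""

    GROUPS = ((0, 1, 2), (3, 4, 5), (6, 7, 8), (9, 10, 11))

    def _planted(self, rng, n=400, pairs=GROUPS, noise=0.05):
        m = sum(len(p) for p in pairs)
        maps = zscore_maps(rng.standard_normal((m, n)))
        # group targets share a common positive background (profile
        # correlations in data are largely positive), with group-specific
        # structure on top
        common = rng.standard_normal(n)
        targets = np.stack(
            [0.5 * common + rng.standard_normal(n) for _ in pairs]
        )
        targets -= targets.mean(axis=1, keepdims=True)
        targets /= targets.std(axis=1, keepdims=True)
        w = np.zeros((m, n))
        for g, pair in enumerate(pairs):
            for i in pair:
                w[i] = targets[g] + noise * rng.standard_normal(n)
        dense = maps.T @ w
        return maps, w, dense, pairs

    def test_partition_recovers_planted_target_groups_exactly(self, rng):
        maps, w, dense, pairs = self._planted(rng)
        prof = connectivity_profiles(SpatialMapSet(maps),
                                     _thresholded_dense(dense))
        conn = maturational_connectome(prof)
        emb = laplacian_embedding(conn, dim=3)
        part = ward_partition(emb)
        assert part.n_groups == len(pairs)
        for pair in pairs:
            assert np.unique(part.labels[list(pair)]).size == 1
        assert np.unique(part.labels[[p[0] for p in pairs]]).size == len(pairs)

    def test_networks_sharing_targets_sit_closer_in_embedding(self, rng):
        """Networks with shared emerging targets (e.g. contralateral
        homologues) land nearer each other in the embedding than networks
        from different groups."""
        maps, w, dense, groups = self._planted(rng, noise=0.2)
        prof = connectivity_profiles(SpatialMapSet(maps),
                                     _thresholded_dense(dense))
        conn = maturational_connectome(prof)
        emb = laplacian_embedding(conn, dim=3)
        label = np.empty(12, dtype=int)
        for g, members in enumerate(groups):
            label[list(members)] = g
        within, between = [], []
        for i in range(12):
            for j in range(i + 1, 12):
                d = np.linalg.norm(emb.coords[i] - emb.coords[j])
                (within if label[i] == label[j] else between).append(d)
        assert np.mean(within) < np.mean(between)


class TestCouplingTrajectory:
    def _cohort(self, k):
        return CohortTable([f"s{i}" for i in range(k)], np.linspace(25, 38, k))

    def test_identical_maps_give_unit_coupling(self, rng):
        n, k = 60, 8
        m = np.zeros(n)
        m[:6] = 6.0  # suprathreshold at z > 5
        cohort = self._cohort(k)
        series = [MaskedSeries(f"s{i}", rng.standard_normal((n, 40)))
                  for i in range(k)]
        traj = coupling_trajectory(m, m.copy(), series, cohort)
        assert np.allclose(traj.coupling, 1.0, atol=1e-12)

    def test_recovers_planted_linear_coupling_slope(self):
        from matnets import default_mask, default_truth_spec, generate_cohort
        from matnets.core import zscore_maps as zs

        spec = default_truth_spec(default_mask((10, 10, 8)), noise_sd=0.1,
                                  seed=21)
        cohort, series, spec = generate_cohort(spec, n_subjects=40,
                                               n_timepoints=200)
        maps = zs(spec.network_maps)
        traj = coupling_trajectory(maps[0], maps[1], series, cohort,
                                   z_thresh=5.0, orders=(1,))
        slope = traj.coefficients[1]
        assert slope > 0
        res = stats.linregress(cohort.age, traj.coupling)
        assert abs(0.045 - slope) < 3 * res.stderr + 0.01

    def test_null_coupling_selects_linear_with_flat_slope(self):
        from matnets import default_mask, default_truth_spec, generate_cohort
        from matnets.core import zscore_maps as zs

        spec = default_truth_spec(default_mask((10, 10, 8)), noise_sd=0.3,
                                  seed=22)
        spec.coupling_slope[:] = 0.0
        cohort, series, spec = generate_cohort(spec, n_subjects=30,
                                               n_timepoints=120)
        maps = zs(spec.network_maps)
        traj = coupling_trajectory(maps[0], maps[1], series, cohort)
        assert traj.poly_order == 1
        res = stats.linregress(cohort.age, traj.coupling)
        assert abs(traj.coefficients[1]) < 2.5 * res.stderr

    def test_empty_suprathreshold_set_raises(self, rng):
        n = 30
        cohort = self._cohort(4)
        series = [MaskedSeries(f"s{i}", rng.standard_normal((n, 20)))
                  for i in range(4)]
        with pytest.raises(ValidationError, match="lower the threshold"):
            coupling_trajectory(np.zeros(n), np.zeros(n), series, cohort)
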