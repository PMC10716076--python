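"""Great-circle distances, distance classes, Moran's I, correlograms."""

import itertools

import numpy as np
import pytest

from craniomorph.io import SiteInfo, load_site_distance_matrix
from craniomorph.spatial import (EARTH_RADIUS_KM, build_distance_classes,
                                 correlogram, great_circle_distance_matrix,
                                 haversine_km, morans_i, site_summaries)


class TestHaversine:
    def test_identical_points_zero(self):
        assert haversine_km(35.0, 139.0, 35.0, 139.0) == 0.0

    def test_one_degree_longitude_at_equator(self):
        d = haversine_km(0.0, 0.0, 0.0, 1.0)
        assert d == pytest.approx(EARTH_RADIUS_KM * np.pi / 180, abs=1e-3)

    def test_antipodal(self):
        d = haversine_km(0.0, 0.0, 0.0, 180.0)
        assert d == pytest.approx(np.pi * EARTH_RADIUS_KM, abs=0.1)

    def test_matrix_symmetric_zero_diagonal(self):
        sites = [SiteInfo(f"s{i}", "HOK", 30.0 + i, 130.0 + i) for i in range(4)]
        D = great_circle_distance_matrix(sites).to_numpy()
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0.0)

    def test_missing_coordinates_error(self):
        sites = [SiteInfo("a", "HOK", 30.0, 130.0), SiteInfo("b", "NEH")]
        with pytest.raises(ValueError, match="b"):
            great_circle_distance_matrix(sites)


class TestDistanceClasses:
    def test_published_matrix_yields_17_classes(self):
        D = load_site_distance_matrix()
        classes = build_distance_classes(D.to_numpy(), 100.0)
        assert len(classes) == 17
        assert classes[0].lower_km == 0.0 and classes[0].upper_km == 100.0

    def test_published_class1_contains_named_short_pairs(self):
        D = load_site_distance_matrix()
        names = list(D.index)
        classes = build_distance_classes(D.to_numpy(), 100.0)
        pairs = {frozenset((names[i], names[j])) for i, j in classes[0].member_pairs}
        assert frozenset(("Yoshigo", "Ikawazu")) in pairs       # 1.32 km
        assert frozenset(("Yamaga", "Einomaru")) in pairs       # 8.85 km
        assert frozenset(("Kitakogane", "Takasago")) in pairs   # ~19 km

    def test_three_sites_direct_binning(self):
        D = np.array([[0, 50, 150], [50, 0, 250], [150, 250, 0]], float)
        classes = build_distance_classes(D, 100.0)
        assert [c.n_pairs for c in classes] == [1, 1, 1]
        assert classes[1].member_pairs == ((0, 2),)

    def test_partition_covers_all_pairs(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 800, size=(9, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        classes = build_distance_classes(D, 100.0)
        assert sum(c.n_pairs for c in classes) == 9 * 8 // 2
        # each pair in exactly one class
        seen = list(itertools.chain.from_iterable(c.member_pairs for c in classes))
        assert len(seen) == len(set(seen))

    def test_means_within_bounds(self):
        D = load_site_distance_matrix().to_numpy()
        for c in build_distance_classes(D, 100.0):
            if c.n_pairs:
                assert c.lower_km <= c.mean_distance_km < c.upper_km


def _brute_force_morans(x, W):
    n = len(x)
    xbar = np.mean(x)
    num = sum(W[i, j] * (x[i] - xbar) * (x[j] - xbar)
              for i in range(n) for j in range(n))
    den = sum((xi - xbar) ** 2 for xi in x)
    return (n / W.sum()) * num / den


class TestMoransI:
    def test_line_adjacency_matches_brute_force(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        W = np.zeros((4, 4))
        for i in range(3):
            W[i, i + 1] = W[i + 1, i] = 1.0
        assert morans_i(x, W) == pytest.approx(_brute_force_morans(x, W), abs=1e-12)

    def test_two_site_identity_minus_one(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        for vals in ([0.0, 1.0], [3.0, 7.5], [-2.0, 11.0]):
            assert morans_i(vals, W) == pytest.approx(-1.0, abs=1e-12)

    def test_null_mean_matches_expectation(self):
        """Permutation null mean of I is -1/(n-1)."""
        rng = np.random.default_rng(17)
        n = 7
        x = rng.normal(size=n)
        W = np.zeros((n, n))
        for i, j in [(0, 1), (1, 2), (2, 3), (4, 5), (5, 6), (0, 6)]:
            W[i, j] = W[j, i] = 1.0
        draws = np.array([morans_i(rng.permutation(x), W) for _ in range(2000)])
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - (-1 / (n - 1))) < 3 * se

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_exhaustive_small_weight_matrices(self, n):
        """Every symmetric binary weight pattern on n <= 5 sites matches
        the brute-force double-sum oracle."""
        rng = np.random.default_rng(n)
        x = rng.normal(size=n)
        iu = list(zip(*np.triu_indices(n, 1)))
        for bits in range(1, 2 ** len(iu)):
            W = np.zeros((n, n))
            for b, (i, j) in enumerate(iu):
                if bits >> b & 1:
                    W[i, j] = W[j, i] = 1.0
            assert morans_i(x, W) == pytest.approx(
                _brute_force_morans(x, W), abs=1e-12)

    def test_sampled_n6_matches_oracle(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=6)
        for _ in range(300):
            W = np.zeros((6, 6))
            iu = np.triu_indices(6, 1)
            mask = rng.random(len(iu[0])) < 0.5
            W[iu[0][mask], iu[1][mask]] = 1.0
            W += W.T
            if W.sum() == 0:
                continue
            assert morans_i(x, W) == pytest.approx(
                _brute_force_morans(x, W), abs=1e-12)

    def test_constant_values_error_and_empty_weights_nan(self):
        W = np.zeros((3, 3))
        assert np.isnan(morans_i([1.0, 2.0, 3.0], W))
        W[0, 1] = W[1, 0] = 1.0
        with pytest.raises(ValueError, match="variance"):
            morans_i([5.0, 5.0, 5.0], W)


class TestCorrelogram:
    def _transect_D(self, n=8, spacing=95.0):
        pos = np.arange(n) * spacing
        return np.abs(pos[:, None] - pos[None, :])

    def test_linear_cline_positive_near_negative_far(self):
        """Isolation-by-distance construction: value = position proxy."""
        D = self._transect_D()
        rng = np.random.default_rng(0)
        hits = 0
        for seed in range(20):
            vals = np.linspace(0, 1, 8) + rng.normal(scale=0.15, size=8)
            cg = correlogram(vals, D, n_perm=99, seed=seed)
            ok = np.flatnonzero(np.isfinite(cg.morans_I))
            hits += (cg.morans_I[ok[0]] > 0) and (cg.morans_I[ok[-1]] < 0)
        assert hits >= 19

    def test_iid_type_I_error_calibrated(self):
        rng = np.random.default_rng(3)
        D = load_site_distance_matrix().to_numpy()
        rej = []
        for rep in range(200):
            vals = rng.standard_normal(16)
            cg = correlogram(vals, D, n_perm=999, seed=int(rng.integers(2**31)))
            ok = np.isfinite(cg.p_perm)
            rej.append(cg.p_perm[ok] < 0.05)
        rate = np.concatenate(rej).mean()
        assert 0.02 <= rate <= 0.08

    def test_site_without_data_flags_isolated_classes(self):
        # sites at 0/50/500: class 1 joins only the first two sites
        D = np.array([[0, 50, 500], [50, 0, 450], [500, 450, 0]], float)
        full = correlogram(np.array([1.0, 2.0, 3.0]), D, n_perm=49, seed=0)
        assert np.isfinite(full.morans_I[0])
        dropped = correlogram(np.array([np.nan, 2.0, 3.0]), D, n_perm=49, seed=0)
        assert np.isnan(dropped.morans_I[0]) and np.isnan(dropped.p_perm[0])

    def test_shared_permutations_reproducible(self):
        D = self._transect_D(6)
        vals = np.array([0.3, 1.2, 0.7, 2.0, 1.4, 0.1])
        a = correlogram(vals, D, n_perm=199, seed=9)
        b = correlogram(vals, D, n_perm=199, seed=9)
        assert np.array_equal(a.p_perm, b.p_perm, equal_nan=True)


class TestSiteSummaries:
    def _dataset_and_gpa(self, rng, n_sites=4, n_per_site=5, offset=0.0):
        from craniomorph.io import AnnotatedDataset
        from craniomorph.landmark_sets import default_set
        from craniomorph.superimposition import gpa
        from craniomorph.synthetic import make_template_skull
        from conftest import record_from

        spec = default_set("neurocranial")
        template = make_template_skull(spec)
        sites = [SiteInfo(f"s{i}", "HOK", 40.0 - i, 140.0) for i in range(n_sites)]
        recs, configs = [], []
        for i in range(n_sites):
            for j in range(n_per_site):
                c = template + rng.normal(scale=1.0, size=template.shape)
                c = c + i * offset  # translation: no shape effect
                recs.append(record_from(c, None, f"s{i}_{j}", site=f"s{i}"))
                configs.append(c)
        ds = AnnotatedDataset(spec, recs, sites)
        return ds, gpa(np.array(configs))

    def test_single_specimen_site_equals_specimen_values(self, rng):
        ds, res = self._dataset_and_gpa(rng, n_sites=3, n_per_site=1)
        summ = site_summaries(ds, res).set_index("site")
        assert summ.loc["s0", "csize"] == pytest.approx(res.csize[0])

    def test_duplicated_specimen_leaves_mean_unchanged(self, rng):
        ds, res = self._dataset_and_gpa(rng, n_sites=2, n_per_site=2)
        summ = site_summaries(ds, res).set_index("site")
        manual = res.csize[:2].mean()
        assert summ.loc["s0", "csize"] == pytest.approx(manual)

    def test_known_site_offsets_recovered_on_pc1(self, rng):
        """Sites shifted along a fixed shape direction should be recovered
        in PC1 site means within Monte-Carlo error."""
        from craniomorph.io import AnnotatedDataset
        from craniomorph.landmark_sets import default_set
        from craniomorph.superimposition import centroid_size, gpa
        from craniomorph.synthetic import make_template_skull, random_tangent_vector
        from conftest import record_from

        spec = default_set("neurocranial")
        template = make_template_skull(spec)
        cs0 = centroid_size(template)
        v = random_tangent_vector(template, rng, 1.0).reshape(-1, 3)
        sites = [SiteInfo(f"s{i}", "HOK", 40.0 - i, 140.0) for i in range(4)]
        sd = 0.5
        n_per = 12
        recs, configs = [], []
        deltas = [0.0, 0.01, 0.02, 0.03]
        for i, d in enumerate(deltas):
            for j in range(n_per):
                c = template + d * cs0 * v + rng.normal(scale=sd, size=template.shape)
                recs.append(record_from(c, None, f"s{i}_{j}", site=f"s{i}"))
                configs.append(c)
        ds = AnnotatedDataset(spec, recs, sites)
        res = gpa(np.array(configs))
        summ = site_summaries(ds, res).set_index("site")
        pc1 = summ["PC1"].to_numpy()
        spacing = np.diff(np.sort(pc1))
        # per-spec means separated by ~0.01 in tangent units; tolerance 2*sd/sqrt(n)
        tol = 2 * (sd / cs0) * np.sqrt(template.size) / np.sqrt(n_per)
        assert np.all(np.abs(spacing - 0.01) < 0.01 + tol)
        assert abs(abs(pc1[-1] - pc1[0]) - 0.03) < 2 * tol
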