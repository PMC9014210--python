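import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from invamicro import beta_div, multivar_stats as ms

from conftest import make_table
from oracles import (kw_exhaustive_p, mantel_exhaustive_p,
                     permanova_exhaustive_p)


def _dm_from_points(pts, ids=None):
    d = squareform(pdist(pts))
    ids = ids or [f"s{i}" for i in range(len(pts))]
    return DistanceMatrix(d, ids=ids)


class TestPermanova:
    def test_pure_between_group_structure(self):
        d = np.ones((4, 4)) - np.eye(4)
        d[0, 1] = d[1, 0] = 0.0
        d[2, 3] = d[3, 2] = 0.0
        dm = DistanceMatrix(d, ids=list("abcd"))
        res = ms.permanova(dm, ["g1", "g1", "g2", "g2"], n_perm=99, seed=0)
        assert res.r2 == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self, rng):
        pts = rng.normal(size=(6, 2))
        pts[:3] += 1.2
        dm = _dm_from_points(pts)
        labels = ["a"] * 3 + ["b"] * 3
        res = ms.permanova(dm, labels, n_perm=719, seed=5)
        p_exact = permanova_exhaustive_p(dm.data, labels)
        # Monte-Carlo error of the permutation p at 719 draws
        se = np.sqrt(p_exact * (1 - p_exact) / 719)
        assert abs(res.p_value - p_exact) <= 3 * se + 2 / 720

    def test_single_group_rejected(self):
        dm = _dm_from_points(np.eye(3))
        with pytest.raises(ValueError):
            ms.permanova(dm, ["g"] * 3, n_perm=99, seed=0)

    def test_nested_refinement_r2_ordering(self, sim_dataset):
        table = sim_dataset.asv_table
        sub = table.subset_samples(
            table.metadata.index[table.metadata.host_type == "invasive"])
        dm = beta_div.unifrac(sub, sim_dataset.tree, weighted=True)
        r2_site = ms.permanova(dm, sub.metadata["site"], n_perm=99,
                               seed=1).r2
        r2_river = ms.permanova(dm, sub.metadata["river"], n_perm=99,
                                seed=1).r2
        assert r2_site >= r2_river - 1e-12

    def test_reproducible_under_seed(self, rng):
        dm = _dm_from_points(rng.normal(size=(12, 3)))
        labels = ["a", "b"] * 6
        p1 = ms.permanova(dm, labels, n_perm=199, seed=3).p_value
        p2 = ms.permanova(dm, labels, n_perm=199, seed=3).p_value
        assert p1 == p2


class TestPairwisePermanova:
    def test_pair_count_and_bonferroni(self, rng):
        pts = rng.normal(size=(12, 2))
        dm = _dm_from_points(pts)
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        results = ms.pairwise_permanova(dm, labels, n_perm=99, seed=0)
        assert len(results) == 3  # k(k-1)/2
        for r in results:
            assert r.adjusted_p == pytest.approx(min(1.0, r.p_value * 3))
            assert r.adjusted_p >= r.p_value


class TestDispersion:
    def test_distances_nonnegative(self, rng):
        dm = _dm_from_points(rng.normal(size=(14, 3)))
        labels = ["a", "b"] * 7
        res = ms.dispersion_test(dm, labels, n_perm=99, seed=0)
        assert (res.extra["centroid_distances"] >= 0).all()

    def test_detects_scaled_dispersion(self):
        rng = np.random.default_rng(1)
        hits = 0
        for rep in range(20):
            a = rng.normal(size=(20, 3))
            b = rng.normal(size=(20, 3)) * 3
            dm = _dm_from_points(np.vstack([a, b]))
            res = ms.dispersion_test(dm, ["a"] * 20 + ["b"] * 20,
                                     n_perm=99, seed=rep)
            hits += res.p_value <= 0.05
        assert hits >= 18  # power >= 0.9

    def test_size_one_group_rejected(self, rng):
        dm = _dm_from_points(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError):
            ms.dispersion_test(dm, ["a", "b", "b", "b", "b"], n_perm=99,
                               seed=0)


class TestEnvfit:
    def _ordination(self, rng, n=20):
        pts = rng.normal(size=(n, 2))
        return beta_div.pcoa(_dm_from_points(pts))

    def test_variable_equal_to_axis_r2_one(self, rng):
        ordn = self._ordination(rng)
        env = type("E", (), {})()
        from invamicro.io_formats import EnvTable
        sites = [f"site{i}" for i in range(len(ordn.sample_ids))]
        env = EnvTable(pd.DataFrame({"v": ordn.coordinates[:, 0]},
                                    index=sites))
        res = ms.envfit(ordn, env, dict(zip(ordn.sample_ids, sites)),
                        n_perm=99, seed=0)
        assert res["v"].r2 == pytest.approx(1.0)

    def test_sum_of_axes_gives_diagonal_arrow(self, rng):
        ordn = self._ordination(rng)
        from invamicro.io_formats import EnvTable
        sites = [f"site{i}" for i in range(len(ordn.sample_ids))]
        v = ordn.coordinates[:, 0] + ordn.coordinates[:, 1]
        env = EnvTable(pd.DataFrame({"v": v}, index=sites))
        res = ms.envfit(ordn, env, dict(zip(ordn.sample_ids, sites)),
                        n_perm=99, seed=0)
        assert res["v"].r2 == pytest.approx(1.0)
        arrow = res["v"].extra["arrow"]
        assert abs(arrow[0]) == pytest.approx(abs(arrow[1]), abs=1e-9)

    def test_constant_variable_flagged_others_proceed(self, rng):
        ordn = self._ordination(rng)
        from invamicro.io_formats import EnvTable
        sites = [f"site{i}" for i in range(len(ordn.sample_ids))]
        env = EnvTable(pd.DataFrame(
            {"flat": 1.0, "ok": ordn.coordinates[:, 0]}, index=sites))
        res = ms.envfit(ordn, env, dict(zip(ordn.sample_ids, sites)),
                        n_perm=99, seed=0)
        assert np.isnan(res["flat"].statistic)
        assert res["ok"].r2 == pytest.approx(1.0)

    def test_missing_values_dropped_per_variable(self, rng):
        ordn = self._ordination(rng)
        from invamicro.io_formats import EnvTable
        sites = [f"site{i}" for i in range(len(ordn.sample_ids))]
        v = ordn.coordinates[:, 0].copy()
        df = pd.DataFrame({"v": v}, index=sites)
        df.iloc[:5, 0] = np.nan
        env = EnvTable(df)
        res = ms.envfit(ordn, env, dict(zip(ordn.sample_ids, sites)),
                        n_perm=99, seed=0)
        assert res["v"].extra["n"] == len(sites) - 5


class TestMantel:
    def test_identity_gives_rho_one_minimal_p(self, rng):
        dm = _dm_from_points(rng.normal(size=(8, 2)))
        res = ms.mantel(dm, dm, n_perm=999, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_matches_exhaustive_enumeration(self, rng):
        d1 = _dm_from_points(rng.normal(size=(5, 2)))
        pts2 = rng.normal(size=(5, 2)) * 0.3 + np.arange(5)[:, None]
        d2 = _dm_from_points(pts2)
        res = ms.mantel(d1, d2, method="spearman", n_perm=999, seed=7)
        p_exact = mantel_exhaustive_p(np.asarray(d1.data),
                                      np.asarray(d2.data))
        se = np.sqrt(p_exact * (1 - p_exact) / 999)
        assert abs(res.p_value - p_exact) <= 3 * se + 2 / 1000

    def test_label_mismatch_rejected(self, rng):
        d1 = _dm_from_points(rng.normal(size=(5, 2)))
        d2 = _dm_from_points(rng.normal(size=(5, 2)),
                             ids=[f"x{i}" for i in range(5)])
        with pytest.raises(ValueError):
            ms.mantel(d1, d2)


class TestCovariationMedianMantel:
    def _site_table(self, rng, n_sites=5, per=3, coupled=True):
        counts, sids, sites, species, types = [], [], [], [], []
        base = rng.normal(0, 1, 30)
        for s in range(n_sites):
            shift = rng.normal(0, 1.2, 30)
            for grp, htype in (("inv", "invasive"), ("nat", "native_mussel")):
                g_shift = shift if coupled else rng.normal(0, 1.2, 30)
                for k in range(per):
                    logw = base + g_shift + rng.normal(0, 0.2, 30)
                    p = np.exp(logw)
                    p /= p.sum()
                    counts.append(rng.multinomial(2000, p))
                    sids.append(f"site{s}_{grp}{k}")
                    sites.append(f"site{s}")
                    species.append(grp)
                    types.append(htype)
        return make_table(np.array(counts), sample_ids=sids, sites=sites,
                          species=species, host_types=types)

    def test_duplicated_group_degenerate(self, rng):
        t = self._site_table(rng, coupled=True)
        inv = t.metadata.index[t.metadata.host_type == "invasive"]
        nat = t.metadata.index[t.metadata.host_type == "native_mussel"]
        # compare the invasive group against itself via two equal halves:
        # with equal per-site sizes, subsample = full set every replicate
        res = ms.covariation_median_mantel(t, inv, inv, n_reps=5,
                                           n_perm=99, seed=0)
        assert np.allclose(res["rho"], 1.0)
        # p is near-minimal; random permutations can rarely re-draw the
        # identity on 5 sites, so allow a few tied replicates
        assert res["median_p"] <= 0.05

    def test_planted_shared_structure_detected(self):
        rng = np.random.default_rng(11)
        hits = 0
        for rep in range(10):
            t = self._site_table(np.random.default_rng(100 + rep),
                                 coupled=True)
            inv = t.metadata.index[t.metadata.host_type == "invasive"]
            nat = t.metadata.index[t.metadata.host_type == "native_mussel"]
            res = ms.covariation_median_mantel(t, inv, nat, n_reps=30,
                                               n_perm=99, seed=rep)
            hits += res["median_p"] < 0.1
        assert hits >= 9

    def test_no_shared_structure_median_near_half(self):
        ps = []
        for rep in range(10):
            t = self._site_table(np.random.default_rng(200 + rep),
                                 coupled=False)
            inv = t.metadata.index[t.metadata.host_type == "invasive"]
            nat = t.metadata.index[t.metadata.host_type == "native_mussel"]
            res = ms.covariation_median_mantel(t, inv, nat, n_reps=20,
                                               n_perm=99, seed=rep)
            ps.append(res["median_p"])
        assert 0.2 < np.mean(ps) < 0.8

    def test_too_few_shared_sites_rejected(self, rng):
        t = self._site_table(rng, n_sites=3)
        inv = t.metadata.index[t.metadata.host_type == "invasive"]
        nat = t.metadata.index[t.metadata.host_type == "native_mussel"]
        with pytest.raises(ValueError, match="shared sites"):
            ms.covariation_median_mantel(t, inv, nat, n_reps=2, n_perm=99,
                                         seed=0)


class TestDistanceDecay:
    def _matrices(self, rng, n=12):
        ids = [f"s{i}" for i in range(n)]
        pos = np.sort(rng.uniform(0, 100, n))
        geo = np.abs(pos[:, None] - pos[None])
        rivers = pd.Series(["r1"] * (n // 2) + ["r2"] * (n - n // 2),
                           index=ids)
        return ids, geo, rivers

    def test_monotone_transform_rho_one(self, rng):
        ids, geo, rivers = self._matrices(rng)
        resp = np.sqrt(geo)
        res = ms.distance_decay(DistanceMatrix(resp, ids=ids),
                                DistanceMatrix(geo, ids=ids), rivers,
                                n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_cross_river_pairs_excluded(self, rng):
        ids, geo, rivers = self._matrices(rng)
        resp = geo + rng.normal(0, 1, geo.shape)
        resp = np.abs(resp + resp.T) / 2
        np.fill_diagonal(resp, 0)
        res = ms.distance_decay(DistanceMatrix(resp, ids=ids),
                                DistanceMatrix(geo, ids=ids), rivers,
                                n_perm=99, seed=0)
        n = len(ids)
        assert res.extra["n_pairs"] + res.extra["n_excluded_pairs"] \
            == n * (n - 1) // 2
        assert res.extra["n_excluded_pairs"] == 36  # 6*6 cross pairs

    def test_planted_decay_recovered(self):
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(300 + rep)
            ids, geo, rivers = self._matrices(rng, n=16)
            resp = geo / 100 + rng.uniform(0, 0.3, geo.shape)
            resp = (resp + resp.T) / 2
            np.fill_diagonal(resp, 0)
            res = ms.distance_decay(DistanceMatrix(resp, ids=ids),
                                    DistanceMatrix(geo, ids=ids), rivers,
                                    n_perm=199, seed=rep)
            hits += res.p_value < 0.05
        assert hits >= 8
        assert res.extra["naive_p"] <= 1.0


class TestGroupCompare:
    def test_identical_samples_wilcoxon_p_one(self):
        res = ms.group_compare([1, 2, 3, 4, 1, 2, 3, 4],
                               ["a"] * 4 + ["b"] * 4,
                               test="wilcoxon_ranksum")
        assert res.p_value == pytest.approx(1.0)

    def test_kw_exact_matches_bruteforce(self):
        values = [1, 2, 3, 10, 20, 30, 100, 200, 300]
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = ms.group_compare(values, labels, test="kruskal_wallis")
        assert res.extra["exact"]
        assert res.p_value == pytest.approx(kw_exhaustive_p(values, labels))

    def test_kw_exact_with_ties(self):
        values = [1, 1, 2, 2, 3, 3, 9, 9]
        labels = ["a"] * 4 + ["b"] * 4
        res = ms.group_compare(values, labels, test="kruskal_wallis")
        assert res.p_value == pytest.approx(kw_exhaustive_p(values, labels))

    def test_pearson_self_correlation(self):
        x = np.array([1.0, 2, 3, 4, 5])
        z = (x - x.mean()) / x.std()
        res = ms.group_compare(z, test="pearson", y=x)
        assert res.statistic == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ms.group_compare([1.0, 2.0], ["a", "a"], test="kruskal_wallis")


def test_permutation_p_floor_property(rng):
    """All permutation tests respect p >= 1/(n_perm+1)."""
    dm = _dm_from_points(rng.normal(size=(10, 2)))
    labels = ["a", "b"] * 5
    for n_perm in (99, 199):
        res = ms.permanova(dm, labels, n_perm=n_perm, seed=0)
        assert res.p_value >= 1 / (n_perm + 1) - 1e-12
        res = ms.mantel(dm, dm, n_perm=n_perm, seed=0)
        assert res.p_value >= 1 / (n_perm + 1) - 1e-12
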