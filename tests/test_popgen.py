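import numpy as np
import pandas as pd
import pytest

from invamicro import popgen
from invamicro.io_formats import (CALL_HET, CALL_HOM_ALT, CALL_HOM_REF,
                                  CALL_MISSING, GenotypeMatrix)
from invamicro.popgen import (allelic_distance, fis, pairwise_fst,
                              remove_fixed_het, site_pi, thin_snps)
from invamicro.simdata import SimConfig, simulate_dataset

from conftest import small_config


def _gm(calls, chrom=None, pos=None, inds=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    chrom = chrom if chrom is not None else ["chr1"] * m
    pos = pos if pos is not None else [100 * (j + 1) for j in range(m)]
    inds = inds or [f"i{k}" for k in range(n)]
    return GenotypeMatrix(inds, np.array(chrom), np.array(pos), calls)


class TestSitePi:
    def test_monomorphic_zero(self):
        g = _gm([[0], [0], [0]])
        pi = site_pi(g)
        assert pi["pi"].tolist() == [0.0]

    def test_two_ref_two_alt_alleles(self):
        # genotypes (0/0, 1/1): 2 ref + 2 alt alleles -> 4/6 pairs differ
        g = _gm([[CALL_HOM_REF], [CALL_HOM_ALT]])
        assert site_pi(g)["pi"].iloc[0] == pytest.approx(2 / 3)

    def test_singleton_allele(self):
        # 1 alt among 10 alleles: pi = 2*9*1/(10*9) = 0.2
        calls = [[CALL_HOM_REF]] * 4 + [[CALL_HET]]
        assert site_pi(_gm(calls))["pi"].iloc[0] == pytest.approx(0.2)

    def test_sites_below_two_alleles_excluded(self):
        g = _gm([[CALL_MISSING, CALL_HET], [CALL_MISSING, CALL_HET]])
        pi = site_pi(g)
        assert len(pi) == 1 and pi["position"].iloc[0] == 200

    def test_per_chromosome_river_average(self):
        calls = [[CALL_HET, CALL_HOM_REF], [CALL_HET, CALL_HOM_REF]]
        g = _gm(calls, chrom=["chr1", "chr2"])
        pops = pd.Series({"i0": "r1", "i1": "r1"})
        avg = popgen.pi_averages(site_pi(g, pops))
        assert len(avg) == 2
        # all-het site on chr1: 2 ref, 2 alt alleles -> 2/3
        assert avg.loc[avg.chromosome == "chr1", "pi"].iloc[0] == \
            pytest.approx(2 / 3)
        assert avg.loc[avg.chromosome == "chr2", "pi"].iloc[0] == 0.0


class TestFis:
    def test_all_het_locus_closed_form(self):
        # at n=20: FIS = 1 - 1/(0.5*40/39) per locus
        calls = np.full((20, 1), CALL_HET)
        g = _gm(calls)
        out = fis(g, n_boot=10, seed=0)
        assert out["fis"].iloc[0] == pytest.approx(1 - 1 / (0.5 * 40 / 39))

    def test_hardy_weinberg_near_zero(self):
        # 4 hom_ref, 4 het, ... exact HWE counts at p=0.5: 25/50/25
        calls = np.array([[CALL_HOM_REF]] * 5 + [[CALL_HET]] * 10
                         + [[CALL_HOM_ALT]] * 5, dtype=np.int8)
        g = _gm(calls)
        out = fis(g, n_boot=10, seed=0)
        # Ho = 0.5 = 2pq; small-sample correction leaves a slight offset
        assert abs(out["fis"].iloc[0]) < 0.05

    def test_monomorphic_population_missing(self):
        calls = np.full((5, 2), CALL_HOM_REF)
        out = fis(_gm(calls), n_boot=10, seed=0)
        assert np.isnan(out["fis"].iloc[0])

    def test_bootstrap_ci_brackets_point(self, sim_dataset):
        g = sim_dataset.genotypes
        pops = pd.Series({i: sim_dataset.asv_table.metadata.at[i, "river"]
                          for i in g.individuals})
        out = fis(g, pops, n_boot=200, seed=1)
        assert ((out["ci_low"] <= out["fis"])
                & (out["fis"] <= out["ci_high"])).all()
        assert (out["fis"] < -0.3).all()  # clonal excess heterozygosity


class TestRemoveFixedHet:
    def test_all_het_removed_strictly(self):
        calls = np.full((30, 2), CALL_HET)
        calls[0, 1] = CALL_HOM_REF  # het in 29/30 -> retained
        g2, removed = remove_fixed_het(_gm(calls))
        assert removed == 1
        assert g2.n_loci == 1 and g2.pos.tolist() == [200]

    def test_missing_calls_ignored_in_fixedness(self):
        calls = np.full((10, 1), CALL_HET)
        calls[3, 0] = CALL_MISSING
        _, removed = remove_fixed_het(_gm(calls))
        assert removed == 1

    def test_planted_count_matches_truth(self, sim_dataset):
        g2, removed = remove_fixed_het(sim_dataset.genotypes)
        assert removed == sim_dataset.truth["n_fixed_het"]

    def test_fis_less_negative_after_removal(self, sim_dataset):
        g = sim_dataset.genotypes
        pops = pd.Series({i: sim_dataset.asv_table.metadata.at[i, "river"]
                          for i in g.individuals})
        before = fis(g, pops, n_boot=10, seed=0)["fis"].mean()
        g2, _ = remove_fixed_het(g)
        after = fis(g2, pops, n_boot=10, seed=0)["fis"].mean()
        assert after > before


class TestThinSnps:
    def test_rule_trace(self):
        g = _gm(np.zeros((2, 3)), pos=[100, 600, 1500])
        out = thin_snps(g, window_bp=1000)
        assert out.pos.tolist() == [100, 1500]

    def test_boundary_inclusive(self):
        g = _gm(np.zeros((2, 2)), pos=[100, 1100])
        assert thin_snps(g, 1000).pos.tolist() == [100, 1100]

    def test_single_snp_kept(self):
        g = _gm(np.zeros((2, 1)), pos=[42])
        assert thin_snps(g).n_loci == 1

    def test_per_chromosome_reset(self):
        g = _gm(np.zeros((2, 4)), chrom=["c1", "c1", "c2", "c2"],
                pos=[100, 500, 100, 500])
        assert thin_snps(g, 1000).n_loci == 2

    def test_unsorted_rejected(self):
        g = _gm(np.zeros((2, 2)), pos=[100, 1100])
        g.pos = np.array([1100, 100])
        with pytest.raises(ValueError):
            thin_snps(g)


class TestAllelicDistance:
    def test_identical_rows_zero(self):
        calls = np.array([[0, 1, 2], [0, 1, 2]], dtype=np.int8)
        d = allelic_distance(_gm(calls))
        assert d["i0", "i1"] == 0.0

    def test_opposite_homozygotes(self):
        d = allelic_distance(_gm([[CALL_HOM_REF], [CALL_HOM_ALT]]))
        assert d["i0", "i1"] == 1.0

    def test_per_locus_half_steps(self):
        # (AA, Aa) vs (Aa, Aa): (0.5 + 0)/2
        d = allelic_distance(_gm([[CALL_HOM_REF, CALL_HET],
                                  [CALL_HET, CALL_HET]]))
        assert d["i0", "i1"] == pytest.approx(0.25)

    def test_equals_halved_dosage_hamming(self, rng):
        calls = rng.integers(0, 3, size=(6, 40)).astype(np.int8)
        d = allelic_distance(_gm(calls))
        manual = np.abs(calls[:, None, :] - calls[None, :, :]).sum(-1) \
            / (2 * 40)
        np.testing.assert_allclose(d.data, manual, atol=1e-12)

    def test_missing_pairs_use_cotyped_loci(self):
        calls = np.array([[CALL_HOM_REF, CALL_HOM_ALT],
                          [CALL_MISSING, CALL_HOM_REF]], dtype=np.int8)
        d = allelic_distance(_gm(calls))
        assert d["i0", "i1"] == pytest.approx(1.0)  # only locus 2 co-typed


class TestPairwiseFst:
    def test_fixed_difference_theta_one(self):
        calls = np.vstack([np.full((10, 50), CALL_HOM_REF),
                           np.full((10, 50), CALL_HOM_ALT)]).astype(np.int8)
        g = _gm(calls)
        pops = pd.Series(["p1"] * 10 + ["p2"] * 10,
                         index=[f"i{k}" for k in range(20)])
        dm, tab = pairwise_fst(g, pops, n_boot=50, seed=0)
        assert tab["theta"].iloc[0] == pytest.approx(1.0)

    def test_hand_computed_two_pop_one_locus(self):
        # pop1 (n=6): 2 hom_alt, 3 het, 1 hom_ref -> p=7/12, Ho=1/2
        # pop2 (n=4): 1 hom_alt, 1 het, 2 hom_ref -> p=3/8, Ho=1/4
        # exact WC84 components: a=-15/1024, b=143/1920, c=1/5
        calls = np.array([[CALL_HOM_ALT]] * 2 + [[CALL_HET]] * 3
                         + [[CALL_HOM_REF]] + [[CALL_HOM_ALT]]
                         + [[CALL_HET]] + [[CALL_HOM_REF]] * 2,
                         dtype=np.int8)
        g = _gm(calls)
        pops = pd.Series(["p1"] * 6 + ["p2"] * 4,
                         index=[f"i{k}" for k in range(10)])
        _, tab = pairwise_fst(g, pops, n_boot=10, seed=0)
        assert tab["theta"].iloc[0] == pytest.approx(-225 / 3991, abs=1e-12)

    def test_panmictic_null_mostly_nonsignificant(self):
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(500 + rep)
            p = rng.uniform(0.2, 0.8, 80)
            calls = rng.binomial(2, p, size=(16, 80)).astype(np.int8)
            g = _gm(calls)
            pops = pd.Series(["p1"] * 8 + ["p2"] * 8,
                             index=[f"i{k}" for k in range(16)])
            _, tab = pairwise_fst(g, pops, n_boot=200, seed=rep)
            hits += tab["boot_p"].iloc[0] > 0.05
        assert hits >= 9

    def test_population_of_one_rejected(self):
        g = _gm(np.zeros((3, 5)))
        pops = pd.Series(["a", "b", "b"], index=["i0", "i1", "i2"])
        with pytest.raises(ValueError):
            pairwise_fst(g, pops)

    def test_theta_monotone_in_divergence(self):
        means = []
        for dv in (0.01, 0.05, 0.15):
            vals = []
            for seed in (1, 2, 3):
                cfg = small_config(seed=seed, river_divergence=dv,
                                   n_snps=300, n_monomorphic=50,
                                   fixed_het_fraction=0.0)
                ds = simulate_dataset(cfg)
                g = ds.genotypes
                alt = np.where(g.calls != CALL_MISSING, g.calls, 0).sum(0)
                tot = 2.0 * (g.calls != CALL_MISSING).sum(0)
                poly = (alt > 0) & (alt < tot)
                pops = pd.Series(
                    {i: ds.asv_table.metadata.at[i, "river"]
                     for i in g.individuals})
                _, tab = pairwise_fst(g.subset_loci(poly), pops,
                                      n_boot=10, seed=seed)
                vals.append(tab["theta"].mean())
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestGeneticsMicrobiomeCorrelation:
    def test_identical_matrices_all_significant(self, rng):
        from scipy.spatial.distance import pdist, squareform
        from skbio import DistanceMatrix
        ids = [f"i{k}" for k in range(12)]
        d = squareform(pdist(rng.normal(size=(12, 2))))
        dm = DistanceMatrix(d, ids=ids)
        rivers = pd.Series(["r1"] * 6 + ["r2"] * 6, index=ids)
        out = popgen.genetics_microbiome_correlation(dm, dm, rivers,
                                                     n_perm=199, seed=0)
        assert out["global_mantel"].statistic == pytest.approx(1.0)
        assert out["global_mantel"].p_value <= 0.05
        assert out["within_river_spearman"].statistic == pytest.approx(1.0)

    def test_filter_chain_counts_additive(self, sim_dataset, tmp_path):
        from invamicro.io_formats import FilterConfig, read_vcf
        vcf = tmp_path / "g.vcf"
        sim_dataset.write_vcf(vcf)
        g = read_vcf(vcf, FilterConfig())
        log = g.filter_log
        removed = (log["indel"] + log["allele_count"] + log["missingness"]
                   + log["quality"] + log["maf"])
        assert log["input"] == log["retained"] + removed
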