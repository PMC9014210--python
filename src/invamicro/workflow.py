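"""End-to-end orchestration of the comparative analysis.

``full_analysis`` runs every stage of the pipeline on one dataset bundle --
rarefaction, alpha diversity, UniFrac structure with PERMANOVA / dispersion
/ envfit / distance decay, host co-variation, functional dissimilarity and
degradation potential, reciprocal source attribution, and the population-
genomic chain with its genetics-vs-microbiome tests -- and returns the
headline statistics in one nested dictionary.  It is the programmatic
equivalent of running every CLI stage in sequence.
"""

from __future__ import annotations

import logging
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import (alpha_div, beta_div, degpot, io_formats, multivar_stats as ms,
               popgen, source_track)
from .simdata import SimDataset

logger = logging.getLogger(__name__)


def _unifrac_metric(tree):
    """Site-profile dissimilarity callable for the co-variation test."""
    def metric(df: pd.DataFrame):
        counts = (df * 10 ** 9).round().astype(np.int64)
        md = pd.DataFrame({"host_species": "mean", "site": df.index,
                           "river": "r", "host_type": "invasive"},
                          index=df.index)
        return beta_div.unifrac(io_formats.CountTable(counts, md), tree,
                                weighted=False)
    return metric


def full_analysis(ds: SimDataset, seed: int, bivalve_depth: int = 4000,
                  env_depth: int = 2000, n_perm: int = 999,
                  n_perm_pairwise: int = 199, n_covary_reps: int = 500,
                  feast_restarts: int = 3, n_boot: int = 1000,
                  vcf_path: str | Path | None = None) -> dict:
    """Run the full comparative analysis on one dataset bundle."""
    rng = np.random.default_rng(seed)

    def subseed() -> int:
        return int(rng.integers(2 ** 31))

    out: dict = {"seed": seed}
    table = ds.asv_table
    md = table.metadata
    bivalves = md.index[md.host_type.isin(["invasive", "native_mussel"])]
    env_samples = md.index[md.host_type.isin(["seston", "sediment"])]

    # rarefaction: bivalves and environmental samples at their own depths
    rare_biv = alpha_div.rarefy(table.subset_samples(bivalves),
                                bivalve_depth, seed=subseed())
    rare_env = alpha_div.rarefy(table.subset_samples(env_samples),
                                env_depth, seed=subseed())
    rare_all = io_formats.CountTable(
        pd.concat([rare_biv.counts, rare_env.counts]),
        pd.concat([rare_biv.metadata, rare_env.metadata]))
    bmd = rare_biv.metadata
    inv = bmd.index[bmd.host_type == "invasive"]
    nat = bmd.index[bmd.host_type == "native_mussel"]

    # ---- alpha diversity ------------------------------------------------
    adf = alpha_div.alpha_diversity_table(rare_biv, ds.tree)
    out["alpha"] = {
        "coverage_mean": float(adf["coverage"].mean()),
        "coverage_sd": float(adf["coverage"].std()),
        "faith_pd_invasive": float(adf.loc[inv, "faith_pd"].mean()),
        "faith_pd_native": float(adf.loc[nat, "faith_pd"].mean()),
        "shannon_invasive": float(adf.loc[inv, "shannon_effective"].mean()),
        "shannon_native": float(adf.loc[nat, "shannon_effective"].mean()),
        "wilcoxon_faith_pd": ms.group_compare(
            adf.loc[list(inv) + list(nat), "faith_pd"].to_numpy(),
            ["inv"] * len(inv) + ["nat"] * len(nat),
            test="wilcoxon_ranksum").p_value,
    }

    # ---- shared ASVs ----------------------------------------------------
    shared = {}
    inv_sp = ds.config.invasive_species
    for sp in ds.config.native_species:
        df = alpha_div.shared_fraction_by_site(rare_all, inv_sp, sp)
        if len(df):
            shared[sp] = float(df["frac_b_shared"].mean())
    out["shared_asv_fraction_native_with_invasive"] = shared

    # ---- community structure -------------------------------------------
    wu = beta_div.unifrac(rare_biv, ds.tree, weighted=True)
    uu = beta_div.unifrac(rare_biv, ds.tree, weighted=False)
    pair_iv = np.ix_([list(wu.ids).index(i) for i in inv],
                     [list(wu.ids).index(i) for i in nat])
    out["beta"] = {
        "mean_wunifrac_inv_vs_native": float(wu.data[pair_iv].mean()),
        "mean_uunifrac_inv_vs_native": float(uu.data[pair_iv].mean()),
    }
    species_labels = bmd["host_species"]
    inv_vs_nat = bmd["host_type"]
    for name, dm in (("wunifrac", wu), ("uunifrac", uu)):
        res = ms.permanova(dm, inv_vs_nat, n_perm=n_perm, seed=subseed())
        out["beta"][f"permanova_invasive_vs_native_{name}_r2"] = res.r2
        out["beta"][f"permanova_invasive_vs_native_{name}_p"] = res.p_value
        res_sp = ms.permanova(dm, species_labels, n_perm=n_perm,
                              seed=subseed())
        out["beta"][f"permanova_species_{name}_r2"] = res_sp.r2
        out["beta"][f"permanova_species_{name}_p"] = res_sp.p_value
    inv_table = rare_biv.subset_samples(inv)
    wu_inv = beta_div.unifrac(inv_table, ds.tree, weighted=True)
    for label, labels in (("site", inv_table.metadata["site"]),
                          ("river", inv_table.metadata["river"])):
        res = ms.permanova(wu_inv, labels, n_perm=n_perm, seed=subseed())
        out["beta"][f"permanova_invasive_{label}_r2"] = res.r2
        out["beta"][f"permanova_invasive_{label}_p"] = res.p_value
    out["beta"]["dispersion_species_p"] = ms.dispersion_test(
        wu, species_labels, n_perm=n_perm, seed=subseed()).p_value
    pairwise = ms.pairwise_permanova(wu, species_labels,
                                     n_perm=n_perm_pairwise, seed=subseed())
    out["beta"]["pairwise_n_significant"] = int(
        sum(r.adjusted_p <= 0.05 for r in pairwise))
    out["beta"]["pairwise_n_pairs"] = len(pairwise)

    # ---- environment fitting -------------------------------------------
    ord_inv = beta_div.pcoa(wu_inv)
    ef = ms.envfit(ord_inv, ds.env, inv_table.metadata["site"],
                   n_perm=n_perm, seed=subseed())
    out["envfit_invasive"] = {
        v: {"r2": r.r2, "p": r.p_value} for v, r in ef.items()
        if r.r2 is not None and not np.isnan(r.statistic)}

    # ---- distance decay along rivers -----------------------------------
    site_of = inv_table.metadata["site"]
    geo = ds.river_distances
    geo_ind = np.array([[geo[site_of[a], site_of[b]] for b in inv]
                        for a in inv])
    from skbio import DistanceMatrix
    dd = ms.distance_decay(wu_inv, DistanceMatrix(geo_ind, ids=list(inv)),
                           inv_table.metadata["river"], n_perm=n_perm,
                           seed=subseed())
    out["distance_decay"] = {"rho": dd.statistic, "perm_p": dd.p_value,
                             "naive_p": dd.extra["naive_p"]}

    # ---- host co-variation (repeated-subsampling Mantel) ---------------
    cov = ms.covariation_median_mantel(
        rare_biv, inv, nat, metric=_unifrac_metric(ds.tree),
        n_reps=n_covary_reps, n_perm=199, seed=subseed())
    out["covariation"] = {"median_p_uunifrac": cov["median_p"],
                          "rho_mean": float(np.mean(cov["rho"]))}

    # ---- predicted function --------------------------------------------
    fdm = beta_div.functional_dissimilarity(ds.pathway_table)
    res = ms.permanova(fdm, md["host_type"].isin(["invasive"]).map(
        {True: "invasive", False: "other"}), n_perm=n_perm, seed=subseed())
    out["function"] = {"permanova_invasive_r2": res.r2,
                       "permanova_invasive_p": res.p_value}

    # ---- degradation potential -----------------------------------------
    pdm = degpot.pathway_dissimilarity(ds.pathway_map, ds.compound_dissim)
    dendro = degpot.build_dendrogram(pdm)
    deg = ds.pathway_map.degradation_pathways()
    scores, _ = degpot.degradation_potential(
        ds.pathway_table.subset_features(deg), dendro)
    inv_all = md.index[md.host_type == "invasive"]
    nat_all = md.index[md.host_type == "native_mussel"]
    out["degradation_potential"] = {
        "invasive_mean": float(scores.loc[inv_all,
                                          "structural_richness"].mean()),
        "native_mean": float(scores.loc[nat_all,
                                        "structural_richness"].mean()),
        "wilcoxon_p": ms.group_compare(
            scores.loc[list(inv_all) + list(nat_all),
                       "structural_richness"].to_numpy(),
            ["inv"] * len(inv_all) + ["nat"] * len(nat_all),
            test="wilcoxon_ranksum").p_value,
    }

    # ---- reciprocal source attribution ---------------------------------
    feast = {}
    for direction, focal in (("native_sink", "invasive"),
                             ("invasive_sink", "native_mussel")):
        ests = source_track.run_design(rare_all, direction,
                                       n_restarts=feast_restarts,
                                       seed=subseed())
        summary, kw = source_track.aggregate_contributions(
            ests, rare_all, grouping="recipient_species"
            if direction == "native_sink" else "site")
        contribs = []
        for est in ests:
            s = est.as_series()
            contribs.append(sum(
                a for src, a in s.items() if src != "unknown"
                and rare_all.metadata.at[src, "host_type"] == focal))
        feast[direction] = {
            "mean_pct": float(100 * np.mean(contribs)),
            "sd_pct": float(100 * np.std(contribs)),
            "kw_p": kw.p_value,
            "n_sinks": len(ests),
        }
    out["source_tracking"] = feast

    # ---- population genomics -------------------------------------------
    if vcf_path is None:
        tmp = tempfile.TemporaryDirectory()
        vcf_path = Path(tmp.name) / "genotypes.vcf"
        ds.write_vcf(vcf_path)
    pops = pd.Series({i: md.at[i, "river"]
                      for i in ds.genotypes.individuals})
    g_pi = io_formats.read_vcf(vcf_path,
                               io_formats.FilterConfig(keep_monomorphic=True))
    pi_avg = popgen.pi_averages(popgen.site_pi(g_pi, pops))
    g = io_formats.read_vcf(vcf_path, io_formats.FilterConfig())
    fis_tab = popgen.fis(g, pops, n_boot=n_boot, seed=subseed())
    g2, n_fixed = popgen.remove_fixed_het(g)
    g3 = popgen.thin_snps(g2)
    d_gen = popgen.allelic_distance(g3)
    fst_dm, fst_tab = popgen.pairwise_fst(g3, pops, n_boot=n_boot,
                                          seed=subseed())
    out["popgen"] = {
        "pi_mean": float(pi_avg["pi"].mean()),
        "fis_mean": float(fis_tab["fis"].mean()),
        "fis_min": float(fis_tab["fis"].min()),
        "fis_max": float(fis_tab["fis"].max()),
        "n_sites_pi_branch": int(g_pi.n_loci),
        "n_variant_snps": int(g.n_loci),
        "n_fixed_het_removed": int(n_fixed),
        "n_snps_final": int(g3.n_loci),
        "fst_mean": float(fst_tab["theta"].mean()),
        "fst_n_significant": int((fst_tab["boot_p"] <= 0.05).sum()),
        "fst_n_pairs": len(fst_tab),
    }

    # ---- genetics vs microbiome ----------------------------------------
    shared_ids = [i for i in d_gen.ids if i in set(wu_inv.ids)]
    site_avg = beta_div.site_averaged_profiles(rare_biv, inv)
    uu_sites = beta_div.unifrac(site_avg, ds.tree, weighted=False)
    # average site-level UniFrac per river pair to go with FST populations
    rivers = sorted(set(pops))
    site_river = {s: site_avg.metadata.at[s, "river"]
                  for s in site_avg.sample_ids}
    rv_mat = np.zeros((len(rivers), len(rivers)))
    for i, r1 in enumerate(rivers):
        for j, r2 in enumerate(rivers):
            if i >= j:
                continue
            vals = [uu_sites[a, b] for a in uu_sites.ids
                    for b in uu_sites.ids
                    if site_river[a] == r1 and site_river[b] == r2]
            rv_mat[i, j] = rv_mat[j, i] = float(np.mean(vals))
    from skbio import DistanceMatrix as DM
    corr = popgen.genetics_microbiome_correlation(
        d_gen.filter(shared_ids), wu_inv.filter(shared_ids),
        inv_table.metadata["river"],
        fst_matrix=fst_dm.filter(rivers),
        site_avg_micro=DM(rv_mat, ids=rivers),
        n_perm=n_perm, seed=subseed())
    out["genetics_microbiome"] = {
        "global_mantel_rho": corr["global_mantel"].statistic,
        "global_mantel_p": corr["global_mantel"].p_value,
        "within_river_rho": corr["within_river_spearman"].statistic,
        "within_river_perm_p": corr["within_river_spearman"].p_value,
        "population_mantel_p": corr["population_mantel"].p_value,
    }
    return out
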