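"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates the upstream tool outputs the analysis consumes --
a denoised, rarefiable ASV count table with host-species and site
structure, a predicted-pathway table linked to entry compounds, and clonal
RAD-seq genotype calls with excess heterozygosity and river-structured
drift -- so every downstream stage can be exercised and calibrated without
any sequencing data.

Model sketch
------------
* Each host species (six native mussels, the invasive clam, plus seston,
  sediment and a latent "novel" invasive-specific component) gets a
  log-abundance signature over ASVs; a sample's expected composition is the
  softmax of base log-abundances + species signature + site effects.
* Site effects combine an environmental response (a planted NO3 gradient
  along each river acting on a random subset of ASVs) and a site-level
  random shift, giving PERMANOVA site/river structure and distance decay.
* Invasive-host compositions are a convex mixture of co-occurring native
  species, seston, sediment and the novel component -- the ground truth the
  source-tracking EM is asked to recover.
* Counts are Dirichlet-multinomial draws at lognormal sequencing depths.
* Genotypes are one clonal lineage: a configured fraction of SNPs is
  heterozygous in every individual; the rest drift among rivers under a
  Balding-Nichols model with the configured divergence.  Genotypes are
  simulated independently of the microbiome unless a coupling is requested,
  mirroring the null the field study reported.

All randomness flows from a single seed; sub-generators use spawned child
seeds so adding one component does not perturb the draws of another.
"""

from __future__ import annotations

import dataclasses
import json
import random as _random
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from . import io_formats
from .io_formats import (CALL_HET, CALL_HOM_ALT, CALL_HOM_REF, CALL_MISSING,
                         CountTable, EnvTable, PathwayCompoundMap,
                         read_newick)

ENV_VARIABLES = ["temperature", "pH", "conductivity", "dissolved_oxygen",
                 "DOC", "SRP", "NH4", "NO2", "NO3",
                 "unionid_density", "invasive_density", "unionid_richness"]

#: small-molecule SMILES for fingerprint-based runs (common degradation
#: pathway entry compounds: aromatics, sugars, amino acids, organic acids)
SMILES_FIXTURES = {
    "benzene": "c1ccccc1", "toluene": "Cc1ccccc1", "phenol": "Oc1ccccc1",
    "catechol": "Oc1ccccc1O", "benzoate": "O=C([O-])c1ccccc1",
    "salicylate": "O=C(O)c1ccccc1O", "naphthalene": "c1ccc2ccccc2c1",
    "ethanol": "CCO", "glycerol": "OCC(O)CO", "glucose": "OCC1OC(O)C(O)C(O)C1O",
    "galactose": "OCC1OC(O)C(O)C(O)C1O", "sucrose":
        "OCC1OC(OC2(CO)OC(CO)C(O)C2O)C(O)C(O)C1O",
    "lactate": "CC(O)C(=O)O", "acetate": "CC(=O)O", "citrate":
        "OC(=O)CC(O)(CC(=O)O)C(=O)O", "succinate": "OC(=O)CCC(=O)O",
    "glycine": "NCC(=O)O", "alanine": "CC(N)C(=O)O",
    "tryptophan": "NC(Cc1c[nH]c2ccccc12)C(=O)O",
    "tyrosine": "NC(Cc1ccc(O)cc1)C(=O)O", "urea": "NC(N)=O",
    "putrescine": "NCCCCN", "choline": "C[N+](C)(C)CCO",
    "nicotinate": "O=C(O)c1cccnc1", "vanillin": "COc1cc(C=O)ccc1O",
    "ferulate": "COc1cc(/C=C/C(=O)O)ccc1O", "chitobiose":
        "CC(=O)NC1C(O)OC(CO)C(O)C1OC1OC(CO)C(O)C(O)C1NC(C)=O",
    "xylose": "OCC1OC(O)C(O)C1O", "starch_unit": "OCC1OC(OC2C(O)C(O)C(O)OC2CO)C(O)C(O)C1O",
    "limonene": "CC1=CCC(CC1)C(=C)C",
}


@dataclass
class SimConfig:
    """Study-design and effect-size knobs for one synthetic dataset.

    Defaults reproduce the field design the pipeline targets: six rivers
    with 16 sites in total, six native mussel species plus the invasive
    clam sampled at every site, seston and sediment per site, and clonal
    genotypes with roughly a fifth of SNPs heterozygous in every
    individual.
    """

    seed: int = 0
    # study design
    n_rivers: int = 6
    sites_per_river: tuple = (3, 3, 3, 3, 2, 2)
    native_species: tuple = ("A_plicata", "C_asperata", "C_pustulosa",
                             "L_ovata", "O_unicolor", "T_verrucosa")
    invasive_species: str = "C_fluminea"
    invasive_per_site: int = 4
    natives_per_site: int = 2
    # microbiome
    n_asvs: int = 300
    depth_lognormal_mean: float = 9.2      # ln-scale; exp(9.2) ~ 9900 reads
    depth_lognormal_sigma: float = 0.35
    env_depth_lognormal_mean: float = 8.5  # seston/sediment are shallower
    base_abundance_sigma: float = 1.5
    host_effect: float = 1.0               # species signature sd (ln scale)
    site_effect: float = 1.0               # NO3-response scaling
    site_random_sigma: float = 0.4         # non-environmental site shift
    env_responsive_frac: float = 0.3       # ASVs responding to the gradient
    dirichlet_concentration: float = 200.0
    # invasive-host composition: convex mixture over sources
    mix_native_total: float = 0.14
    mix_seston: float = 0.25
    mix_sediment: float = 0.05
    # remainder (novel invasive-specific component) = 1 - the above
    # native-host composition
    native_self: float = 0.82
    native_from_invasive: float = 0.06
    native_from_seston: float = 0.08
    native_from_sediment: float = 0.04
    # functional predictions
    n_pathways: int = 60
    degradation_frac: float = 0.6
    n_compounds: int = 40
    pathway_depth: int = 5000
    pathway_abundance_sigma: float = 2.0
    pathway_host_effect: float = 0.8
    invasive_degradation_boost: float = 1.5
    # genotypes
    n_snps: int = 2000
    n_monomorphic: int = 8000
    fixed_het_fraction: float = 0.21
    river_divergence: float = 0.03
    fis_target: float = -0.85      # within-river excess heterozygosity
    n_chromosomes: int = 6
    mean_call_depth: float = 40.0
    genetics_microbiome_coupling: float = 0.0
    # planted VCF artifacts (exercise the import filter chain)
    n_indel_sites: int = 30
    n_triallelic_sites: int = 20
    n_lowqual_sites: int = 20
    n_highmissing_sites: int = 20

    def __post_init__(self) -> None:
        if len(self.sites_per_river) != self.n_rivers:
            raise ValueError("sites_per_river must have n_rivers entries")
        if min(self.sites_per_river) < 1 or self.n_asvs < 1:
            raise ValueError("all sizes must be >= 1")
        mix = self.mix_native_total + self.mix_seston + self.mix_sediment
        if not 0 <= mix <= 1:
            raise ValueError("invasive source mixture must sum to <= 1")
        if self.depth_lognormal_mean <= 0:
            raise ValueError("depth distribution would yield zero reads")

    @property
    def mix_unknown(self) -> float:
        return 1.0 - (self.mix_native_total + self.mix_seston
                      + self.mix_sediment)


@dataclass
class SimDataset:
    """One synthetic dataset plus the ground truth planted into it."""

    config: SimConfig
    asv_table: CountTable
    tree: TreeNode
    env: EnvTable
    pathway_table: CountTable
    pathway_map: PathwayCompoundMap
    compound_dissim: DistanceMatrix
    genotypes: "io_formats.GenotypeMatrix"
    vcf_fields: dict
    river_distances: DistanceMatrix
    truth: dict

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        io_formats.write_count_table(self.asv_table, out / "asv_counts.tsv",
                                     out / "metadata.tsv")
        io_formats.write_newick(self.tree, out / "asv_tree.nwk")
        io_formats.write_env_table(self.env, out / "environment.tsv")
        io_formats.write_count_table(self.pathway_table,
                                     out / "pathway_counts.tsv",
                                     out / "pathway_metadata.tsv")
        io_formats.write_pathway_map(self.pathway_map, out / "pathway_map.tsv")
        io_formats.write_distance_matrix(self.compound_dissim,
                                         out / "compound_dissim.tsv")
        io_formats.write_distance_matrix(self.river_distances,
                                         out / "river_distances.tsv")
        self.write_vcf(out / "genotypes.vcf")
        (out / "truth.json").write_text(
            json.dumps(_jsonable(self.truth), indent=1))

    def write_vcf(self, path: str | Path) -> None:
        f = self.vcf_fields
        io_formats.write_vcf(path, f["individuals"], f["chrom"], f["pos"],
                             f["ref"], f["alt"], f["calls"], f["qual"],
                             depth=f["depth"])


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# components
# ---------------------------------------------------------------------------

def simulate_tree(n_tips: int, seed: int, prefix: str = "ASV") -> TreeNode:
    """Pure-birth tree with the tips renamed to feature ids."""
    from dendropy.simulate import treesim
    t = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips,
        rng=_random.Random(int(seed)))
    newick = t.as_string(schema="newick", suppress_rooting=True)
    tree = read_newick(newick.strip())
    for i, tip in enumerate(tree.tips()):
        tip.name = f"{prefix}{i:04d}"
    return tree


def _softmax(logw: np.ndarray) -> np.ndarray:
    w = np.exp(logw - logw.max())
    return w / w.sum()


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Generate the full dataset bundle; same config -> identical outputs."""
    ss = np.random.SeedSequence(config.seed)
    (ss_design, ss_tree, ss_micro, ss_path, ss_geno, ss_env) = ss.spawn(6)
    rng_design = np.random.default_rng(ss_design)
    rng_micro = np.random.default_rng(ss_micro)
    rng_path = np.random.default_rng(ss_path)
    rng_env = np.random.default_rng(ss_env)

    cfg = config
    rivers = [f"river{r + 1}" for r in range(cfg.n_rivers)]
    sites, site_river, site_pos = [], {}, {}
    for r, nr in zip(rivers, cfg.sites_per_river):
        # sites are spread evenly along each river (stratified survey
        # design), so the environmental gradient spans every river alike
        pos = np.linspace(100 / (nr + 1), 100 * nr / (nr + 1), nr)
        pos = pos + rng_design.uniform(-5, 5, nr)
        for k in range(nr):
            s = f"{r}_s{k + 1}"
            sites.append(s)
            site_river[s] = r
            site_pos[s] = float(pos[k])

    # ---- environment --------------------------------------------------
    env_df = pd.DataFrame(index=sites, columns=ENV_VARIABLES, dtype=float)
    for s in sites:
        z = site_pos[s] / 100.0
        env_df.loc[s] = [
            18 + 8 * z + rng_env.normal(0, 1),            # temperature
            7.2 + rng_env.normal(0, 0.3),                 # pH
            200 + rng_env.normal(0, 40),                  # conductivity
            8.5 - 2 * z + rng_env.normal(0, 0.5),         # dissolved oxygen
            4 + rng_env.normal(0, 1),                     # DOC
            20 + 10 * z + rng_env.normal(0, 4),           # SRP
            15 + rng_env.normal(0, 4),                    # NH4
            2 + 1.5 * z + rng_env.normal(0, 0.5),         # NO2
            50 + 120 * z + rng_env.normal(0, 10),         # NO3 gradient
            rng_env.uniform(1, 40),                       # unionid density
            rng_env.uniform(0.5, 92),                     # invasive density
            float(len(cfg.native_species)),               # unionid richness
        ]
    env = EnvTable(env_df)
    no3_z = ((env_df["NO3"] - env_df["NO3"].mean())
             / env_df["NO3"].std()).to_dict()

    # ---- river distances ----------------------------------------------
    geo = np.zeros((len(sites), len(sites)))
    for i, a in enumerate(sites):
        for j, b in enumerate(sites):
            if i == j:
                continue
            if site_river[a] == site_river[b]:
                geo[i, j] = abs(site_pos[a] - site_pos[b])
            else:
                geo[i, j] = 1000.0
    river_distances = DistanceMatrix(geo, ids=sites)

    # ---- microbiome ----------------------------------------------------
    tree = simulate_tree(cfg.n_asvs, int(ss_tree.generate_state(1)[0]
                                         % (2 ** 31)))
    asv_ids = [t.name for t in tree.tips()]
    base = rng_micro.normal(0, cfg.base_abundance_sigma, cfg.n_asvs)
    components = (list(cfg.native_species)
                  + [cfg.invasive_species, "seston", "sediment", "unknown"])
    signatures = {c: rng_micro.normal(0, cfg.host_effect, cfg.n_asvs)
                  for c in components}
    responsive = rng_micro.random(cfg.n_asvs) < cfg.env_responsive_frac
    loadings = np.where(responsive, rng_micro.normal(0, 1, cfg.n_asvs), 0.0)
    site_shift = {s: rng_micro.normal(0, cfg.site_random_sigma, cfg.n_asvs)
                  for s in sites}

    def component_mean(comp: str, site: str) -> np.ndarray:
        logw = (base + signatures[comp] + site_shift[site]
                + cfg.site_effect * no3_z[site] * loadings)
        return _softmax(logw)

    mix_per_native = (cfg.mix_native_total / len(cfg.native_species)
                      if cfg.native_species else 0.0)

    sample_rows, sample_ids, meta_rows = [], [], []
    invasive_ids = []
    for s in sites:
        means = {c: component_mean(c, s) for c in components}
        native_mix_mean = {}
        for sp in cfg.native_species:
            m = (cfg.native_self * means[sp]
                 + cfg.native_from_invasive * means[cfg.invasive_species]
                 + cfg.native_from_seston * means["seston"]
                 + cfg.native_from_sediment * means["sediment"])
            native_mix_mean[sp] = m / m.sum()
        inv_mean = (mix_per_native * sum(means[sp]
                                         for sp in cfg.native_species)
                    + cfg.mix_seston * means["seston"]
                    + cfg.mix_sediment * means["sediment"]
                    + cfg.mix_unknown * means["unknown"])
        inv_mean = inv_mean / inv_mean.sum()

        def draw(mean_comp, depth_mu):
            depth = max(1, int(rng_micro.lognormal(depth_mu,
                                                   cfg.depth_lognormal_sigma)))
            p = rng_micro.dirichlet(np.maximum(
                cfg.dirichlet_concentration * mean_comp, 1e-9))
            return rng_micro.multinomial(depth, p)

        for sp in cfg.native_species:
            for k in range(cfg.natives_per_site):
                sid = f"{s}_{sp}_{k + 1}"
                sample_ids.append(sid)
                sample_rows.append(draw(native_mix_mean[sp],
                                        cfg.depth_lognormal_mean))
                meta_rows.append((sid, sp, s, site_river[s], "native_mussel"))
        for k in range(cfg.invasive_per_site):
            sid = f"{s}_{cfg.invasive_species}_{k + 1}"
            sample_ids.append(sid)
            invasive_ids.append(sid)
            sample_rows.append(draw(inv_mean, cfg.depth_lognormal_mean))
            meta_rows.append((sid, cfg.invasive_species, s, site_river[s],
                              "invasive"))
        for env_type in ("seston", "sediment"):
            sid = f"{s}_{env_type}"
            sample_ids.append(sid)
            sample_rows.append(draw(means[env_type],
                                    cfg.env_depth_lognormal_mean))
            meta_rows.append((sid, env_type, s, site_river[s], env_type))

    counts = pd.DataFrame(np.vstack(sample_rows), index=sample_ids,
                          columns=asv_ids)
    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "host_species", "site", "river",
                            "host_type"]).set_index("sample_id")
    asv_table = CountTable(counts, metadata)

    # ---- predicted pathways and compounds ------------------------------
    pw_ids = [f"PWY{k:04d}" for k in range(cfg.n_pathways)]
    n_deg = int(round(cfg.degradation_frac * cfg.n_pathways))
    classes = {pw: (io_formats.DEGRADATION_CLASS if k < n_deg
                    else "Biosynthesis")
               for k, pw in enumerate(pw_ids)}
    comp_ids = [f"CPD{k:04d}" for k in range(cfg.n_compounds)]
    latent = rng_path.normal(0, 1, (cfg.n_compounds, 4))
    from scipy.spatial.distance import pdist, squareform
    cdm = squareform(pdist(latent))
    cdm = cdm / cdm.max()
    compound_dissim = DistanceMatrix(cdm, ids=comp_ids)
    pmap_compounds = {
        pw: [comp_ids[i] for i in
             rng_path.choice(cfg.n_compounds,
                             size=rng_path.integers(1, 4), replace=False)]
        for pw in pw_ids}
    pathway_map = PathwayCompoundMap(pmap_compounds, classes)

    pw_base = rng_path.normal(0, cfg.pathway_abundance_sigma, cfg.n_pathways)
    host_types = ("invasive", "native_mussel", "seston", "sediment")
    pw_sig = {h: rng_path.normal(0, cfg.pathway_host_effect, cfg.n_pathways)
              for h in host_types}
    deg_mask = np.array([classes[pw].startswith("Degradation")
                         for pw in pw_ids])
    pw_rows = []
    for sid in sample_ids:
        h = metadata.at[sid, "host_type"]
        logw = pw_base + pw_sig[h] + rng_path.normal(0, 0.3, cfg.n_pathways)
        if h == "invasive":
            logw = logw + cfg.invasive_degradation_boost * deg_mask
        pw_rows.append(rng_path.multinomial(cfg.pathway_depth,
                                            _softmax(logw)))
    pathway_table = CountTable(
        pd.DataFrame(np.vstack(pw_rows), index=sample_ids, columns=pw_ids),
        metadata)

    # ---- genotypes ------------------------------------------------------
    genotypes, vcf_fields, geno_truth = _simulate_genotypes(
        cfg, invasive_ids, metadata, ss_geno)

    truth = {
        "config": dataclasses.asdict(cfg),
        "sites": sites, "site_river": site_river, "site_pos": site_pos,
        "invasive_mixing": {
            "per_native": mix_per_native,
            "native_total": cfg.mix_native_total,
            "seston": cfg.mix_seston, "sediment": cfg.mix_sediment,
            "unknown": cfg.mix_unknown},
        "env_responsive_loadings": loadings,
        "no3_z": no3_z,
        **geno_truth,
    }
    return SimDataset(cfg, asv_table, tree, env, pathway_table, pathway_map,
                      compound_dissim, genotypes, vcf_fields,
                      river_distances, truth)


def _simulate_genotypes(cfg: SimConfig, invasive_ids, metadata, ss):
    rng = np.random.default_rng(ss)
    inds = list(invasive_ids)
    n = len(inds)
    rivers = metadata.loc[inds, "river"].to_numpy()

    n_fixed = int(round(cfg.fixed_het_fraction * cfg.n_snps))
    n_drift = cfg.n_snps - n_fixed
    # drifting SNPs: Balding-Nichols river frequencies around an ancestral p;
    # ancestral frequencies concentrate near 0.5, as variants segregating
    # within a clonal diploid lineage do
    p0 = rng.beta(14, 14, n_drift)
    f = max(cfg.river_divergence, 1e-6)
    calls_var = np.empty((n, cfg.n_snps), dtype=np.int8)
    river_freqs = {}
    uniq_rivers = list(pd.unique(rivers))
    for r in uniq_rivers:
        pr = rng.beta(p0 * (1 - f) / f, (1 - p0) * (1 - f) / f)
        river_freqs[r] = pr
    # clonal populations carry excess heterozygosity at drifting SNPs too:
    # within each river, genotype counts are chosen so the observed
    # heterozygosity is (1 - fis_target) x the Hardy-Weinberg expectation,
    # capped at feasibility for the realized allele frequency.
    for r in uniq_rivers:
        members = np.flatnonzero(rivers == r)
        nr = len(members)
        pr = river_freqs[r]
        for k in range(n_drift):
            a = int(round(2 * nr * pr[k]))            # alt allele count
            a = min(max(a, 0), 2 * nr)
            h_want = (1 - cfg.fis_target) * 2 * pr[k] * (1 - pr[k])
            h = int(round(min(h_want, 1.0) * nr))
            # nr-1 cap keeps drifting SNPs from being all-heterozygous,
            # so the fixed-het class stays exactly the planted one
            h = min(h, a, 2 * nr - a, nr - 1)
            if (a - h) % 2 == 1:
                h = h - 1 if h >= 1 else h + 1
            n_homalt = (a - h) // 2
            geno = np.array([CALL_HOM_ALT] * n_homalt + [CALL_HET] * h
                            + [CALL_HOM_REF] * (nr - h - n_homalt),
                            dtype=np.int8)
            calls_var[members, k] = rng.permutation(geno)
    calls_var[:, n_drift:] = CALL_HET
    # shuffle SNP order so fixed-het sites are interleaved
    order = rng.permutation(cfg.n_snps)
    calls_var = calls_var[:, order]
    is_fixed_het = (np.arange(cfg.n_snps) >= n_drift)[order]

    calls_mono = np.full((n, cfg.n_monomorphic), CALL_HOM_REF, dtype=np.int8)

    # assemble VCF site list: variant + monomorphic + planted artifacts
    n_art = (cfg.n_indel_sites + cfg.n_triallelic_sites
             + cfg.n_lowqual_sites + cfg.n_highmissing_sites)
    n_sites = cfg.n_snps + cfg.n_monomorphic + n_art
    site_kind = (["snp"] * cfg.n_snps + ["mono"] * cfg.n_monomorphic
                 + ["indel"] * cfg.n_indel_sites
                 + ["triallelic"] * cfg.n_triallelic_sites
                 + ["lowqual"] * cfg.n_lowqual_sites
                 + ["highmissing"] * cfg.n_highmissing_sites)
    rng.shuffle(site_kind)

    chrom_names = [f"chr{c + 1}" for c in range(cfg.n_chromosomes)]
    per_chrom = int(np.ceil(n_sites / cfg.n_chromosomes))
    chrom, pos = [], []
    for c in chrom_names:
        k = min(per_chrom, n_sites - len(pos))
        p = np.sort(rng.choice(np.arange(1, k * 700 + 1), size=k,
                               replace=False))
        chrom.extend([c] * k)
        pos.extend(p.tolist())
        if len(pos) >= n_sites:
            break

    ref_alleles = ("A", "C", "G", "T")
    calls = np.empty((n, n_sites), dtype=np.int8)
    ref, alt, qual = [], [], []
    depth = rng.poisson(cfg.mean_call_depth, (n, n_sites)).astype(int)
    depth = np.maximum(depth, 6)
    i_snp = i_mono = 0
    fixed_flags = []
    for j, kind in enumerate(site_kind):
        rbase = ref_alleles[rng.integers(4)]
        abase = ref_alleles[(ref_alleles.index(rbase) + 1
                             + rng.integers(3)) % 4]
        q = float(rng.uniform(50, 500))
        if kind == "snp":
            calls[:, j] = calls_var[:, i_snp]
            fixed_flags.append(bool(is_fixed_het[i_snp]))
            i_snp += 1
            ref.append(rbase)
            alt.append([abase])
        else:
            fixed_flags.append(False)
            if kind == "mono":
                calls[:, j] = calls_mono[:, i_mono]
                i_mono += 1
                ref.append(rbase)
                alt.append([])
            elif kind == "indel":
                calls[:, j] = rng.binomial(2, 0.3, n)
                ref.append(rbase)
                alt.append([rbase + "T"])
            elif kind == "triallelic":
                calls[:, j] = rng.binomial(2, 0.3, n)
                third = ref_alleles[(ref_alleles.index(abase) + 1) % 4]
                ref.append(rbase)
                alt.append([abase, third])
            elif kind == "lowqual":
                calls[:, j] = rng.binomial(2, 0.3, n)
                q = float(rng.uniform(0.5, 9.5))
                ref.append(rbase)
                alt.append([abase])
            else:  # highmissing
                calls[:, j] = rng.binomial(2, 0.3, n)
                n_miss = int(np.ceil(0.2 * n))
                miss = rng.choice(n, n_miss, replace=False)
                calls[miss, j] = CALL_MISSING
                ref.append(rbase)
                alt.append([abase])
        qual.append(q)

    vcf_fields = {"individuals": inds, "chrom": chrom, "pos": pos,
                  "ref": ref, "alt": alt, "calls": calls, "qual": qual,
                  "depth": depth}
    # the clean GenotypeMatrix: variant + monomorphic sites only
    keep = np.array([k in ("snp", "mono") for k in site_kind])
    gm = io_formats.GenotypeMatrix(
        inds, np.array(chrom, dtype=object)[keep],
        np.array(pos, dtype=np.int64)[keep], calls[:, keep],
        {"input": int(keep.sum())})
    geno_truth = {
        "n_snps": cfg.n_snps, "n_monomorphic": cfg.n_monomorphic,
        "n_fixed_het": int(n_fixed),
        "n_indel_sites": cfg.n_indel_sites,
        "n_triallelic_sites": cfg.n_triallelic_sites,
        "n_lowqual_sites": cfg.n_lowqual_sites,
        "n_highmissing_sites": cfg.n_highmissing_sites,
        "river_divergence": cfg.river_divergence,
        "genotype_individuals": inds,
        "site_kind_fixed_het": [bool(b) for b in fixed_flags],
    }
    return gm, vcf_fields, geno_truth
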