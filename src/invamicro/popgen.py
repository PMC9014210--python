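"""Population-genomic summaries for a clonal diploid invader.

Operates on filtered :class:`GenotypeMatrix` objects (VCF import and the
site filter chain live in :mod:`invamicro.io_formats`).  The analysis chain
reflects the peculiarities of clonal, androgenetic populations:

* per-site nucleotide diversity (pi), monomorphic sites included, averaged
  per chromosome and river;
* F_IS per population (1 - Hobs/Hexp with small-sample-corrected expected
  heterozygosity, ratio of locus averages) with a loci bootstrap CI --
  strongly negative values are the signature of clonal reproduction with
  fixed heterozygosity;
* removal of SNPs heterozygous in every individual, then positional
  thinning to at most one SNP per window;
* percent-allelic-difference distances between individuals;
* pairwise Weir & Cockerham (1984) theta between populations with a loci
  bootstrap significance test;
* correlation of genetic structure with microbiome structure at the
  individual, within-river, and population (FST vs. site-averaged UniFrac)
  levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .io_formats import CALL_HET, CALL_MISSING, GenotypeMatrix
from .multivar_stats import StatTestResult, distance_decay, mantel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# allele bookkeeping
# ---------------------------------------------------------------------------

def _allele_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(alt allele count, total non-missing allele count) per locus."""
    ok = calls != CALL_MISSING
    alt = np.where(ok, calls, 0).sum(axis=0).astype(float)
    total = 2.0 * ok.sum(axis=0)
    return alt, total


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

def site_pi(g: GenotypeMatrix, populations=None) -> pd.DataFrame:
    """Per-site pi = 2 * c_ref * c_alt / (n * (n-1)) over non-missing alleles.

    Sites with fewer than two non-missing alleles are excluded from the
    averages (logged).  When ``populations`` maps individual -> population,
    pi is computed within each population; otherwise over all individuals.
    Returns a long table (population, chromosome, position, pi).
    """
    pops = _pop_series(g, populations)
    rows = []
    for pop in pd.unique(pops):
        idx = np.flatnonzero(pops == pop)
        calls = g.calls[idx]
        alt, total = _allele_counts(calls)
        valid = total >= 2
        n_excl = int((~valid).sum())
        if n_excl:
            logger.info("site_pi: %d sites with <2 alleles in %s excluded",
                        n_excl, pop)
        ref = total - alt
        with np.errstate(invalid="ignore", divide="ignore"):
            pi = np.where(valid, 2.0 * ref * alt
                          / np.maximum(total * (total - 1.0), 1.0), np.nan)
        for j in np.flatnonzero(valid):
            rows.append((pop, g.chrom[j], int(g.pos[j]), float(pi[j])))
    return pd.DataFrame(rows, columns=["population", "chromosome",
                                       "position", "pi"])


def pi_averages(pi_table: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean of per-site pi per chromosome per population."""
    return (pi_table.groupby(["population", "chromosome"])["pi"]
            .mean().reset_index())


# ---------------------------------------------------------------------------
# F_IS
# ---------------------------------------------------------------------------

def fis(g: GenotypeMatrix, populations=None, n_boot: int = 1000,
        seed: int = 0) -> pd.DataFrame:
    """Per-population F_IS = 1 - mean(Hobs)/mean(Hexp) with bootstrap CI.

    Hexp per locus is the small-sample-corrected gene diversity
    ``2 p q * 2n / (2n - 1)``; monomorphic loci are excluded.  The ratio of
    locus averages (not the average of ratios) is used, and the CI is the
    2.5/97.5 percentile of loci bootstraps.
    """
    pops = _pop_series(g, populations)
    rng = np.random.default_rng(seed)
    rows = []
    for pop in pd.unique(pops):
        idx = np.flatnonzero(pops == pop)
        if len(idx) < 2:
            raise ValueError(f"population {pop!r} has < 2 individuals")
        calls = g.calls[idx]
        ok = calls != CALL_MISSING
        n_ind = ok.sum(axis=0).astype(float)
        alt, total = _allele_counts(calls)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / total
        ho = np.where(n_ind > 0,
                      ((calls == CALL_HET) & ok).sum(axis=0) / n_ind, np.nan)
        he = 2.0 * p * (1.0 - p) * total / np.maximum(total - 1.0, 1.0)
        poly = (p > 0) & (p < 1) & (n_ind >= 1)
        if poly.sum() == 0:
            rows.append((pop, np.nan, np.nan, np.nan, 0))
            continue
        ho_p, he_p = ho[poly], he[poly]
        point = 1.0 - ho_p.mean() / he_p.mean()
        boots = np.empty(n_boot)
        nl = len(ho_p)
        for b in range(n_boot):
            sel = rng.integers(0, nl, nl)
            boots[b] = 1.0 - ho_p[sel].mean() / he_p[sel].mean()
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append((pop, float(point), float(lo), float(hi), int(nl)))
    return pd.DataFrame(rows, columns=["population", "fis", "ci_low",
                                       "ci_high", "n_loci"])


# ---------------------------------------------------------------------------
# filters specific to clonal data
# ---------------------------------------------------------------------------

def remove_fixed_het(g: GenotypeMatrix) -> tuple[GenotypeMatrix, int]:
    """Drop SNPs whose every non-missing call is heterozygous."""
    calls = g.calls
    ok = calls != CALL_MISSING
    any_typed = ok.any(axis=0)
    all_het = np.where(ok, calls == CALL_HET, True).all(axis=0) & any_typed
    out = g.subset_loci(~all_het)
    removed = int(all_het.sum())
    out.filter_log["fixed_het_removed"] = removed
    return out, removed


def thin_snps(g: GenotypeMatrix, window_bp: int = 1000) -> GenotypeMatrix:
    """Greedy left-to-right thinning to <= 1 SNP per window per chromosome.

    A SNP is kept iff its position is at least ``window_bp`` basepairs after
    the previously kept SNP; the first SNP of each chromosome is always
    kept.  Deterministic, matching the common ``--thin`` semantics.
    """
    keep = np.zeros(g.n_loci, dtype=bool)
    last_kept: dict = {}
    prev: dict = {}
    for j in range(g.n_loci):
        c = g.chrom[j]
        if c in prev and g.pos[j] <= prev[c]:
            raise ValueError("loci must be position-sorted within chromosome")
        prev[c] = g.pos[j]
        if c not in last_kept or g.pos[j] - last_kept[c] >= window_bp:
            keep[j] = True
            last_kept[c] = g.pos[j]
    out = g.subset_loci(keep)
    out.filter_log["thinned_removed"] = int((~keep).sum())
    return out


# ---------------------------------------------------------------------------
# distances and differentiation
# ---------------------------------------------------------------------------

def allelic_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Percent allelic difference between individuals.

    Per co-typed locus a pair differs by |g_i - g_j| alleles under 0/1/2
    dosage coding (same homozygote 0, hom vs. het 1, opposite homozygotes
    2); the distance is the summed difference over 2x the co-typed loci.
    """
    calls = g.calls.astype(float)
    ok = g.calls != CALL_MISSING
    n = g.n_individuals
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            if m == 0:
                logger.warning("individuals %s and %s share no typed loci",
                               g.individuals[i], g.individuals[j])
                d[i, j] = d[j, i] = np.nan
                continue
            diff = np.abs(calls[i, both] - calls[j, both]).sum()
            d[i, j] = d[j, i] = diff / (2.0 * m)
    return DistanceMatrix(d, ids=g.individuals)


def _wc_components(calls1: np.ndarray, calls2: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) per-locus a and b+c components, two pops."""
    r = 2
    stats = []
    for calls in (calls1, calls2):
        ok = calls != CALL_MISSING
        n_i = ok.sum(axis=0).astype(float)            # individuals typed
        alt = np.where(ok, calls, 0).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = alt / (2.0 * n_i)
            h_i = ((calls == CALL_HET) & ok).sum(axis=0) / n_i
        stats.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = stats
    n_bar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * n_bar - (n1 ** 2 + n2 ** 2) / (r * n_bar)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) \
            / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / nc) * (s2 - (p_bar * (1 - p_bar)
                                  - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar)
                                     - (r - 1) / r * s2
                                     - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2
    usable = (n1 >= 1) & (n2 >= 1) & np.isfinite(a) & np.isfinite(b + c)
    return a[usable], (a + b + c)[usable]


def pairwise_fst(g: GenotypeMatrix, populations, n_boot: int = 1000,
                 seed: int = 0) -> tuple[DistanceMatrix, pd.DataFrame]:
    """Pairwise Weir-Cockerham theta with loci-bootstrap p-values.

    theta is the ratio of sums of the per-locus variance components;
    negative estimates are reported unclipped (the distance-matrix view
    floors them at 0 only for downstream metric use).  p is the fraction of
    loci bootstraps with theta <= 0.
    """
    pops = _pop_series(g, populations)
    uniq = sorted(pd.unique(pops))
    if len(uniq) < 2:
        raise ValueError("need >= 2 populations")
    for pop in uniq:
        if (pops == pop).sum() < 2:
            raise ValueError(f"population {pop!r} has < 2 individuals")
    rng = np.random.default_rng(seed)
    k = len(uniq)
    theta = np.zeros((k, k))
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            c1 = g.calls[np.flatnonzero(pops == uniq[i])]
            c2 = g.calls[np.flatnonzero(pops == uniq[j])]
            a, abc = _wc_components(c1, c2)
            denom = abc.sum()
            t = float(a.sum() / denom) if denom != 0 else np.nan
            theta[i, j] = theta[j, i] = t
            boots = np.empty(n_boot)
            nl = len(a)
            for b in range(n_boot):
                sel = rng.integers(0, nl, nl)
                db = abc[sel].sum()
                boots[b] = a[sel].sum() / db if db != 0 else 0.0
            p = float(np.mean(boots <= 0.0))
            rows.append((uniq[i], uniq[j], t, p, nl))
    fst_df = pd.DataFrame(rows, columns=["pop1", "pop2", "theta",
                                         "boot_p", "n_loci"])
    dm = DistanceMatrix(np.maximum(theta, 0.0), ids=uniq)
    return dm, fst_df


@dataclass
class PopGenSummary:
    pi_by_chrom_river: pd.DataFrame
    fis_table: pd.DataFrame
    fst_matrix: DistanceMatrix
    fst_table: pd.DataFrame
    snp_counts: dict[str, int]


# ---------------------------------------------------------------------------
# genetics vs. microbiome
# ---------------------------------------------------------------------------

def genetics_microbiome_correlation(
        d_gen: DistanceMatrix, d_micro: DistanceMatrix, river_labels,
        d_geo: DistanceMatrix | None = None,
        fst_matrix: DistanceMatrix | None = None,
        site_avg_micro: DistanceMatrix | None = None,
        n_perm: int = 999, seed: int = 0) -> dict[str, StatTestResult]:
    """Genetic-structure vs. microbiome-structure correlation battery.

    (i) a global Mantel test of individual genetic distances against
    individual microbiome dissimilarities over the shared individuals;
    (ii) a within-river Spearman on the same-river pairs (genetic distance
    as the "geography"); (iii) when FST and site-averaged microbiome
    matrices are given, a population-level Mantel of the two.
    """
    shared = [i for i in d_gen.ids if i in set(d_micro.ids)]
    if len(shared) < 4:
        raise ValueError("fewer than 4 shared individuals")
    dg = d_gen.filter(shared)
    dmi = d_micro.filter(shared)
    out = {"global_mantel": mantel(dg, dmi, method="spearman",
                                   n_perm=n_perm, seed=seed)}
    rivers = pd.Series(river_labels)
    out["within_river_spearman"] = distance_decay(
        dmi, dg, rivers, n_perm=n_perm, seed=seed + 1)
    if fst_matrix is not None and site_avg_micro is not None:
        out["population_mantel"] = mantel(
            fst_matrix, site_avg_micro.filter(fst_matrix.ids),
            method="spearman", n_perm=n_perm, seed=seed + 2)
    return out


def _pop_series(g: GenotypeMatrix, populations) -> np.ndarray:
    if populations is None:
        return np.array(["all"] * g.n_individuals)
    pops = pd.Series(populations)
    missing = [i for i in g.individuals if i not in pops.index]
    if missing:
        raise ValueError(f"no population for individuals: {missing}")
    return pops.loc[g.individuals].to_numpy()
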