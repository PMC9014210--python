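"""Permutation-based multivariate statistics for distance matrices.

Implements the resampling machinery the comparative analysis relies on:
PERMANOVA with pairwise post-hocs, the multivariate dispersion
(betadisper-style) test, envfit vector fitting onto ordinations, Mantel
tests, the repeated-subsampling median-p Mantel procedure for host
microbiome co-variation, distance-decay correlations restricted to
within-river pairs, and univariate group comparisons.

Every permutation test takes an explicit seed and reports it; p-values are
computed as ``(1 + #{perm stat >= observed}) / (1 + n_perm)`` so the
smallest attainable p is ``1/(n_perm+1)``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .beta_div import OrdinationResult, bray_curtis, pcoa
from .io_formats import CountTable, EnvTable

logger = logging.getLogger(__name__)


@dataclass
class StatTestResult:
    name: str
    statistic: float
    p_value: float
    n_permutations: int = 0
    r2: float | None = None
    adjusted_p: float | None = None
    seed: int | None = None
    extra: dict = field(default_factory=dict)


def _perm_p(obs: float, perm: np.ndarray) -> float:
    return (1 + int(np.sum(perm >= obs - 1e-12))) / (1 + len(perm))


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _permanova_stats(d2: np.ndarray, groups: list[np.ndarray]
                     ) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared distances and group index arrays."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for idx in groups:
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    a = len(groups)
    if ss_within == 0:
        return (np.inf if ss_between > 0 else 0.0), ss_between / ss_total
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return f, ss_between / ss_total


def permanova(dm: DistanceMatrix, labels, n_perm: int = 999,
              seed: int = 0) -> StatTestResult:
    """One-factor PERMANOVA with unrestricted label permutation."""
    labels = _align_labels(dm, labels)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    d2 = np.asarray(dm.data, dtype=float) ** 2
    lab = np.asarray(labels)
    groups = [np.flatnonzero(lab == g) for g in uniq]
    f_obs, r2 = _permanova_stats(d2, groups)
    rng = np.random.default_rng(seed)
    perm_f = np.empty(n_perm)
    idx = np.arange(len(lab))
    for k in range(n_perm):
        rng.shuffle(idx)
        plab = lab[idx]
        pg = [np.flatnonzero(plab == g) for g in uniq]
        perm_f[k], _ = _permanova_stats(d2, pg)
    return StatTestResult("permanova_pseudo_F", f_obs, _perm_p(f_obs, perm_f),
                          n_perm, r2=r2, seed=seed)


def pairwise_permanova(dm: DistanceMatrix, labels, n_perm: int = 999,
                       seed: int = 0) -> list[StatTestResult]:
    """PERMANOVA per unordered group pair, Bonferroni-adjusted."""
    labels = _align_labels(dm, labels)
    uniq = sorted(pd.unique(labels))
    if len(uniq) < 3:
        raise ValueError("pairwise PERMANOVA expects >= 3 groups")
    pairs = list(itertools.combinations(uniq, 2))
    results = []
    ids = np.asarray(dm.ids)
    lab = np.asarray(labels)
    for k, (g1, g2) in enumerate(pairs):
        keep = ids[np.isin(lab, [g1, g2])]
        sub = dm.filter(keep)
        sub_lab = pd.Series(lab[np.isin(lab, [g1, g2])], index=keep)
        res = permanova(sub, sub_lab, n_perm=n_perm, seed=seed + k)
        res.name = f"permanova[{g1} vs {g2}]"
        res.adjusted_p = min(1.0, res.p_value * len(pairs))
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# Dispersion homogeneity (betadisper-style)
# ---------------------------------------------------------------------------

def _pcoa_blocks(dm: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Real and imaginary PCoA coordinate blocks of a distance matrix."""
    d = np.asarray(dm.data, dtype=float)
    a = -0.5 * d ** 2
    g = a - a.mean(axis=1, keepdims=True) - a.mean(axis=0, keepdims=True) \
        + a.mean()
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = 1e-10 * max(abs(vals[0]), 1.0)
    real = vecs[:, vals > tol] * np.sqrt(vals[vals > tol])
    imag = vecs[:, vals < -tol] * np.sqrt(-vals[vals < -tol])
    return real, imag


def _centroid_distances_from_blocks(real: np.ndarray, imag: np.ndarray,
                                    groups: list[np.ndarray]) -> np.ndarray:
    """Distance of each sample to its group centroid in PCoA space.

    Negative-eigenvalue axes contribute imaginary components whose squared
    distances are subtracted (the standard betadisper correction); the
    difference is floored at zero before the square root.
    """
    n = real.shape[0]
    z = np.empty(n)
    for idx in groups:
        cr = real[idx].mean(axis=0)
        dr2 = ((real[idx] - cr) ** 2).sum(axis=1)
        if imag.shape[1]:
            ci = imag[idx].mean(axis=0)
            di2 = ((imag[idx] - ci) ** 2).sum(axis=1)
        else:
            di2 = 0.0
        z[idx] = np.sqrt(np.maximum(dr2 - di2, 0.0))
    return z


def _centroid_distances(dm: DistanceMatrix, labels: pd.Series) -> np.ndarray:
    real, imag = _pcoa_blocks(dm)
    lab = np.asarray(labels)
    groups = [np.flatnonzero(lab == g) for g in pd.unique(lab)]
    return _centroid_distances_from_blocks(real, imag, groups)


def _anova_f(z: np.ndarray, groups: list[np.ndarray]) -> float:
    grand = z.mean()
    ss_b = sum(len(i) * (z[i].mean() - grand) ** 2 for i in groups)
    ss_w = sum(((z[i] - z[i].mean()) ** 2).sum() for i in groups)
    a, n = len(groups), len(z)
    if ss_w == 0:
        return np.inf if ss_b > 0 else 0.0
    return (ss_b / (a - 1)) / (ss_w / (n - a))


def dispersion_test(dm: DistanceMatrix, labels, n_perm: int = 999,
                    seed: int = 0) -> StatTestResult:
    """Permutation test of homogeneity of multivariate dispersions."""
    labels = _align_labels(dm, labels)
    lab = np.asarray(labels)
    uniq = pd.unique(lab)
    sizes = [int((lab == g).sum()) for g in uniq]
    if len(uniq) < 2 or min(sizes) < 2:
        raise ValueError("dispersion test needs >= 2 groups of >= 2 samples")
    real, imag = _pcoa_blocks(dm)
    groups = [np.flatnonzero(lab == g) for g in uniq]
    z = _centroid_distances_from_blocks(real, imag, groups)
    f_obs = _anova_f(z, groups)
    rng = np.random.default_rng(seed)
    perm_f = np.empty(n_perm)
    idx = np.arange(len(lab))
    # full re-fit per permutation: centroids and distances are recomputed
    # for the permuted grouping, keeping the test exact under exchangeability
    for k in range(n_perm):
        rng.shuffle(idx)
        plab = lab[idx]
        pg = [np.flatnonzero(plab == g) for g in uniq]
        pz = _centroid_distances_from_blocks(real, imag, pg)
        perm_f[k] = _anova_f(pz, pg)
    return StatTestResult("betadisper_F", f_obs, _perm_p(f_obs, perm_f),
                          n_perm, seed=seed,
                          extra={"centroid_distances": z})


# ---------------------------------------------------------------------------
# envfit
# ---------------------------------------------------------------------------

def envfit(ordination: OrdinationResult, env: EnvTable, sample_site_map,
           n_axes: int = 2, n_perm: int = 999, seed: int = 0
           ) -> dict[str, StatTestResult]:
    """Fit environmental vectors onto ordination axes.

    Per variable, R^2 is the squared multiple correlation of the variable
    with the first ``n_axes`` sample coordinates; significance is by
    permuting the variable over samples.  Samples whose site lacks a
    measurement are dropped for that variable only.
    """
    site_map = pd.Series(sample_site_map)
    coords = ordination.axes(n_axes)
    ids = ordination.sample_ids
    rng = np.random.default_rng(seed)
    results: dict[str, StatTestResult] = {}
    for var in env.variables:
        v = np.array([env.data.at[site_map[s], var] if site_map[s]
                      in env.data.index else np.nan for s in ids])
        ok = ~np.isnan(v)
        if ok.sum() < 3:
            logger.warning("envfit: variable %s has <3 samples; skipped", var)
            continue
        y = v[ok]
        if np.ptp(y) == 0:
            results[var] = StatTestResult(f"envfit[{var}]", np.nan, np.nan,
                                          extra={"error": "constant variable"})
            continue
        x = coords[ok]
        r2_obs, arrow = _envfit_r2(x, y)
        perm = np.empty(n_perm)
        for k in range(n_perm):
            perm[k], _ = _envfit_r2(x, rng.permutation(y))
        results[var] = StatTestResult(
            f"envfit[{var}]", r2_obs, _perm_p(r2_obs, perm), n_perm,
            r2=r2_obs, seed=seed, extra={"arrow": arrow, "n": int(ok.sum())})
    return results


def _envfit_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    beta, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    fitted = xc @ beta
    sst = (yc ** 2).sum()
    r2 = float((fitted ** 2).sum() / sst) if sst > 0 else 0.0
    norm = np.linalg.norm(beta)
    arrow = beta / norm if norm > 0 else beta
    return r2, arrow


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def mantel(d1: DistanceMatrix, d2: DistanceMatrix, method: str = "spearman",
           n_perm: int = 999, seed: int = 0) -> StatTestResult:
    """Mantel correlation between two distance matrices (one-sided, r > 0)."""
    if set(d1.ids) != set(d2.ids):
        raise ValueError("distance matrices have mismatched labels")
    d2 = d2.filter(d1.ids)
    n = len(d1.ids)
    if n < 4:
        raise ValueError("Mantel needs at least 4 objects")
    iu = np.triu_indices(n, 1)
    a = np.asarray(d1.data)[iu]
    bmat = np.asarray(d2.data)
    corr = _corr_fn(method)
    r_obs = corr(a, bmat[iu])
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    order = np.arange(n)
    for k in range(n_perm):
        rng.shuffle(order)
        perm[k] = corr(a, bmat[np.ix_(order, order)][iu])
    return StatTestResult(f"mantel_{method}", r_obs, _perm_p(r_obs, perm),
                          n_perm, seed=seed)


def _corr_fn(method: str):
    if method == "pearson":
        def f(x, y):
            return float(np.corrcoef(x, y)[0, 1])
    elif method == "spearman":
        def f(x, y):
            rx = stats.rankdata(x)
            ry = stats.rankdata(y)
            return float(np.corrcoef(rx, ry)[0, 1])
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return f


def covariation_median_mantel(table: CountTable, group_a, group_b,
                              metric=None, n_reps: int = 500,
                              n_perm: int = 999, seed: int = 0,
                              method: str = "spearman") -> dict:
    """Repeated-subsampling Mantel test of co-variation of two host groups.

    Per replicate: at every site where both groups occur, draw equal-size
    random subsamples (size = the smaller group size at that site), average
    each group's feature proportions per site, compute the site x site
    dissimilarity of each group's averaged profiles, and Mantel-test the two
    matrices.  Reports the median of the replicate p-values and the full
    correlation distribution.

    ``metric`` maps a site x feature proportion DataFrame to a
    DistanceMatrix; the default is Bray-Curtis.
    """
    if metric is None:
        def metric(df):
            scaled = (df * 10 ** 9).round().astype(np.int64)
            return bray_curtis(scaled)
    md = table.metadata
    a = [s for s in group_a]
    b = [s for s in group_b]
    sites_a = md.loc[a, "site"]
    sites_b = md.loc[b, "site"]
    shared = sorted(set(sites_a) & set(sites_b))
    if len(shared) < 4:
        raise ValueError("need >= 4 shared sites (site-level Mantel is "
                         "undefined below 4 sites)")
    props = table.proportions()
    rng = np.random.default_rng(seed)
    p_values = np.empty(n_reps)
    rhos = np.empty(n_reps)
    a_by_site = {s: [i for i in a if md.at[i, "site"] == s] for s in shared}
    b_by_site = {s: [i for i in b if md.at[i, "site"] == s] for s in shared}
    for rep in range(n_reps):
        prof_a, prof_b = [], []
        for s in shared:
            k = min(len(a_by_site[s]), len(b_by_site[s]))
            sel_a = rng.choice(a_by_site[s], size=k, replace=False)
            sel_b = rng.choice(b_by_site[s], size=k, replace=False)
            prof_a.append(props.loc[sel_a].mean(axis=0))
            prof_b.append(props.loc[sel_b].mean(axis=0))
        da = metric(pd.DataFrame(prof_a, index=shared))
        db = metric(pd.DataFrame(prof_b, index=shared))
        res = mantel(da, db, method=method, n_perm=n_perm,
                     seed=int(rng.integers(2 ** 31)))
        p_values[rep] = res.p_value
        rhos[rep] = res.statistic
    return {"median_p": float(np.median(p_values)),
            "p_values": p_values, "rho": rhos, "n_sites": len(shared),
            "seed": seed}


# ---------------------------------------------------------------------------
# Distance decay along rivers
# ---------------------------------------------------------------------------

def distance_decay(d_response: DistanceMatrix, d_geo: DistanceMatrix,
                   river_labels, n_perm: int = 999, seed: int = 0
                   ) -> StatTestResult:
    """Spearman correlation of dissimilarity with river distance, restricted
    to same-river pairs.

    Both the naive asymptotic p (distance pairs treated as independent; it
    is anti-conservative) and a Mantel-style permutation p restricted to
    within-river relabelings are reported; the permutation p is the
    headline value.
    """
    ids = list(d_response.ids)
    d_geo = d_geo.filter(ids)
    rivers = pd.Series(river_labels).loc[ids]
    lab = rivers.to_numpy()
    n = len(ids)
    iu = np.triu_indices(n, 1)
    same_river = lab[iu[0]] == lab[iu[1]]
    n_excluded = int((~same_river).sum())
    if n_excluded:
        logger.info("distance_decay: excluded %d cross-river pairs",
                    n_excluded)
    resp = np.asarray(d_response.data)
    geo = np.asarray(d_geo.data)
    x = geo[iu][same_river]
    y = resp[iu][same_river]
    if len(x) < 4:
        raise ValueError("fewer than 4 same-river pairs")
    rho_obs, p_naive = stats.spearmanr(x, y)
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    order = np.arange(n)
    for k in range(n_perm):
        # permute ids within rivers only, so the pair structure is preserved
        perm_order = order.copy()
        for r in pd.unique(lab):
            idx = np.flatnonzero(lab == r)
            perm_order[idx] = rng.permutation(perm_order[idx])
        py = resp[np.ix_(perm_order, perm_order)][iu][same_river]
        perm[k] = stats.spearmanr(x, py)[0]
    return StatTestResult("distance_decay_spearman", float(rho_obs),
                          _perm_p(rho_obs, perm), n_perm, seed=seed,
                          extra={"naive_p": float(p_naive),
                                 "n_pairs": int(len(x)),
                                 "n_excluded_pairs": n_excluded})


# ---------------------------------------------------------------------------
# Univariate group comparisons
# ---------------------------------------------------------------------------

def group_compare(values, labels=None, test: str = "kruskal_wallis",
                  y=None) -> StatTestResult:
    """Kruskal-Wallis / Wilcoxon rank-sum / Pearson comparison.

    For the rank tests, exact enumeration over all distinct group
    assignments is used when total n <= 10; otherwise the tie-corrected
    asymptotic distribution.
    """
    if test == "pearson":
        x = np.asarray(values, dtype=float)
        yv = np.asarray(y, dtype=float)
        r, p = stats.pearsonr(x, yv)
        return StatTestResult("pearson_r", float(r), float(p))
    values = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    groups = [values[lab == g] for g in pd.unique(lab)]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    n = len(values)
    if test == "kruskal_wallis":
        if len(groups) < 2:
            raise ValueError("need >= 2 groups")
        h, p_asym = stats.kruskal(*groups)
        if n <= 10:
            p = _exact_kw_p(values, [len(g) for g in groups], float(h))
            return StatTestResult("kruskal_wallis_H", float(h), p,
                                  extra={"exact": True,
                                         "asymptotic_p": float(p_asym)})
        return StatTestResult("kruskal_wallis_H", float(h), float(p_asym))
    if test == "wilcoxon_ranksum":
        if len(groups) != 2:
            raise ValueError("rank-sum test needs exactly 2 groups")
        method = "exact" if n <= 10 and not _has_ties(values) else "asymptotic"
        res = stats.mannwhitneyu(groups[0], groups[1],
                                 alternative="two-sided", method=method,
                                 use_continuity=False)
        return StatTestResult("wilcoxon_ranksum_U", float(res.statistic),
                              float(res.pvalue))
    raise ValueError(f"unknown test {test!r}")


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def _kw_h(ranks: np.ndarray, group_idx: list[np.ndarray], tie_factor: float
          ) -> float:
    n = len(ranks)
    h = 12 / (n * (n + 1)) * sum(
        len(i) * (ranks[i].mean() - (n + 1) / 2) ** 2 for i in group_idx)
    return h / tie_factor


def _exact_kw_p(values: np.ndarray, sizes: list[int], h_obs: float) -> float:
    """Exact Kruskal-Wallis p by enumerating distinct group assignments."""
    n = len(values)
    ranks = stats.rankdata(values)
    ties = np.unique(values, return_counts=True)[1]
    tie_factor = 1 - ((ties ** 3 - ties).sum() / (n ** 3 - n))
    count = 0
    total = 0
    for assign in _assignments(list(range(n)), sizes):
        total += 1
        h = _kw_h(ranks, [np.array(a) for a in assign], tie_factor)
        if h >= h_obs - 1e-12:
            count += 1
    return count / total


def _assignments(indices: list[int], sizes: list[int]):
    """All ways to split ``indices`` into ordered groups of given sizes."""
    if len(sizes) == 1:
        yield [indices]
        return
    # groups are labeled (distinct species), so all labeled splits count
    for combo in itertools.combinations(indices, sizes[0]):
        remaining = [i for i in indices if i not in combo]
        for tail in _assignments(remaining, sizes[1:]):
            yield [list(combo)] + tail


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _align_labels(dm: DistanceMatrix, labels) -> pd.Series:
    if isinstance(labels, pd.Series):
        missing = set(dm.ids) - set(labels.index)
        if missing:
            raise ValueError(f"labels missing for samples: {sorted(missing)}")
        return labels.loc[list(dm.ids)]
    labels = pd.Series(list(labels), index=list(dm.ids))
    return labels
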