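"""Beta diversity: UniFrac (unweighted and weighted), Bray-Curtis, the
centered log-ratio transform for predicted-pathway tables, and PCoA.

Unweighted UniFrac between samples A and B is the fraction of tree length
unique to one of the two samples,

    U(A,B) = sum_b l_b [branch in exactly one] / sum_b l_b [branch in either]

and weighted UniFrac uses the normalised abundance form

    W(A,B) = sum_b l_b |p_bA - p_bB| / sum_b l_b (p_bA + p_bB)

with ``p_b`` the total relative abundance of the tips below branch ``b``
(the alpha=1 generalised-UniFrac form).  Neither metric is guaranteed to be
metric in the triangle-inequality sense; only symmetry and identity are
asserted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

from .alpha_div import BranchIndex
from .io_formats import CountTable


def _branch_proportions(table: CountTable, bi: BranchIndex) -> np.ndarray:
    """samples x branches matrix of subtree relative abundances."""
    feats = table.feature_ids
    missing = sorted(set(feats) - set(bi.tip_names))
    if missing:
        raise ValueError(f"features absent from tree: {missing}")
    col = {t: i for i, t in enumerate(bi.tip_names)}
    counts = np.zeros((len(table.sample_ids), len(bi.tip_names)))
    arr = table.counts.to_numpy(dtype=float)
    for j, f in enumerate(feats):
        counts[:, col[f]] = arr[:, j]
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        empty = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"empty samples: {empty}")
    props = counts / totals[:, None]
    return props @ bi.incidence.T


def unifrac(table: CountTable, tree: TreeNode, weighted: bool,
            normalized: bool = True) -> DistanceMatrix:
    """Pairwise UniFrac over all samples of the table.

    ``normalized`` applies only to the weighted form; the raw variant
    divides by nothing and is then not bounded by 1.
    """
    bi = BranchIndex(tree)
    pb = _branch_proportions(table, bi)  # samples x branches
    l = bi.lengths
    n = pb.shape[0]
    d = np.zeros((n, n))
    if weighted:
        for i in range(n):
            diff = np.abs(pb[i] - pb[i + 1:])
            num = diff @ l
            if normalized:
                den = (pb[i] + pb[i + 1:]) @ l
                vals = np.where(den > 0, num / np.where(den > 0, den, 1), 0.0)
            else:
                vals = num
            d[i, i + 1:] = vals
    else:
        pres = pb > 0
        for i in range(n):
            union = (pres[i] | pres[i + 1:]) @ l
            sym = (pres[i] ^ pres[i + 1:]) @ l
            vals = np.where(union > 0, sym / np.where(union > 0, union, 1), 0.0)
            d[i, i + 1:] = vals
    d = d + d.T
    return DistanceMatrix(d, ids=table.sample_ids)


def bray_curtis(data: CountTable | pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity on non-negative sample profiles."""
    if isinstance(data, CountTable):
        df = data.counts
    else:
        df = data
    arr = df.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("Bray-Curtis requires non-negative values; "
                         "use shifted clr or Euclidean for transformed tables")
    if (arr.sum(axis=1) == 0).any():
        raise ValueError("all-zero sample in Bray-Curtis input")
    d = squareform(pdist(arr, metric="braycurtis"))
    return DistanceMatrix(d, ids=[str(i) for i in df.index])


def clr_transform(table: CountTable | pd.DataFrame,
                  pseudocount: float = 0.5) -> pd.DataFrame:
    """Centered log-ratio transform; each output row sums to zero."""
    df = table.counts if isinstance(table, CountTable) else table
    x = df.to_numpy(dtype=float) + pseudocount
    if (x <= 0).any():
        raise ValueError("clr requires strictly positive values after "
                         "pseudocount addition")
    logx = np.log(x)
    out = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def functional_dissimilarity(table: CountTable, pseudocount: float = 0.5,
                             method: str = "bray_shifted") -> DistanceMatrix:
    """Dissimilarity between clr-transformed predicted-pathway profiles.

    Bray-Curtis is undefined on the negative values the clr produces, so the
    default shifts every clr value by the table minimum before computing
    Bray-Curtis; ``method='euclidean'`` gives the Aitchison distance
    instead.
    """
    clr = clr_transform(table, pseudocount)
    if method == "bray_shifted":
        shifted = clr - clr.to_numpy().min()
        return bray_curtis(shifted)
    if method == "euclidean":
        d = squareform(pdist(clr.to_numpy(), metric="euclidean"))
        return DistanceMatrix(d, ids=[str(i) for i in clr.index])
    raise ValueError(f"unknown method {method!r}")


@dataclass
class OrdinationResult:
    """PCoA coordinates with the full eigenvalue spectrum.

    Negative eigenvalues (non-Euclidean input) are reported, never clipped;
    coordinates are only returned for positive-eigenvalue axes.
    """

    sample_ids: list[str]
    coordinates: np.ndarray         # samples x positive axes
    eigenvalues: np.ndarray         # all, decreasing
    proportion_explained: np.ndarray

    def axes(self, n: int = 2) -> np.ndarray:
        if self.coordinates.shape[1] < n:
            raise ValueError(f"only {self.coordinates.shape[1]} positive axes")
        return self.coordinates[:, :n]


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical (Gower) principal coordinates of a distance matrix."""
    d = np.asarray(dm.data, dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix not symmetric")
    n = d.shape[0]
    a = -0.5 * d ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    g = a - row - col + a.mean()
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    pos = eigvals > 1e-10 * max(abs(eigvals[0]), 1.0)
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    denom = eigvals.sum()
    prop = eigvals / denom if denom != 0 else np.zeros(n)
    return OrdinationResult(list(dm.ids), coords, eigvals, prop)


def site_averaged_profiles(table: CountTable, sample_ids=None) -> CountTable:
    """Mean relative abundance per site over the given samples.

    Returns a pseudo count table (proportions scaled to a common integer
    depth) whose "samples" are sites; used for population-level analyses
    that compare site-averaged microbiomes.
    """
    ids = list(sample_ids) if sample_ids is not None else table.sample_ids
    sub = table.subset_samples(ids)
    props = sub.proportions()
    by_site = props.groupby(sub.metadata["site"]).mean()
    scale = 1_000_000
    counts = (by_site * scale).round().astype(np.int64)
    md = pd.DataFrame({
        "host_species": "site_mean", "site": by_site.index,
        "river": [sub.metadata.loc[sub.metadata["site"] == s, "river"].iloc[0]
                  for s in by_site.index],
        "host_type": "invasive"}, index=by_site.index)
    return CountTable(counts, md)
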