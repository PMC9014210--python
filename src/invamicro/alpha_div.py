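"""Rarefaction, coverage and alpha diversity (taxonomic and phylogenetic).

Indices implemented:

* Shannon diversity reported as an effective number of species, ``exp(H)``
  with ``H = -sum p_i ln p_i`` (natural log).
* Faith's phylogenetic diversity: total branch length of the minimal rooted
  subtree spanning the tips present in a sample.  The rooted convention is
  used, so a single present tip scores its full root path; this matches the
  behaviour of picante-style implementations.
* Allen's phylogenetic entropy ``H_p = sum_b l_b * (-p_b ln p_b)`` over
  branches, where ``p_b`` is the total relative abundance of the tips below
  branch ``b``.  The effective number of species is ``exp(H_p / Tbar)``
  where ``Tbar`` is the abundance-weighted mean root-to-tip distance, which
  reduces the index to ``exp(H)`` on star trees with unit branches.
* Chao's nonparametric sample-coverage estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io_formats import CountTable

logger = logging.getLogger(__name__)


@dataclass
class AlphaDiversityRecord:
    sample_id: str
    richness: int
    shannon_effective: float
    faith_pd: float
    allen_entropy: float
    allen_effective: float
    coverage: float


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples whose total count is below ``depth`` are dropped (logged).  The
    same seed always yields the same table.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    kept_rows = []
    kept_ids = []
    dropped = []
    counts = table.counts.to_numpy()
    for i, sid in enumerate(table.sample_ids):
        total = int(counts[i].sum())
        if total < depth:
            dropped.append(sid)
            continue
        row = rng.multivariate_hypergeometric(counts[i], depth)
        kept_rows.append(row)
        kept_ids.append(sid)
    if dropped:
        logger.warning("rarefy: dropped %d samples below depth %d: %s",
                       len(dropped), depth, dropped)
    if not kept_ids:
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    new_counts = pd.DataFrame(np.vstack(kept_rows), index=kept_ids,
                              columns=table.feature_ids)
    return CountTable(new_counts, table.metadata.loc[kept_ids])


# ---------------------------------------------------------------------------
# Taxonomic indices
# ---------------------------------------------------------------------------

def shannon_effective(counts: np.ndarray) -> float:
    """exp of Shannon entropy (natural log) over nonzero proportions."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("sample has no reads")
    p = counts[counts > 0] / total
    return float(np.exp(-(p * np.log(p)).sum()))


def chao_coverage(counts: np.ndarray) -> float:
    """Chao's coverage estimator from singleton/doubleton counts."""
    counts = np.asarray(counts)
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("coverage needs integer counts")
        counts = np.round(counts).astype(np.int64)
    n = int(counts.sum())
    if n < 1:
        raise ValueError("sample has no reads")
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f1 == 0:
        return 1.0
    return 1.0 - (f1 / n) * ((n - 1) * f1 / ((n - 1) * f1 + 2 * f2))


# ---------------------------------------------------------------------------
# Phylogenetic indices
# ---------------------------------------------------------------------------

class BranchIndex:
    """Branch incidence structure of a rooted tree over its tips.

    ``incidence[b, t]`` is 1 when tip ``t`` descends from branch ``b`` (the
    branch above each non-root node).  Shared by Faith's PD, Allen entropy
    and UniFrac so the tree is traversed once.
    """

    def __init__(self, tree: TreeNode):
        tips = list(tree.tips())
        self.tip_names = [t.name for t in tips]
        tip_idx = {t: i for i, t in enumerate(self.tip_names)}
        self._tip_idx = tip_idx
        nodes = [n for n in tree.postorder(include_self=False)]
        self.lengths = np.array([n.length or 0.0 for n in nodes])
        inc = np.zeros((len(nodes), len(tips)), dtype=bool)
        below: dict[int, np.ndarray] = {}
        for bi, node in enumerate(nodes):
            if node.is_tip():
                inc[bi, tip_idx[node.name]] = True
            else:
                for child in node.children:
                    inc[bi] |= below[id(child)]
            below[id(node)] = inc[bi]
        self.incidence = inc
        # root-to-tip depth per tip = sum of lengths of branches above it
        self.tip_depths = self.lengths @ inc

    def tip_vector(self, values: dict[str, float] | pd.Series) -> np.ndarray:
        if isinstance(values, pd.Series):
            values = values.to_dict()
        missing = sorted(set(values) - set(self.tip_names))
        if missing:
            raise ValueError(f"features absent from tree: {missing}")
        v = np.zeros(len(self.tip_names))
        for name, val in values.items():
            v[self._tip_idx[name]] = val
        return v

    def branch_abundance(self, tip_values: np.ndarray) -> np.ndarray:
        """Per-branch sum of tip values below the branch."""
        return self.incidence @ tip_values


def faith_pd(present_features, tree: TreeNode | BranchIndex) -> float:
    """Total branch length of the rooted subtree spanning the present tips."""
    bi = tree if isinstance(tree, BranchIndex) else BranchIndex(tree)
    present = set(present_features)
    missing = sorted(present - set(bi.tip_names))
    if missing:
        raise ValueError(f"features absent from tree: {missing}")
    mask = np.array([t in present for t in bi.tip_names])
    spanned = bi.incidence @ mask > 0
    return float(bi.lengths[spanned].sum())


def allen_entropy(proportions: dict[str, float] | pd.Series,
                  tree: TreeNode | BranchIndex) -> tuple[float, float]:
    """Phylogenetic entropy (nats) and its effective number of species."""
    bi = tree if isinstance(tree, BranchIndex) else BranchIndex(tree)
    p_tip = bi.tip_vector(proportions)
    if p_tip.sum() <= 0:
        raise ValueError("proportions sum to zero")
    p_tip = p_tip / p_tip.sum()
    p_b = bi.branch_abundance(p_tip)
    pos = p_b > 0
    entropy = float((bi.lengths[pos] * (-p_b[pos] * np.log(p_b[pos]))).sum())
    tbar = float((p_tip * bi.tip_depths).sum())
    effective = float(np.exp(entropy / tbar)) if tbar > 0 else 1.0
    return entropy, effective


# ---------------------------------------------------------------------------
# Shared-ASV fractions
# ---------------------------------------------------------------------------

def shared_asv_fraction(table: CountTable, group_a, group_b
                        ) -> tuple[float, float]:
    """Fractions of group A's ASVs also seen in group B, and vice versa."""
    a = list(group_a)
    b = list(group_b)
    if not a or not b:
        raise ValueError("empty sample group")
    if set(a) & set(b):
        raise ValueError("groups must be disjoint")
    pres_a = set(np.array(table.feature_ids)[
        (table.counts.loc[a].to_numpy() > 0).any(axis=0)])
    pres_b = set(np.array(table.feature_ids)[
        (table.counts.loc[b].to_numpy() > 0).any(axis=0)])
    shared = pres_a & pres_b
    return (len(shared) / len(pres_a) if pres_a else 0.0,
            len(shared) / len(pres_b) if pres_b else 0.0)


def shared_fraction_by_site(table: CountTable, species_a: str, species_b: str
                            ) -> pd.DataFrame:
    """Per-site shared-ASV fractions between two host species.

    Only sites where both species were sampled contribute; the mean over
    those co-occurrence sites is the headline pairing value.
    """
    md = table.metadata
    rows = []
    for site in sorted(md["site"].unique()):
        a = md.index[(md["site"] == site) & (md["host_species"] == species_a)]
        b = md.index[(md["site"] == site) & (md["host_species"] == species_b)]
        if len(a) == 0 or len(b) == 0:
            continue
        fa, fb = shared_asv_fraction(table, a, b)
        rows.append((site, fa, fb))
    return pd.DataFrame(rows, columns=["site", "frac_a_shared",
                                       "frac_b_shared"])


# ---------------------------------------------------------------------------
# Per-sample summary
# ---------------------------------------------------------------------------

def alpha_diversity_table(table: CountTable, tree: TreeNode) -> pd.DataFrame:
    """All alpha indices for every sample in the table."""
    bi = BranchIndex(tree)
    records = []
    for sid in table.sample_ids:
        row = table.counts.loc[sid]
        counts = row.to_numpy()
        present = row.index[counts > 0]
        props = row[row > 0] / counts.sum()
        ent, eff = allen_entropy(props, bi)
        records.append(AlphaDiversityRecord(
            sample_id=sid,
            richness=int((counts > 0).sum()),
            shannon_effective=shannon_effective(counts),
            faith_pd=faith_pd(present, bi),
            allen_entropy=ent,
            allen_effective=eff,
            coverage=chao_coverage(counts),
        ))
    return pd.DataFrame([r.__dict__ for r in records]).set_index("sample_id")
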