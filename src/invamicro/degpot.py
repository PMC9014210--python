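"""Chemical-structure-based degradation potential of inferred functions.

The score asks: how structurally diverse are the compounds a community is
predicted to degrade?  The chain is

1. pairwise structural dissimilarity between the entry compounds of all
   degradation (Degradation-Utilization-Assimilation class) pathways,
   either 1 - Tanimoto similarity of topological fingerprints computed from
   SMILES, or a user-supplied precomputed matrix;
2. averaging compound dissimilarities over all cross pairs to obtain a
   pathway x pathway dissimilarity;
3. UPGMA clustering of pathways into an ultrametric dendrogram;
4. per sample, the total dendrogram branch length spanned by the pathways
   predicted present -- a phylogenetic-diversity-style "structural
   richness" -- plus the pairwise presence-based (unweighted UniFrac)
   dissimilarity between samples on the same dendrogram.

The per-sample structural richness is the headline degradation potential;
it is presence-based, so scaling predicted pathway abundances leaves it
unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .alpha_div import BranchIndex, faith_pd
from .beta_div import unifrac
from .io_formats import CountTable, PathwayCompoundMap

logger = logging.getLogger(__name__)


@dataclass
class DegradationScore:
    sample_id: str
    structural_richness: float
    n_degradation_pathways: int


def compound_dissimilarity(structures: dict[str, str] | None = None,
                           precomputed: DistanceMatrix | None = None,
                           fp_size: int = 2048) -> DistanceMatrix:
    """1 - Tanimoto dissimilarity on topological (path) fingerprints.

    ``structures`` maps compound id -> SMILES.  A ``precomputed`` matrix is
    validated and passed through (entries must lie in [0, 1]).
    """
    if precomputed is not None:
        data = np.asarray(precomputed.data)
        if (data < 0).any() or (data > 1 + 1e-12).any():
            raise ValueError("compound dissimilarities must lie in [0, 1]")
        return precomputed
    if not structures:
        raise ValueError("need SMILES structures or a precomputed matrix")
    from rdkit import Chem, RDLogger
    from rdkit.Chem import DataStructs

    RDLogger.DisableLog("rdApp.*")
    ids = sorted(structures)
    fps = {}
    bad = []
    for cid in ids:
        mol = Chem.MolFromSmiles(structures[cid])
        if mol is None:
            bad.append(cid)
            continue
        fps[cid] = Chem.RDKFingerprint(mol, fpSize=fp_size)
    if bad:
        raise ValueError(f"unparseable SMILES for compounds: {bad}")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim = DataStructs.TanimotoSimilarity(fps[ids[i]], fps[ids[j]])
            d[i, j] = d[j, i] = 1.0 - sim
    return DistanceMatrix(d, ids=ids)


def pathway_dissimilarity(pmap: PathwayCompoundMap,
                          cd: DistanceMatrix) -> DistanceMatrix:
    """Mean cross-pair compound dissimilarity between degradation pathways."""
    pathways = pmap.degradation_pathways()
    if len(pathways) < 2:
        raise ValueError("need >= 2 degradation pathways")
    comp_idx = {c: i for i, c in enumerate(cd.ids)}
    sets = {}
    for pw in pathways:
        comps = pmap.compounds.get(pw, [])
        if not comps:
            raise ValueError(f"pathway {pw!r} has no mapped compounds")
        missing = [c for c in comps if c not in comp_idx]
        if missing:
            raise ValueError(f"pathway {pw!r} compounds missing from "
                             f"dissimilarity matrix: {missing}")
        sets[pw] = np.array([comp_idx[c] for c in comps])
    data = np.asarray(cd.data)
    n = len(pathways)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            block = data[np.ix_(sets[pathways[i]], sets[pathways[j]])]
            d[i, j] = d[j, i] = float(block.mean())
    return DistanceMatrix(d, ids=pathways)


def build_dendrogram(d_pathways: DistanceMatrix) -> TreeNode:
    """UPGMA dendrogram of pathways; equal-height ties broken by the
    lexicographically smallest member id, so the topology is deterministic.

    Tip depth equals half the merge height, so the cophenetic distance of
    the output reproduces the UPGMA merge heights exactly.
    """
    data = np.asarray(d_pathways.data, dtype=float)
    if np.isnan(data).any():
        raise ValueError("NaN in pathway dissimilarities")
    ids = list(d_pathways.ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need >= 2 pathways")
    # active clusters: key -> (node, size, height, min_member_id)
    nodes = {i: (TreeNode(name=ids[i], length=0.0), 1, 0.0, ids[i])
             for i in range(n)}
    dist = {frozenset((i, j)): data[i, j]
            for i in range(n) for j in range(i + 1, n)}
    next_key = n
    while len(nodes) > 1:
        keys = sorted(nodes)
        best = None
        for a in keys:
            for b in keys:
                if b <= a:
                    continue
                cand = (dist[frozenset((a, b))],
                        min(nodes[a][3], nodes[b][3]),
                        max(nodes[a][3], nodes[b][3]))
                if best is None or cand < best[0]:
                    best = (cand, a, b)
        _, a, b = best
        na, sa, ha, ma = nodes[a]
        nb, sb, hb, mb = nodes[b]
        height = dist[frozenset((a, b))]
        na.length = height / 2 - ha
        nb.length = height / 2 - hb
        parent = TreeNode(length=0.0, children=[na, nb])
        for other in keys:
            if other in (a, b):
                continue
            so = nodes[other][1]
            d_new = (dist[frozenset((a, other))] * sa
                     + dist[frozenset((b, other))] * sb) / (sa + sb)
            dist[frozenset((next_key, other))] = d_new
        del nodes[a], nodes[b]
        nodes[next_key] = (parent, sa + sb, height / 2, min(ma, mb))
        next_key += 1
    root = next(iter(nodes.values()))[0]
    root.length = 0.0
    return root


def degradation_potential(pathway_table: CountTable, dendro: TreeNode,
                          presence_threshold: float = 0.0
                          ) -> tuple[pd.DataFrame, DistanceMatrix]:
    """Per-sample structural richness plus the pairwise presence-based
    (unweighted UniFrac) dissimilarity between samples on the dendrogram.

    ``pathway_table`` must already be restricted to degradation pathways;
    a pathway is present when its predicted abundance exceeds
    ``presence_threshold``.
    """
    tips = {t.name for t in dendro.tips()}
    feats = [f for f in pathway_table.feature_ids if f in tips]
    missing = set(pathway_table.feature_ids) - tips
    if missing:
        raise ValueError(f"pathways absent from dendrogram: {sorted(missing)}")
    bi = BranchIndex(dendro)
    scores = []
    for sid in pathway_table.sample_ids:
        row = pathway_table.counts.loc[sid]
        present = row.index[row > presence_threshold]
        if len(present) == 0:
            logger.warning("sample %s has no degradation pathways; score 0",
                           sid)
            scores.append(DegradationScore(sid, 0.0, 0))
            continue
        scores.append(DegradationScore(
            sid, faith_pd(present, bi), int(len(present))))
    # presence-based table for the pairwise dendrogram UniFrac
    pres = (pathway_table.counts > presence_threshold).astype(np.int64)
    nonempty = pres.sum(axis=1) > 0
    dm = None
    if nonempty.sum() >= 2:
        sub = CountTable(pres.loc[nonempty],
                         pathway_table.metadata.loc[nonempty])
        dm = unifrac(sub, dendro, weighted=False)
    df = pd.DataFrame([s.__dict__ for s in scores]).set_index("sample_id")
    return df, dm
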