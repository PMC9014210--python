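"""Domain types and file formats shared by the whole pipeline.

The pipeline moves data between a small number of containers:

* :class:`CountTable` -- integer sample x feature matrix (ASVs or predicted
  pathways) with aligned per-sample metadata (host species, site, river,
  host type).
* phylogenetic trees -- :class:`skbio.TreeNode`, read from newick; the same
  container is reused for compound dendrograms.
* :class:`skbio.DistanceMatrix` -- all beta-diversity, geographic and
  genetic distance matrices.
* :class:`GenotypeMatrix` -- diploid biallelic genotype calls derived from a
  VCF, with the multi-stage site filter chain used for clonal RAD-seq data.
* :class:`EnvTable` -- per-site environmental measurements (missing values
  allowed).
* :class:`PathwayCompoundMap` -- degradation pathway -> entry compounds.

All tabular formats are plain TSV; trees are newick; genotypes are VCF.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger(__name__)

REQUIRED_METADATA = ("host_species", "site", "river", "host_type")
HOST_TYPES = ("invasive", "native_mussel", "seston", "sediment")

CALL_HOM_REF = 0
CALL_HET = 1
CALL_HOM_ALT = 2
CALL_MISSING = -1


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# CountTable
# ---------------------------------------------------------------------------

@dataclass
class CountTable:
    """Sample x feature count matrix with aligned sample metadata.

    ``counts`` is an integer DataFrame indexed by sample id with feature ids
    as columns.  ``metadata`` is indexed by the same sample ids and must
    carry the keys ``host_species``, ``site``, ``river`` and ``host_type``.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dup}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise FormatError(f"duplicate feature ids: {dup}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise FormatError("counts must be integers")
        if (arr < 0).any():
            raise FormatError("counts must be non-negative")
        missing = self.counts.index.difference(self.metadata.index)
        if len(missing):
            raise FormatError(
                f"samples lacking metadata: {sorted(missing.tolist())}"
            )
        absent = [k for k in REQUIRED_METADATA if k not in self.metadata.columns]
        if absent:
            raise FormatError(f"metadata missing required columns: {absent}")
        self.metadata = self.metadata.loc[self.counts.index]

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def feature_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        ids = list(sample_ids)
        return CountTable(self.counts.loc[ids], self.metadata.loc[ids])

    def subset_features(self, feature_ids: Sequence[str]) -> "CountTable":
        return CountTable(self.counts[list(feature_ids)], self.metadata)

    def proportions(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals, axis=0)


def read_count_table(path: str | Path, metadata_path: str | Path) -> CountTable:
    """Read a counts TSV (rows=samples, columns=features) plus metadata TSV."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    for col in counts.columns:
        bad = counts[col][~counts[col].apply(
            lambda v: float(v) == int(float(v)) if _is_number(v) else False)]
        if len(bad):
            raise FormatError(
                f"non-integer count at row {bad.index[0]!r}, column {col!r}: "
                f"{bad.iloc[0]!r}"
            )
    counts = counts.astype(np.int64)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype=str)
    metadata.index = metadata.index.astype(str)
    return CountTable(counts, metadata)


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def write_count_table(table: CountTable, path: str | Path,
                      metadata_path: str | Path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="sample_id")
    table.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def read_newick(path_or_str: str | Path) -> TreeNode:
    """Parse a single newick tree; missing branch lengths default to 0."""
    src = str(path_or_str)
    stripped = src.strip()
    if stripped.startswith("(") or stripped.endswith(";"):
        text = stripped
    else:
        text = Path(src).read_text()
    _check_parens(text)
    tree = TreeNode.read([text], convert_underscores=False)
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise FormatError(f"negative branch length on {node.name!r}")
    if tree.length is None:
        tree.length = 0.0
    if n_missing:
        logger.warning("%d branch lengths absent; defaulted to 0", n_missing)
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise FormatError("duplicate tip labels in tree")
    return tree


def _check_parens(text: str) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FormatError(
                    f"unbalanced parenthesis at character {offset}"
                )
    if depth != 0:
        raise FormatError(
            f"unbalanced parentheses: {depth} unclosed at end of input"
        )


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path))


# ---------------------------------------------------------------------------
# Distance matrices and environmental tables
# ---------------------------------------------------------------------------

def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    dm = DistanceMatrix(df.to_numpy(dtype=float), ids=[str(i) for i in df.index])
    if (dm.data < 0).any():
        raise FormatError("distance matrix has negative entries")
    return dm


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", index_label="id")


class EnvTable:
    """Per-site environmental measurements; missing values permitted."""

    def __init__(self, data: pd.DataFrame):
        if data.index.duplicated().any():
            raise FormatError("duplicate site ids in environmental table")
        if data.shape[1] == 0:
            raise FormatError("environmental table has no variables")
        self.data = data.astype(float)

    @property
    def site_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def variables(self) -> list[str]:
        return self.data.columns.tolist()


def read_env_table(path: str | Path) -> EnvTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return EnvTable(df)


def write_env_table(env: EnvTable, path: str | Path) -> None:
    env.data.to_csv(path, sep="\t", index_label="site_id")


# ---------------------------------------------------------------------------
# Pathway -> compound map
# ---------------------------------------------------------------------------

DEGRADATION_CLASS = "Degradation-Utilization-Assimilation"


@dataclass
class PathwayCompoundMap:
    """Mapping from each pathway to its entry compounds and pathway class."""

    compounds: dict[str, list[str]]
    classes: dict[str, str]

    def __post_init__(self) -> None:
        for pw, cls in self.classes.items():
            if not cls:
                raise FormatError(f"pathway {pw!r} has empty class label")
        for pw, comps in self.compounds.items():
            if self.classes.get(pw, "").startswith("Degradation") and not comps:
                raise FormatError(f"degradation pathway {pw!r} maps to no compound")

    @property
    def pathway_ids(self) -> list[str]:
        return sorted(self.compounds)

    def degradation_pathways(self) -> list[str]:
        return sorted(p for p, c in self.classes.items()
                      if c.startswith("Degradation"))


def read_pathway_map(path: str | Path) -> PathwayCompoundMap:
    """TSV with columns pathway_id, compound_id, class."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"pathway_id", "compound_id", "class"}
    if not need.issubset(df.columns):
        raise FormatError(f"pathway map needs columns {sorted(need)}")
    compounds: dict[str, list[str]] = {}
    for pw, comp in zip(df["pathway_id"], df["compound_id"]):
        compounds.setdefault(pw, []).append(comp)
    classes = dict(zip(df["pathway_id"], df["class"]))
    return PathwayCompoundMap(compounds, classes)


def write_pathway_map(pmap: PathwayCompoundMap, path: str | Path) -> None:
    rows = [(pw, c, pmap.classes[pw])
            for pw in sorted(pmap.compounds) for c in pmap.compounds[pw]]
    pd.DataFrame(rows, columns=["pathway_id", "compound_id", "class"]).to_csv(
        path, sep="\t", index=False)


def read_smiles_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV (compound_id, SMILES)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("SMILES table needs two columns: compound_id, smiles")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass
class FilterConfig:
    """Site/call filter chain settings for VCF import.

    The chain is applied in a fixed order: indel removal -> allele count
    (biallelic) -> per-call depth (calls below ``min_depth`` set missing) ->
    site missingness -> site quality -> minor allele frequency.  The MAF
    stage is skipped when ``keep_monomorphic`` is set (the nucleotide
    diversity branch of the pipeline, which needs invariant sites).
    """

    biallelic_only: bool = True
    min_depth: int = 5
    max_missing_frac: float = 0.10
    min_qual: float = 10.0
    min_maf: float = 0.05
    keep_monomorphic: bool = False


@dataclass
class GenotypeMatrix:
    """Diploid calls for individuals x loci, with positions and filter log.

    ``calls`` uses 0=hom ref, 1=het, 2=hom alt, -1=missing.  Positions are
    1-based (VCF convention) and strictly increasing within chromosome.
    """

    individuals: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    calls: np.ndarray
    filter_log: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.pos)):
            raise FormatError("calls shape does not match individuals x loci")
        valid = np.isin(self.calls, [CALL_HOM_REF, CALL_HET, CALL_HOM_ALT,
                                     CALL_MISSING])
        if not valid.all():
            raise FormatError("invalid genotype call codes")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise FormatError(
                    f"positions not strictly increasing on chromosome {c}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.pos)

    def subset_loci(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.individuals, self.chrom[mask],
                              self.pos[mask], self.calls[:, mask],
                              dict(self.filter_log))

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.individuals.index(i) for i in ids]
        return GenotypeMatrix(list(ids), self.chrom, self.pos,
                              self.calls[idx, :], dict(self.filter_log))


def read_vcf(path: str | Path, filters: FilterConfig | None = None
             ) -> GenotypeMatrix:
    """Read a VCF and apply the site/call filter chain.

    Returns the genotype matrix of sites passing the chain, with per-stage
    retained-site counts in ``filter_log``.
    """
    import cyvcf2

    if filters is None:
        filters = FilterConfig()
    try:
        vcf = cyvcf2.VCF(str(path), gts012=True)
    except OSError as exc:  # pragma: no cover - cyvcf2 error path
        raise IOError(f"cannot read VCF {path}: {exc}") from exc
    individuals = list(vcf.samples)
    n = len(individuals)

    chroms, positions, calls_rows = [], [], []
    log = {"input": 0, "indel": 0, "allele_count": 0, "missingness": 0,
           "quality": 0, "maf": 0}
    for var in vcf:
        log["input"] += 1
        # stage 1: indel removal
        if var.is_indel:
            log["indel"] += 1
            continue
        # stage 2: allele count (<=2 alleles)
        if filters.biallelic_only and len(var.ALT) > 1:
            log["allele_count"] += 1
            continue
        gts = np.asarray(var.gt_types, dtype=np.int8)  # 0,1,2,3=missing
        calls = np.where(gts == 3, CALL_MISSING, gts)
        # stage 3: per-call depth -> missing
        depths = var.format("DP")
        if depths is not None:
            depths = np.asarray(depths).reshape(-1)
            calls = np.where(depths < filters.min_depth, CALL_MISSING, calls)
        # stage 4: site missingness
        miss_frac = float(np.mean(calls == CALL_MISSING))
        if miss_frac > filters.max_missing_frac:
            log["missingness"] += 1
            continue
        # stage 5: site quality
        qual = var.QUAL
        if qual is not None and qual < filters.min_qual:
            log["quality"] += 1
            continue
        # stage 6: minor allele frequency (skipped when keeping monomorphic)
        if not filters.keep_monomorphic:
            ok = calls >= 0
            n_alleles = 2 * int(ok.sum())
            if n_alleles == 0:
                log["maf"] += 1
                continue
            alt = int(calls[ok].sum())
            maf = min(alt, n_alleles - alt) / n_alleles
            if maf < filters.min_maf:
                log["maf"] += 1
                continue
        chroms.append(var.CHROM)
        positions.append(var.POS)
        calls_rows.append(calls)

    log["retained"] = len(positions)
    if not positions:
        warnings.warn("all sites removed by the filter chain", stacklevel=2)
        return GenotypeMatrix(individuals, np.empty(0, dtype=object),
                              np.empty(0, dtype=np.int64),
                              np.empty((n, 0), dtype=np.int8), log)
    calls_mat = np.vstack(calls_rows).T  # individuals x loci
    return GenotypeMatrix(individuals, np.array(chroms, dtype=object),
                          np.array(positions, dtype=np.int64), calls_mat, log)


_GT_STRINGS = {CALL_HOM_REF: "0/0", CALL_HET: "0/1", CALL_HOM_ALT: "1/1",
               CALL_MISSING: "./."}


def write_vcf(path: str | Path, individuals: Sequence[str],
              chrom: Sequence[str], pos: Sequence[int],
              ref: Sequence[str], alt: Sequence[Sequence[str]],
              calls: np.ndarray, qual: Sequence[float],
              depth: np.ndarray | None = None) -> None:
    """Write a minimal VCF 4.2 with GT (and DP when given) per call.

    ``alt`` entries are lists of alternate alleles (so multi-allelic and
    indel sites can be emitted for filter-chain testing).  ``calls`` uses the
    GenotypeMatrix coding and applies to the first alternate allele.
    """
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
             '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">']
    contigs = []
    for c in chrom:
        if c not in contigs:
            contigs.append(c)
    for c in contigs:
        lines.append(f"##contig=<ID={c}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
              "INFO", "FORMAT"] + list(individuals)
    lines.append("\t".join(header))
    fmt = "GT:DP" if depth is not None else "GT"
    for j in range(len(pos)):
        alts = ",".join(alt[j]) if alt[j] else "."
        fields = [str(chrom[j]), str(pos[j]), ".", ref[j], alts,
                  f"{qual[j]:g}", "PASS", ".", fmt]
        for i in range(len(individuals)):
            gt = _GT_STRINGS[int(calls[i, j])]
            if depth is not None:
                fields.append(f"{gt}:{int(depth[i, j])}")
            else:
                fields.append(gt)
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")
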