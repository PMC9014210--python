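# Methods

This note documents the models, conventions and numerical choices behind
`invamicro`, and what the synthetic-data generator does and does not
emulate.

## Scope and data model

The package implements the desk side of a comparative study of the gut
microbiome of an invasive clonal clam and co-occurring native freshwater
mussels, together with the clam's population genomics. It starts from the
outputs of upstream tools — a denoised ASV count table, an ASV phylogeny,
a predicted-pathway (PICRUSt2-style) table, and a VCF of RAD-seq genotype
calls — and carries them through diversity, community-structure,
source-attribution, functional and population-genomic analyses. Upstream
inference (denoising, tree placement, functional prediction, variant
calling) is out of scope.

## Alpha diversity

* **Rarefaction** subsamples each sample without replacement
  (multivariate hypergeometric) to a fixed depth; samples below the depth
  are dropped and logged. Bivalve samples are rarefied to 4,000 reads and
  the shallower environmental (seston/sediment) samples to 2,000, the
  depths the study design prescribes.
* **Shannon diversity** uses natural logs and is reported as an effective
  number of species, `exp(H)`.
* **Faith's PD** uses the *rooted* convention: the score of a single tip is
  its full root path. Conventions differ between tools; the rooted form is
  what picante-style implementations produce and is stated here explicitly
  because unrooted Faith's PD of a singleton is zero.
* **Allen's phylogenetic entropy** is `H_p = Σ_b l_b (−p_b ln p_b)` over
  branches, with `p_b` the relative abundance of the subtree below branch
  `b`. Its effective number of species is `exp(H_p / T̄)` with `T̄` the
  abundance-weighted mean root-to-tip distance. This normalisation is a
  convention choice (others exist); it was selected because it makes the
  phylogenetic effective number collapse to the taxonomic `exp(H)` on star
  trees with unit branches, so the two indices are directly comparable.
* **Chao coverage** is `1 − (f₁/n)·[(n−1)f₁ / ((n−1)f₁ + 2f₂)]`;
  with no singletons the estimate is exactly 1.

## Beta diversity

Unweighted UniFrac is the fraction of tree length unique to one of two
communities; weighted UniFrac is the normalised (generalised-UniFrac
α = 1) abundance form. Both are computed from a branch × tip incidence
matrix built once per tree; an independent per-branch enumeration oracle
checks them to 1e-12 in the tests. Neither UniFrac nor Bray-Curtis is
asserted to satisfy the triangle inequality — only symmetry and identity.

Predicted-pathway tables are clr-transformed (pseudocount 0.5 by default)
before dissimilarity. Bray-Curtis is undefined on the negative clr values,
so the default "functional Bray-Curtis" shifts the clr table by its global
minimum first; the Euclidean (Aitchison) distance is available as the
mathematically cleaner alternative. Both are exposed because the combination
of clr with Bray-Curtis, while used in practice, is irregular.

PCoA is the classical Gower double-centering eigendecomposition. Negative
eigenvalues are reported, never clipped; coordinates are returned for
positive-eigenvalue axes only.

## Permutation statistics

All permutation tests use `p = (1 + #{perm ≥ obs}) / (1 + n_perm)` with an
explicit seed, so the smallest attainable p is `1/(n_perm+1)` and results
are exactly reproducible. PERMANOVA is the one-factor Gower partition with
unrestricted label permutation; pairwise post-hocs are Bonferroni-adjusted.
The dispersion test computes betadisper-style distances to group centroids
in PCoA space (imaginary-axis correction, floored at zero) and *re-fits
centroids for every permuted grouping*, which keeps its type-I error at the
nominal level (permuting fixed distances is mildly liberal). envfit reports
the squared multiple correlation of a variable with the first two
ordination axes and permutes the variable; samples whose site lacks a
measurement are dropped per variable.

The host co-variation procedure repeats, 500 times: draw equal-size random
subsamples of the two host groups at every shared site, average each
group's ASV proportions per site, compute a site × site dissimilarity for
each group, and Mantel-test the two matrices. The median of the 500
p-values is the headline. Site-averaged profiles are used because that is
the only reading that yields two equal-dimension site matrices; per-site
subsample size is the smaller group size at that site. At least four
shared sites are required (a Mantel test is undefined below four objects).

Distance-decay correlations (dissimilarity vs. river distance restricted to
same-river pairs) report both the naive asymptotic Spearman p — which
treats non-independent pairs as independent and is anti-conservative — and
a within-river permutation p; the permutation p is the headline.

Kruskal-Wallis and rank-sum comparisons switch to exact enumeration over
all labeled group assignments when total n ≤ 10.

## Degradation potential

The chain is: pairwise compound structural dissimilarity (1 − Tanimoto on
2048-bit topological path fingerprints from SMILES, or a user-supplied
matrix in [0,1]) → pathway × pathway dissimilarity as the mean over all
cross compound pairs → UPGMA dendrogram → per-sample structural richness =
Faith's PD on the dendrogram over the degradation pathways predicted
present (abundance > 0). The score is presence-based and therefore
invariant to abundance scaling. A pairwise presence-based (unweighted
UniFrac) matrix on the same dendrogram is emitted alongside for
community-level comparisons, since "structural richness" is per-sample but
UniFrac is pairwise — both quantities are useful and both are provided.

UPGMA was chosen over complete/Ward linkage because the pathway
dissimilarity is itself a mean over compound pairs, and mean linkage keeps
the dendrogram heights on that same scale; equal-height ties are broken by
the lexicographically smallest member id so the topology is deterministic.
Tip depth is half the merge height, making the cophenetic distance of the
output equal the UPGMA merge heights exactly. The specific fingerprint is a
documented stand-in: published analyses of this kind rarely state the
fingerprint type, and any dissimilarity in [0,1] can be supplied instead.

## Source attribution

Each sink is modelled as `Multinomial(N, Σ_j α_j γ_j)` over candidate
source profiles plus an unknown source, and `α` is estimated by EM. Known
source profiles are fixed at their smoothed observed proportions
(pseudocount 1e-6 of depth); full FEAST-style joint re-estimation of source
compositions is deliberately not done. The unknown profile starts uniform
and is re-estimated each M-step as a MAP update under a symmetric Dirichlet
prior with total weight 4 × sink depth. The prior is essential, not
cosmetic: with a free unknown profile the global maximum-likelihood
solution is always `α_unknown = 1` with the unknown equal to the empirical
sink distribution, and measured recovery error was ~0.2; with the prior,
mean |α̂ − α| ≈ 0.02 at depth 5,000 with three sources. The reported
`ll_trace` is the EM objective (data log-likelihood plus the log-prior),
which is non-decreasing by construction.

The reciprocal design enumerates one task per sink specimen: native-mussel
sinks draw sources from all co-occurring other-species specimens (other
mussels, invasive hosts, seston, sediment); invasive sinks draw from
co-occurring native mussels, seston and sediment. Sources enter
per-specimen and are aggregated per species afterwards. Two identical
source profiles make their individual proportions non-identifiable (their
sum is still meaningful); this triggers a warning.

Known limitation: when candidate sources are strongly correlated with the
sink's own unexplained component (e.g. all communities at a site share a
site signature), part of that component is attributed to the correlated
sources rather than to "unknown". This source-absorption bias is inherent
to mixture-based source tracking and inflates host-to-host contribution
estimates on strongly site-structured data.

## Population genomics

VCF import applies a fixed filter chain — indel removal → allele count
(≤ 2) → per-call depth (< 5 ⇒ call set missing) → site missingness
(> 10% ⇒ site dropped) → site quality (< 10) → minor allele frequency
(< 0.05, boundary inclusive) — with per-stage retained counts logged.
Depth acts per genotype call *before* site missingness is evaluated,
reproducing the two-stage vcftools behaviour; missingness is per site.
The nucleotide-diversity branch keeps monomorphic sites (the MAF stage is
skipped); π per site is `2·c_ref·c_alt / (n(n−1))` over non-missing
alleles, averaged unweighted per chromosome and river, zeros included.

F_IS is `1 − H̄_obs/H̄_exp` (ratio of locus averages) with the
small-sample-corrected gene diversity `2pq·2n/(2n−1)`, monomorphic loci
excluded, and a loci-bootstrap percentile CI. SNPs heterozygous in every
typed individual — the signature of a clonal diploid lineage — are removed
before structure analyses, then loci are thinned greedily to ≤ 1 SNP per
kb (first SNP per chromosome kept; deterministic, matching `--thin`
semantics). Individual distances are percent allelic differences (dosage
Hamming / 2·loci). Pairwise F_ST is Weir & Cockerham's θ as a ratio of
sums over loci, negative estimates unclipped, with significance as the
fraction of loci bootstraps at or below zero.

Genetics–microbiome correlation runs at three levels: a global Mantel of
individual allelic distances against individual microbiome dissimilarities,
a within-river Spearman via the distance-decay machinery, and a
population-level Mantel of pairwise F_ST against UniFrac between
site-averaged microbiomes (mean relative abundances per site, averaged per
river pair).

## The synthetic-data generator

The generator emulates the statistical structure of the field design, not
its sequences: 6 rivers, 16 sites, six native mussel species plus the
invasive clam at every site (4 invasive, 2 per native species), one seston
and one sediment sample per site; ~300 ASVs on a pure-birth tree;
lognormal sequencing depths (median ≈ 10,000 for bivalves, ≈ 5,000 for
environmental samples). Each host species has a lognormal signature over
ASVs; sites add an environmental response — a NO3 gradient along river
position acting on a random 30% of ASVs — plus a site-level random shift.
Invasive-host compositions are a convex mixture of the co-occurring native
species (14% in total), seston (25%), sediment (5%) and a novel
invasive-specific component (56%); native hosts are mostly their own
signature with small environmental and invasive admixture. Counts are
Dirichlet-multinomial draws. These mixing weights are the planted truth the
source-tracking stage is evaluated against.

Sites are spread evenly along each river. This is a deliberate design
choice: with 2–3 sites per river, random positions let river-mean NO3
differ by chance, which would create river-level microbiome structure that
spuriously correlates with the river-structured genetics. Balanced
positions keep the environmental driver orthogonal to river identity, so
the generator genuinely implements "microbiome driven by environment, not
genotype" — the qualitative configuration the end-to-end tests probe.

Genotypes are one clonal lineage: 21% of SNPs are heterozygous in every
individual (the fraction observed in clonal clam RAD data), and the rest
drift among rivers under a Balding-Nichols model (divergence 0.03, chosen
so pairwise F_ST is weak, ≈ 0.01, but significant at the full design size)
with within-river excess heterozygosity tuned toward F_IS ≈ −0.85 where
allele frequencies permit (feasibility caps the excess at loci away from
p = 0.5, so realized F_IS is ≈ −0.6). Ancestral frequencies concentrate
near 0.5, as variants segregating within a clonal diploid do. The VCF
writer plants counted indel, triallelic, low-quality and high-missingness
sites so the import filter chain can be checked against exact truth.
Predicted pathways get host-type signatures with a planted invasive boost
(+1.5 on the log scale) on degradation pathways, making the invasive
degradation-potential excess detectable and sign-stable at the default
design size.

What the generator does **not** emulate: sequencing error and chimeras,
taxonomic identity of ASVs, compositional zero-inflation beyond the
multinomial, linkage between SNPs beyond shared river frequencies, real
MetaCyc pathway/compound structure, and realistic π magnitudes (the
simulated variant density is far higher than RAD data, so simulated π is
~0.1, not ~0.005). Passing tests therefore demonstrate correctness of the
computations and calibration of the statistics under the planted model,
not agreement with any field dataset's printed values.

All randomness flows from one seed through spawned child sequences, so
adding a component does not perturb earlier draws and equal configs give
byte-identical outputs.

## Problem sizes used by the test suite and acceptance script

Unit tests run on a scaled-down design (3 rivers, 6 sites, 2 native
species, 80 ASVs, 400 SNPs). The end-to-end test and
`scripts/acceptance.py` use the full default design (288 samples, 300
ASVs, 2,000 variant + 8,000 monomorphic sites); null calibrations use 500
replicates of 15–20 samples at 99 permutations. These sizes were chosen so
the whole suite completes in a few minutes on one CPU while keeping every
statistical check at its stated power.

## Known limitations

* Single-factor PERMANOVA only; no strata, no partial Mantel, no db-RDA.
* The Allen effective-number normalisation is one of several conventions.
* Source-tracking estimates are biased toward correlated sources (above).
* WC84 θ under strong excess heterozygosity is biased slightly downward at
  low divergence; negative estimates are reported as computed.
* Hill-number continuum beyond q = 0, 1 is not implemented.
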