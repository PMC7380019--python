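# Methods

`rflscan` reimplements, at desk scale, the standard discovery procedure for
restorer-of-fertility-like (RFL) pentatricopeptide-repeat (PPR) genes in
plant genome assemblies and the downstream molecular-evolution analysis.
This note documents the models, the numerical choices, what the synthetic
data emulate, and the limits of what the tests demonstrate.

## ORF extraction

Candidate proteins are the maximal stop-free stretches of all six
translated frames, with no start-codon requirement: the motif scan decides
what is a PPR gene, and demanding ATG initiation would discard genuine
repeat tracts on partial scaffolds. The default length cutoff is 93 aa
(inclusive: a 93-aa ORF passes), matching the shortest RFL proteins
reported in reference annotations. Codons containing ambiguity codes
translate to `X`; `X` scores zero (background) at every motif position,
and fully masked stretches yield no ORFs. Coordinates are 0-based
half-open internally and 1-based inclusive in every output (GFF3
convention); tabular reports render reverse-strand spans high→low.

## Motif model and family classification

Each motif class (P: 35 aa, L: 36 aa, S: 31 aa) is a position-specific
log-odds profile in bits: column frequencies with Laplace (add-one)
pseudocounts over the seed alignment, against a background of equilibrium
amino-acid frequencies. The published barley analysis used profile HMMs
that are not printed anywhere; profiles are therefore an *input artifact*
here. The repository ships synthetic seed alignments (40 rows around a
canonical P-motif consensus, with distinct heavily diverged L/S variants)
that drive all tests and simulations; reproducing a published annotation
requires the published motif models.

Scanning is glocal: the whole profile is aligned to every protein window
whose width lies within ±4 aa of the nominal motif length (natural PPR
motifs span 31–36 aa), under affine gap penalties (open 11, extend 1
bits). Per end position the best-scoring window is kept (ties to the
smaller start); hits above the per-motif threshold (default 8 bits;
configurable — only the protein-level thresholds are published) are then
reduced to the maximum-total-score non-overlapping set by weighted
interval scheduling. An admissible prefilter makes this exact scan fast:
the width-unconstrained "fit" alignment score per end position upper
bounds every fixed-width window score (extra leading/trailing gaps only
subtract), so windows are enumerated only where that bound clears the
threshold. The unit tests verify exact equality with a brute-force
all-windows enumeration.

The protein score is the *sum* of chained per-motif bit scores — an
approximation to a full-sequence hmmsearch score, which adds its
per-domain scores under an E-value model. Classification uses the
published strict thresholds: P-class requires summed score > 100 and no
L/S motifs; PLS-class requires > 240 with at least one L and one S motif
(a strict P-L-S triplet grammar is reported as a column, not used as a
filter). Motif-structure strings are hyphen-joined tokens of inter-motif
segment lengths and class letters, zero-length segments omitted.

## RFL assignment and genomic architecture

A P-class model is called RFL when two tests agree, reconstructing the
published two-route identification (phylogenetic placement and
orthogroup membership):

1. its nearest neighbour in a labelled reference panel, by global
   identity (Needleman–Wunsch, BLOSUM62, 11/1 gaps; identical columns /
   alignment columns), is RFL-labelled at ≥ 60% identity (default floor,
   motivated by the 64–100% interspecific identity range of RFL
   orthologues); and
2. a neighbor-joining placement of the query among the panel sequences
   keeps the RFL-labelled leaves plus the query monophyletic with
   respect to the non-RFL leaves (tree rooted at the first non-RFL
   sequence). This "no outsider inside the joint clade" reading is
   robust to queries slightly more diverged than the panel crown, which
   a strict crown-membership test misclassifies.

Pseudogene rule: a gene is flagged when the mitochondrial-targeting
prediction is negative or a motif hit shorter than its nominal length
abuts either ORF terminus (motif truncated by the ORF/scaffold
boundary). The built-in targeting predictor is a deliberately naive
N-terminal heuristic — arginine+serine enrichment minus acidic content
over the first 60 aa, threshold 0.15 — and is labelled as such in the
output log; externally computed prediction tables can be supplied
per-gene instead.

Clusters are single-linkage groups along each sequence with inter-gene
gap ≤ `max_gap` (default 3 Mb: reported sub-clusters span ~2 Mb while
singlets sit ≥ 10 Mb apart, and no numeric criterion is published — the
default separates the two regimes and is configurable). Gene density
counts gene midpoints per half-open 2-Mb tiling window. Full-length
means ≥ 10 motifs; shorter RFLs are retained with `full_length=False`.

## Orthogrouping (POGs)

Greedy incremental clustering with CD-HIT `-c X -n 5 -g 1 -G 0 -aS 0.99
-d 0` semantics: sequences sorted by decreasing length; each joins the
best-identity existing representative meeting the identity threshold and
the coverage constraint (≥ 99% of the shorter sequence spanned by the
local alignment), else founds a cluster. Identity is identical columns /
alignment columns of the best local alignment (`-G 0`), computed with
Biopython's exact PairwiseAligner (BLOSUM62, 11/1). Ties in best
assignment go to the longer representative, then the smaller id. The
k-mer prefilter counts shared 5-mers *with multiplicity* (repeat
proteins share few distinct k-mers) and only skips pairs provably below
the threshold: with at most `L(1-c)/c` non-identical columns, each
destroying at most `n` k-mers of the shorter sequence, a qualifying pair
shares at least `(L-n+1) - n⌊L(1-c)/c⌋` k-mers. Disabling the filter
never changes the result (tested).

The hierarchy runs three rounds at 98/96/93% identity, re-clustering
representatives each round; a POG is the union of members through the
hierarchy, its representative the longest member. Amino-acid mode is
assumed (the published thresholds and tool defaults imply protein
input). POGs may contain several reference genes; they are reported, not
split. Member identities are recorded along the merge chain (identity to
the representative at join time, propagated conservatively as a
minimum), not recomputed against the final representative.

## Codon site models

Per eligible POG (members from **more than 4** accessions; sequences
**longer than 400** aa — both strict), member proteins are aligned with a
deterministic progressive aligner (UPGMA guide tree on 3-mer distances;
profile–profile Needleman–Wunsch with expected-BLOSUM62 column scores,
affine gaps 10/0.5). It targets the near-identical sequences of an
orthogroup, not remote homology. The alignment is back-translated to
codons; columns containing a gap, stop or ambiguous codon are removed
before fitting (the count is reported, and site indices map back through
the retained-column index). The tree is neighbor-joining
(scikit-bio) on maximum-likelihood pairwise JTT distances, negative
branch lengths clamped to zero — a deliberate stand-in for a full ML
search: the topology only enters as a fixed input to the codon fit, and
the original procedure itself seeds its search with NJ/BioNJ trees.

The substitution model is GY94 with F3x4 codon frequencies estimated
empirically from the data: rates κπ_j / π_j / ωκπ_j / ωπ_j for
synonymous transitions/transversions and nonsynonymous
transitions/transversions, zero for multi-position changes; the
generator is scaled by the mixture-average rate so branch lengths are
expected substitutions per codon under every model. Site models:

* **M0** — single ω; branch lengths optimised here and then held fixed
  for the site models (configurable), the standard practice that
  stabilises the boundary-heavy mixture optimisations.
* **M1a** — p₀ with ω₀ ∈ (0,1), p₁ with ω₁ = 1.
* **M2a** — M1a plus p₂ with ω₂ ≥ 1.
* **M7** — beta(p,q)-distributed ω discretised into K = 10
  equal-probability categories at their medians.
* **M8** — M7 plus a point mass ω_s ≥ 1.

Likelihoods use Felsenstein pruning with per-node, per-site rescaling;
transition matrices come from one symmetrised eigendecomposition per ω
(the GY94 generator is reversible). Optimisation is bounded L-BFGS-B on
(κ, class parameters[, branch lengths]) with stick-breaking proportions;
bounds κ ∈ [0.1, 20], ω ∈ [10⁻⁴, 50], ω₂/ω_s ∈ [1, 50], beta parameters
∈ [0.005, 99], branch lengths ∈ [10⁻⁸, 25]. Site models restart from
three spread deterministic starting points (M0's smooth surface gets
one); restarts are configurable. A fit whose optimizer did not converge
is flagged, not discarded.

LRTs compare M1a–M2a and M7–M8 with 2 df, the statistic clamped at zero
(a negative raw statistic flags an optimizer failure). Following the
published significance bands, no multiple-testing correction is applied;
outputs carry the band string (`*` for p < 0.1 through `****` for
p < 10⁻²⁰).

**BEB.** Posteriors of the ω > 1 class integrate over hyperparameter
uncertainty on a uniform grid (10 points per dimension by default;
reduced grids allowed): for M2a, (p₀, p₁) on the simplex triangle, ω₀ on
(0,1), ω₂ on (1,11); for M8, p₀ on (0,1), beta p and q on (0,2), ω_s on
(1,11). Grid points are weighted by their data likelihood; κ, branch
lengths and codon frequencies stay at their MLEs, and each class
generator keeps the MLE mixture scaling so branch lengths retain their
fitted meaning across grid points. With uninformative data the site
posterior correctly collapses to the prior mean of the grid weights.

**Motif-position profile.** Each retained codon column is mapped to a
residue of a reference member (the longest full-length member; which
member anchored the published per-position figure is not stated), that
residue to its 1–35 offset within an annotated motif (longer motifs
contribute only offsets ≤ 35), and BEB positive-selection posteriors are
averaged per offset, separately for cluster-resident genes and singlets.

## Synthetic data

The generators define the study conditions for every test:

* **Genomes** — chromosomes of uniform random background DNA with
  planted genes: an arginine/serine-rich 40-aa targeting peptide, an
  acidic linker, 11–19 tandem P motifs sampled from the packaged profile
  at 5% per-position substitution, a short tail; reverse-translated with
  uniform synonymous codon choice and bracketed by in-frame stops so the
  recovered ORF coincides with the planted interval. Cluster/singlet
  layout, intra-cluster gaps (10 kb) and inter-feature gaps (150 kb) are
  configured per run; `suggested_max_gap` gives the separating threshold
  for annotation. Pseudogenes alternate between two mechanisms: no
  targeting peptide, or truncation 3 aa into the final motif (within the
  ±4 aa hit-length tolerance, so the clipped motif is still detected and
  trips the boundary rule). A truth table accompanies every simulation
  and every pipeline test compares against it, never against captured
  output.
* **Accession families** — variants with an exact number of
  substitutions, `round((1−t)·L)` at uniform random positions, realising
  each identity target within 1/L; no indels by default.
* **Codon alignments** — per-site class draws (or an explicit per-site ω
  array), root codons from the F3x4 stationary distribution, evolution
  by exp(Q(ω)t) down the tree; stop codons cannot arise because the
  generator excludes them. Per-site truth (class, ω) is emitted.

What the synthetic data do **not** emulate: introns and UTR structure,
assembly fragmentation and chimerism of short-read data, capture bias,
indel evolution within orthogroups, and profile misspecification
(simulated motifs come from the same profiles that scan them). Passing
tests therefore demonstrate the correctness of the algorithms under the
stated models, not recovery rates on real exome-capture data.

## Problem sizes and determinism

The test and acceptance workloads use 8 taxa × 400–500 codons for
parameter recovery (20 M0 and 10 M2a replicates), 3–5-taxon trees for
the exhaustive-summation likelihood oracle, 100 random fixtures of ≤ 60
sequences for the clustering oracle, a 1-Mb chromosome with the
2/8/4-gene sub-cluster + singlet layout for architecture recovery, and
two 8-motif genes for the motif-position profile. These sizes were
chosen so each check carries clear statistical signal; every stage is
seed-deterministic and a run's config (with hash) is serialised next to
its outputs.

## Known limitations

* Summed per-motif scores approximate full-sequence hmmsearch scores;
  absolute counts against published thresholds depend on that choice
  (the published text does not state which score variant was
  thresholded).
* The shipped profiles are synthetic fixtures; published motif models
  must be supplied to reproduce published annotations.
* The naive targeting-peptide heuristic is a stand-in; real analyses
  should import predictions from a dedicated tool.
* Greedy clustering reproduces CD-HIT's rules, not its implementation
  bit-for-bit (different aligner, exact rather than heuristic
  prefilter).
* M7/M8 fitting uses the common K = 10 median-discretisation; very
  skewed beta shapes are represented coarsely.
* The M1a–M2a null distribution at the boundary is conservative when
  referred to χ²₂; reported p-values inherit that conservatism.
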