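# Methods

`netcombo` prioritizes minimal drug combinations for a complex disease by
combining a mechanistic view (what the disease and each drug do to the
transcriptome, represented as co-expression networks) with a chemocentric
view (what the drugs are, represented by their SMILES strings and target
sets). This note records the models, the parameter choices and their
rationale, what the synthetic data does and does not emulate, and the
numerical decisions a maintainer would want spelled out.

## Candidate-gene scoring

Input is a genes × samples matrix of normalized, non-negative expression
values (FPKM-like) with a strict paired design: every subject contributes
exactly one disease and one control sample, and at least 10 matched pairs
are required at the pipeline level (configurable). All log transforms use
log2(v + 1); the pseudocount guards against zeros in normalized RNA-seq.

Two nonparametric tests capture two distinct notions of deregulation:

* a **Wilcoxon signed-rank test** on per-subject (disease − control)
  differences of the log values detects location shifts. Zero differences
  are discarded; the exact null distribution is used for up to 25 remaining
  pairs, otherwise the normal approximation with continuity correction.
  All-zero genes are degenerate and get p = 1 with a warning.
* a **two-sided F-test** on the ratio of sample variances
  s²_disease / s²_control of the log values detects variability changes,
  with p = 2·min(P(F ≤ f), P(F ≥ f)) under F(n_d − 1, n_c − 1), capped at 1.
  Zero variance in both groups gives p = 1; in exactly one group, the
  smallest positive double (maximal evidence), both warned.

Neither p-value filters genes. Each gene instead receives, per test t,

    SS_t = | logFC · (−log10 p_t) |

where logFC is the difference of mean log2(v + 1) between conditions. The
log base is a free choice (any base produces identical rankings); log10 is
the convention for p-values. Both SS lists use the same expression logFC —
including the variance branch, where the formula is applied as written; a
consequence is that genes with a pure variance change and no mean shift are
ranked mostly through their −log10 p factor. Each list is ranked from
highest to lowest SS with lexicographic gene-id tie-breaking (bitwise
reproducibility), and the **union of the top 10%** (floor(0.1·G) per list)
is carried forward. No multiple-testing correction is applied, by design:
the p-values act only inside a ranking score.

## Consensus co-expression inference

The disease network is inferred from the disease samples of the selected
genes; drug mechanism-of-action (MOA) networks are inferred the same way
from replicate perturbational profiles on a reduced "landmark" gene panel
(default 100 genes; a stand-in for assay panels an order of magnitude
larger). A drug qualifies for MOA inference only with **more than five
replicates**.

The ensemble grid crosses three post-processing algorithms — CLR (z-score
against row/column background, negatives clipped, combined as
√(z_i² + z_j²)), ARACNE (data-processing-inequality pruning: an edge is
removed when some third gene makes it the strict minimum of a triangle;
tolerance ε = 0), MRNET (max-relevance min-redundancy forward-selection
scores) — with three association estimators (|Pearson|, |Spearman|,
empirical mutual information) and, for MI only, two discretizers
(equal-frequency, equal-width; default bin count ⌈√n⌉). Every resulting
matrix is min-max rescaled to [0, 1]. The exact consensus operator of the
ensemble tool the design follows is not reproduced bit-for-bit; here each
adjacency is edge-rank-normalized to [0, 1] and the consensus weight is the
element-wise **median of normalized ranks**, after which only the top 2N
edges are retained (configurable). Rank-median aggregation is robust to a
minority of discordant ensemble members and is invariant to monotone
rescalings of individual inference outputs.

**Hub ranking.** Nodes are ranked on six lists — weighted degree, mean
shortest-path distance to reachable nodes (ascending; listed separately
from closeness, so implemented as a distinct measure), betweenness,
closeness, eigenvector centrality, and SS (the larger of the two test SS
values, covering both deregulation types) — and aggregated by mean-rank
**Borda consensus** with lexicographic tie-breaking. Path-based measures
convert weights to distances via d = 1 − w + 10⁻⁶; centralities are
computed per connected component, and an isolated node gets the worst
path-based ranks.

## Prior-knowledge filtering

Association sources are grouped into three categories — Interaction,
Regulation, Functional — each holding any number of layers (a manifest
lists file, type, category; the concrete nine-source catalog of the
original study is not reproduced). A bipartite gene–term layer projects to
a gene–gene network by connecting genes that share at least one term;
gene–gene layers pass through after symmetrization (optionally they can be
projected by shared partners instead). Layers merge **within** a category
by edge union, and the final prior keeps only edges present in **all
three** categories. The disease network is then restricted to
prior-supported edges, preserving weights and isolated nodes (node-set
stability for ranking); a support rate below 1% triggers a
namespace-mismatch warning. A single gene identifier namespace is assumed
throughout.

## Drug features

* **MOA distance**: Hamming–Ipsen–Mikhailov between MOA networks.
  H is the mean absolute adjacency difference over unordered pairs
  (weighted networks compared directly; a binary option exists). IM is the
  L2 distance between Laplacian spectral densities: frequencies
  ω_i = √λ_i (the trivial zero eigenvalue dropped), each smoothed by a
  Lorentzian of width γ, normalized to unit mass on [0, ∞) using the
  closed-form Lorentzian integral, with γ calibrated per node count by
  root-finding so that IM(empty, complete) = 1 (γ ≈ 0.45–0.48 for
  N = 10–100; cached). The integral is evaluated on a 4096-point grid
  reaching √(2N) + 10γ + 5, which holds the calibration fixed point to
  well under 10⁻³. HIM = √(H² + IM²)/√2 (equal weighting, ξ = 1).
* **Structural distance**: Levenshtein edit distance between raw SMILES
  (no canonicalization by default — distances are taken on the strings as
  retrieved; canonicalization is an opt-in concern for the caller). The
  edit distance is computed by `edlib`; tests cross-check it against an
  independent dynamic-programming oracle.
* **Target dispersion**: mean unweighted shortest-path length over all
  cross pairs of two drugs' target sets on the filtered disease network.
  Identical genes contribute 0; pairs in different components contribute a
  finite penalty |V|, which dominates any realizable path while keeping
  objectives finite.
* **Effect score**: ES = N_t / M_R with N_t the number of targets mapped
  into the network and M_R the median Borda consensus rank of those
  targets (mean of the middle two for even counts). Many central targets
  give a high score. Rank indices are the Borda consensus ranks, which
  aggregate the centrality measures and SS.

Drugs without a mapped target or with fewer than six replicates are
excluded with a logged reason. All pairwise tables are symmetric with zero
diagonals (a drug's self-distance is unused by the objectives).

## Multi-objective optimization

A combination x ⊆ Σ is a binary chromosome over the drug universe. Five
objectives are maximized: the pairwise sums of HIM, Levenshtein and target
shortest-path distances, each normalized by **1/|x|** (as specified in the
optimization design; pair-count normalization is available behind a config
flag), the **mean** member effect score (coverage; the aggregation was
left open in the design — the mean keeps this axis independent of size,
whereas a sum would reward cardinality and duplicate the size objective;
sum available via config), and −|x|. Combinations with fewer than two
drugs carry a large finite sentinel vector dominated by every valid
vector, so selection purges them without operator repair.

The search uses a population of 100; each generation creates exactly 20
offspring, each by one-point crossover (probability 0.70; two distinct
uniformly chosen parents, random cut, first child kept) or bit-swap
mutation (probability 0.30; a uniformly chosen parent is cloned, then each
position fires with probability 0.10 and exchanges its bit with a
uniformly chosen other position — the popcount is conserved). Parents and
offspring compete under **NSGA-II**: fast non-dominated sorting, fronts
admitted in order, the partial front truncated by descending crowding
distance (boundary points infinite; index order breaks ties, making
selection deterministic). The default budget is 2,000 generations
(convergence traces show the exploratory phase ending around 1,000 on
realistic problem sizes); tests and the acceptance script use 500–2,500
depending on what they measure.

The **Hall of Fame** keeps the 10 best solutions of the whole run. It is
backed by an unbounded archive of all mutually non-dominated evaluated
individuals (deduplicated by chromosome; equal objective vectors from
different chromosomes are all retained), with the public 10-member view
truncated by crowding distance. Keeping the full archive guarantees that
no evaluated individual ever dominates a reported member.

**Stability** is assessed by rerunning the optimizer (default 10 runs)
with distinct seeds derived from one master seed. All runs' HoF members
are aggregated into a drug–drug frequency network (edge weight = number of
HoF solutions containing both drugs) and pairwise run overlap is
summarized by the Jaccard index of drug-pair sets.

All randomness flows through a single `numpy.random.Generator` per run;
identical seeds reproduce populations, traces, HoFs and output files
bitwise.

## Synthetic study conditions

The generators provide self-contained inputs with the statistical
structure the method assumes, sized so a full run completes in minutes on
one CPU: 300 genes × 15 matched pairs, 10 interleaved co-expression
modules (within-module correlation 0.6 via a shared module factor,
residual SD 0.8, subject effect SD 0.3 for the paired structure), 10%
planted mean-shift genes (±1.5 log2 units) and 10% disjoint planted
variance genes (residual SD ×4 in disease) — variance inflation of 2–4×
and log2 shifts above 1 are typical magnitudes for strongly deregulated
tumor genes. The ground-truth network is the union of within-module
cliques; prior layers subsample it (70% per layer, every truth edge
guaranteed per category) and add 10% spurious edges, which survive the
triple intersection only when drawn in all three categories.

The drug library (20 drugs, 100 landmark genes, 8 replicates) plants one
ideal pair: disjoint hub-gene target sets centered on the two most distant
high-degree nodes of the filtered disease network, replicate profiles
perturbing different landmark modules, and SMILES-like strings built from
a token grammar such that the planted pair's edit distance is the strict
maximum over all pairs (the two planted strings are long and mutually
alphabet-disjoint, while every ordinary string carries short motifs of
both). The strict maximum makes the planted pair Pareto-optimal by
construction: no other pair can match it on the structural axis and any
larger combination loses on size. Three "redundant" pairs of ordinary
drugs share targets, giving them visibly smaller target dispersion.

What the fixtures do **not** emulate: count-level noise models and
normalization pipelines of real RNA-seq, chemically valid SMILES (only
string-distance structure matters to the method), real perturbational
signature inference, and literature-curated prior sources with their
biases. Passing recovery tests therefore demonstrates that the pipeline's
machinery behaves as specified under its own assumptions, not that those
assumptions hold on any particular real dataset.

## Known limitations

* The Wilcoxon differences are taken on the log scale; a rank test on raw
  differences can order ties differently for skewed data.
* The variance branch of the significance score inherits the expression
  logFC, so variance-only genes depend entirely on the p-value factor for
  their rank.
* The IM component's γ calibration targets the empty/complete pair;
  between arbitrary weighted graphs IM is not formally bounded by 1, so
  HIM is clipped at 1 as a safety net (never observed to bind on random
  graph pairs in the test suite).
* The unreachable-pair penalty |V| makes target dispersion saturate on
  highly fragmented disease networks.
* NSGA-II with 20 offspring per generation is a faithful but slow
  exploration scheme for large drug universes; the defaults are tuned to
  libraries of tens to a few hundred drugs.
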