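# netcombo

Network-pharmacology prioritization of **minimal drug combinations**.

Treating a complex disease with several drugs at once works best when the
drugs complement each other: different mechanisms of action, different
chemical structures, targets spread over distant parts of the disease
network, and together a wide, central footprint on that network — all with
as few compounds as possible. `netcombo` turns this intuition into a tested
computational pipeline for researchers doing transcriptomics-based drug
repositioning: given paired disease/control expression data, a drug library
(SMILES, targets, perturbational replicate profiles) and prior-knowledge
association layers, it searches the space of drug subsets with a
multi-objective genetic algorithm and returns a Pareto archive of candidate
combinations.

## Method at a glance

1. **Gene scoring.** Per gene, a paired Wilcoxon signed-rank test (mean
   shift) and a two-sided variance F-test, combined into significance
   scores SS_t = |logFC · (−log10 p_t)|; the union of the top 10% of both
   rankings is kept.
2. **Disease network.** Ensemble co-expression inference over
   {CLR, ARACNE, MRNET} × {|Pearson|, |Spearman|, empirical MI} ×
   {equal-frequency, equal-width discretization}, aggregated as the
   element-wise median of rank-normalized adjacencies.
3. **Prior filtering.** Association layers (Interaction / Regulation /
   Functional) are projected to gene–gene networks, merged by union within
   a category, intersected across the three categories, and used to keep
   only prior-supported co-expression edges.
4. **Hub ranking.** Borda (mean-rank) consensus of degree, mean shortest
   path, betweenness, closeness, eigenvector centrality and SS.
5. **Drug features.** Pairwise Hamming–Ipsen–Mikhailov distances between
   drug MOA networks, Levenshtein distances between SMILES, mean shortest
   paths between target sets, and per-drug effect scores ES = N_t / M_R
   (target count over median target rank).
6. **Optimization.** NSGA-II genetic algorithm over binary chromosomes
   (population 100, 20 offspring per generation, 70% one-point crossover /
   30% bit-swap mutation, 30% bit initialization, 10% per-bit swap rate)
   maximizing (MOA_x, SMILES_x, TARGETS_x, COVERAGE_x, −|x|), with a
   crowding-truncated Hall of Fame of 10 and a repeated-run stability
   analysis producing a combination-frequency network.

A synthetic-fixtures module generates complete input bundles with planted
ground truth (differential genes, network modules, an "ideal" drug pair),
so the whole pipeline is testable end to end without external data.

## Worked example

```python
from netcombo import (
    build_bundle, build_feature_tables, rank_hub_genes,
    run_optimizer, GAConfig,
)

bundle = build_bundle(seed=1)          # 300 genes, 15 pairs, 20 drugs
table = bundle.score_table
selected = table[table.selected == 1]
ranking = rank_hub_genes(
    bundle.filtered, selected[["SS_wilcoxon", "SS_ftest"]].max(axis=1)
)
feats = build_feature_tables(bundle.drugs, bundle.filtered, ranking)
state = run_optimizer(feats, GAConfig(generations=500), seed=1)
for combo in state.hof_combinations()[:3]:
    print(combo["drugs"], {k: round(v, 3) for k, v in combo["objectives"].items()})
```

prints (about 10 s on one CPU):

```
['DRUG_B', 'DRUG_04'] {'moa': 0.03, 'smiles': 65.0, 'targets': 19.375, 'coverage': 0.614, 'neg_size': -2.0}
['DRUG_10', 'DRUG_11'] {'moa': 0.034, 'smiles': 7.0, 'targets': 21.062, 'coverage': 0.118, 'neg_size': -2.0}
['DRUG_A', 'DRUG_B'] {'moa': 0.028, 'smiles': 75.0, 'targets': 24.0, 'coverage': 0.629, 'neg_size': -2.0}
```

Each Hall-of-Fame member is one trade-off on the Pareto front: a drug list
with its five objective values (pairwise MOA / structural / target-path
dissimilarity sums normalized by combination size, mean effect score, and
negated size). The planted ideal pair `DRUG_A`+`DRUG_B` — constructed with
maximally dissimilar structures, distant disjoint hub targets and high
coverage — is recovered among them: it holds the best structural
(`smiles` 75.0), target-dispersion (`targets` 24.0) and coverage values of
any pair.

The same run is available from the shell:

```bash
netcombo simulate --out demo --seed 1        # write a synthetic bundle
netcombo run --config demo/config.yaml       # full pipeline -> demo/results/
```

which writes gene scores, networks, feature tables, `hof.json`, objective
traces and the combination-frequency network, plus a run manifest with the
seed and a parameter hash. Every stage also has its own subcommand
(`score-genes`, `infer-network`, `build-prior`, `filter-network`,
`rank-hubs`, `drug-features`, `optimize`, `stability`).

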