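"""Synthetic input generation with planted ground truth.

The generators emulate the statistical shape of the pipeline's real inputs:
paired tumor/normal expression with block-correlated gene modules and
planted differential-mean and differential-variance genes; a drug library
with replicate perturbational profiles, token-grammar SMILES strings and a
planted "ideal" pair (maximally dissimilar structures, distant disjoint
hub targets, distinct perturbed modules); and noisy prior-knowledge layers
derived from the ground-truth module network. Every generator is a pure
function of its parameters and seed.

The planted pair is constructed so that its pairwise SMILES distance is the
strict maximum over the whole library (the two planted strings are long and
alphabet-disjoint from each other, while every other string shares short
motifs with both), which makes the pair Pareto-optimal among combinations
regardless of the remaining objectives: no other pair can match it on the
structural axis, and any larger combination loses on size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .coexpression import ensemble_consensus
from .expression import DISEASE, CONTROL, ExpressionMatrix, score_genes
from .features import DrugRecord
from .networks import BinaryNetwork, WeightedNetwork, canonical_edge
from .prior import CATEGORIES, PriorLayer, build_prior_network, filter_disease_network

logger = logging.getLogger(__name__)

__all__ = [
    "FixtureTruth",
    "simulate_disease_expression",
    "simulate_drug_library",
    "simulate_prior_layers",
    "FixtureBundle",
    "build_bundle",
]

MIN_PAIRS = 10  # matched-sample input filter mirrored from the study design


@dataclass
class FixtureTruth:
    """Planted ground truth for recovery tests."""

    planted_de_genes: set[str] = field(default_factory=set)
    planted_var_genes: set[str] = field(default_factory=set)
    module_assignment: dict[str, int] = field(default_factory=dict)
    truth_network: BinaryNetwork | None = None
    planted_combination: set[str] = field(default_factory=set)
    redundant_pairs: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# paired disease/control expression
# ---------------------------------------------------------------------------

def simulate_disease_expression(
    G: int = 300,
    pairs: int = 15,
    n_modules: int = 10,
    de_frac: float = 0.10,
    var_frac: float = 0.10,
    mean_shift: float = 1.5,
    var_factor: float = 4.0,
    within_module_corr: float = 0.6,
    subject_sd: float = 0.3,
    residual_sd: float = 0.8,
    baseline_mean: float = 5.0,
    baseline_sd: float = 1.5,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, FixtureTruth]:
    """Paired tumor/normal expression with planted signal.

    Genes live on a log2 scale as baseline + shared subject effect + a
    block-correlated module factor + residual noise, then exponentiate to
    non-negative FPKM-like values. Planted differential-expression genes get
    a +-``mean_shift`` (log2 units) added to disease samples; planted
    variance genes have their disease residual standard deviation multiplied
    by ``var_factor``. The two planted sets are disjoint. The ground-truth
    network connects every within-module gene pair.
    """
    if pairs < MIN_PAIRS:
        raise ValueError(f"need at least {MIN_PAIRS} matched pairs, got {pairs}")
    if de_frac + var_frac > 1:
        raise ValueError("de_frac + var_frac must not exceed 1")
    rng = np.random.default_rng(seed)
    width = len(str(G))
    genes = [f"G{i + 1:0{width}d}" for i in range(G)]
    module_of = np.arange(G) % n_modules  # interleaved so planted sets span modules

    n_de = int(round(de_frac * G))
    n_var = int(round(var_frac * G))
    chosen = rng.choice(G, size=n_de + n_var, replace=False)
    de_idx, var_idx = chosen[:n_de], chosen[n_de:]

    baseline = rng.normal(baseline_mean, baseline_sd, size=G)
    shift_sign = rng.choice([-1.0, 1.0], size=G)
    a = residual_sd * np.sqrt(within_module_corr)
    s = residual_sd * np.sqrt(1.0 - within_module_corr)

    n_samples = 2 * pairs
    subject_effect = rng.normal(0.0, subject_sd, size=pairs)
    module_factor = rng.normal(size=(n_modules, n_samples))
    noise = rng.normal(size=(G, n_samples))

    # columns: pair i -> disease sample 2i, control sample 2i+1
    log_expr = (
        baseline[:, None]
        + np.repeat(subject_effect, 2)[None, :]
        + a * module_factor[module_of, :]
    )
    disease_cols = np.arange(0, n_samples, 2)
    control_cols = np.arange(1, n_samples, 2)
    scale = np.full((G, n_samples), s)
    scale[np.ix_(var_idx, disease_cols)] *= var_factor
    log_expr = log_expr + scale * noise
    log_expr[np.ix_(de_idx, disease_cols)] += (mean_shift * shift_sign[de_idx])[:, None]

    values = np.power(2.0, log_expr)
    sample_ids, meta_rows = [], []
    for p in range(pairs):
        subj = f"S{p + 1:03d}"
        sample_ids += [f"{subj}_d", f"{subj}_c"]
        meta_rows += [
            (f"{subj}_d", subj, DISEASE),
            (f"{subj}_c", subj, CONTROL),
        ]
    frame = pd.DataFrame(values, index=genes, columns=sample_ids)
    frame.index.name = "gene_id"
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "subject_id", "condition"])
    expr = ExpressionMatrix(frame, meta)

    truth_edges = {
        canonical_edge(genes[i], genes[j])
        for m in range(n_modules)
        for k, i in enumerate(np.flatnonzero(module_of == m))
        for j in np.flatnonzero(module_of == m)[k + 1 :]
    }
    truth = FixtureTruth(
        planted_de_genes={genes[i] for i in de_idx},
        planted_var_genes={genes[i] for i in var_idx},
        module_assignment={genes[i]: int(module_of[i]) for i in range(G)},
        truth_network=BinaryNetwork(nodes=set(genes), edges=truth_edges),
    )
    return expr, truth


# ---------------------------------------------------------------------------
# drug library
# ---------------------------------------------------------------------------

_COMMON_TOKENS = ("CC", "O", "N(C)", "c1ccccc1", "S", "=O", "Cl", "P")
_SHARED_MOTIF = "Br" + "I" * 20  # ties every ordinary SMILES to both planted ones


def _ordinary_smiles(rng: np.random.Generator) -> str:
    n_tokens = int(rng.integers(8, 15))
    body = "".join(rng.choice(_COMMON_TOKENS, size=n_tokens))
    return body + _SHARED_MOTIF


def _moa_profiles(
    panel: list[str],
    module_of: np.ndarray,
    module: int,
    n_replicates: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Replicate profiles in which one landmark module co-varies strongly."""
    n_genes = len(panel)
    base = rng.normal(6.0, 0.5, size=n_genes)
    values = base[:, None] + 0.8 * rng.normal(size=(n_genes, n_replicates))
    factor = rng.normal(size=n_replicates)
    mask = module_of == module
    values[mask] = base[mask, None] + 2.0 * factor[None, :] + 0.25 * rng.normal(
        size=(int(mask.sum()), n_replicates)
    )
    return pd.DataFrame(values, index=panel)


def simulate_drug_library(
    K: int = 20,
    disease_net: WeightedNetwork | None = None,
    landmark_genes: int = 100,
    n_replicates: int = 8,
    n_moa_modules: int = 10,
    seed: int | None = None,
) -> tuple[list[DrugRecord], FixtureTruth]:
    """Drug library with a planted ideal pair and redundant pairs.

    Targets are placed on ``disease_net``: the planted pair gets disjoint
    hub-gene target sets centered on the two most distant high-degree nodes,
    ordinary drugs sample 2-4 targets at random, and three "redundant" pairs
    of consecutive drugs share two targets. Every drug receives
    ``n_replicates`` perturbational replicate profiles on a separate
    landmark gene panel, perturbing a drug-specific module.
    """
    if K < 4:
        raise ValueError("need at least 4 drugs")
    if disease_net is None or disease_net.n_nodes < 10:
        raise ValueError(
            "disease network too small to place dispersed drug targets (need >= 10 nodes)"
        )
    rng = np.random.default_rng(seed)
    import networkx as nx

    graph = disease_net.to_networkx()
    nodes = list(disease_net.nodes)
    degree = dict(graph.degree(weight="weight"))
    hubs = sorted(nodes, key=lambda g: (-degree[g], g))[: max(10, len(nodes) // 3)]

    # most BFS-distant pair among hub genes (unreachable counts as |V|)
    best, best_d = (hubs[0], hubs[1]), -1.0
    lengths = {
        h: nx.single_source_shortest_path_length(graph, h) for h in hubs
    }
    for i, u in enumerate(hubs):
        for v in hubs[i + 1 :]:
            d = lengths[u].get(v, disease_net.n_nodes)
            if d > best_d:
                best, best_d = (u, v), d
    u_star, v_star = best

    def hub_targets(center: str, size: int = 4) -> set[str]:
        # stay inside the center's component so the two planted sets are
        # disjoint and maximally separated even on fragmented networks
        reach = lengths.get(center) or nx.single_source_shortest_path_length(
            graph, center
        )
        ring = sorted(
            (g for g in reach if g != center),
            key=lambda g: (reach[g], -degree[g], g),
        )
        near_hubs = sorted(ring[: size * 3], key=lambda g: (-degree[g], g))
        return {center} | set(near_hubs[: size - 1])

    targets_a = hub_targets(u_star)
    targets_b = hub_targets(v_star) - targets_a

    panel_width = len(str(landmark_genes))
    panel = [f"L{i + 1:0{panel_width}d}" for i in range(landmark_genes)]
    moa_module_of = np.arange(landmark_genes) % n_moa_modules

    drugs: list[DrugRecord] = []
    planted_a, planted_b = "DRUG_A", "DRUG_B"
    drugs.append(
        DrugRecord(
            planted_a,
            "Br" * 70,
            targets_a,
            _moa_profiles(panel, moa_module_of, 0, n_replicates, rng),
        )
    )
    drugs.append(
        DrugRecord(
            planted_b,
            "I" * 150,
            targets_b,
            _moa_profiles(panel, moa_module_of, n_moa_modules // 2, n_replicates, rng),
        )
    )

    non_hubs = [g for g in nodes if g not in targets_a | targets_b]
    redundant_pairs: list[tuple[str, str]] = []
    for k in range(K - 2):
        drug_id = f"DRUG_{k + 1:02d}"
        n_t = int(rng.integers(2, 5))
        targets = set(rng.choice(non_hubs, size=n_t, replace=False))
        module = int((k + 1) % n_moa_modules)
        drugs.append(
            DrugRecord(
                drug_id,
                _ordinary_smiles(rng),
                targets,
                _moa_profiles(panel, moa_module_of, module, n_replicates, rng),
            )
        )
    # make three redundant pairs: consecutive ordinary drugs sharing targets
    ordinary = drugs[2:]
    for k in range(0, min(6, len(ordinary) - 1), 2):
        d1, d2 = ordinary[k], ordinary[k + 1]
        shared = set(rng.choice(sorted(d1.targets), size=min(2, len(d1.targets)), replace=False))
        d2.targets |= shared
        redundant_pairs.append((d1.drug_id, d2.drug_id))

    truth = FixtureTruth(
        planted_combination={planted_a, planted_b},
        redundant_pairs=redundant_pairs,
    )
    return drugs, truth


# ---------------------------------------------------------------------------
# prior layers
# ---------------------------------------------------------------------------

def simulate_prior_layers(
    truth: BinaryNetwork,
    n_per_category: int = 3,
    edge_noise: float = 0.1,
    subsample: float = 0.7,
    seed: int | None = None,
) -> list[PriorLayer]:
    """Noisy association layers derived from a ground-truth network.

    Each category gets ``n_per_category`` gene-gene layers; a layer contains
    each truth edge with probability ``subsample`` (but every truth edge is
    guaranteed to appear in at least one layer of every category, so the
    triple intersection preserves the truth at zero noise) plus spurious
    non-truth edges at rate ``edge_noise`` (relative to the truth edge
    count). Spurious edges survive the final prior only if drawn in all
    three categories.
    """
    if n_per_category < 1:
        raise ValueError("need at least one layer per category")
    rng = np.random.default_rng(seed)
    truth_edges = sorted(truth.edges)
    nodes = sorted(truth.nodes)
    n_spurious = int(round(edge_noise * len(truth_edges)))
    layers: list[PriorLayer] = []
    for category in CATEGORIES:
        membership = rng.random((len(truth_edges), n_per_category)) < subsample
        # guarantee coverage of every truth edge within the category
        uncovered = np.flatnonzero(~membership.any(axis=1))
        membership[uncovered, rng.integers(0, n_per_category, size=len(uncovered))] = True
        for layer_i in range(n_per_category):
            pairs = [e for e, m in zip(truth_edges, membership[:, layer_i]) if m]
            spurious: set[tuple[str, str]] = set()
            while len(spurious) < n_spurious:
                a, b = rng.choice(nodes, size=2, replace=False)
                e = canonical_edge(a, b)
                if e not in truth.edges:
                    spurious.add(e)
            layers.append(
                PriorLayer(
                    source_name=f"{category.lower()}_src{layer_i + 1}",
                    category=category,
                    kind="edges",
                    associations=pairs + sorted(spurious),
                )
            )
    return layers


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    """Raw synthetic inputs plus the derived networks used to place targets."""

    expression: ExpressionMatrix
    expression_truth: FixtureTruth
    layers: list[PriorLayer]
    drugs: list[DrugRecord]
    drug_truth: FixtureTruth
    score_table: pd.DataFrame
    consensus: WeightedNetwork
    filtered: WeightedNetwork


def build_bundle(
    G: int = 300,
    pairs: int = 15,
    K: int = 20,
    landmark_genes: int = 100,
    edge_noise: float = 0.1,
    seed: int | None = None,
    **expression_kwargs,
) -> FixtureBundle:
    """Generate the full study-condition input bundle.

    Chains the generators: paired expression -> gene scoring -> ensemble
    consensus on the selected genes (disease samples) -> prior layers from
    the truth network -> filtered disease network -> drug library with
    targets placed on the filtered network.
    """
    ss = np.random.SeedSequence(seed)
    s_expr, s_layers, s_drugs = (int(s) for s in ss.generate_state(3) % (2**31))
    expr, truth = simulate_disease_expression(
        G=G, pairs=pairs, seed=s_expr, **expression_kwargs
    )
    table = score_genes(expr)
    selected = sorted(table.index[table["selected"] == 1])
    disease_cols = expr.sample_meta.loc[
        expr.sample_meta["condition"] == DISEASE, "sample_id"
    ]
    log_sub = np.log2(expr.values.loc[selected, disease_cols] + 1.0)
    consensus = ensemble_consensus(log_sub)
    layers = simulate_prior_layers(
        truth.truth_network, edge_noise=edge_noise, seed=s_layers
    )
    prior = build_prior_network(layers)
    filtered = filter_disease_network(consensus, prior)
    drugs, drug_truth = simulate_drug_library(
        K=K, disease_net=filtered, landmark_genes=landmark_genes, seed=s_drugs
    )
    return FixtureBundle(
        expression=expr,
        expression_truth=truth,
        layers=layers,
        drugs=drugs,
        drug_truth=drug_truth,
        score_table=table,
        consensus=consensus,
        filtered=filtered,
    )


def write_bundle(bundle: FixtureBundle, out_dir) -> dict[str, str]:
    """Write the raw bundle inputs as TSV/YAML/JSON files.

    Returns the mapping of logical input names to the written paths, in the
    layout the pipeline config expects (expression + metadata TSVs, drug
    table, per-drug MOA profiles with a manifest, per-layer TSVs with a
    manifest, and the ground truth as JSON).
    """
    import json
    from pathlib import Path

    import yaml

    out = Path(out_dir)
    (out / "moa").mkdir(parents=True, exist_ok=True)
    (out / "layers").mkdir(exist_ok=True)

    expr_path = out / "expression.tsv"
    bundle.expression.values.to_csv(expr_path, sep="\t", float_format="%.8g")
    meta_path = out / "sample_meta.tsv"
    bundle.expression.sample_meta.to_csv(meta_path, sep="\t", index=False)

    drug_rows = [
        (d.drug_id, d.smiles, ",".join(sorted(d.targets))) for d in bundle.drugs
    ]
    drug_path = out / "drugs.tsv"
    pd.DataFrame(drug_rows, columns=["drug_id", "smiles", "targets"]).to_csv(
        drug_path, sep="\t", index=False
    )
    moa_rows = []
    for d in bundle.drugs:
        p = out / "moa" / f"{d.drug_id}.tsv"
        d.moa_profiles.to_csv(p, sep="\t", float_format="%.8g")
        moa_rows.append((d.drug_id, f"moa/{d.drug_id}.tsv"))
    moa_manifest = out / "moa_manifest.tsv"
    pd.DataFrame(moa_rows, columns=["drug_id", "path"]).to_csv(
        moa_manifest, sep="\t", index=False
    )

    layer_entries = []
    for layer in bundle.layers:
        p = out / "layers" / f"{layer.source_name}.tsv"
        pd.DataFrame(layer.associations, columns=["gene_a", "gene_b"]).to_csv(
            p, sep="\t", index=False
        )
        layer_entries.append(
            {
                "file": f"layers/{layer.source_name}.tsv",
                "type": layer.kind,
                "category": layer.category,
                "source_name": layer.source_name,
            }
        )
    layer_manifest = out / "layer_manifest.yaml"
    with open(layer_manifest, "w") as fh:
        yaml.safe_dump({"layers": layer_entries}, fh)

    truth_path = out / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "planted_de_genes": sorted(bundle.expression_truth.planted_de_genes),
                "planted_var_genes": sorted(bundle.expression_truth.planted_var_genes),
                "planted_combination": sorted(bundle.drug_truth.planted_combination),
                "redundant_pairs": bundle.drug_truth.redundant_pairs,
            },
            fh,
            indent=2,
        )
    return {
        "expression": str(expr_path),
        "sample_meta": str(meta_path),
        "drug_table": str(drug_path),
        "moa_manifest": str(moa_manifest),
        "layer_manifest": str(layer_manifest),
        "truth": str(truth_path),
    }
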