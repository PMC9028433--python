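"""Multilayer prior-knowledge network construction and filtering.

Association layers (protein interaction, regulation, functional annotation)
are each projected to a binary gene-gene network: genes sharing at least one
common association (e.g. the same pathway) are connected. Layers within a
category are merged by edge union; the final prior keeps only edges present
in *all three* categories. The disease co-expression network is then
restricted to prior-supported edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .networks import BinaryNetwork, WeightedNetwork, canonical_edge

logger = logging.getLogger(__name__)

__all__ = [
    "PriorLayer",
    "CATEGORIES",
    "project_layer",
    "merge_category",
    "intersect_categories",
    "build_prior_network",
    "filter_disease_network",
]

CATEGORIES = ("Interaction", "Regulation", "Functional")

Category = Literal["Interaction", "Regulation", "Functional"]
LayerKind = Literal["edges", "bipartite"]


@dataclass
class PriorLayer:
    """One association source.

    ``associations`` holds deduplicated pairs: (gene, gene) for ``edges``
    layers, (gene, term) for ``bipartite`` layers.
    """

    source_name: str
    category: Category
    kind: LayerKind
    associations: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"category must be one of {CATEGORIES}, got {self.category!r}"
            )
        if self.kind not in ("edges", "bipartite"):
            raise ValueError(f"kind must be 'edges' or 'bipartite', got {self.kind!r}")
        self.associations = sorted(set(map(tuple, self.associations)))

    @classmethod
    def read_tsv(
        cls, path: str | Path, source_name: str, category: Category, kind: LayerKind
    ) -> "PriorLayer":
        df = pd.read_csv(path, sep="\t", dtype=str)
        pairs = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
        return cls(source_name, category, kind, pairs)


def project_layer(layer: PriorLayer, project_gene_gene: bool = False) -> BinaryNetwork:
    """Project a layer to a binary gene-gene network.

    Bipartite layers connect two genes iff they share at least one term.
    Gene-gene layers pass through after symmetrization and deduplication
    (set ``project_gene_gene`` to instead connect genes sharing a common
    interaction partner).
    """
    if not layer.associations:
        logger.warning("layer %s is empty; projecting to empty network", layer.source_name)
        return BinaryNetwork()
    if layer.kind == "edges" and not project_gene_gene:
        return BinaryNetwork.from_pairs(layer.associations)
    # shared-association projection: group genes per term (or per partner)
    members: dict[str, set[str]] = {}
    if layer.kind == "bipartite":
        for gene, term in layer.associations:
            members.setdefault(term, set()).add(gene)
    else:
        for a, b in layer.associations:
            members.setdefault(b, set()).add(a)
            members.setdefault(a, set()).add(b)
    edges = set()
    for group in members.values():
        for g1, g2 in combinations(sorted(group), 2):
            edges.add(canonical_edge(g1, g2))
    genes = {g for group in members.values() for g in group}
    return BinaryNetwork(nodes=genes, edges=edges)


def merge_category(layers: Sequence[BinaryNetwork]) -> BinaryNetwork:
    """Edge-set union of all layers in one category."""
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    for net in layers:
        nodes |= net.nodes
        edges |= net.edges
    return BinaryNetwork(nodes=nodes, edges=edges)


def intersect_categories(
    interaction: BinaryNetwork,
    regulation: BinaryNetwork,
    functional: BinaryNetwork,
) -> BinaryNetwork:
    """Final prior: edges present in all three category networks.

    The node set is restricted to endpoints of surviving edges.
    """
    edges = interaction.edges & regulation.edges & functional.edges
    if not edges:
        logger.warning(
            "prior-knowledge triple intersection is EMPTY; filtering the disease "
            "network by it would erase every edge"
        )
    nodes = {g for e in edges for g in e}
    return BinaryNetwork(nodes=nodes, edges=edges)


def build_prior_network(
    layers: Iterable[PriorLayer], project_gene_gene: bool = False
) -> BinaryNetwork:
    """Project, merge per category, and intersect the three categories."""
    per_category: dict[str, list[BinaryNetwork]] = {c: [] for c in CATEGORIES}
    for layer in layers:
        per_category[layer.category].append(project_layer(layer, project_gene_gene))
    merged = {c: merge_category(nets) for c, nets in per_category.items()}
    return intersect_categories(
        merged["Interaction"], merged["Regulation"], merged["Functional"]
    )


def filter_disease_network(
    coexpr: WeightedNetwork, prior: BinaryNetwork
) -> WeightedNetwork:
    """Keep co-expression edges whose gene pair is prior-supported.

    Weights are preserved on surviving edges; isolated nodes are retained so
    the node set is stable for downstream ranking. A support rate below 1%
    usually means an identifier-namespace mismatch and is warned about.
    """
    n_before = coexpr.n_edges()
    kept = [
        (a, b, w) for a, b, w in coexpr.edges() if canonical_edge(a, b) in prior.edges
    ]
    if n_before and len(kept) / n_before < 0.01:
        logger.warning(
            "only %d of %d co-expression edges are prior-supported (<1%%); "
            "check that gene identifier namespaces match",
            len(kept),
            n_before,
        )
    return WeightedNetwork.from_edges(coexpr.nodes, kept)
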