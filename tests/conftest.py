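"""Shared fixtures: toy paired expression, random feature tables, and one
session-scoped default synthetic bundle with its derived feature tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from netcombo.coexpression import rank_hub_genes
from netcombo.expression import CONTROL, DISEASE, ExpressionMatrix
from netcombo.features import DrugFeatureTables, build_feature_tables
from netcombo.fixtures import FixtureBundle, build_bundle


def make_paired_expression(
    disease: np.ndarray, control: np.ndarray, gene_ids: list[str] | None = None
) -> ExpressionMatrix:
    """Build an ExpressionMatrix from genes x pairs arrays (linear scale)."""
    disease = np.atleast_2d(np.asarray(disease, dtype=float))
    control = np.atleast_2d(np.asarray(control, dtype=float))
    g, pairs = disease.shape
    if gene_ids is None:
        gene_ids = [f"g{i + 1}" for i in range(g)]
    cols, meta = [], []
    data = np.empty((g, 2 * pairs))
    for p in range(pairs):
        subj = f"sub{p + 1}"
        cols += [f"{subj}_d", f"{subj}_c"]
        meta += [(f"{subj}_d", subj, DISEASE), (f"{subj}_c", subj, CONTROL)]
        data[:, 2 * p] = disease[:, p]
        data[:, 2 * p + 1] = control[:, p]
    frame = pd.DataFrame(data, index=gene_ids, columns=cols)
    meta_df = pd.DataFrame(meta, columns=["sample_id", "subject_id", "condition"])
    return ExpressionMatrix(frame, meta_df)


def random_feature_tables(n_drugs: int = 8, seed: int = 0) -> DrugFeatureTables:
    """Random but valid feature tables for optimizer unit tests."""
    rng = np.random.default_rng(seed)
    ids = [f"d{i:02d}" for i in range(n_drugs)]

    def sym(scale: float, integer: bool = False) -> pd.DataFrame:
        m = rng.random((n_drugs, n_drugs)) * scale
        m = np.triu(m, k=1)
        m = m + m.T
        if integer:
            m = np.round(m).astype(int)
        return pd.DataFrame(m, index=ids, columns=ids)

    es = pd.Series(rng.random(n_drugs) + 0.1, index=ids, name="ES")
    return DrugFeatureTables(
        him=sym(1.0), lev=sym(40.0, integer=True), sp=sym(10.0), es=es
    )


@pytest.fixture(scope="session")
def default_bundle() -> FixtureBundle:
    """The default study-condition bundle (300 genes, 15 pairs, 20 drugs)."""
    return build_bundle(seed=1)


@pytest.fixture(scope="session")
def default_ranking(default_bundle) -> pd.DataFrame:
    table = default_bundle.score_table
    selected = table[table["selected"] == 1]
    ss = selected[["SS_wilcoxon", "SS_ftest"]].max(axis=1)
    return rank_hub_genes(default_bundle.filtered, ss)


@pytest.fixture(scope="session")
def default_features(default_bundle, default_ranking) -> DrugFeatureTables:
    return build_feature_tables(
        default_bundle.drugs, default_bundle.filtered, default_ranking
    )
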