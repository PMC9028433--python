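"""Candidate-gene scoring from paired disease/control expression.

Two complementary notions of transcriptional deregulation are scored per
gene: a shift in location between disease and matched control samples
(paired Wilcoxon signed-rank test) and a change in expression variability
between the two conditions (two-sided F-test on sample variances). Neither
p-value is used as a filter; instead each gene receives a significance score

    SS_t = | logFC * (-log10 p_t) |

per test t, the two SS lists are ranked from highest to lowest, and the
union of the top fraction (default 10%) of both rankings is carried forward
to network inference.

All log transforms use log2(v + 1); inputs are normalized, non-negative
expression values (FPKM-like), so a pseudocount is required for zeros.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "compute_paired_logfc",
    "paired_wilcoxon",
    "variance_f_test",
    "significance_scores",
    "rank_scores",
    "score_genes",
    "select_candidate_genes",
]

DISEASE = "disease"
CONTROL = "control"


class PairingError(ValueError):
    """Raised when the sample metadata does not describe a paired design."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with paired disease/control metadata.

    Parameters
    ----------
    values
        DataFrame of non-negative normalized expression, indexed by unique
        gene ids, columns are sample ids.
    sample_meta
        DataFrame with columns ``sample_id``, ``subject_id``, ``condition``
        (``disease`` or ``control``); every subject must contribute exactly
        one sample per condition.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        meta = self.sample_meta
        required = {"sample_id", "subject_id", "condition"}
        if not required.issubset(meta.columns):
            raise ValueError(f"sample metadata needs columns {sorted(required)}")
        bad = set(meta["condition"]) - {DISEASE, CONTROL}
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")
        missing = set(meta["sample_id"]) - set(self.values.columns)
        if missing:
            raise ValueError(f"metadata samples absent from matrix: {sorted(missing)}")
        counts = meta.groupby(["subject_id", "condition"]).size().unstack(fill_value=0)
        for cond in (DISEASE, CONTROL):
            if cond not in counts.columns:
                counts[cond] = 0
        unpaired = counts[(counts[DISEASE] != 1) | (counts[CONTROL] != 1)]
        if len(unpaired):
            raise PairingError(
                "unpaired subjects (need exactly one disease and one control "
                f"sample each): {sorted(unpaired.index)}"
            )
        subjects = sorted(meta["subject_id"].unique())
        by = meta.set_index(["subject_id", "condition"])["sample_id"]
        self._disease_samples = [by[(s, DISEASE)] for s in subjects]
        self._control_samples = [by[(s, CONTROL)] for s in subjects]
        self.subjects = subjects

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_pairs(self) -> int:
        return len(self.subjects)

    def paired_log_values(self) -> tuple[np.ndarray, np.ndarray]:
        """log2(v+1) matrices for (disease, control), columns subject-aligned."""
        d = np.log2(self.values[self._disease_samples].to_numpy() + 1.0)
        c = np.log2(self.values[self._control_samples].to_numpy() + 1.0)
        return d, c

    @classmethod
    def read_tsv(cls, expression_path: str | Path, meta_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(expression_path, sep="\t", index_col=0)
        values.index = values.index.astype(str)
        meta = pd.read_csv(meta_path, sep="\t", dtype=str)
        return cls(values, meta)


def compute_paired_logfc(expr: ExpressionMatrix) -> pd.Series:
    """Per-gene log2 fold change: mean log2(v+1) disease minus control."""
    d, c = expr.paired_log_values()
    return pd.Series(d.mean(axis=1) - c.mean(axis=1), index=expr.gene_ids, name="logFC")


def paired_wilcoxon(expr: ExpressionMatrix, exact_max_pairs: int = 25) -> pd.Series:
    """Two-sided Wilcoxon signed-rank p-value per gene on paired differences.

    Differences are taken on the log2(v+1) scale. Zero differences are
    discarded (Wilcoxon's original treatment); the exact null distribution is
    used when at most ``exact_max_pairs`` non-zero pairs remain, otherwise the
    normal approximation with continuity correction. Genes whose differences
    are all zero are degenerate and get p = 1 with a warning.
    """
    if expr.n_pairs < 2:
        raise ValueError("paired Wilcoxon requires at least 2 pairs")
    d, c = expr.paired_log_values()
    diffs = d - c
    pvals = np.ones(len(diffs))
    n_degenerate = 0
    for g in range(len(diffs)):
        delta = diffs[g]
        nonzero = delta[delta != 0]
        if len(nonzero) == 0:
            n_degenerate += 1
            continue
        method = "exact" if len(nonzero) <= exact_max_pairs else "approx"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.wilcoxon(
                delta,
                zero_method="wilcox",
                alternative="two-sided",
                correction=True,
                method=method,
            )
        pvals[g] = min(res.pvalue, 1.0)
    if n_degenerate:
        logger.warning(
            "%d gene(s) had all-zero paired differences; p set to 1", n_degenerate
        )
    return pd.Series(pvals, index=expr.gene_ids, name="p_wilcoxon")


def variance_f_test(expr: ExpressionMatrix) -> pd.Series:
    """Two-sided F-test p-value per gene comparing disease vs control variance.

    F = s2_disease / s2_control on log2(v+1) values; the two-sided p-value is
    2 * min(P(F <= f), P(F >= f)) under F(n_d - 1, n_c - 1), capped at 1.
    Degenerate genes: zero variance in both groups gives p = 1; zero variance
    in exactly one group gives the smallest positive float (maximal evidence
    of a variance difference), both with a warning.
    """
    d, c = expr.paired_log_values()
    n_d, n_c = d.shape[1], c.shape[1]
    if n_d < 3 or n_c < 3:
        raise ValueError("variance F-test requires at least 3 samples per condition")
    var_d = d.var(axis=1, ddof=1)
    var_c = c.var(axis=1, ddof=1)
    pvals = np.ones(len(var_d))
    both_zero = (var_d == 0) & (var_c == 0)
    one_zero = ((var_d == 0) | (var_c == 0)) & ~both_zero
    ok = ~both_zero & ~one_zero
    f = var_d[ok] / var_c[ok]
    cdf = stats.f.cdf(f, n_d - 1, n_c - 1)
    sf = stats.f.sf(f, n_d - 1, n_c - 1)
    pvals[ok] = np.minimum(1.0, 2.0 * np.minimum(cdf, sf))
    pvals[one_zero] = np.finfo(float).tiny
    if both_zero.any():
        logger.warning(
            "%d gene(s) with zero variance in both conditions; p set to 1",
            int(both_zero.sum()),
        )
    if one_zero.any():
        logger.warning(
            "%d gene(s) with zero variance in one condition; p floored at %g",
            int(one_zero.sum()),
            float(np.finfo(float).tiny),
        )
    return pd.Series(pvals, index=expr.gene_ids, name="p_ftest")


def significance_scores(logfc: pd.Series | np.ndarray, pvals: pd.Series | np.ndarray) -> pd.Series:
    """SS = |logFC * (-log10 p)| per gene, for one test's p-values."""
    logfc = pd.Series(logfc)
    p = np.asarray(pvals, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]; floor zeros upstream")
    ss = np.abs(logfc.to_numpy() * (-np.log10(p)))
    return pd.Series(ss, index=logfc.index, name="SS")


def rank_scores(ss: pd.Series) -> pd.Series:
    """Dense 1..G ranks, 1 = highest SS; ties broken lexicographically by gene id."""
    order = sorted(ss.index, key=lambda g: (-ss[g], g))
    ranks = pd.Series(0, index=ss.index, dtype=int)
    ranks[order] = np.arange(1, len(order) + 1)
    return ranks


def score_genes(expr: ExpressionMatrix, fraction: float = 0.10) -> pd.DataFrame:
    """Build the full per-gene score table and mark the selected union.

    Returns a DataFrame indexed by gene id with columns logFC, p_wilcoxon,
    p_ftest, SS_wilcoxon, SS_ftest, rank_wilcoxon, rank_ftest, selected.
    """
    logfc = compute_paired_logfc(expr)
    p_w = paired_wilcoxon(expr)
    p_f = variance_f_test(expr)
    ss_w = significance_scores(logfc, p_w)
    ss_f = significance_scores(logfc, p_f)
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "p_wilcoxon": p_w,
            "p_ftest": p_f,
            "SS_wilcoxon": ss_w,
            "SS_ftest": ss_f,
            "rank_wilcoxon": rank_scores(ss_w),
            "rank_ftest": rank_scores(ss_f),
        }
    )
    table.index.name = "gene_id"
    selected = select_candidate_genes(table, fraction=fraction)
    table["selected"] = table.index.isin(selected).astype(int)
    return table


def select_candidate_genes(table: pd.DataFrame, fraction: float = 0.10) -> set[str]:
    """Union of the top ``floor(fraction * G)`` genes of each SS ranking."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    g = len(table)
    k = int(np.floor(fraction * g))
    if k < 1:
        raise ValueError(
            f"top fraction {fraction} of {g} genes selects zero genes; "
            "increase the fraction or the gene universe"
        )
    top_w = set(table.index[table["rank_wilcoxon"] <= k])
    top_f = set(table.index[table["rank_ftest"] <= k])
    return top_w | top_f
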