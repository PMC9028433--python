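"""Ensemble co-expression network inference and hub-gene ranking.

A robust consensus network is inferred by running every combination of a
post-processing algorithm (CLR, ARACNE, MRNET) with an association estimator
(|Pearson|, |Spearman|, empirical mutual information under an equal-frequency
or equal-width discretization). Each resulting adjacency is rank-normalized
to [0, 1] and the consensus is the element-wise median; only the strongest
edges (default: top 2N) are retained.

Hub genes are then ranked by Borda aggregation of six lists: weighted
degree, mean shortest-path distance, betweenness, closeness, eigenvector
centrality and the significance score from expression scoring. The Borda
consensus of a node is the mean of its ranks across the lists; ties are
broken lexicographically by gene id so rankings are bitwise reproducible.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .networks import WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "infer_adjacency",
    "consensus_network",
    "ensemble_consensus",
    "borda_consensus",
    "rank_hub_genes",
    "DEFAULT_GRID",
]

ALGORITHMS = ("clr", "aracne", "mrnet")
ESTIMATORS = ("pearson", "spearman", "mi_empirical")
DISCRETIZERS = ("equal_freq", "equal_width")

#: the full inference grid; discretizers only multiply the MI estimator
DEFAULT_GRID = {
    "algorithms": list(ALGORITHMS),
    "estimators": list(ESTIMATORS),
    "discretizers": list(DISCRETIZERS),
}

DISTANCE_EPSILON = 1e-6


# ---------------------------------------------------------------------------
# association estimators
# ---------------------------------------------------------------------------

def _abs_correlation(values: np.ndarray, method: str) -> np.ndarray:
    data = values
    if method == "spearman":
        data = stats.rankdata(values, axis=1)
    sd = data.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data)
    corr = np.abs(np.nan_to_num(corr, nan=0.0))
    if constant.any():
        logger.warning(
            "%d constant gene(s); their associations set to 0", int(constant.sum())
        )
        corr[constant, :] = 0.0
        corr[:, constant] = 0.0
    np.fill_diagonal(corr, 0.0)
    return np.clip(corr, 0.0, 1.0)


def _discretize(values: np.ndarray, method: str, bins: int) -> np.ndarray:
    """Per-gene discretization into integer bins 0..bins-1."""
    g, n = values.shape
    out = np.zeros((g, n), dtype=np.int64)
    for i in range(g):
        row = values[i]
        if row.max() == row.min():
            continue  # constant gene -> single bin
        if method == "equal_freq":
            qs = np.quantile(row, np.linspace(0, 1, bins + 1)[1:-1])
            out[i] = np.searchsorted(qs, row, side="right")
        elif method == "equal_width":
            edges = np.linspace(row.min(), row.max(), bins + 1)[1:-1]
            out[i] = np.searchsorted(edges, row, side="right")
        else:
            raise ValueError(f"unknown discretizer {method!r}")
    return out


def _mi_matrix(disc: np.ndarray, bins: int) -> np.ndarray:
    """Empirical mutual information (nats) between all gene pairs.

    Joint counts for every pair are accumulated with one boolean matrix
    product per bin pair, which keeps the G^2 * bins^2 work in BLAS.
    """
    g, n = disc.shape
    indicators = [(disc == b).astype(np.float64) for b in range(bins)]
    marg = np.stack([ind.sum(axis=1) for ind in indicators])  # bins x G
    mi = np.zeros((g, g))
    for a in range(bins):
        pa = marg[a][:, None]  # G x 1
        if not pa.any():
            continue
        for b in range(bins):
            pb = marg[b][None, :]
            cab = indicators[a] @ indicators[b].T  # joint counts, G x G
            with np.errstate(divide="ignore", invalid="ignore"):
                term = (cab / n) * np.log(cab * n / (pa * pb))
            mi += np.nan_to_num(term, nan=0.0, posinf=0.0, neginf=0.0)
    np.fill_diagonal(mi, 0.0)
    return np.maximum(mi, 0.0)


def _association_matrix(
    values: np.ndarray, estimator: str, discretizer: str, bins: int | None
) -> np.ndarray:
    n = values.shape[1]
    if estimator in ("pearson", "spearman"):
        return _abs_correlation(values, estimator)
    if estimator == "mi_empirical":
        if bins is None:
            bins = max(2, int(round(np.sqrt(n))))
        disc = _discretize(values, discretizer, bins)
        constant = values.std(axis=1) == 0
        mi = _mi_matrix(disc, bins)
        if constant.any():
            mi[constant, :] = 0.0
            mi[:, constant] = 0.0
        return mi
    raise ValueError(f"unknown estimator {estimator!r}")


# ---------------------------------------------------------------------------
# post-processing algorithms
# ---------------------------------------------------------------------------

def _clr(m: np.ndarray) -> np.ndarray:
    """Context-likelihood-of-relatedness transform.

    Each association is z-scored against its row and column backgrounds;
    negative z-scores are clipped to 0 and combined as sqrt(zi^2 + zj^2).
    """
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (m - mu) / sd
    z = np.nan_to_num(z, nan=0.0)
    z = np.maximum(z, 0.0)
    out = np.sqrt(z**2 + z.T**2)
    np.fill_diagonal(out, 0.0)
    return out


def _aracne(m: np.ndarray, epsilon: float = 0.0) -> np.ndarray:
    """Data-processing-inequality pruning.

    For every triangle the weakest edge is removed: edge (i, j) is dropped
    when some third gene k satisfies m_ij < min(m_ik, m_jk) - epsilon. All
    removals are marked first, then applied simultaneously.
    """
    g = m.shape[0]
    # min over each pair of legs through k: shape (i, j, k)
    legs = np.minimum(m[:, None, :], m[None, :, :])
    # exclude k == i and k == j (diagonal entries are 0, so min(...) is 0
    # there and the strict inequality below cannot fire for non-negative m)
    maxmin = legs.max(axis=2)
    pruned = m.copy()
    pruned[m < maxmin - epsilon] = 0.0
    np.fill_diagonal(pruned, 0.0)
    return pruned


def _mrnet(m: np.ndarray) -> np.ndarray:
    """Max-relevance min-redundancy forward-selection scores.

    For each target gene the remaining genes are selected greedily by the
    MRMR score u_j = relevance(j, target) - mean redundancy of j against the
    already-selected set; the score of a pair is the maximum over both
    selection directions, clipped at 0.
    """
    g = m.shape[0]
    scores = np.zeros((g, g))
    for t in range(g):
        rel = m[:, t].copy()
        rel[t] = -np.inf
        red_sum = np.zeros(g)
        selected: list[int] = []
        available = np.ones(g, dtype=bool)
        available[t] = False
        for _ in range(g - 1):
            if selected:
                u = rel - red_sum / len(selected)
            else:
                u = rel.copy()
            u[~available] = -np.inf
            j = int(np.argmax(u))
            scores[j, t] = max(scores[j, t], u[j])
            available[j] = False
            selected.append(j)
            red_sum += m[:, j]
    out = np.maximum(scores, scores.T)
    out = np.maximum(out, 0.0)
    np.fill_diagonal(out, 0.0)
    return out


def _rescale_unit(m: np.ndarray) -> np.ndarray:
    """Min-max rescale off-diagonal values to [0, 1] (constant matrix -> 0)."""
    m = 0.5 * (m + m.T)  # remove float-accumulation asymmetry
    iu = np.triu_indices(m.shape[0], k=1)
    vals = m[iu]
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        return np.zeros_like(m)
    out = (m - lo) / (hi - lo)
    np.fill_diagonal(out, 0.0)
    return np.clip(out, 0.0, 1.0)


def infer_adjacency(
    expr: pd.DataFrame,
    algorithm: str = "clr",
    estimator: str = "pearson",
    discretizer: str = "equal_freq",
    bins: int | None = None,
    aracne_epsilon: float = 0.0,
) -> WeightedNetwork:
    """Infer one weighted co-expression network (genes x samples input).

    The pairwise association matrix (absolute correlation or empirical MI on
    discretized data) is post-processed by the named algorithm and min-max
    rescaled to [0, 1].
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    values = expr.to_numpy(dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    assoc = _association_matrix(values, estimator, discretizer, bins)
    if algorithm == "clr":
        post = _clr(assoc)
    elif algorithm == "aracne":
        post = _aracne(assoc, aracne_epsilon)
    else:
        post = _mrnet(assoc)
    return WeightedNetwork(list(expr.index.astype(str)), _rescale_unit(post))


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def _rank_normalized(adj: np.ndarray) -> np.ndarray:
    """Edge-rank-normalize an adjacency: weights -> average ranks / n_pairs."""
    n = adj.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = stats.rankdata(adj[iu], method="average") / len(iu[0])
    out = np.zeros_like(adj)
    out[iu] = ranks
    return out + out.T


def consensus_network(
    networks: Sequence[WeightedNetwork],
    keep_top: int | None = None,
) -> WeightedNetwork:
    """Element-wise median of rank-normalized adjacencies, thresholded.

    ``keep_top`` is the number of strongest consensus edges retained
    (default 2N, N = node count); ties are resolved deterministically by
    (descending weight, node indices).
    """
    if not networks:
        raise ValueError("consensus of an empty network list")
    nodes = networks[0].nodes
    for net in networks[1:]:
        if net.nodes != nodes:
            raise ValueError("all networks must share the same node set/order")
    n = len(nodes)
    stack = np.stack([_rank_normalized(net.adjacency) for net in networks])
    med = np.median(stack, axis=0)
    if keep_top is None:
        keep_top = 2 * n
    iu, ju = np.triu_indices(n, k=1)
    weights = med[iu, ju]
    order = sorted(range(len(weights)), key=lambda k: (-weights[k], iu[k], ju[k]))
    keep = order[: min(keep_top, len(order))]
    out = np.zeros_like(med)
    for k in keep:
        if weights[k] > 0:
            out[iu[k], ju[k]] = out[ju[k], iu[k]] = weights[k]
    return WeightedNetwork(list(nodes), out)


def ensemble_consensus(
    expr: pd.DataFrame,
    algorithms: Iterable[str] = ALGORITHMS,
    estimators: Iterable[str] = ESTIMATORS,
    discretizers: Iterable[str] = DISCRETIZERS,
    bins: int | None = None,
    keep_top: int | None = None,
) -> WeightedNetwork:
    """Run the full inference grid and return the consensus network.

    Discretizers apply only to the empirical-MI estimator, so the grid size
    is |algorithms| * (|correlation estimators| + |discretizers|).
    """
    nets = []
    for algorithm in algorithms:
        for estimator in estimators:
            if estimator == "mi_empirical":
                for disc in discretizers:
                    nets.append(
                        infer_adjacency(expr, algorithm, estimator, disc, bins)
                    )
            else:
                nets.append(infer_adjacency(expr, algorithm, estimator, bins=bins))
    return consensus_network(nets, keep_top=keep_top)


# ---------------------------------------------------------------------------
# hub ranking
# ---------------------------------------------------------------------------

def _strict_ranks(values: dict[str, float], higher_better: bool) -> dict[str, int]:
    """1..N ranks (1 = best) with lexicographic gene-id tie-breaking."""
    sign = -1.0 if higher_better else 1.0
    order = sorted(values, key=lambda g: (sign * values[g], g))
    return {g: r for r, g in enumerate(order, start=1)}


def _mean_shortest_path(graph: nx.Graph, nodes: Sequence[str]) -> dict[str, float]:
    out = {}
    for node in nodes:
        lengths = nx.single_source_dijkstra_path_length(graph, node, weight="distance")
        lengths.pop(node, None)
        out[node] = float(np.mean(list(lengths.values()))) if lengths else np.inf
    return out


def _eigenvector(graph: nx.Graph) -> dict[str, float]:
    """Principal-eigenvector centrality, computed densely per component."""
    cent: dict[str, float] = {}
    for comp in nx.connected_components(graph):
        members = sorted(comp)
        if len(members) == 1:
            cent[members[0]] = 0.0
            continue
        adj = nx.to_numpy_array(graph, nodelist=members, weight="weight")
        vals, vecs = np.linalg.eigh(adj)
        vec = np.abs(vecs[:, -1])
        vec /= np.linalg.norm(vec)
        cent.update(zip(members, vec.tolist()))
    return cent


def borda_consensus(rank_table: pd.DataFrame) -> pd.DataFrame:
    """Mean-rank Borda aggregation of ranked lists.

    ``rank_table`` holds one column of 1..N ranks per list, indexed by item.
    Adds ``mean_rank`` (the Borda score) and ``consensus_rank`` (1..N by
    ascending mean rank, ties broken lexicographically by item id) and
    returns the table sorted by consensus rank.
    """
    table = rank_table.copy()
    table["mean_rank"] = rank_table.mean(axis=1)
    order = sorted(table.index, key=lambda g: (table.loc[g, "mean_rank"], g))
    consensus = {g: r for r, g in enumerate(order, start=1)}
    table["consensus_rank"] = [consensus[g] for g in table.index]
    return table.sort_values("consensus_rank")


def rank_hub_genes(net: WeightedNetwork, ss: pd.Series) -> pd.DataFrame:
    """Borda consensus ranking of network nodes.

    Six ranked lists are aggregated: weighted degree, mean shortest-path
    distance (ascending = more central; edge distance = 1 - weight + 1e-6),
    betweenness, closeness, eigenvector centrality and SS. The consensus
    score is the mean rank across lists; the final ``consensus_rank`` is a
    permutation of 1..N with lexicographic tie-breaking.

    Returns a DataFrame indexed by gene id, sorted by ``consensus_rank``,
    with the per-measure ranks and the mean rank as columns.
    """
    graph = net.to_networkx(DISTANCE_EPSILON)
    nodes = list(net.nodes)
    ss = pd.Series(ss)
    missing = [g for g in nodes if g not in ss.index]
    if missing:
        logger.warning(
            "%d node(s) missing a significance score; assigned worst SS rank",
            len(missing),
        )
    ss_full = {g: float(ss[g]) if g in ss.index else -np.inf for g in nodes}

    degree = dict(graph.degree(weight="weight"))
    msp = _mean_shortest_path(graph, nodes)
    betweenness = nx.betweenness_centrality(graph, weight="distance", normalized=True)
    closeness = {
        g: nx.closeness_centrality(graph, u=g, distance="distance") for g in nodes
    }
    eigen = _eigenvector(graph)

    rank_lists = {
        "rank_degree": _strict_ranks(degree, higher_better=True),
        "rank_shortest_path": _strict_ranks(msp, higher_better=False),
        "rank_betweenness": _strict_ranks(betweenness, higher_better=True),
        "rank_closeness": _strict_ranks(closeness, higher_better=True),
        "rank_eigenvector": _strict_ranks(eigen, higher_better=True),
        "rank_ss": _strict_ranks(ss_full, higher_better=True),
    }
    table = pd.DataFrame(rank_lists, index=nodes)
    table.index.name = "gene_id"
    return borda_consensus(table)
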