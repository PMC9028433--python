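"""Per-drug and per-pair feature tables consumed by the optimizer.

Four features characterize a drug library against a disease network:

* **MOA distance** — each drug's mechanism of action is represented by the
  consensus co-expression network of its replicate perturbational profiles;
  pairs of drugs are compared with the Hamming-Ipsen-Mikhailov (HIM) graph
  distance, a [0, 1] combination of local edge differences (Hamming) and the
  L2 distance between Lorentzian-smoothed Laplacian spectral densities
  (Ipsen-Mikhailov).
* **Structural distance** — Levenshtein edit distance between raw SMILES
  strings (no canonicalization by default).
* **Target dispersion** — mean unweighted shortest-path length between the
  two drugs' target sets on the filtered disease network; unreachable pairs
  contribute a penalty of |V|.
* **Effect score** — ES = N_t / M_R: number of network-mapped targets over
  the median Borda consensus rank of those targets, so many central targets
  give a high score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import edlib
import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .coexpression import ensemble_consensus
from .networks import WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "DrugRecord",
    "DrugFeatureTables",
    "build_moa_networks",
    "him_distance",
    "hamming_component",
    "ipsen_mikhailov_component",
    "calibrate_gamma",
    "smiles_distance",
    "target_path_distance",
    "effect_score",
    "build_feature_tables",
]

MIN_REPLICATES = 6  # "more than five replicates" inclusion rule


@dataclass
class DrugRecord:
    """One drug: identifier, SMILES, target genes, optional MOA profiles."""

    drug_id: str
    smiles: str
    targets: set[str]
    moa_profiles: pd.DataFrame | None = None  # genes x replicates

    def n_replicates(self) -> int:
        return 0 if self.moa_profiles is None else self.moa_profiles.shape[1]


@dataclass
class DrugFeatureTables:
    """Pairwise HIM / Levenshtein / shortest-path matrices and the ES vector.

    Matrices are symmetric with zero diagonals, indexed by drug id in a
    fixed order shared by all tables.
    """

    him: pd.DataFrame
    lev: pd.DataFrame
    sp: pd.DataFrame
    es: pd.Series
    excluded: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = list(self.him.index)
        for name, m in (("him", self.him), ("lev", self.lev), ("sp", self.sp)):
            if list(m.index) != ids or list(m.columns) != ids:
                raise ValueError(f"{name} table index mismatch")
            arr = m.to_numpy(dtype=float)
            if not np.allclose(arr, arr.T):
                raise ValueError(f"{name} table must be symmetric")
            if np.any(np.diag(arr) != 0):
                raise ValueError(f"{name} table must have a zero diagonal")
        if list(self.es.index) != ids:
            raise ValueError("es vector index mismatch")
        if not np.all(np.isfinite(self.es)) or np.any(self.es <= 0):
            raise ValueError("effect scores must be finite and positive")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.him.index)

    @property
    def n_drugs(self) -> int:
        return len(self.him)


# ---------------------------------------------------------------------------
# MOA networks
# ---------------------------------------------------------------------------

def build_moa_networks(
    drugs: Sequence[DrugRecord],
    min_replicates: int = MIN_REPLICATES,
    **ensemble_kwargs,
) -> dict[str, WeightedNetwork]:
    """Consensus co-expression network per drug with enough replicates.

    Drugs below ``min_replicates`` replicate profiles are excluded (logged);
    profiles must share one gene panel.
    """
    networks: dict[str, WeightedNetwork] = {}
    for drug in drugs:
        if drug.n_replicates() < min_replicates:
            logger.info(
                "drug %s excluded from MOA inference: %d replicate(s) < %d",
                drug.drug_id,
                drug.n_replicates(),
                min_replicates,
            )
            continue
        networks[drug.drug_id] = ensemble_consensus(drug.moa_profiles, **ensemble_kwargs)
    if not networks:
        raise ValueError("no drug passed the replicate threshold for MOA inference")
    return networks


# ---------------------------------------------------------------------------
# Hamming-Ipsen-Mikhailov distance
# ---------------------------------------------------------------------------

_GAMMA_CACHE: dict[int, float] = {}
_GRID_POINTS = 4096


def _spectral_omegas(net: WeightedNetwork) -> np.ndarray:
    """Vibrational frequencies sqrt(lambda_i) of the weighted Laplacian.

    The single trivial zero eigenvalue is dropped, leaving N-1 frequencies.
    """
    adj = net.adjacency
    lap = np.diag(adj.sum(axis=1)) - adj
    eig = np.linalg.eigvalsh(lap)
    return np.sqrt(np.clip(eig[1:], 0.0, None))


def _omega_grid(n: int, gamma: float) -> np.ndarray:
    upper = np.sqrt(2.0 * n) + 10.0 * gamma + 5.0
    return np.linspace(0.0, upper, _GRID_POINTS)


def _lorentzian_density(
    omegas: np.ndarray, gamma: float, grid: np.ndarray
) -> np.ndarray:
    """Normalized sum of Lorentzians rho(w) on [0, inf), evaluated on grid."""
    # closed-form normalization: integral of each Lorentzian over [0, inf)
    norm = np.sum(np.pi / 2.0 + np.arctan(omegas / gamma))
    dens = (gamma / ((grid[None, :] - omegas[:, None]) ** 2 + gamma**2)).sum(axis=0)
    return dens / norm


def _im_from_omegas(
    om1: np.ndarray, om2: np.ndarray, n: int, gamma: float
) -> float:
    grid = _omega_grid(n, gamma)
    d1 = _lorentzian_density(om1, gamma, grid)
    d2 = _lorentzian_density(om2, gamma, grid)
    return float(np.sqrt(np.trapezoid((d1 - d2) ** 2, grid)))


def calibrate_gamma(n: int) -> float:
    """Lorentzian width such that IM(empty_N, complete_N) = 1 (cached per N)."""
    if n < 2:
        raise ValueError("IM needs at least 2 nodes")
    if n in _GAMMA_CACHE:
        return _GAMMA_CACHE[n]
    empty = np.zeros(n - 1)
    complete = np.full(n - 1, np.sqrt(n))

    def objective(gamma: float) -> float:
        return _im_from_omegas(empty, complete, n, gamma) - 1.0

    gamma = float(brentq(objective, 1e-3, 5.0, xtol=1e-10))
    _GAMMA_CACHE[n] = gamma
    return gamma


def hamming_component(g1: WeightedNetwork, g2: WeightedNetwork) -> float:
    """Mean absolute adjacency difference over the N(N-1)/2 node pairs."""
    if g1.nodes != g2.nodes:
        raise ValueError("networks must share the same node set and order")
    n = g1.n_nodes
    iu = np.triu_indices(n, k=1)
    return float(np.abs(g1.adjacency[iu] - g2.adjacency[iu]).mean())


def ipsen_mikhailov_component(
    g1: WeightedNetwork, g2: WeightedNetwork, gamma: float | None = None
) -> float:
    """L2 distance between Laplacian spectral densities, calibrated to [0, 1]."""
    if g1.nodes != g2.nodes:
        raise ValueError("networks must share the same node set and order")
    n = g1.n_nodes
    if gamma is None:
        gamma = calibrate_gamma(n)
    return _im_from_omegas(_spectral_omegas(g1), _spectral_omegas(g2), n, gamma)


def him_distance(
    g1: WeightedNetwork, g2: WeightedNetwork, gamma: float | None = None
) -> float:
    """HIM = sqrt(H^2 + IM^2) / sqrt(2), in [0, 1]."""
    h = hamming_component(g1, g2)
    im = ipsen_mikhailov_component(g1, g2, gamma)
    return float(min(1.0, np.sqrt(h**2 + im**2) / np.sqrt(2.0)))


# ---------------------------------------------------------------------------
# SMILES edit distance
# ---------------------------------------------------------------------------

def smiles_distance(s1: str, s2: str) -> int:
    """Levenshtein distance between two SMILES strings (no canonicalization)."""
    if not s1 or not s2:
        return len(s1) + len(s2)
    return int(edlib.align(s1, s2, task="distance")["editDistance"])


# ---------------------------------------------------------------------------
# target shortest paths
# ---------------------------------------------------------------------------

def _sp_lengths_from(
    graph: nx.Graph, sources: Iterable[str]
) -> dict[str, dict[str, int]]:
    return {
        s: nx.single_source_shortest_path_length(graph, s) for s in sources
    }


def target_path_distance(
    net: WeightedNetwork,
    t1: set[str],
    t2: set[str],
    _lengths: Mapping[str, Mapping[str, int]] | None = None,
) -> float:
    """Mean unweighted shortest-path length between two target sets.

    Averages over all (g1 in t1, g2 in t2) pairs; identical genes contribute
    0 and pairs in different components contribute the penalty |V|. Targets
    must already be intersected with the network node set.
    """
    t1, t2 = set(t1), set(t2)
    if not t1 or not t2:
        raise ValueError("both target sets must map into the network")
    unknown = (t1 | t2) - set(net.nodes)
    if unknown:
        raise ValueError(f"targets not in network: {sorted(unknown)}")
    penalty = net.n_nodes
    if _lengths is None:
        graph = net.to_networkx()
        _lengths = _sp_lengths_from(graph, t1)
    total = 0.0
    for g1 in t1:
        row = _lengths[g1]
        for g2 in t2:
            total += row.get(g2, penalty) if g1 != g2 else 0.0
    return total / (len(t1) * len(t2))


# ---------------------------------------------------------------------------
# effect score
# ---------------------------------------------------------------------------

def effect_score(targets: set[str], ranking: pd.DataFrame | pd.Series) -> float:
    """ES = N_t / M_R on the Borda consensus ranking.

    ``ranking`` is either the hub-ranking table (uses ``consensus_rank``) or
    a Series mapping gene id to rank. N_t counts targets present in the
    ranking; M_R is their median rank (mean of the middle two for even N_t).
    """
    ranks = ranking["consensus_rank"] if isinstance(ranking, pd.DataFrame) else ranking
    mapped = [g for g in targets if g in ranks.index]
    if not mapped:
        raise ValueError("no target maps into the ranked network")
    m_r = float(np.median([ranks[g] for g in mapped]))
    return len(mapped) / m_r


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def build_feature_tables(
    drugs: Sequence[DrugRecord],
    disease_net: WeightedNetwork,
    ranking: pd.DataFrame,
    min_replicates: int = MIN_REPLICATES,
    moa_networks: Mapping[str, WeightedNetwork] | None = None,
    **ensemble_kwargs,
) -> DrugFeatureTables:
    """Compute all four feature tables for the qualifying drug library.

    Drugs are dropped (with a logged reason, recorded in ``excluded``) when
    they have no target mapped into the disease network or too few MOA
    replicates. ``moa_networks`` may be supplied to reuse precomputed
    consensus networks.
    """
    excluded: dict[str, str] = {}
    net_nodes = set(disease_net.nodes)
    kept: list[DrugRecord] = []
    for drug in drugs:
        mapped = drug.targets & net_nodes
        if not mapped:
            excluded[drug.drug_id] = "no target mapped into the disease network"
        elif moa_networks is not None and drug.drug_id in moa_networks:
            kept.append(drug)
        elif drug.n_replicates() < min_replicates:
            excluded[drug.drug_id] = (
                f"only {drug.n_replicates()} MOA replicates (< {min_replicates})"
            )
        else:
            kept.append(drug)
    for drug_id, reason in excluded.items():
        logger.info("drug %s excluded: %s", drug_id, reason)
    if len(kept) < 2:
        raise ValueError("fewer than 2 drugs qualify for feature computation")

    if moa_networks is None:
        moa_networks = build_moa_networks(kept, min_replicates, **ensemble_kwargs)
    ids = [d.drug_id for d in kept]
    k = len(ids)

    # HIM: cache spectral densities so each network is decomposed once
    gamma = calibrate_gamma(moa_networks[ids[0]].n_nodes)
    n_moa = moa_networks[ids[0]].n_nodes
    grid = _omega_grid(n_moa, gamma)
    dens = {
        d: _lorentzian_density(_spectral_omegas(moa_networks[d]), gamma, grid)
        for d in ids
    }
    iu = np.triu_indices(n_moa, k=1)
    flat = {d: moa_networks[d].adjacency[iu] for d in ids}
    him = np.zeros((k, k))
    for i, j in combinations(range(k), 2):
        h = float(np.abs(flat[ids[i]] - flat[ids[j]]).mean())
        im = float(np.sqrt(np.trapezoid((dens[ids[i]] - dens[ids[j]]) ** 2, grid)))
        him[i, j] = him[j, i] = min(1.0, np.sqrt(h**2 + im**2) / np.sqrt(2.0))

    lev = np.zeros((k, k), dtype=int)
    for i, j in combinations(range(k), 2):
        lev[i, j] = lev[j, i] = smiles_distance(kept[i].smiles, kept[j].smiles)

    graph = disease_net.to_networkx()
    mapped_targets = {d.drug_id: d.targets & net_nodes for d in kept}
    all_targets = set().union(*mapped_targets.values())
    lengths = _sp_lengths_from(graph, all_targets)
    sp = np.zeros((k, k))
    for i, j in combinations(range(k), 2):
        sp[i, j] = sp[j, i] = target_path_distance(
            disease_net,
            mapped_targets[ids[i]],
            mapped_targets[ids[j]],
            _lengths=lengths,
        )

    es = pd.Series(
        [effect_score(mapped_targets[d], ranking) for d in ids], index=ids, name="ES"
    )
    return DrugFeatureTables(
        him=pd.DataFrame(him, index=ids, columns=ids),
        lev=pd.DataFrame(lev, index=ids, columns=ids),
        sp=pd.DataFrame(sp, index=ids, columns=ids),
        es=es,
        excluded=excluded,
    )
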