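"""Genetic-algorithm mechanics, NSGA-II selection and stability analysis."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from netcombo.optimizer import (
    GAConfig,
    HallOfFame,
    SENTINEL,
    crowding_distance,
    evaluate_combination,
    fast_nondominated_sort,
    initialize_population,
    nsga2_select,
    one_point_crossover,
    run_optimizer,
    stability_analysis,
    swap_mutation,
)

from conftest import random_feature_tables


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _pair_tables(him=0.6, lev=10, sp=4.0, es=(1.0, 0.5)):
    ids = ["a", "b"]
    mk = lambda v: pd.DataFrame([[0, v], [v, 0]], index=ids, columns=ids)
    from netcombo.features import DrugFeatureTables

    return DrugFeatureTables(
        him=mk(him), lev=mk(lev), sp=mk(sp), es=pd.Series(es, index=ids)
    )


def test_pair_objectives_use_size_normalization():
    feats = _pair_tables()
    obj = evaluate_combination(np.array([1, 1]), feats)
    assert obj[0] == pytest.approx(0.6 / 2)  # 1/|x|, not 1/pairs
    assert obj[1] == pytest.approx(10 / 2)
    assert obj[2] == pytest.approx(4.0 / 2)
    assert obj[3] == pytest.approx(0.75)  # mean ES
    assert obj[4] == -2.0


def test_pair_count_normalization_flag():
    feats = _pair_tables()
    obj = evaluate_combination(np.array([1, 1]), feats, GAConfig(pair_norm="pairs"))
    assert obj[0] == pytest.approx(0.6)


def test_invalid_combinations_get_sentinel():
    feats = _pair_tables()
    assert np.array_equal(evaluate_combination(np.array([0, 0]), feats), SENTINEL)
    assert np.array_equal(evaluate_combination(np.array([1, 0]), feats), SENTINEL)


def test_three_drug_toy_matches_hand_arithmetic():
    feats = random_feature_tables(4, seed=9)
    bits = np.array([1, 1, 0, 1])
    obj = evaluate_combination(bits, feats)
    idx = [0, 1, 3]
    pairs = list(combinations(idx, 2))
    him = sum(feats.him.iloc[i, j] for i, j in pairs) / 3
    lev = sum(feats.lev.iloc[i, j] for i, j in pairs) / 3
    sp = sum(feats.sp.iloc[i, j] for i, j in pairs) / 3
    cov = feats.es.iloc[idx].mean()
    assert obj == pytest.approx([him, lev, sp, cov, -3.0])


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------

def test_initialization_extremes_and_rate():
    rng = np.random.default_rng(0)
    assert not initialize_population(5, 20, 0.0, rng).any()
    assert initialize_population(5, 20, 1.0, rng).all()
    pop = initialize_population(10_000, 100, 0.30, np.random.default_rng(1))
    assert pop.mean() == pytest.approx(0.30, abs=0.01)


def test_crossover_splice_and_identity():
    p1 = np.array([1, 1, 1, 1], dtype=np.int8)
    p2 = np.array([0, 0, 0, 0], dtype=np.int8)
    assert np.array_equal(one_point_crossover(p1, p2, 2), [1, 1, 0, 0])
    assert np.array_equal(one_point_crossover(p1, p1.copy(), 3), p1)
    with pytest.raises(ValueError):
        one_point_crossover(p1, p2, 0)
    with pytest.raises(ValueError):
        one_point_crossover(p1, p2, 4)


def test_crossover_child_bit_count_over_all_cuts():
    rng = np.random.default_rng(3)
    p1 = (rng.random(12) < 0.5).astype(np.int8)
    p2 = (rng.random(12) < 0.5).astype(np.int8)
    counts = [one_point_crossover(p1, p2, c).sum() for c in range(1, 12)]
    lo = min(p1.sum(), p2.sum()) - 12
    assert min(counts) >= 0 and max(counts) <= 12
    # every splice mixes prefixes/suffixes of the parents
    for c, n_ones in zip(range(1, 12), counts):
        assert n_ones == p1[:c].sum() + p2[c:].sum()


def test_mutation_identity_at_zero_probability():
    chrom = np.array([1, 0, 1, 1, 0], dtype=np.int8)
    out = swap_mutation(chrom, 0.0, np.random.default_rng(0))
    assert np.array_equal(out, chrom)


def test_mutation_conserves_popcount():
    rng = np.random.default_rng(4)
    for _ in range(200):
        chrom = (rng.random(30) < 0.4).astype(np.int8)
        out = swap_mutation(chrom, 0.3, rng)
        assert out.sum() == chrom.sum()


def test_mutation_trigger_rate_near_ten_percent():
    rng = np.random.default_rng(5)
    chrom = (rng.random(100) < 0.3).astype(np.int8)
    log: list[int] = []
    for _ in range(5000):
        swap_mutation(chrom, 0.10, rng, trigger_log=log)
    rate = sum(log) / (5000 * 100)
    assert rate == pytest.approx(0.10, abs=0.005)


# ---------------------------------------------------------------------------
# NSGA-II
# ---------------------------------------------------------------------------

def _brute_force_fronts(objs: np.ndarray) -> list[list[int]]:
    n = len(objs)
    dominates = lambda a, b: (objs[a] >= objs[b]).all() and (objs[a] > objs[b]).any()
    remaining = set(range(n))
    fronts = []
    while remaining:
        front = [
            i
            for i in remaining
            if not any(dominates(j, i) for j in remaining if j != i)
        ]
        fronts.append(sorted(front))
        remaining -= set(front)
    return fronts


def test_front_assignment_matches_brute_force():
    rng = np.random.default_rng(6)
    for _ in range(10):
        objs = rng.random((int(rng.integers(5, 80)), 5))
        fronts = [sorted(f.tolist()) for f in fast_nondominated_sort(objs)]
        assert fronts == _brute_force_fronts(objs)


def test_single_individual_is_front_zero():
    objs = np.array([[1.0, 2.0, 3.0, 4.0, -2.0]])
    assert nsga2_select(objs, 1).tolist() == [0]


def test_duplicate_vectors_selected_deterministically():
    objs = np.array([[1.0, 1.0], [1.0, 1.0], [0.5, 0.5]])
    picked = nsga2_select(objs, 1)
    assert picked.tolist() == [0]  # index order breaks the tie


def test_selection_respects_front_order_and_crowding():
    rng = np.random.default_rng(7)
    objs = rng.random((40, 5))
    k = 15
    picked = nsga2_select(objs, k)
    assert len(picked) == k and len(set(picked.tolist())) == k
    fronts = _brute_force_fronts(objs)
    flat = []
    for f in fronts:
        flat.extend(f)
        if len(flat) >= k:
            break
    # every fully admitted front is contained in the selection
    acc = 0
    for f in fronts:
        if acc + len(f) <= k:
            assert set(f) <= set(picked.tolist())
            acc += len(f)
        else:
            break
    with pytest.raises(ValueError):
        nsga2_select(objs, 41)


def test_crowding_boundary_points_are_infinite():
    objs = np.array([[0.0, 1.0], [0.5, 0.5], [1.0, 0.0]])
    crowd = crowding_distance(objs)
    assert np.isinf(crowd[0]) and np.isinf(crowd[2])
    assert np.isfinite(crowd[1])


# ---------------------------------------------------------------------------
# Hall of Fame
# ---------------------------------------------------------------------------

def test_hof_never_admits_invalid_or_dominated():
    hof = HallOfFame(capacity=3)
    bits = np.eye(4, dtype=np.int8)
    hof.update(np.array([[0, 0, 0, 0]]), SENTINEL[None, :])
    assert hof.members() == []
    good = np.array([1.0, 1.0, 1.0, 1.0, -2.0])
    better = np.array([2.0, 2.0, 2.0, 2.0, -2.0])
    hof.update(np.array([[1, 1, 0, 0]]), good[None, :])
    hof.update(np.array([[0, 0, 1, 1]]), better[None, :])
    members = hof.members()
    assert len(members) == 1
    assert np.array_equal(members[0][1], better)


def test_hof_truncates_to_capacity_by_crowding():
    hof = HallOfFame(capacity=3)
    n = 8
    # a 2-objective front: all mutually non-dominated
    objs = np.column_stack(
        [np.arange(n, dtype=float), np.arange(n, dtype=float)[::-1], np.zeros(n),
         np.zeros(n), np.full(n, -2.0)]
    )
    chroms = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        chroms[i, i] = 1
        chroms[i, (i + 1) % n] = 1
    hof.update(chroms, objs)
    assert hof.archive_size == n
    members = hof.members()
    assert len(members) == 3
    member_objs = np.array([m[1] for m in members])
    # boundary (most extreme) points survive truncation
    assert 0.0 in member_objs[:, 0] and float(n - 1) in member_objs[:, 0]


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_run():
    feats = random_feature_tables(10, seed=1)
    cfg = GAConfig(generations=60)
    return run_optimizer(feats, cfg, seed=11), feats, cfg


def test_run_produces_fixed_population_and_offspring(small_run):
    state, _, cfg = small_run
    assert len(state.population) == cfg.population_size
    assert sum(state.operator_counts.values()) == cfg.generations * cfg.offspring
    # traces cover every generation and objective
    assert len(state.traces) == cfg.generations * 5


def test_run_is_bitwise_reproducible(small_run):
    state, feats, cfg = small_run
    again = run_optimizer(feats, cfg, seed=11)
    assert np.array_equal(state.population, again.population)
    assert np.array_equal(state.objectives, again.objectives)
    pd.testing.assert_frame_equal(state.traces, again.traces)
    assert state.hof_combinations() == again.hof_combinations()


def test_hof_members_are_valid_and_unbeaten(small_run):
    state, feats, cfg = small_run
    members = state.hof.members()
    assert 0 < len(members) <= cfg.hof_size
    for bits, obj in members:
        assert bits.sum() >= 2  # sentinel safety
        # no final-population individual dominates a HoF member
        dominated = (
            (state.objectives >= obj).all(axis=1)
            & (state.objectives > obj).any(axis=1)
        )
        assert not dominated.any()


def test_operator_split_near_seventy_thirty(small_run):
    feats = random_feature_tables(10, seed=1)
    state = run_optimizer(feats, GAConfig(generations=500), seed=2)
    frac = state.operator_counts["crossover"] / (500 * 20)
    assert frac == pytest.approx(0.70, abs=0.015)


def test_stability_identical_seeds_fully_overlap():
    feats = random_feature_tables(8, seed=2)
    cfg = GAConfig(generations=30)
    result = stability_analysis(feats, cfg, n_runs=3, seeds=[5, 5, 5])
    assert np.allclose(result.jaccard, 1.0)


def test_stability_frequency_matches_counting_oracle():
    feats = random_feature_tables(8, seed=3)
    cfg = GAConfig(generations=40)
    result = stability_analysis(feats, cfg, n_runs=3, seed=7)
    counts: dict[tuple[str, str], int] = {}
    for state in result.states:
        for combo in state.hof_combinations():
            for a, b in combinations(sorted(combo["drugs"]), 2):
                counts[(a, b)] = counts.get((a, b), 0) + 1
    freq = {
        (r.drug_a, r.drug_b): r.count for r in result.frequency.itertuples()
    }
    assert freq == counts
    # reproducibility of the whole analysis
    again = stability_analysis(feats, cfg, n_runs=3, seed=7)
    pd.testing.assert_frame_equal(result.frequency, again.frequency)
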