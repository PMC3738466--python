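import numpy as np
import pytest

import poprep.flddecode as fld
from poprep.flddecode import (
    build_null_pruned,
    build_pseudopopulation,
    conflict_graph,
    fit_fld,
    prune_category,
    run_fld_task,
)
from poprep.imgprops import CategoryScheme
from poprep.neurogen import ResponseDataset, TuningConfig, simulate_population
from poprep.stimgen import StimulusConfig, generate_stimulus_set


def make_dataset(rates, reps=6, seed=0):
    rng = np.random.default_rng(seed)
    rates = np.asarray(rates, dtype=float)
    counts = rng.poisson(rates[:, :, None] * 0.1, rates.shape + (reps,))
    return ResponseDataset(
        counts=counts,
        background_counts=rng.poisson(1.0, (rates.shape[0], 10)),
        object_ids=[f"o{j}" for j in range(rates.shape[1])],
        neuron_ids=[f"n{i}" for i in range(rates.shape[0])],
    )


def test_pseudopopulation_single_trial_forced():
    counts = np.arange(12).reshape(2, 6, 1)
    ds = ResponseDataset(
        counts=counts,
        background_counts=np.zeros((2, 3), dtype=int),
        object_ids=[f"o{j}" for j in range(6)],
        neuron_ids=["n0", "n1"],
    )
    pps = build_pseudopopulation(ds, n_vectors=7, seed=0)
    for j in range(6):
        assert (pps.vectors[j] == counts[:, j, 0]).all()


def test_pseudopopulation_values_are_observed_counts(small_dataset):
    pps = build_pseudopopulation(small_dataset, n_vectors=5, seed=1)
    for j in range(small_dataset.n_objects):
        for i in range(small_dataset.n_neurons):
            observed = set(small_dataset.counts[i, j])
            assert set(pps.vectors[j, :, i]) <= observed


def test_pseudopopulation_bootstrap_mean_consistent():
    rng = np.random.default_rng(2)
    ds = make_dataset(rng.uniform(20, 80, (3, 4)), reps=20, seed=3)
    pps = build_pseudopopulation(ds, n_vectors=10_000, seed=4)
    for i in range(3):
        for j in range(4):
            trials = ds.counts[i, j]
            se = trials.std(ddof=1) / np.sqrt(10_000)
            assert abs(
                pps.vectors[j, :, i].mean() - trials.mean()
            ) <= 3 * se + 1e-9


def test_fit_fld_separates_gaussians():
    rng = np.random.default_rng(5)
    X = np.vstack([
        rng.normal(0, 1, (50, 4)), rng.normal(4, 1, (50, 4))
    ])
    y = np.array([False] * 50 + [True] * 50)
    w, thr = fit_fld(X, y)
    pred = X @ w > thr
    assert (pred == y).mean() > 0.95


def test_fit_fld_singular_scatter_shrinkage():
    # duplicated feature column makes the scatter singular
    rng = np.random.default_rng(6)
    base = rng.normal(size=(40, 2))
    X = np.hstack([base, base[:, :1]])
    y = np.array([False] * 20 + [True] * 20)
    X[y] += 3.0
    w, thr = fit_fld(X, y)
    assert np.isfinite(w).all()
    assert ((X @ w > thr) == y).mean() > 0.9


def planted_dataset(gain=60.0, n_neurons=16, n_objects=20, seed=0):
    rng = np.random.default_rng(seed)
    rates = np.full((n_neurons, n_objects), 10.0)
    gains = rng.uniform(0.5, 1.5, n_neurons)
    rates[:, : n_objects // 2] += gain * gains[:, None]
    return make_dataset(rates, reps=7, seed=seed + 1)


def test_fld_separable_planted_categories():
    ds = planted_dataset()
    positive = set(ds.object_ids[:10])
    out = run_fld_task(ds, positive, n_loops=15, n_runs=20, seed=0)
    assert out["performance"] >= 0.95
    assert out["p"] <= 1 / 20


def test_fld_null_is_chance():
    ds = planted_dataset()
    positive = set(ds.object_ids[:10])
    out = run_fld_task(ds, positive, n_loops=15, n_runs=30, seed=1)
    sd = max(out["null_sd"], 1e-3)
    assert abs(out["null_mean"] - 0.5) < 3 * sd / np.sqrt(1) + 0.1


def test_fld_small_positive_set_rejected(small_dataset):
    with pytest.raises(ValueError, match=">= 2"):
        run_fld_task(small_dataset, {small_dataset.object_ids[0]})


def test_fld_no_leakage_of_left_out_objects(monkeypatch):
    ds = planted_dataset(n_objects=10)
    pps = fld.build_pseudopopulation(ds, 7, seed=0)
    vectors = pps.vectors
    labels = np.array([True] * 5 + [False] * 5)
    seen = []
    real_fit = fld.fit_fld

    def spy(X, y, shrinkage=None):
        seen.append(np.asarray(X).copy())
        return real_fit(X, y, shrinkage)

    monkeypatch.setattr(fld, "fit_fld", spy)
    rng = np.random.default_rng(3)
    for _ in range(10):
        fld._one_loop(vectors, labels, rng)
    # training matrices contain exactly (n_objects - 2) * n_vectors rows,
    # and no row may equal any vector of a fully excluded object
    for X in seen:
        assert X.shape[0] == (10 - 2) * 7
        present = {tuple(row) for row in X}
        n_excluded = sum(
            all(tuple(v) not in present for v in vectors[j])
            for j in range(10)
        )
        assert n_excluded >= 2


def schemes_and_twins():
    shape = CategoryScheme(
        scheme_kind="shape_based",
        categories={
            "s1": {"a", "b", "e"}, "s2": {"c", "f"}, "s3": {"d", "g", "h"},
        },
    )
    twins = {
        "t1": frozenset({"a", "b"}),
        "t2": frozenset({"c"}), "t3": frozenset({"d"}),
        "t4": frozenset({"e"}), "t5": frozenset({"f"}),
        "t6": frozenset({"g"}), "t7": frozenset({"h"}),
    }
    return shape, twins


def test_prune_unconstrained_keeps_all():
    scheme = CategoryScheme(
        scheme_kind="shape_based",
        categories={f"s{i}": {f"o{i}"} for i in range(4)},
    )
    twins = {f"t{i}": frozenset({f"o{i}"}) for i in range(8)}
    twins.update({f"u{i}": frozenset({f"o{i+4}"}) for i in range(4)})
    universe = {f"o{i}" for i in range(8)}
    out = prune_category(
        {"o0", "o1", "o2", "o3"}, [scheme],
        {f"t{i}": frozenset({f"o{i}"}) for i in range(8)},
        universe, seed=0,
    )
    assert out.positive == frozenset({"o0", "o1", "o2", "o3"})


@pytest.mark.parametrize("seed", range(10))
def test_prune_never_keeps_both_twins(seed):
    shape, twins = schemes_and_twins()
    universe = set("abcdefgh")
    out = prune_category({"a", "b", "c", "d"}, [shape], twins, universe,
                         seed=seed)
    assert not {"a", "b"} <= out.positive
    # and no two members of the positive set share a shape category
    for name, cat in shape.categories.items():
        assert len(out.positive & cat) <= 1
        assert len(out.negative & cat) <= 1


def brute_force_mis(g):
    import networkx as nx
    from itertools import combinations

    nodes = list(g.nodes)
    for size in range(len(nodes), 0, -1):
        for sub in combinations(nodes, size):
            if not any(g.has_edge(a, b) for a, b in combinations(sub, 2)):
                return size
    return 0


@pytest.mark.parametrize("seed", range(5))
def test_prune_matches_bruteforce_maximum(seed):
    rng = np.random.default_rng(seed)
    n = 12
    objects = [f"o{i}" for i in range(n)]
    cats = {
        f"c{k}": set(rng.choice(objects, rng.integers(2, 5), replace=False))
        for k in range(4)
    }
    scheme = CategoryScheme(scheme_kind="low_level", categories={
        k: frozenset(v) for k, v in cats.items()
    })
    twin_ids = rng.integers(0, 8, n)
    twins = {}
    for o, t in zip(objects, twin_ids):
        twins.setdefault(f"t{t}", set()).add(o)
    twins = {k: frozenset(v) for k, v in twins.items()}
    out = prune_category(set(objects), [scheme], twins, set(objects),
                         seed=seed)
    g = conflict_graph(objects, [scheme], twins)
    assert len(out.positive) == brute_force_mis(g)


def test_prune_too_small_flagged():
    scheme = CategoryScheme(
        scheme_kind="shape_based", categories={"all": set("abcd")}
    )
    twins = {x: frozenset({x}) for x in "abcd"}
    out = prune_category(set("abc"), [scheme], twins, set("abcd"), seed=0)
    assert len(out.positive) == 1
    assert out.too_small


def test_null_pruned_sizes_and_constraints():
    shape, twins = schemes_and_twins()
    universe = set("abcdefgh")
    out = build_null_pruned([shape], twins, pos_size=2, neg_size=3,
                            universe=universe, seed=1)
    assert len(out.positive) == 2 and len(out.negative) == 3
    assert out.positive.isdisjoint(out.negative)
    for cat in shape.categories.values():
        assert len(out.positive & cat) <= 1
        assert len(out.negative & cat) <= 1


def test_null_pruned_infeasible_size_raises():
    shape, twins = schemes_and_twins()
    with pytest.raises(RuntimeError, match="could not sample"):
        build_null_pruned([shape], twins, pos_size=7, neg_size=1,
                          universe=set("abcdefgh"), seed=0, max_retries=5)
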