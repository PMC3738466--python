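import numpy as np
import networkx as nx
import pytest

from poprep.dmst import (
    DMSTParams,
    Forest,
    ROOT,
    build_forest,
    consensus_forest,
    exact_forest,
    pair_agreement,
    stability_scan,
)
from tests.conftest import random_dissimilarity


def two_groups(n_per=3, within=0.1, between=1.0):
    n = 2 * n_per
    d = np.full((n, n), between)
    for g in (range(n_per), range(n_per, n)):
        for i in g:
            for j in g:
                d[i, j] = within
    np.fill_diagonal(d, 0.0)
    return d


def test_params_validation():
    with pytest.raises(ValueError, match="lambda"):
        DMSTParams(lambda_=-0.1)
    with pytest.raises(ValueError, match="d_max"):
        DMSTParams(lambda_=0.5, d_max=0)


def test_forest_invariants_enforced():
    with pytest.raises(ValueError, match="cycle"):
        Forest(np.array([1, 0]), ["a", "b"], d_max=3)
    with pytest.raises(ValueError, match="depth"):
        Forest(np.array([ROOT, 0, 1, 2]), list("abcd"), d_max=2)


def test_input_validation():
    d = np.array([[0.0, 1.0], [2.0, 0.0]])
    with pytest.raises(ValueError, match="symmetric"):
        build_forest(d, DMSTParams(lambda_=0.5))
    with pytest.raises(ValueError, match="non-negative"):
        build_forest(-two_groups(), DMSTParams(lambda_=0.5))


def test_lambda_zero_gives_singletons():
    rng = np.random.default_rng(0)
    d = random_dissimilarity(7, rng)
    f = build_forest(d, DMSTParams(lambda_=0.0, d_max=3, seed=1))
    assert f.n_clusters == 7
    assert all(len(t) == 1 for t in f.trees())


def test_two_tight_groups_recovered():
    d = two_groups()
    f = build_forest(d, DMSTParams(lambda_=0.5, d_max=3, seed=0))
    assert f.trees() == [frozenset({0, 1, 2}), frozenset({3, 4, 5})]
    ex = exact_forest(d, 0.5, 3)
    assert f.cost(d, 0.5) == pytest.approx(ex.cost(d, 0.5))


def test_exact_solver_brute_force_oracle_tiny():
    """Exhaustive enumeration over all parent assignments at n=5."""
    import itertools

    rng = np.random.default_rng(5)
    d = random_dissimilarity(5, rng)
    lam, d_max = 0.4, 2
    best = np.inf
    for parents in itertools.product([ROOT, 0, 1, 2, 3, 4], repeat=5):
        if any(p == i for i, p in enumerate(parents)):
            continue
        try:
            f = Forest(np.array(parents), list(range(5)), d_max)
        except ValueError:
            continue
        best = min(best, f.cost(d, lam))
    ex = exact_forest(d, lam, d_max)
    assert ex.cost(d, lam) == pytest.approx(best)


@pytest.mark.parametrize("seed", range(10))
def test_message_passing_matches_exact_sample(seed):
    rng = np.random.default_rng(100 + seed)
    d = random_dissimilarity(7, rng)
    lam = rng.uniform(0.2, 0.8)
    ex = exact_forest(d, lam, 3)
    ap = build_forest(d, DMSTParams(lambda_=lam, d_max=3, seed=seed,
                                    n_iter=150))
    assert ap.cost(d, lam) <= ex.cost(d, lam) + 1e-9


def test_cluster_count_monotone_in_lambda():
    rng = np.random.default_rng(2)
    d = random_dissimilarity(15, rng)
    means = []
    for lam in (0.05, 0.2, 0.4, 0.7, 1.2):
        counts = [
            build_forest(
                d, DMSTParams(lambda_=lam, d_max=4, seed=s, n_iter=80,
                              anneal_steps=500)
            ).n_clusters
            for s in range(8)
        ]
        means.append(np.mean(counts))
    assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))


def test_depth_bound_respected():
    rng = np.random.default_rng(3)
    d = random_dissimilarity(12, rng)
    for d_max in (1, 2, 4):
        f = build_forest(d, DMSTParams(lambda_=0.6, d_max=d_max, seed=0,
                                       n_iter=80, anneal_steps=500))
        assert f.depths().max() <= d_max


def test_d_max_one_is_all_centers():
    rng = np.random.default_rng(4)
    d = random_dissimilarity(6, rng)
    f = build_forest(d, DMSTParams(lambda_=0.1, d_max=1, seed=0,
                                   n_iter=50, anneal_steps=200))
    assert f.n_clusters == 6


def test_pair_agreement():
    assert pair_agreement([0, 0, 1, 1], [1, 1, 0, 0]) == 1.0
    assert pair_agreement([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(
        2 / 6
    )


def test_stability_scan_planted_structure():
    d = two_groups(n_per=4, within=0.1, between=1.0)
    out = stability_scan(
        d, lambda_grid=[0.3, 0.4, 0.5], dmax_grid=[3],
        n_runs=5, seed=0, n_iter=60,
    )
    table = out["table"]
    assert len(table) == 3
    assert (table["mean_n_clusters"] == 2.0).all()
    assert (table["sd_n_clusters"] < 0.1).all()
    assert out["stable_regions"][3] == (0.3, 0.5)


def test_stability_scan_single_cell():
    d = two_groups()
    out = stability_scan(d, [0.5], [3], n_runs=3, seed=0, n_iter=50)
    assert len(out["table"]) == 1
    with pytest.raises(ValueError, match="non-empty"):
        stability_scan(d, [], [3])


def test_consensus_of_identical_runs():
    d = two_groups()
    runs = [
        build_forest(d, DMSTParams(lambda_=0.5, d_max=3, seed=s,
                                   n_iter=80, anneal_steps=300))
        for s in range(4)
    ]
    # the optimum is unique here, so all runs coincide
    assert all((r.parents == runs[0].parents).all() for r in runs[1:])
    cf = consensus_forest(runs, link_threshold=0.5)
    assert (cf.link_weights == 1.0).all()
    assert cf.trees() == runs[0].trees()


def test_consensus_split_link_weight():
    base = np.array([ROOT, 0, 1])
    alt = np.array([ROOT, 0, 0])  # leaf 2 disagrees on its parent
    runs = [
        Forest(base, [0, 1, 2], d_max=4),
        Forest(alt, [0, 1, 2], d_max=4),
    ]
    cf = consensus_forest(runs, link_threshold=0.0)
    frame = cf.to_frame().set_index("child")
    assert frame.loc[0, "weight"] == 1.0  # root link in both runs
    assert frame.loc[1, "weight"] == 1.0
    assert frame.loc[2, "weight"] == 0.5


def test_consensus_threshold_zero_is_max_spanning_structure():
    rng = np.random.default_rng(6)
    d = random_dissimilarity(6, rng)
    runs = [
        build_forest(d, DMSTParams(lambda_=0.4, d_max=3, seed=s,
                                   n_iter=60, anneal_steps=300))
        for s in range(6)
    ]
    cf = consensus_forest(runs, link_threshold=0.0)
    # oracle: maximum spanning tree of the augmented link-frequency graph
    g = nx.Graph()
    counts: dict = {}
    for f in runs:
        for i, p in enumerate(f.parents):
            key = ("R", i) if p == ROOT else tuple(sorted((i, p)))
            counts[key] = counts.get(key, 0) + 1
    for (a, b), c in counts.items():
        g.add_edge(a, b, weight=c / len(runs))
    mst = nx.maximum_spanning_tree(g)
    oracle_weight = sum(w for _, _, w in mst.edges(data="weight"))
    got_weight = cf.link_weights.sum()
    assert got_weight == pytest.approx(oracle_weight)


def test_consensus_high_threshold_promotes_singletons():
    base = np.array([ROOT, 0, 1])
    runs = [Forest(base, [0, 1, 2], d_max=4)]
    cf = consensus_forest(runs, link_threshold=1.5)
    assert cf.n_clusters == 3


def test_forest_serialization_roundtrip():
    f = Forest(np.array([ROOT, 0, 0, ROOT]), list("abcd"), d_max=3,
               link_weights=np.array([1.0, 0.5, 0.75, 1.0]))
    frame = f.to_frame()
    assert set(frame.columns) == {"child", "parent", "weight"}
    assert frame.loc[frame["child"] == "a", "parent"].iloc[0] == "ROOT"
    assert frame.loc[frame["child"] == "b", "parent"].iloc[0] == "a"
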