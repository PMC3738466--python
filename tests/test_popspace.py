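import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from poprep.neurogen import ResponseDataset
from poprep.popspace import (
    PopulationMatrix,
    SimilarityMatrix,
    animate_segregation_test,
    face_selectivity_index,
    hierarchical_branch_test,
    normalize_responses,
    pca_property_correlation,
    select_k,
    similarity_matrix,
    to_newick,
)


def dataset_from_rates(rates, reps=1):
    """Deterministic dataset whose mean rates equal ``rates`` (Hz)."""
    rates = np.asarray(rates, dtype=float)
    counts = np.repeat(
        (rates[:, :, None] * 0.1).astype(int), reps, axis=2
    )
    n = rates.shape[0]
    return ResponseDataset(
        counts=counts,
        background_counts=np.zeros((n, 5), dtype=int),
        object_ids=[f"o{j}" for j in range(rates.shape[1])],
        neuron_ids=[f"n{i}" for i in range(n)],
    )


def test_normalize_forced_example():
    ds = dataset_from_rates([[10, 20, 30]])
    pm = normalize_responses(ds)
    assert np.allclose(pm.values[:, 0], [-1.0, 0.0, 1.0])


def test_normalize_column_means_and_sds(small_dataset):
    pm = normalize_responses(small_dataset)
    assert np.allclose(pm.values.mean(axis=0), 0.0, atol=1e-9)
    assert np.allclose(pm.values.std(axis=0, ddof=1), 1.0, atol=1e-9)


def test_constant_neuron_dropped():
    ds = dataset_from_rates([[10, 20, 30], [10, 10, 10]])
    with pytest.warns(UserWarning, match="zero-variance"):
        pm = normalize_responses(ds)
    assert pm.n_neurons == 1 and pm.neuron_ids == ["n0"]


def test_similarity_identical_and_negated_vectors():
    values = np.array([
        [1.0, -0.5, 2.0, 0.3],
        [1.0, -0.5, 2.0, 0.3],
        [-1.0, 0.5, -2.0, -0.3],
    ])
    sm = similarity_matrix(
        PopulationMatrix(values, ["a", "b", "c"], list("wxyz"))
    )
    assert sm.r[0, 1] == pytest.approx(1.0)
    assert sm.d[0, 1] == pytest.approx(0.0)
    assert sm.r[0, 2] == pytest.approx(-1.0)
    assert sm.d[0, 2] == pytest.approx(2.0)
    assert np.allclose(np.diag(sm.r), 1.0)
    assert (sm.d >= 0).all() and (sm.d <= 2).all()


def test_similarity_null_correlations_moderate():
    # independent standard-normal 94-neuron vectors: |r| < 0.5 in >= 99%
    rng = np.random.default_rng(0)
    x = rng.normal(size=(1000, 94))
    y = rng.normal(size=(1000, 94))
    xz = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
    yz = (y - y.mean(1, keepdims=True)) / y.std(1, keepdims=True)
    r = (xz * yz).mean(axis=1)
    assert (np.abs(r) < 0.5).mean() >= 0.99


def test_similarity_invariant_to_neuron_order(small_dataset):
    pm = normalize_responses(small_dataset)
    rng = np.random.default_rng(1)
    perm = rng.permutation(pm.n_neurons)
    pm2 = PopulationMatrix(
        pm.values[:, perm], pm.object_ids,
        [pm.neuron_ids[i] for i in perm],
    )
    assert np.allclose(similarity_matrix(pm).r, similarity_matrix(pm2).r)


def test_pca_recovers_planted_area_signal():
    rng = np.random.default_rng(3)
    n_obj, n_neu = 40, 30
    area = rng.random(n_obj)
    loading = rng.normal(size=n_neu)
    values = np.outer(area - area.mean(), loading)
    values += 0.05 * rng.normal(size=values.shape)
    pm = PopulationMatrix(
        values, [f"o{i}" for i in range(n_obj)],
        [f"n{i}" for i in range(n_neu)],
    )
    props = pd.DataFrame({"area": area}, index=pm.object_ids)
    out = pca_property_correlation(pm, props, n_components=2)
    pc1 = out[(out["component"] == 1) & (out["property"] == "area")]
    assert pc1["abs_r"].iloc[0] > 0.8
    assert pc1["p"].iloc[0] < 1e-6


def test_pca_unrelated_property_rarely_significant():
    rng = np.random.default_rng(4)
    hits = 0
    for _ in range(50):
        values = rng.normal(size=(25, 10))
        pm = PopulationMatrix(
            values, [f"o{i}" for i in range(25)],
            [f"n{i}" for i in range(10)],
        )
        props = pd.DataFrame(
            {"x": rng.random(25)}, index=pm.object_ids
        )
        out = pca_property_correlation(pm, props, n_components=1)
        hits += out["p"].iloc[0] < 0.05
    assert hits <= 10  # ~5% expected


def test_pca_explained_variance_sums_to_total(small_dataset):
    from sklearn.decomposition import PCA

    pm = normalize_responses(small_dataset)
    pca = PCA(svd_solver="full").fit(pm.values)
    total = pm.values.var(axis=0, ddof=1).sum()
    assert np.isclose(pca.explained_variance_.sum(), total, atol=1e-6)


def test_pca_too_many_components_rejected():
    pm = PopulationMatrix(np.zeros((3, 5)), list("abc"), list("vwxyz"))
    with pytest.raises(ValueError, match="components"):
        pca_property_correlation(
            pm, pd.DataFrame({"a": [1, 2, 3]}, index=list("abc")),
            n_components=4,
        )


def planted_similarity(n_per_block=12, gap=0.9, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_block
    labels = np.array([0] * n_per_block + [1] * n_per_block)
    r = np.where(
        labels[:, None] == labels[None, :], 0.8, 0.8 - gap
    ) + noise * rng.normal(size=(n, n))
    r = np.clip((r + r.T) / 2, -1, 1)
    np.fill_diagonal(r, 1.0)
    ids = [f"o{i}" for i in range(n)]
    return SimilarityMatrix(r, ids), labels


def test_branch_test_recovers_planted_blocks():
    sm, labels = planted_similarity()
    out = hierarchical_branch_test(
        sm, pd.Series(labels.astype(bool), index=sm.object_ids)
    )
    assert out["p"] < 0.001
    assert out["table"].to_numpy().sum() == len(labels)


def test_branch_test_null_p_uniform():
    rng = np.random.default_rng(5)
    pvals = []
    for s in range(300):
        sm, _ = planted_similarity(seed=s)
        labels = pd.Series(
            rng.permutation([True] * 12 + [False] * 12),
            index=sm.object_ids,
        )
        pvals.append(hierarchical_branch_test(sm, labels)["p"])
    # the 2x2 count statistic is discrete, so exact uniformity is not
    # attainable; require controlled (possibly conservative) type-I error
    pvals = np.array(pvals)
    upper05 = st.binom.ppf(0.995, len(pvals), 0.05) / len(pvals)
    upper01 = st.binom.ppf(0.995, len(pvals), 0.01) / len(pvals)
    assert (pvals < 0.05).mean() <= upper05
    assert (pvals < 0.01).mean() <= upper01
    assert np.median(pvals) > 0.2


def test_branch_test_single_label_flagged():
    sm, _ = planted_similarity()
    out = hierarchical_branch_test(
        sm, pd.Series(True, index=sm.object_ids)
    )
    assert np.isnan(out["p"])


def test_newick_roundtrip(small_dataset):
    import io

    from Bio import Phylo

    pm = normalize_responses(small_dataset)
    sm = similarity_matrix(pm)
    out = hierarchical_branch_test(
        sm, pd.Series(True, index=sm.object_ids)
    )
    nwk = to_newick(out["linkage"], sm.object_ids)
    tree = Phylo.read(io.StringIO(nwk), "newick")
    assert tree.count_terminals() == pm.n_objects


def blobs(k, seed, n_per=20, dim=4, spread=8.0):
    rng = np.random.default_rng(seed)
    centers = rng.normal(scale=spread, size=(k, dim))
    X = np.concatenate([
        c + rng.normal(size=(n_per, dim)) for c in centers
    ])
    return X


def test_select_k_five_blobs():
    hits = 0
    for s in range(10):
        out = select_k(blobs(5, s), k_range=range(1, 9), seed=s)
        hits += out["k_bic"] == 5
    assert hits >= 9


def test_select_k_single_gaussian():
    hits = 0
    for s in range(10):
        out = select_k(blobs(1, s, n_per=60), k_range=range(1, 6), seed=s)
        hits += out["k_bic"] == 1
    assert hits >= 9


def test_select_k_forced_range():
    out = select_k(blobs(2, 0), k_range=[3], seed=0)
    assert out["k_bic"] == out["k_aic"] == 3


def test_select_k_invalid_range():
    with pytest.raises(ValueError, match="k_range"):
        select_k(blobs(2, 0, n_per=5), k_range=[40], seed=0)


def test_animate_segregation_zero_statistic():
    # equal fractions by construction: alternating labels, two point-blobs
    values = np.array(
        [[i % 2 * 10.0, (i // 2) % 2] for i in range(16)]
    )
    pm = PopulationMatrix(
        values, [f"o{i}" for i in range(16)], ["a", "b"]
    )
    labels = pd.Series(
        [i // 2 % 2 == 0 for i in range(16)], index=pm.object_ids
    )
    out = animate_segregation_test(pm, labels, n_runs=5, n_perm=50, seed=0)
    assert out["statistic"] == pytest.approx(0.0)
    assert out["p"] == pytest.approx(1.0)


def test_animate_segregation_detects_planted_gain():
    rng = np.random.default_rng(7)
    labels = np.array([True] * 12 + [False] * 12)
    values = np.where(labels[:, None], 3.0, -3.0) + rng.normal(
        size=(24, 6)
    )
    pm = PopulationMatrix(
        values, [f"o{i}" for i in range(24)],
        [f"n{i}" for i in range(6)],
    )
    out = animate_segregation_test(
        pm, pd.Series(labels, index=pm.object_ids),
        n_runs=20, n_perm=500, seed=1,
    )
    assert out["p"] < 0.05


def test_animate_segregation_single_class_rejected():
    pm = PopulationMatrix(np.zeros((4, 2)), list("abcd"), ["x", "y"])
    with pytest.raises(ValueError, match="non-empty"):
        animate_segregation_test(
            pm, pd.Series(True, index=pm.object_ids), n_runs=2, n_perm=10
        )


def test_fsi_forced_values():
    ds = dataset_from_rates([[20, 20, 10, 10], [10, 10, 10, 10],
                             [10, 10, 0, 0]])
    fsi = face_selectivity_index(ds, ["o0", "o1"])
    assert fsi["n0"] == pytest.approx(1 / 3)
    assert fsi["n1"] == pytest.approx(0.0)
    assert fsi["n2"] == pytest.approx(1.0)


def test_fsi_zero_denominator_flagged():
    ds = dataset_from_rates([[0, 0, 0, 0]])
    fsi = face_selectivity_index(ds, ["o0"])
    assert np.isnan(fsi["n0"])
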