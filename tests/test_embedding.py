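import numpy as np
import pytest
from scipy.sparse.csgraph import shortest_path
from sklearn.metrics import silhouette_score
from sklearn.neighbors import kneighbors_graph

from neuromotif.embedding import (cluster_types, correlate_gradient,
                                  embed_tsne, fit_soma_to_gradient,
                                  gradient_index, motifs_along_gradient,
                                  select_root)


def two_cluster_distances(n=30, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.vstack([rng.normal(0, 1, (n // 2, 5)),
                     rng.normal(20, 1, (n - n // 2, 5))])
    D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    labels = np.array([0] * (n // 2) + [1] * (n - n // 2))
    return D, labels


def test_tsne_deterministic_and_validated():
    D, _ = two_cluster_distances()
    a = embed_tsne(D, perplexity=5, seed=0)
    b = embed_tsne(D, perplexity=5, seed=0)
    np.testing.assert_array_equal(a.coords, b.coords)
    with pytest.raises(ValueError, match="perplexity"):
        embed_tsne(D, perplexity=40, seed=0)
    with pytest.raises(ValueError, match="symmetric"):
        embed_tsne(D + np.triu(np.ones_like(D)), perplexity=5)


def test_tsne_separates_clusters():
    D, labels = two_cluster_distances()
    emb = embed_tsne(D, perplexity=5, seed=0)
    assert silhouette_score(emb.coords, labels) > 0


def test_tsne_equidistant_quartet():
    D = (np.ones((4, 4)) - np.eye(4)) * 10.0
    emb = embed_tsne(D, perplexity=2, seed=0)
    d = np.linalg.norm(emb.coords[:, None] - emb.coords[None, :], axis=-1)
    vals = d[np.triu_indices(4, 1)]
    assert np.ptp(vals) / vals.mean() < 0.5


def test_gradient_collinear_points():
    coords = np.column_stack([np.arange(10.0), np.zeros(10)])
    gi, k = gradient_index(coords, root=0, k=2)
    np.testing.assert_allclose(gi, np.arange(10) / 9.0, atol=1e-12)
    assert gi[0] == 0.0 and gi.max() == 1.0


def test_gradient_matches_shortest_path_oracle():
    rng = np.random.default_rng(1)
    coords = rng.normal(0, 5, size=(40, 2))
    gi, k = gradient_index(coords, root=3, k=6)
    G = kneighbors_graph(coords, n_neighbors=k, mode="distance")
    dist = shortest_path(G, directed=False)[3]
    np.testing.assert_allclose(gi, dist / dist.max(), atol=1e-12)
    assert np.all((gi >= 0) & (gi <= 1))
    assert (gi == 0).sum() == 1


def test_gradient_anchor_normalization():
    coords = np.column_stack([np.arange(10.0), np.zeros(10)])
    gi, _ = gradient_index(coords, root=0, k=2, anchor=5)
    # normalized by the anchor's distance; points beyond it clip at 1
    np.testing.assert_allclose(gi[:6], np.arange(6) / 5.0)
    np.testing.assert_allclose(gi[6:], 1.0)


def test_gradient_invariant_to_rigid_motion():
    rng = np.random.default_rng(2)
    coords = rng.normal(0, 5, size=(30, 2))
    gi, _ = gradient_index(coords, root=0)
    th = 0.7
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    gi2, _ = gradient_index(coords @ R.T + [13.0, -4.0], root=0)
    np.testing.assert_allclose(gi, gi2, atol=1e-9)


def test_select_root_rules():
    ids = ["n1", "n2", "n3", "n4"]
    doms = ["SSp-m", "SSp-bfd", "SSp-bfd", None]
    si = np.array([100.0, 400.0, 200.0, 50.0])
    coords = np.zeros((4, 2))
    # most dorsal (smallest SI) barrel-dominant neuron wins
    assert select_root(coords, ids, doms, si) == "n3"
    # depth tie broken by lexicographically smaller id
    si_tie = np.array([100.0, 200.0, 200.0, 50.0])
    assert select_root(coords, ids, doms, si_tie) == "n2"
    # no barrel-dominant neuron: extremal embedding point, with warning
    coords2 = np.array([[0, 0], [1, 1], [5, 5], [2, 2]], float)
    with pytest.warns(UserWarning, match="falling back"):
        got = select_root(coords2, ids, ["SSp-m", None, None, None], si)
    assert got == "n3"


def test_cluster_types_recover_blobs_and_ordering():
    rng = np.random.default_rng(3)
    blobs = [rng.normal([0, 0], 0.3, (10, 2)),
             rng.normal([10, 0], 0.3, (10, 2)),
             rng.normal([20, 0], 0.3, (10, 2))]
    coords = np.vstack(blobs)
    gradient = np.concatenate([np.full(10, 0.1), np.full(10, 0.5),
                               np.full(10, 0.9)])
    labels = cluster_types(coords, gradient, k=3)
    assert set(labels) == {1, 2, 3}
    for blob_idx in range(3):
        segment = labels[blob_idx * 10:(blob_idx + 1) * 10]
        assert len(set(segment)) == 1
    means = [gradient[labels == t].mean() for t in (1, 2, 3)]
    assert means[0] <= means[1] <= means[2]
    assert np.all(cluster_types(coords, gradient, k=1) == 1)
    with pytest.raises(ValueError):
        cluster_types(coords[:2], gradient[:2], k=3)


def test_correlate_gradient_basics():
    gi = np.linspace(0, 1, 20)
    r, p = correlate_gradient(gi, np.exp(gi))
    assert r == pytest.approx(1.0)
    r2, _ = correlate_gradient(gi, -gi)
    assert r2 == pytest.approx(-1.0)
    with pytest.warns(UserWarning, match="constant"):
        r3, p3 = correlate_gradient(gi, np.ones(20))
    assert np.isnan(r3)


def test_fit_soma_to_gradient():
    rng = np.random.default_rng(4)
    somata = rng.uniform(0, 1000, size=(30, 2))
    coef_true = np.array([2e-4, -1e-4, 0.3])
    gi = somata @ coef_true[:2] + coef_true[2]
    coef, mse = fit_soma_to_gradient(somata, gi)
    np.testing.assert_allclose(coef, coef_true, rtol=1e-6)
    assert mse < 1e-12
    # closed-form normal-equation oracle
    X = np.hstack([somata, np.ones((30, 1))])
    beta = np.linalg.solve(X.T @ X, X.T @ gi)
    np.testing.assert_allclose(coef, beta, rtol=1e-9)
    # permuted indices lose the structure: mse near the index variance
    gi_perm = rng.permutation(gi)
    _, mse_perm = fit_soma_to_gradient(somata, gi_perm)
    assert mse_perm > 0.5 * gi.var()


def test_motifs_along_gradient_hand_means():
    motifs = [("A",), ("A",), ("B", "C"), ("A",), ("B", "C")]
    gi = np.array([0.1, 0.2, 0.8, 0.3, 0.6])
    table = motifs_along_gradient(motifs, gi)
    assert list(table.index) == ["A", "B - C"]
    assert table.loc["A", "mean_gradient"] == pytest.approx(0.2)
    assert table.loc["B - C", "mean_gradient"] == pytest.approx(0.7)
    single = motifs_along_gradient([("A",)], [0.5])
    assert len(single) == 1
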