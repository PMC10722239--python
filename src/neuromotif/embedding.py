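"""2-D embedding of the dissimilarity matrix and the morphological gradient.

The all-pairs CPD dissimilarity matrix is embedded in two dimensions
with t-SNE in precomputed-distance mode.  Each neuron then receives a
*gradient index*: the geodesic (shortest-path) distance from a root
point along a k-nearest-neighbor graph over the embedding, normalized
to [0, 1] by the largest index.  The root is the most dorsal
barrel-cortex-dominant neuron, so the index increases toward ventral
morphologies.  Hierarchical (Ward) clustering of the embedding cuts the
gradient into three morphotypes, renumbered so the mean gradient index
increases with the type label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.stats import spearmanr
from sklearn.cluster import AgglomerativeClustering
from sklearn.manifold import TSNE
from sklearn.neighbors import kneighbors_graph

from .cpd import DissimilarityMatrix


@dataclass
class EmbeddingResult:
    neuron_ids: list[str]
    coords: np.ndarray              # (n, 2)
    perplexity: float
    seed: int
    root_id: str | None = None
    gradient_index: np.ndarray | None = None    # (n,), in [0, 1]
    morph_type: np.ndarray | None = None        # (n,), labels 1..k
    knn_k: int | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coords, index=self.neuron_ids,
                          columns=["tsne_1", "tsne_2"])
        if self.gradient_index is not None:
            df["gradient_index"] = self.gradient_index
        if self.morph_type is not None:
            df["morph_type"] = self.morph_type
        return df


def embed_tsne(D: DissimilarityMatrix | np.ndarray, perplexity: float = 30.0,
               seed: int = 0, neuron_ids: list[str] | None = None) -> EmbeddingResult:
    """t-SNE embedding of a symmetric zero-diagonal dissimilarity matrix.

    Deterministic for a fixed seed (random initialization, as required
    by precomputed-distance mode).  Perplexity is clipped below n.
    """
    if isinstance(D, DissimilarityMatrix):
        neuron_ids = D.neuron_ids
        values = D.values
    else:
        values = np.asarray(D, float)
        neuron_ids = neuron_ids or [str(i) for i in range(len(values))]
    n = len(values)
    if perplexity >= n:
        raise ValueError(f"perplexity ({perplexity}) must be < n ({n})")
    if not np.allclose(values, values.T, atol=1e-6):
        raise ValueError("dissimilarity matrix must be symmetric")
    tsne = TSNE(n_components=2, metric="precomputed", init="random",
                perplexity=perplexity, random_state=seed)
    coords = tsne.fit_transform(values)
    return EmbeddingResult(neuron_ids=list(neuron_ids), coords=coords,
                           perplexity=perplexity, seed=seed)


def gradient_index(coords: np.ndarray, root: int, k: int = 10,
                   anchor: int | None = None) -> tuple[np.ndarray, int]:
    """Normalized geodesic distance from the root over a k-NN graph.

    ``k`` grows until the graph is connected.  Returns ``(indices, k)``
    with ``indices[root] == 0`` and ``max(indices) == 1``.  With
    ``anchor`` set, distances are normalized by the anchor's geodesic
    distance instead of the maximum, and indices are clipped to [0, 1]
    (neurons beyond the anchor saturate at 1).
    """
    coords = np.asarray(coords, float)
    n = len(coords)
    if n < 2:
        raise ValueError("gradient index undefined for n < 2")
    k = min(max(1, k), n - 1)
    while True:
        G = kneighbors_graph(coords, n_neighbors=k, mode="distance")
        n_comp, _ = connected_components(G, directed=False)
        if n_comp == 1 or k >= n - 1:
            break
        k += 1
    dist = shortest_path(G, directed=False, indices=root)
    top = dist.max() if anchor is None else dist[anchor]
    if not np.isfinite(top) or top <= 0:
        raise ValueError("embedding graph is disconnected or degenerate")
    return np.clip(dist / top, 0.0, 1.0), k


def select_root(coords: np.ndarray, neuron_ids: list[str],
                dominant_targets: list[str | None], soma_si_um: np.ndarray,
                root_area: str = "SSp-bfd") -> str:
    """Root neuron for the gradient: the most dorsal (smallest
    superior-inferior coordinate) neuron dominantly targeting
    ``root_area``; ties broken by lexicographically smaller id.  Without
    any such neuron, falls back (with a warning) to the neuron at the
    extreme upper-right of the embedding.
    """
    cand = [(float(si), nid) for nid, dom, si
            in zip(neuron_ids, dominant_targets, soma_si_um)
            if dom == root_area]
    if cand:
        return min(cand)[1]
    warnings.warn(f"no {root_area}-dominant neuron; falling back to the "
                  "extremal embedding point", stacklevel=2)
    extreme = int(np.argmax(np.asarray(coords).sum(axis=1)))
    return neuron_ids[extreme]


def cluster_types(coords: np.ndarray, gradient: np.ndarray, k: int = 3,
                  linkage: str = "ward") -> np.ndarray:
    """Agglomerative clustering of the embedding into k morphotypes,
    renumbered 1..k by increasing mean gradient index."""
    coords = np.asarray(coords, float)
    if len(coords) < k:
        raise ValueError(f"need at least {k} neurons for {k} clusters")
    if k == 1:
        return np.ones(len(coords), dtype=int)
    raw = AgglomerativeClustering(n_clusters=k, linkage=linkage).fit_predict(coords)
    means = {lab: float(np.mean(gradient[raw == lab])) for lab in np.unique(raw)}
    order = sorted(means, key=means.get)
    remap = {lab: i + 1 for i, lab in enumerate(order)}
    return np.asarray([remap[lab] for lab in raw], dtype=int)


def correlate_gradient(indices, values) -> tuple[float, float]:
    """Spearman rank correlation (two-sided p) between gradient indices
    and a morphometric vector; NaN correlation for a constant vector."""
    indices = np.asarray(indices, float)
    values = np.asarray(values, float)
    if len(indices) != len(values) or len(indices) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(values) == 0 or np.ptp(indices) == 0:
        warnings.warn("constant vector: correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    r, p = spearmanr(indices, values)
    return float(r), float(p)


def fit_soma_to_gradient(somata_2d, indices) -> tuple[np.ndarray, float]:
    """OLS fit of the (superior-inferior, left-right) soma coordinates to
    the gradient index; returns (coefficients incl. intercept, MSE of the
    unitless gradient residual)."""
    S = np.asarray(somata_2d, float).reshape(-1, 2)
    y = np.asarray(indices, float)
    if len(S) < 3:
        raise ValueError("need n >= 3")
    X = np.hstack([S, np.ones((len(S), 1))])
    if np.linalg.matrix_rank(X) < 3:
        warnings.warn("rank-deficient design: degenerate fit", stacklevel=2)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    mse = float(((X @ coef - y) ** 2).mean())
    return coef, mse


def motifs_along_gradient(motifs: list[tuple], indices) -> pd.DataFrame:
    """Mean gradient index per unique motif, sorted ascending."""
    indices = np.asarray(indices, float)
    if len(motifs) != len(indices):
        raise ValueError("one motif and one index per neuron required")
    df = pd.DataFrame({"motif": motifs, "gradient_index": indices})
    out = (df.groupby("motif", sort=False)["gradient_index"]
             .agg(["mean", "count"])
             .rename(columns={"mean": "mean_gradient", "count": "n_neurons"})
             .sort_values("mean_gradient"))
    out.index = [" - ".join(m) if m else "(subthreshold)" for m in out.index]
    return out
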