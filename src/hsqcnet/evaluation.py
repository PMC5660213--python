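"""Retrieval, cluster-map and benchmark evaluation of spectral embeddings.

Implements every evaluation procedure the pipeline relies on:

* nearest-neighbour retrieval (top 5/10/20 reports in the K-dim space),
* the 2D cluster map via PCA of the K-dim embeddings,
* expanding-hypersphere precision-recall curves averaged over queries,
* accuracy versus hypersphere radius,
* closest-retrieval curves with the most-frequently-occurring (MO) baseline,
* the linear PCA-on-pixels baseline embedding,
* the noise-robustness experiment (distance to the clean embedding as pixel
  noise grows along an arithmetic schedule).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .network import NetworkWeights, embed_images
from .spectra import DatasetManifest, SpectrumImage, median_filter_cross
from .synthetic import NoiseProtocol, inject_noise, noise_schedule

__all__ = [
    "EmbeddingSet",
    "PRCurve",
    "NoiseRunResult",
    "embed_dataset",
    "nearest_neighbors",
    "pca_project",
    "pca_baseline",
    "precision_recall_curve",
    "accuracy_vs_radius",
    "closest_retrieval_curve",
    "mo_baseline_curve",
    "noise_experiment",
    "export_cluster_map",
    "read_cluster_map",
]


@dataclass
class EmbeddingSet:
    """K-dimensional coordinates of a set of labelled spectra."""

    ids: np.ndarray
    labels: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.labels = np.asarray(self.labels)
        self.coords = np.asarray(self.coords, dtype=float)
        if not (len(self.ids) == len(self.labels) == len(self.coords)):
            raise ValueError("ids, labels and coordinates must align")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def K(self) -> int:
        return self.coords.shape[1]


@dataclass
class PRCurve:
    """Mean precision-recall curve with its trapezoidal area."""

    recall: np.ndarray
    precision: np.ndarray
    auc: float
    n_queries: int = 0


@dataclass
class NoiseRunResult:
    """Distance of one noisy rendering to its clean original."""

    compound_id: str
    level_index: int
    fraction: float
    rep_index: int
    distance_to_original: float
    space: str
    rank1_family: str | None = None


def embed_dataset(
    weights: NetworkWeights,
    images: dict,
    manifest: DatasetManifest,
    batch_size: int = 64,
) -> EmbeddingSet:
    """Evaluation-mode embeddings of a whole dataset, in manifest order."""
    ids = manifest.spectrum_ids
    coords = embed_images(weights, [images[i] for i in ids], batch_size=batch_size)
    return EmbeddingSet(np.array(ids), np.array(manifest.families), coords)


def _ranked_neighbors(corpus: EmbeddingSet, queries: EmbeddingSet):
    """Per-query corpus orderings by (distance, spectrum_id), self excluded."""
    D = cdist(queries.coords, corpus.coords)
    # stable deterministic tie-break: secondary sort key is the corpus id
    id_order = np.argsort(corpus.ids, kind="stable")
    rank_of_id = np.empty(len(corpus), dtype=int)
    rank_of_id[id_order] = np.arange(len(corpus))
    orders = []
    for q in range(len(queries)):
        keys = np.lexsort((rank_of_id, D[q]))
        keys = keys[corpus.ids[keys] != queries.ids[q]]  # never self
        orders.append(keys)
    return D, orders


def nearest_neighbors(
    corpus: EmbeddingSet, queries: EmbeddingSet | None = None, k: int = 10
) -> pd.DataFrame:
    """Top-k Euclidean neighbours per query (self excluded, id-stable ties).

    Returns a tidy report: query_id, rank, neighbor_id, neighbor family and
    distance, with distances non-decreasing within each query.
    """
    if queries is None:
        queries = corpus
    limit = len(corpus) - int(bool(set(queries.ids) & set(corpus.ids)))
    if k > limit:
        raise ValueError(f"k={k} too large for a corpus of {len(corpus)} rows")
    D, orders = _ranked_neighbors(corpus, queries)
    rows = []
    for q, order in enumerate(orders):
        for rank, j in enumerate(order[:k], start=1):
            rows.append(
                {
                    "query_id": queries.ids[q],
                    "rank": rank,
                    "neighbor_id": corpus.ids[j],
                    "family": corpus.labels[j],
                    "distance": D[q, j],
                }
            )
    return pd.DataFrame(rows)


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Deterministic PCA sign convention: largest-magnitude loading positive."""
    flipped = components.copy()
    for i in range(flipped.shape[0]):
        j = np.abs(flipped[i]).argmax()
        if flipped[i, j] < 0:
            flipped[i] = -flipped[i]
    return flipped


def pca_project(space: EmbeddingSet, out_dim: int = 2) -> EmbeddingSet:
    """Project embeddings onto their top principal axes (for the 2D map)."""
    if out_dim > space.K:
        raise ValueError("out_dim cannot exceed the embedding dimension")
    if len(space) <= out_dim:
        raise ValueError("need more points than output dimensions")
    pca = PCA(n_components=out_dim, svd_solver="full")
    pca.fit(space.coords)
    comps = _fix_signs(pca.components_)
    proj = (space.coords - pca.mean_) @ comps.T
    return EmbeddingSet(space.ids, space.labels, proj)


def pca_baseline(images: dict, manifest: DatasetManifest, k: int = 10) -> EmbeddingSet:
    """Linear comparator: PCA of flattened pixel vectors into k dimensions.

    This is the no-network baseline the learned embedding is judged against;
    deterministic given the manifest order.
    """
    ids = manifest.spectrum_ids
    if len(ids) <= k:
        raise ValueError(f"need more than k={k} images for the PCA baseline")
    X = np.stack(
        [np.asarray(images[i].pixels if hasattr(images[i], "pixels") else images[i])
         for i in ids]
    ).reshape(len(ids), -1).astype(np.float64)
    pca = PCA(n_components=k, svd_solver="randomized", random_state=0)
    pca.fit(X)
    comps = _fix_signs(pca.components_)
    proj = (X - pca.mean_) @ comps.T
    return EmbeddingSet(np.array(ids), np.array(manifest.families), proj)


_RECALL_GRID = np.linspace(0.0, 1.0, 101)


def precision_recall_curve(
    corpus: EmbeddingSet, queries: EmbeddingSet
) -> PRCurve:
    """Expanding-hypersphere precision-recall, averaged over queries.

    For each query the corpus is ranked by distance; at every rank precision
    is TP/(TP+FP) and recall TP/(number of same-family corpus members).  Each
    per-query curve is summarized as interpolated precision on a common
    101-point recall grid (precision at recall level g = best precision
    attainable at any rank reaching recall >= g), curves are averaged across
    queries, and the area is the trapezoidal integral of the mean curve.
    Queries whose family is absent from the corpus are skipped.
    """
    D, orders = _ranked_neighbors(corpus, queries)
    curves = []
    for q, order in enumerate(orders):
        rel = (corpus.labels[order] == queries.labels[q]).astype(float)
        R = rel.sum()
        if R == 0:
            continue
        tp = np.cumsum(rel)
        ranks = np.arange(1, len(order) + 1)
        precision = tp / ranks
        recall = tp / R
        # interpolated precision on the grid: max precision at recall >= g
        best_from = np.maximum.accumulate(precision[::-1])[::-1]
        idx = np.searchsorted(recall, _RECALL_GRID, side="left")
        interp = np.where(idx < len(order), best_from[np.minimum(idx, len(order) - 1)], 0.0)
        curves.append(interp)
    if not curves:
        raise ValueError("no query has a same-family member in the corpus")
    mean_curve = np.mean(curves, axis=0)
    auc = float(np.trapezoid(mean_curve, _RECALL_GRID))
    return PRCurve(_RECALL_GRID.copy(), mean_curve, auc, n_queries=len(curves))


def accuracy_vs_radius(space: EmbeddingSet, radii) -> np.ndarray:
    """Fraction of same-family co-members captured within each radius.

    For every node, the fraction of its true family co-members (self
    excluded) lying within distance r, averaged over nodes with at least one
    co-member; non-decreasing in r.
    """
    if len(space) < 2:
        raise ValueError("need at least 2 points")
    radii = np.asarray(radii, dtype=float)
    D = cdist(space.coords, space.coords)
    same = space.labels[:, None] == space.labels[None, :]
    np.fill_diagonal(same, False)
    n_co = same.sum(axis=1)
    keep = n_co > 0
    out = np.zeros(len(radii))
    for i, r in enumerate(radii):
        captured = ((D <= r) & same).sum(axis=1)
        out[i] = float(np.mean(captured[keep] / n_co[keep]))
    return out


def closest_retrieval_curve(
    corpus: EmbeddingSet, queries: EmbeddingSet
) -> np.ndarray:
    """Fraction of queries whose family is among the first k distinct families.

    Families are ordered per query by first occurrence along the distance
    ranking; entry k-1 of the returned curve is the fraction of queries whose
    true family appears within the first k family predictions.  The curve is
    non-decreasing and reaches 1 at k = number of corpus families.
    """
    _, orders = _ranked_neighbors(corpus, queries)
    fams = np.unique(corpus.labels)
    n_fam = len(fams)
    hits = np.zeros(n_fam)
    n_q = 0
    for q, order in enumerate(orders):
        if queries.labels[q] not in fams:
            continue
        n_q += 1
        seen: dict = {}
        for j in order:
            lab = corpus.labels[j]
            if lab not in seen:
                seen[lab] = len(seen)
                if lab == queries.labels[q]:
                    hits[len(seen) - 1] += 1
                    break
    if n_q == 0:
        raise ValueError("no query family present in the corpus")
    return np.cumsum(hits) / n_q


def mo_baseline_curve(manifest_or_corpus, query_labels) -> np.ndarray:
    """Most-frequently-occurring baseline closest-retrieval curve.

    Predicts families in descending order of member count (ties broken by
    ascending label), identically for every query; entry k-1 is the fraction
    of queries whose family lies in the first k predictions.
    """
    if isinstance(manifest_or_corpus, DatasetManifest):
        labels = np.array(manifest_or_corpus.families)
    else:
        labels = np.asarray(manifest_or_corpus.labels)
    fams, counts = np.unique(labels, return_counts=True)
    order = np.lexsort((fams, -counts))
    ranked = fams[order]
    query_labels = np.asarray(query_labels)
    pos = {f: i for i, f in enumerate(ranked)}
    hits = np.zeros(len(ranked))
    for lab in query_labels:
        if lab in pos:
            hits[pos[lab]] += 1
    return np.cumsum(hits) / len(query_labels)


def noise_experiment(
    weights: NetworkWeights,
    image: SpectrumImage,
    protocol: NoiseProtocol,
    compound_id: str = "query",
    space_for_distance: str = "kdim",
    reference_space: EmbeddingSet | None = None,
    corpus: EmbeddingSet | None = None,
    preprocess: bool = True,
) -> pd.DataFrame:
    """Noise-robustness protocol: embed noisy renderings, track distances.

    For every (level, rep) entry of the schedule, pixel noise is injected at
    that level's fraction, the noisy raster is preprocessed like any other
    input (cross median filter, unless ``preprocess`` is False) and embedded,
    and its distance to the clean image's embedding is recorded — in the
    K-dim space (default) or in the 2D PCA map fitted on ``reference_space``.
    When a ``corpus`` is supplied, the family of the rank-1 corpus neighbour
    of each noisy embedding is recorded as well.
    """
    if space_for_distance not in ("kdim", "pca2d"):
        raise ValueError("space_for_distance must be 'kdim' or 'pca2d'")
    pca = None
    if space_for_distance == "pca2d":
        if reference_space is None:
            raise ValueError("pca2d distances need a reference_space")
        pca = PCA(n_components=2, svd_solver="full").fit(reference_space.coords)
    entries = noise_schedule(protocol)
    clean = median_filter_cross(image) if preprocess else image
    noisy_images = []
    fractions = []
    for level, fraction, rep, seed in entries:
        noisy, realized = inject_noise(image, fraction, seed)
        if preprocess:
            noisy = median_filter_cross(noisy)
        noisy_images.append(noisy.pixels)
        fractions.append(realized)
    emb = embed_images(weights, [clean.pixels] + noisy_images)
    e0, noisy_emb = emb[0], emb[1:]
    if pca is not None:
        both = pca.transform(np.vstack([e0[None, :], noisy_emb]))
        e0, noisy_emb = both[0], both[1:]
    dists = np.linalg.norm(noisy_emb - e0[None, :], axis=1)
    rank1 = [None] * len(entries)
    if corpus is not None:
        corpus_coords = corpus.coords if pca is None else pca.transform(corpus.coords)
        D = cdist(noisy_emb, corpus_coords)
        rank1 = [corpus.labels[j] for j in D.argmin(axis=1)]
    rows = [
        NoiseRunResult(
            compound_id, level, float(frac), rep, float(d), space_for_distance, r1
        ).__dict__
        for (level, _, rep, _), frac, d, r1 in zip(entries, fractions, dists, rank1)
    ]
    return pd.DataFrame(rows)


def export_cluster_map(
    space: EmbeddingSet, path: str | os.PathLike, plot: bool = False
) -> None:
    """Write the cluster map: id, family, 2D PCA coordinates, K-dim coordinates.

    Optionally renders a static scatter image (same basename, .png) coloured
    by family.  The TSV round-trips bit-exactly via :func:`read_cluster_map`.
    """
    if len(space) == 0:
        raise ValueError("cannot export an empty embedding set")
    flat = pca_project(space, out_dim=2) if len(space) > 2 and space.K >= 2 else None
    df = pd.DataFrame({"spectrum_id": space.ids, "family": space.labels})
    if flat is not None:
        df["x"] = flat.coords[:, 0]
        df["y"] = flat.coords[:, 1]
    for k in range(space.K):
        df[f"c{k}"] = space.coords[:, k]
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    if plot and flat is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 6))
        fams = np.unique(space.labels)
        cmap = plt.get_cmap("tab20")
        for i, fam in enumerate(fams):
            sel = space.labels == fam
            ax.scatter(flat.coords[sel, 0], flat.coords[sel, 1],
                       s=14, color=cmap(i % 20), label=str(fam))
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.set_title("Embedding cluster map (2D PCA)")
        if len(fams) <= 20:
            ax.legend(fontsize=6, markerscale=0.7, ncol=2)
        fig.tight_layout()
        fig.savefig(os.path.splitext(str(path))[0] + ".png", dpi=120)
        plt.close(fig)


def read_cluster_map(path: str | os.PathLike) -> EmbeddingSet:
    """Reload a cluster-map TSV written by :func:`export_cluster_map`."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    k_cols = [c for c in df.columns if c.startswith("c") and c[1:].isdigit()]
    coords = df[sorted(k_cols, key=lambda c: int(c[1:]))].to_numpy(dtype=float)
    return EmbeddingSet(
        df["spectrum_id"].to_numpy(), df["family"].astype(str).to_numpy(), coords
    )
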