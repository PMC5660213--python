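"""Retrieval and evaluation metrics against independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from hsqcnet.evaluation import (
    EmbeddingSet,
    accuracy_vs_radius,
    closest_retrieval_curve,
    export_cluster_map,
    mo_baseline_curve,
    nearest_neighbors,
    pca_project,
    precision_recall_curve,
    read_cluster_map,
    noise_experiment,
)
from hsqcnet.network import ArchitectureSpec, init_weights
from hsqcnet.spectra import AxisCalibration, SpectrumImage
from hsqcnet.synthetic import NoiseProtocol


def _random_instance(rng, n_corpus=20, n_query=8, n_fam=4, dim=3):
    fams = [f"fam{i}" for i in range(n_fam)]
    corpus = EmbeddingSet(
        np.array([f"c{i:02d}" for i in range(n_corpus)]),
        np.array(rng.choice(fams, n_corpus)),
        rng.standard_normal((n_corpus, dim)),
    )
    queries = EmbeddingSet(
        np.array([f"q{i:02d}" for i in range(n_query)]),
        np.array(rng.choice(fams, n_query)),
        rng.standard_normal((n_query, dim)),
    )
    return corpus, queries


def _brute_order(corpus, query_coord, query_id):
    d = np.sqrt(((corpus.coords - query_coord) ** 2).sum(axis=1))
    order = sorted(range(len(corpus)), key=lambda j: (d[j], corpus.ids[j]))
    return [j for j in order if corpus.ids[j] != query_id], d


def _brute_pr_auc(corpus, queries):
    grid = np.linspace(0.0, 1.0, 101)
    curves = []
    for q in range(len(queries)):
        order, d = _brute_order(corpus, queries.coords[q], queries.ids[q])
        rel = [corpus.labels[j] == queries.labels[q] for j in order]
        R = sum(rel)
        if R == 0:
            continue
        tp = 0
        precision, recall = [], []
        for rank, r in enumerate(rel, start=1):
            tp += r
            precision.append(tp / rank)
            recall.append(tp / R)
        interp = [
            max((p for p, rc in zip(precision, recall) if rc >= g), default=0.0)
            for g in grid
        ]
        curves.append(interp)
    mean = np.mean(curves, axis=0)
    return float(np.trapezoid(mean, grid)), mean


class TestEmbeddingSet:
    def test_validation(self):
        with pytest.raises(ValueError):
            EmbeddingSet(np.array(["a"]), np.array(["f", "g"]), np.zeros((1, 2)))
        with pytest.raises(ValueError):
            EmbeddingSet(np.array(["a"]), np.array(["f"]),
                         np.array([[np.nan, 0.0]]))

    def test_shape_accessors(self):
        s = EmbeddingSet(np.array(["a", "b"]), np.array(["f", "f"]),
                         np.zeros((2, 5)))
        assert len(s) == 2 and s.K == 5


class TestNearestNeighbors:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            corpus, queries = _random_instance(rng)
            table = nearest_neighbors(corpus, queries, k=6)
            for q in range(len(queries)):
                order, d = _brute_order(corpus, queries.coords[q], queries.ids[q])
                sub = table[table["query_id"] == queries.ids[q]]
                assert list(sub["neighbor_id"]) == [corpus.ids[j] for j in order[:6]]
                assert np.allclose(sub["distance"], [d[j] for j in order[:6]])
                assert (np.diff(sub["distance"]) >= 0).all()

    def test_exact_copy_is_rank_one_at_distance_zero(self):
        rng = np.random.default_rng(1)
        corpus, _ = _random_instance(rng)
        queries = EmbeddingSet(
            np.array(["qq"]), np.array([corpus.labels[3]]), corpus.coords[3:4].copy()
        )
        top = nearest_neighbors(corpus, queries, k=1).iloc[0]
        assert top["neighbor_id"] == corpus.ids[3]
        assert top["distance"] == 0.0

    def test_ties_broken_by_ascending_id(self):
        coords = np.zeros((3, 2))
        corpus = EmbeddingSet(np.array(["b", "a", "c"]),
                              np.array(["f", "f", "f"]), coords)
        queries = EmbeddingSet(np.array(["q"]), np.array(["f"]), np.zeros((1, 2)))
        table = nearest_neighbors(corpus, queries, k=3)
        assert list(table["neighbor_id"]) == ["a", "b", "c"]

    def test_self_excluded_when_query_in_corpus(self):
        rng = np.random.default_rng(2)
        corpus, _ = _random_instance(rng, n_corpus=10)
        table = nearest_neighbors(corpus, corpus, k=3)
        for q in corpus.ids:
            assert q not in set(table[table["query_id"] == q]["neighbor_id"])

    def test_oversized_k_rejected(self):
        rng = np.random.default_rng(3)
        corpus, queries = _random_instance(rng, n_corpus=5)
        with pytest.raises(ValueError):
            nearest_neighbors(corpus, queries, k=6)


class TestPrecisionRecall:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            corpus, queries = _random_instance(rng, n_corpus=18, n_query=7)
            pr = precision_recall_curve(corpus, queries)
            auc_ref, curve_ref = _brute_pr_auc(corpus, queries)
            assert pr.auc == pytest.approx(auc_ref, abs=1e-12)
            assert np.allclose(pr.precision, curve_ref)

    def test_perfectly_separated_families_score_one(self):
        corpus = EmbeddingSet(
            np.array(["a", "b", "c", "d"]),
            np.array(["f1", "f1", "f2", "f2"]),
            np.array([[0.0, 0], [0.1, 0], [10, 0], [10.1, 0]]),
        )
        queries = EmbeddingSet(
            np.array(["qa", "qc"]), np.array(["f1", "f2"]),
            np.array([[0.05, 0], [10.05, 0]]),
        )
        assert precision_recall_curve(corpus, queries).auc == pytest.approx(1.0)

    def test_queries_without_family_in_corpus_are_skipped(self):
        corpus = EmbeddingSet(np.array(["a", "b"]), np.array(["f1", "f1"]),
                              np.zeros((2, 2)))
        queries = EmbeddingSet(
            np.array(["q1", "q2"]), np.array(["f1", "zz"]), np.ones((2, 2))
        )
        assert precision_recall_curve(corpus, queries).n_queries == 1
        orphan = EmbeddingSet(np.array(["q2"]), np.array(["zz"]), np.ones((1, 2)))
        with pytest.raises(ValueError):
            precision_recall_curve(corpus, orphan)


class TestAccuracyVsRadius:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        corpus, _ = _random_instance(rng, n_corpus=15)
        radii = [0.5, 1.0, 2.0, 5.0]
        got = accuracy_vs_radius(corpus, radii)
        labels, X = corpus.labels, corpus.coords
        fracs_per_radius = []
        for r in radii:
            fracs = []
            for i in range(len(corpus)):
                co = [j for j in range(len(corpus))
                      if j != i and labels[j] == labels[i]]
                if not co:
                    continue
                within = sum(
                    np.sqrt(((X[i] - X[j]) ** 2).sum()) <= r for j in co
                )
                fracs.append(within / len(co))
            fracs_per_radius.append(np.mean(fracs))
        assert np.allclose(got, fracs_per_radius)
        assert (np.diff(got) >= 0).all()

    def test_degenerate_inputs_rejected(self):
        single = EmbeddingSet(np.array(["a"]), np.array(["f"]), np.zeros((1, 2)))
        with pytest.raises(ValueError):
            accuracy_vs_radius(single, [1.0])


class TestClosestRetrieval:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            corpus, queries = _random_instance(rng, n_corpus=16, n_query=6)
            got = closest_retrieval_curve(corpus, queries)
            n_fam = len(np.unique(corpus.labels))
            hits = np.zeros(n_fam)
            for q in range(len(queries)):
                order, _ = _brute_order(corpus, queries.coords[q], queries.ids[q])
                seen = []
                for j in order:
                    if corpus.labels[j] not in seen:
                        seen.append(corpus.labels[j])
                    if corpus.labels[j] == queries.labels[q]:
                        hits[len(seen) - 1] += 1
                        break
            ref = np.cumsum(hits) / len(queries)
            assert np.allclose(got, ref)
            assert got[-1] == pytest.approx(1.0)
            assert (np.diff(got) >= -1e-12).all()


class TestMOBaseline:
    def test_hand_computed_instance(self):
        # corpus: f1 x3, f2 x2, f3 x1 -> prediction order f1, f2, f3
        labels = ["f1", "f1", "f1", "f2", "f2", "f3"]
        queries = ["f1", "f2", "f3", "f2"]
        curve = mo_baseline_curve(
            EmbeddingSet(np.array([f"s{i}" for i in range(6)]),
                         np.array(labels), np.zeros((6, 2))),
            queries,
        )
        assert np.allclose(curve, [1 / 4, 3 / 4, 1.0])

    def test_count_ties_broken_by_label(self):
        labels = ["b", "b", "a", "a"]
        curve = mo_baseline_curve(
            EmbeddingSet(np.array(["1", "2", "3", "4"]), np.array(labels),
                         np.zeros((4, 2))),
            ["b"],
        )
        assert np.allclose(curve, [0.0, 1.0])  # 'a' predicted first on the tie


class TestPCAProjection:
    def test_distances_preserved_for_full_rank_projection(self):
        rng = np.random.default_rng(7)
        # points lying in a 3D subspace of a 6D ambient space
        basis = np.linalg.qr(rng.standard_normal((6, 3)))[0].T
        coords = rng.standard_normal((12, 3)) @ basis
        space = EmbeddingSet(
            np.array([f"s{i}" for i in range(12)]),
            np.array(["f"] * 12), coords,
        )
        proj = pca_project(space, out_dim=3)
        d_in = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        d_out = np.sqrt(((proj.coords[:, None] - proj.coords[None, :]) ** 2).sum(-1))
        assert np.allclose(d_in, d_out, atol=1e-9)

    def test_deterministic_and_validated(self):
        rng = np.random.default_rng(8)
        space = EmbeddingSet(
            np.array([f"s{i}" for i in range(10)]),
            np.array(["f"] * 10), rng.standard_normal((10, 4)),
        )
        a = pca_project(space, out_dim=2)
        b = pca_project(space, out_dim=2)
        assert np.array_equal(a.coords, b.coords)
        with pytest.raises(ValueError):
            pca_project(space, out_dim=5)


class TestClusterMap:
    def test_tsv_roundtrip_bitexact(self, tmp_path):
        rng = np.random.default_rng(9)
        space = EmbeddingSet(
            np.array([f"s{i}" for i in range(8)]),
            np.array(["f1"] * 4 + ["f2"] * 4),
            rng.standard_normal((8, 5)),
        )
        path = tmp_path / "map.tsv"
        export_cluster_map(space, path)
        back = read_cluster_map(path)
        assert list(back.ids) == list(space.ids)
        assert list(back.labels) == list(space.labels)
        assert np.array_equal(back.coords, space.coords)

    def test_empty_rejected(self, tmp_path):
        empty = EmbeddingSet(np.array([]), np.array([]), np.zeros((0, 2)))
        with pytest.raises(ValueError):
            export_cluster_map(empty, tmp_path / "m.tsv")


class TestNoiseExperiment:
    def _setup(self):
        cal = AxisCalibration.default(48)
        rng = np.random.default_rng(0)
        img = SpectrumImage((rng.random(cal.shape()) < 0.05).astype(np.uint8), cal)
        weights = init_weights(ArchitectureSpec(input_side=48, embedding_dim=4),
                               seed=0)
        return img, weights

    def test_row_counts_and_columns(self):
        img, weights = self._setup()
        proto = NoiseProtocol(n_levels=3, max_fraction=0.3, n_reps=2, seed=1)
        df = noise_experiment(weights, img, proto, compound_id="x")
        assert len(df) == 6
        assert set(df["level_index"]) == {0, 1, 2}
        assert (df.groupby("level_index").size() == 2).all()
        assert np.isfinite(df["distance_to_original"]).all()
        assert df["rank1_family"].isna().all()

    def test_rank1_labels_with_corpus(self):
        img, weights = self._setup()
        rng = np.random.default_rng(1)
        corpus = EmbeddingSet(
            np.array(["a", "b"]), np.array(["f1", "f2"]),
            rng.standard_normal((2, 4)),
        )
        proto = NoiseProtocol(n_levels=2, max_fraction=0.2, n_reps=1, seed=2)
        df = noise_experiment(weights, img, proto, corpus=corpus)
        assert set(df["rank1_family"]) <= {"f1", "f2"}

    def test_pca2d_requires_reference(self):
        img, weights = self._setup()
        proto = NoiseProtocol(n_levels=2, max_fraction=0.2, n_reps=1, seed=2)
        with pytest.raises(ValueError):
            noise_experiment(weights, img, proto, space_for_distance="pca2d")
        with pytest.raises(ValueError):
            noise_experiment(weights, img, proto, space_for_distance="bogus")
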