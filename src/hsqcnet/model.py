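"""Model/Results interface tying the pipeline together.

`SiameseSpectralModel` holds a labelled image dataset (real or synthetic) and
the network architecture; `fit()` trains one siamese network on a
cross-validation fold and returns a `SiameseResults` carrying the learned
weights, the training log and the evaluation surface (embeddings, retrieval,
precision-recall, cluster-map export, noise experiment); `fit_cv()` runs the
full 10-fold protocol and returns per-fold and aggregate metrics.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import (
    EmbeddingSet,
    PRCurve,
    closest_retrieval_curve,
    embed_dataset,
    export_cluster_map,
    mo_baseline_curve,
    nearest_neighbors,
    pca_baseline,
    precision_recall_curve,
    noise_experiment,
)
from .network import (
    ArchitectureSpec,
    NetworkWeights,
    embed_images,
    load_checkpoint,
    save_checkpoint,
)
from .spectra import AxisCalibration, DatasetManifest, filter_families
from .synthetic import (
    NoiseProtocol,
    PerturbationModel,
    build_dataset,
    generate_templates,
    load_dataset,
)
from .training import FoldSplit, TrainingConfig, crossvalidate, make_folds, train_siamese

__all__ = ["SiameseSpectralModel", "SiameseResults", "CrossValidationResults"]


class SiameseSpectralModel:
    """Siamese contrastive embedding model over a labelled HSQC dataset."""

    def __init__(
        self,
        manifest: DatasetManifest,
        images: dict,
        arch: ArchitectureSpec | None = None,
        min_family_size: int = 5,
    ):
        self.manifest = filter_families(manifest, min_family_size)
        if len(self.manifest) == 0:
            raise ValueError(
                f"no family has >= {min_family_size} spectra; dataset unusable"
            )
        self.images = {i: images[i] for i in self.manifest.spectrum_ids}
        first = next(iter(self.images.values()))
        side = (first.pixels if hasattr(first, "pixels") else np.asarray(first)).shape[0]
        self.arch = arch or ArchitectureSpec(input_side=side)
        if self.arch.input_side != side:
            raise ValueError(
                f"architecture input_side {self.arch.input_side} does not match "
                f"image side {side}"
            )

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_dataset_dir(
        cls,
        data_dir: str | os.PathLike,
        input_side: int | None = None,
        arch: ArchitectureSpec | None = None,
        calibration: AxisCalibration | None = None,
        min_family_size: int = 5,
    ) -> "SiameseSpectralModel":
        """Build from a manifest TSV + PNG directory on disk."""
        if calibration is None:
            calibration = AxisCalibration.default(input_side or 512)
        manifest, images = load_dataset(data_dir, calibration)
        return cls(manifest, images, arch=arch, min_family_size=min_family_size)

    @classmethod
    def from_synthetic(
        cls,
        n_families: int = 20,
        members: int | None = 8,
        input_side: int = 128,
        seed: int = 0,
        perturbation: PerturbationModel | None = None,
        arch: ArchitectureSpec | None = None,
        peaks_range: tuple[int, int] = (5, 15),
        size_range: tuple[int, int] = (5, 25),
    ) -> "SiameseSpectralModel":
        """Build from a freshly generated synthetic corpus.

        With ``members`` set, every family has exactly that many spectra
        (the balanced benchmark layout); with ``members=None`` family sizes
        follow the generator's right-skewed distribution over ``size_range``.
        Unless a ``perturbation`` is given, the standard benchmark
        perturbations (:meth:`PerturbationModel.benchmark`) are used.
        """
        calibration = AxisCalibration.default(input_side)
        templates = generate_templates(
            n_families, peaks_range=peaks_range, size_range=size_range,
            calibration=calibration, seed=seed,
        )
        if members is not None:
            for t in templates:
                t.n_members = members
        manifest, images = build_dataset(
            templates, perturbation or PerturbationModel.benchmark(), calibration,
            seed=seed + 1,
        )
        model = cls(manifest, images, arch=arch or ArchitectureSpec(input_side=input_side))
        model.calibration = calibration
        model.templates = templates
        return model

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        config: TrainingConfig | None = None,
        split: FoldSplit | None = None,
        fold: int = 0,
        n_folds: int = 10,
        verbose: bool = False,
    ) -> "SiameseResults":
        """Train one network; returns a results object with the evaluation API."""
        config = config or TrainingConfig()
        if split is None:
            split = make_folds(self.manifest, n_folds=n_folds, seed=config.seed)[fold]
        weights, log = train_siamese(
            self.manifest, self.images, split, self.arch, config, verbose=verbose
        )
        return SiameseResults(self, weights, log, split, config)

    def fit_cv(
        self,
        config: TrainingConfig | None = None,
        n_folds: int = 10,
        verbose: bool = False,
    ) -> "CrossValidationResults":
        """Full cross-validation: one network per fold, metrics averaged."""
        config = config or TrainingConfig()
        per_fold, aggregate, outputs = crossvalidate(
            self.manifest, self.images, self.arch, config, n_folds=n_folds,
            verbose=verbose,
        )
        return CrossValidationResults(self, per_fold, aggregate, outputs, config)

    def pca_baseline(self, k: int = 10) -> EmbeddingSet:
        """The linear pixel-PCA comparator on this dataset."""
        return pca_baseline(self.images, self.manifest, k=k)


@dataclass
class SiameseResults:
    """Fitted siamese embedding: weights, log, split and evaluation methods."""

    model: SiameseSpectralModel
    weights: NetworkWeights
    log: pd.DataFrame
    split: FoldSplit
    config: TrainingConfig

    # -- embeddings ---------------------------------------------------------

    def embed(self, ids=None) -> EmbeddingSet:
        """Evaluation-mode embeddings of (a subset of) the model's dataset."""
        manifest = self.model.manifest if ids is None else self.model.manifest.subset(ids)
        return embed_dataset(self.weights, self.model.images, manifest)

    def embed_images(self, images) -> np.ndarray:
        """Embed arbitrary preprocessed images with the fitted network."""
        return embed_images(self.weights, images)

    def corpus_embedding(self) -> EmbeddingSet:
        return self.embed(list(self.split.train_ids))

    def test_embedding(self) -> EmbeddingSet:
        return self.embed(list(self.split.test_ids))

    # -- evaluation ---------------------------------------------------------

    def precision_recall(self, queries: EmbeddingSet | None = None) -> PRCurve:
        """PR curve of (default) test queries against the training corpus."""
        return precision_recall_curve(
            self.corpus_embedding(), queries or self.test_embedding()
        )

    def closest_retrieval(self, queries: EmbeddingSet | None = None) -> np.ndarray:
        return closest_retrieval_curve(
            self.corpus_embedding(), queries or self.test_embedding()
        )

    def mo_baseline(self) -> np.ndarray:
        corpus = self.corpus_embedding()
        test = self.test_embedding()
        return mo_baseline_curve(corpus, test.labels)

    def retrieve(self, queries: EmbeddingSet | None = None, k: int = 10) -> pd.DataFrame:
        return nearest_neighbors(
            self.corpus_embedding(), queries or self.test_embedding(), k=k
        )

    def noise_experiment(
        self, spectrum_id: str, protocol: NoiseProtocol | None = None, **kw
    ) -> pd.DataFrame:
        """Run the noise-robustness protocol on one of the model's spectra."""
        return noise_experiment(
            self.weights,
            self.model.images[spectrum_id],
            protocol or NoiseProtocol(),
            compound_id=spectrum_id,
            **kw,
        )

    def export_cluster_map(self, path, plot: bool = False) -> None:
        export_cluster_map(self.embed(), path, plot=plot)

    # -- persistence / reporting -------------------------------------------

    def save(self, path) -> None:
        save_checkpoint(path, self.weights, config=self.config.__dict__)

    def summary(self) -> str:
        """Human-readable fit summary."""
        pr = self.precision_recall()
        crc = self.closest_retrieval()
        lines = [
            "Siamese spectral embedding results",
            "=" * 44,
            f"spectra:            {len(self.model.manifest)}",
            f"families:           {self.model.manifest.family_sizes().size}",
            f"input side:         {self.model.arch.input_side}",
            f"embedding dim (K):  {self.model.arch.embedding_dim}",
            f"train/val/test:     {len(self.split.train_ids)}/"
            f"{len(self.split.validation_ids)}/{len(self.split.test_ids)}",
            f"iterations run:     {int(self.log['iteration'].max())}",
            f"final train loss:   {self.log['train_loss'].iloc[-1]:.4f}",
            f"best validation AP: {self.log['best_val_ap'].max():.4f}",
            f"test PR-AUC:        {pr.auc:.4f}",
            f"retrieval@1:        {crc[0]:.4f}",
            f"retrieval@5:        {crc[min(5, len(crc)) - 1]:.4f}",
        ]
        return "\n".join(lines)


@dataclass
class CrossValidationResults:
    """Per-fold and aggregate cross-validated metrics."""

    model: SiameseSpectralModel
    per_fold: pd.DataFrame
    aggregate: pd.Series
    fold_outputs: list
    config: TrainingConfig

    def summary(self) -> str:
        lines = [
            "Cross-validated siamese embedding",
            "=" * 44,
            self.per_fold.to_string(float_format=lambda v: f"{v:.4f}"),
            "-" * 44,
            "mean: " + "  ".join(
                f"{k}={v:.4f}" for k, v in self.aggregate.items()
            ),
        ]
        return "\n".join(lines)
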