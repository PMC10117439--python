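"""Model/Results front end for the brain-graph classifier.

Mirrors the fitting idiom of mainstream statistical-modelling packages:
construct a :class:`BrainGCN` from a dataset of brain graphs, call
``fit()``, and receive a :class:`BrainGCNResults` carrying the trained
weights, the training log, held-out metrics and a ``summary()`` table.
Saliency analysis hangs off the results object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluate import auc_rank, confusion_metrics
from .gcn import (
    ModelConfig,
    TrainConfig,
    TrainedModel,
    predict_proba,
    train,
)
from .graphs import BrainGraphSample, FeatureScaler, zscore_features
from .saliency import saliency_scores, top_k_table

__all__ = ["BrainGCN", "BrainGCNResults"]


class BrainGCN:
    """Graph-classification model over a dataset of brain graphs.

    Parameters
    ----------
    dataset : list of BrainGraphSample
        One graph per subject, all sharing a GraphTypeSpec.
    model_config, train_config : optional
        Architecture and optimisation settings; defaults follow the
        reference protocol (hidden 64, pool ratio 0.8, Adam 1e-4,
        batch 30, dropout 0.5, max 1000 epochs, patience 500).
    zscore : bool
        Standardise node features with training-set statistics (default).
    """

    def __init__(
        self,
        dataset: list[BrainGraphSample],
        model_config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
        zscore: bool = True,
    ) -> None:
        if not dataset:
            raise ValueError("dataset is empty")
        specs = {s.spec for s in dataset}
        if len(specs) != 1:
            raise ValueError("all graphs must share one GraphTypeSpec")
        self.dataset = list(dataset)
        self.spec = dataset[0].spec
        self.model_config = model_config or ModelConfig()
        self.train_config = train_config or TrainConfig()
        self.zscore = zscore

    @classmethod
    def from_subjects(
        cls, subjects, spec, atlas, caches=None, **kwargs
    ) -> "BrainGCN":
        """Build the graphs from raw subjects, then construct the model."""
        from .graphs import build_dataset

        dataset = build_dataset(subjects, spec, atlas, caches=caches)
        return cls(dataset, **kwargs)

    def fit(
        self, train_ids: list[str] | None = None, test_ids: list[str] | None = None
    ) -> "BrainGCNResults":
        """Train on ``train_ids`` (default: all subjects) and wrap the result."""
        all_ids = [s.subject_id for s in self.dataset]
        train_ids = list(train_ids) if train_ids is not None else all_ids
        test_ids = list(test_ids) if test_ids is not None else []
        scaler: FeatureScaler | None = None
        if self.zscore:
            scaled, scaler = zscore_features(self.dataset, train_ids)
        else:
            scaled = self.dataset
        trained = train(scaled, train_ids, self.model_config, self.train_config)
        return BrainGCNResults(self, trained, scaled, scaler, train_ids, test_ids)


class BrainGCNResults:
    """Fitted classifier: weights, log, metrics, saliency, summary."""

    def __init__(self, model, trained, scaled_dataset, scaler, train_ids, test_ids):
        self.model = model
        self.trained: TrainedModel = trained
        self._scaled = {s.subject_id: s for s in scaled_dataset}
        self.scaler = scaler
        self.train_ids = list(train_ids)
        self.test_ids = list(test_ids)

    # -- prediction -----------------------------------------------------
    def _samples(self, ids) -> list[BrainGraphSample]:
        return [self._scaled[i] for i in ids]

    def predict_proba(self, ids=None) -> np.ndarray:
        ids = ids if ids is not None else self.test_ids or self.train_ids
        return predict_proba(self.trained, self._samples(ids))

    def predict(self, ids=None) -> np.ndarray:
        return self.predict_proba(ids).argmax(axis=1)

    # -- evaluation ------------------------------------------------------
    def metrics(self, ids=None) -> dict[str, float]:
        """Six-metric report on the given subjects (default: test set)."""
        ids = ids if ids is not None else self.test_ids
        if not ids:
            raise ValueError("no held-out subjects to score")
        samples = self._samples(ids)
        y_true = np.array([s.label for s in samples])
        proba = predict_proba(self.trained, samples)[:, 1]
        y_pred = (proba >= 0.5).astype(int)
        tp = int(((y_pred == 1) & (y_true == 1)).sum())
        fp = int(((y_pred == 1) & (y_true == 0)).sum())
        tn = int(((y_pred == 0) & (y_true == 0)).sum())
        fn = int(((y_pred == 0) & (y_true == 1)).sum())
        out = confusion_metrics(tp, fp, tn, fn)
        out["auc"] = auc_rank(y_true, proba)
        return out

    # -- explainability --------------------------------------------------
    def saliency(self, roi_names=None) -> pd.DataFrame:
        """Selection-frequency saliency over the training subjects."""
        return saliency_scores(
            self.trained, self._samples(self.train_ids), roi_names
        )

    def top_salient(self, k: int = 10, roi_names=None) -> pd.DataFrame:
        return top_k_table(self.saliency(roi_names), k)

    # -- reporting -------------------------------------------------------
    @property
    def training_log(self) -> pd.DataFrame:
        return pd.DataFrame(self.trained.log)

    def summary(self) -> str:
        cfg_m = self.trained.model_cfg
        cfg_t = self.trained.train_cfg
        lines = [
            "Brain-graph GCN classification results",
            "=" * 46,
            f"graph type        {self.model.spec.name}",
            f"subjects          {len(self._scaled)} "
            f"(train {len(self.train_ids)}, test {len(self.test_ids)})",
            f"architecture      3 x (conv -> TopK pool -> readout), "
            f"hidden {cfg_m.hidden_dim}, ratio {cfg_m.pool_ratio}",
            f"training          Adam lr {cfg_t.learning_rate}, batch {cfg_t.batch_size}, "
            f"dropout {cfg_m.dropout}",
            f"epochs run        {len(self.trained.log)} "
            f"(best validation loss at epoch {self.trained.best_epoch})",
        ]
        if self.test_ids:
            m = self.metrics()
            lines.append("-" * 46)
            for name in ("accuracy", "auc", "sensitivity", "specificity", "f1", "precision"):
                lines.append(f"{name:<14s}{m[name]:8.3f}")
        return "\n".join(lines)
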