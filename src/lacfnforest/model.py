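"""User-facing Model/Results interface to the laminar forest classifier.

``LACFNForest`` is constructed from data (arrays, a DataFrame, or an
``ExpressionMatrix``/``LabelVector`` pair) plus configuration; ``fit()``
trains the ensemble and returns a ``LACFNForestResults`` carrying the trained
model, the training-sample routing, in-sample diagnostics, and ``predict`` /
``summary`` / ``save`` methods.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, LabelVector
from .evaluation import macro_metrics
from .evolution import EvolutionConfig, PSOConfig
from .laminar import (
    LaminarConfig,
    LaminarModel,
    SampleRouting,
    train_laminar,
)


class LACFNForest:
    """Laminar augmented cascading flexible neural forest classifier.

    Parameters
    ----------
    X : (n, d) array of preprocessed (z-scored) expression values.
    y : (n,) integer class indices in [0, M).
    config, evo_config, pso_config : optional configuration blocks for the
        ensemble shape, the structure search, and the parameter swarm.
    class_names : optional class labels used by reporting.

    Examples
    --------
    >>> model = LACFNForest(X, y, config=LaminarConfig(seed=1))
    >>> res = model.fit()
    >>> res.predict(X_new)
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        config: LaminarConfig | None = None,
        evo_config: EvolutionConfig | None = None,
        pso_config: PSOConfig | None = None,
        class_names: list[str] | None = None,
    ) -> None:
        self.exog = np.asarray(X, dtype=float)
        self.endog = np.asarray(y, dtype=int)
        if self.exog.ndim != 2:
            raise ValueError("X must be 2-dimensional (samples x genes)")
        if self.endog.shape[0] != self.exog.shape[0]:
            raise ValueError("X and y disagree on sample count")
        if self.endog.min() < 0:
            raise ValueError("class indices must be non-negative")
        self.config = config or LaminarConfig()
        self.evo_config = evo_config or EvolutionConfig()
        self.pso_config = pso_config or PSOConfig()
        M = int(self.endog.max()) + 1
        self.class_names = class_names or [f"class{c}" for c in range(M)]

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        label_col: str,
        **kwargs,
    ) -> "LACFNForest":
        """Build from a samples-in-rows DataFrame with a label column."""
        if label_col not in data.columns:
            raise ValueError(f"label column {label_col!r} not in frame")
        labels = data[label_col].astype(str)
        class_names = sorted(labels.unique())
        lut = {c: i for i, c in enumerate(class_names)}
        X = data.drop(columns=[label_col]).to_numpy(dtype=float)
        y = labels.map(lut).to_numpy()
        return cls(X, y, class_names=class_names, **kwargs)

    @classmethod
    def from_expression(
        cls,
        matrix: ExpressionMatrix,
        labels: LabelVector,
        **kwargs,
    ) -> "LACFNForest":
        """Build from a preprocessed expression matrix and aligned labels."""
        if matrix.missing_mask.any():
            raise ValueError("matrix has missing values; preprocess first")
        aligned = labels.aligned_to(matrix)
        return cls(matrix.values, aligned.as_indices(),
                   class_names=list(aligned.class_names), **kwargs)

    def fit(self) -> "LACFNForestResults":
        model, routing = train_laminar(
            self.exog, self.endog, self.config, self.evo_config, self.pso_config
        )
        return LACFNForestResults(self, model, routing)


class LACFNForestResults:
    """Fitted-model results: trained ensemble, routing, and diagnostics."""

    def __init__(
        self,
        model: LACFNForest,
        laminar_model: LaminarModel,
        routing: SampleRouting,
    ) -> None:
        self.model = model
        self.laminar_model = laminar_model
        self.routing = routing
        pred, scores = laminar_model.predict(model.exog)
        self.in_sample_prediction = np.asarray(pred)
        self.in_sample_scores = scores
        p, r, f = macro_metrics(
            model.endog, self.in_sample_prediction, len(model.class_names)
        )
        self.train_precision, self.train_recall, self.train_f1 = p, r, f
        self.train_accuracy = float(
            np.mean(self.in_sample_prediction == model.endog)
        )

    def predict(
        self, X: np.ndarray, return_scores: bool = False
    ):
        """Class indices for new samples (optionally with combined scores)."""
        pred, scores = self.laminar_model.predict(np.asarray(X, dtype=float))
        return (pred, scores) if return_scores else pred

    def predict_labels(self, X: np.ndarray) -> list[str]:
        return [self.model.class_names[c] for c in self.predict(X)]

    def summary(self) -> str:
        """Plain-text fit report: ensemble shape, per-layer structure,
        cascade validation traces, routing, and in-sample macro metrics."""
        lm = self.laminar_model
        cfg = lm.config
        n, d = self.model.exog.shape
        buf = io.StringIO()
        w = buf.write
        w("Laminar Augmented Cascading Flexible Neural Forest\n")
        w("=" * 60 + "\n")
        w(f"Samples: {n}    Genes: {d}    Classes: {lm.codebook.num_classes}"
          f"    Binary tasks: {lm.codebook.num_bits}\n")
        w(f"Layers trained: {len(lm.layers)} (configured {cfg.num_layers}), "
          f"widening: {cfg.widening}, K={cfg.k_base}\n")
        w(f"Layer weights: {np.round(lm.layer_weights_, 4).tolist()}\n")
        w(f"Confidence region: "
          f"{' u '.join(f'[{a}, {b}]' for a, b in cfg.confidence.intervals)}"
          f", final threshold {cfg.confidence.final_threshold}\n")
        w("-" * 60 + "\n")
        for layer in lm.layers:
            w(f"Layer {layer.layer_index}: {len(layer.forests)} DFNForests\n")
            for i, forest in enumerate(layer.forests):
                fs = forest.function_set
                trace = [round(a, 3) for a in forest.val_accuracy_trace]
                w(f"  forest {i} [{fs.name or fs.arities}]"
                  f" levels={len(forest.levels)}"
                  f" ({len(forest.levels[0].trees)} FNTs/level)"
                  f" val trace={trace}\n")
        w("-" * 60 + "\n")
        exits = np.bincount(self.routing.exit_layer,
                            minlength=len(lm.layers) + 1)[1:]
        for li, c in enumerate(exits, start=1):
            w(f"Exited at layer {li}: {int(c)} samples\n")
        w("-" * 60 + "\n")
        w(f"Training accuracy:        {self.train_accuracy:.4f}\n")
        w(f"Training macro precision: {self.train_precision:.4f}\n")
        w(f"Training macro recall:    {self.train_recall:.4f}\n")
        w(f"Training macro F1:        {self.train_f1:.4f}\n")
        return buf.getvalue()

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.laminar_model.to_json())

    @staticmethod
    def load_model(path: str | Path) -> LaminarModel:
        return LaminarModel.from_json(Path(path).read_text())
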