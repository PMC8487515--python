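"""Cross-validation, macro metrics, and learning curves.

The evaluation protocol is stratified 5-fold cross-validation, optionally
repeated (the reference protocol averages 10 repeats), reporting macro
precision, recall and F1 — unweighted means over classes, so minority
subtypes count as much as majority ones. Deviations are reported both across
folds and across repeats. All reported numbers are recomputable from the
stored per-fold predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold

from .evolution import EvolutionConfig, PSOConfig
from .laminar import LaminarConfig, train_laminar


def macro_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, num_classes: int | None = None
) -> tuple[float, float, float]:
    """(macro precision, macro recall, macro F1). A class never predicted
    contributes precision 0 (with a warning suppressed to a defined value)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    labels = (
        np.arange(num_classes)
        if num_classes is not None
        else np.unique(np.concatenate([y_true, y_pred]))
    )
    p, r, f, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="macro", zero_division=0
    )
    return float(p), float(r), float(f)


@dataclass
class CVReport:
    """Aggregated cross-validation results.

    ``fold_metrics`` is one (precision, recall, f1) triple per fold per
    repeat; ``fold_predictions`` stores (true, predicted) label indices per
    fold so every summary number can be recomputed.
    """

    k: int
    repeats: int
    seed: int
    fold_metrics: list[list[tuple[float, float, float]]]
    fold_predictions: list[list[tuple[list[int], list[int]]]]
    config_snapshot: dict = field(default_factory=dict)

    def _stack(self) -> np.ndarray:
        return np.asarray(self.fold_metrics, dtype=float)  # (R, k, 3)

    @property
    def mean_precision(self) -> float:
        return float(self._stack()[:, :, 0].mean())

    @property
    def mean_recall(self) -> float:
        return float(self._stack()[:, :, 1].mean())

    @property
    def mean_f1(self) -> float:
        return float(self._stack()[:, :, 2].mean())

    def sd_across_folds(self) -> tuple[float, float, float]:
        m = self._stack().reshape(-1, 3)
        return tuple(float(v) for v in m.std(axis=0, ddof=1 if len(m) > 1 else 0))

    def sd_across_repeats(self) -> tuple[float, float, float]:
        m = self._stack().mean(axis=1)  # per-repeat means
        ddof = 1 if m.shape[0] > 1 else 0
        return tuple(float(v) for v in m.std(axis=0, ddof=ddof))

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "repeats": self.repeats,
                "seed": self.seed,
                "fold_metrics": self.fold_metrics,
                "fold_predictions": [
                    [[list(t), list(p)] for t, p in rep]
                    for rep in self.fold_predictions
                ],
                "config_snapshot": self.config_snapshot,
                "summary": {
                    "macro_precision": self.mean_precision,
                    "macro_recall": self.mean_recall,
                    "macro_f1": self.mean_f1,
                    "sd_across_folds": self.sd_across_folds(),
                    "sd_across_repeats": self.sd_across_repeats(),
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CVReport":
        d = json.loads(text)
        return cls(
            d["k"], d["repeats"], d["seed"],
            [[tuple(m) for m in rep] for rep in d["fold_metrics"]],
            [[(list(t), list(p)) for t, p in rep]
             for rep in d["fold_predictions"]],
            d.get("config_snapshot", {}),
        )


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    cfg: LaminarConfig | None = None,
    evo_cfg: EvolutionConfig | None = None,
    pso_cfg: PSOConfig | None = None,
    k: int = 5,
    repeats: int = 1,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold cross-validation of the laminar classifier.

    Every sample is tested exactly once per repeat; each repeat reshuffles
    the fold assignment with a derived seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] < k:
        raise ValueError("need at least k samples")
    cfg = cfg or LaminarConfig()
    M = int(y.max()) + 1

    all_metrics: list[list[tuple[float, float, float]]] = []
    all_preds: list[list[tuple[list[int], list[int]]]] = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=(seed + 1009 * rep) % (2**31))
        rep_metrics, rep_preds = [], []
        for fold, (tr, te) in enumerate(skf.split(X, y)):
            fold_cfg = replace(cfg, seed=seed + 31 * rep + fold)
            model, _ = train_laminar(X[tr], y[tr], fold_cfg, evo_cfg, pso_cfg)
            pred, _ = model.predict(X[te])
            rep_metrics.append(macro_metrics(y[te], pred, M))
            rep_preds.append((y[te].tolist(), np.asarray(pred).tolist()))
        all_metrics.append(rep_metrics)
        all_preds.append(rep_preds)

    snapshot = {
        "num_layers": cfg.num_layers, "k_base": cfg.k_base,
        "widening": cfg.widening, "k": k, "repeats": repeats,
    }
    return CVReport(k, repeats, seed, all_metrics, all_preds, snapshot)


def learning_curve(
    X: np.ndarray,
    y: np.ndarray,
    fractions: list[float],
    cfg: LaminarConfig | None = None,
    evo_cfg: EvolutionConfig | None = None,
    pso_cfg: PSOConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> list[dict]:
    """Train/validation scores versus training-set size.

    For each fraction, a stratified subsample is cross-validated (validation
    score = mean test-fold macro F1) and the model is also scored on its own
    training folds (train score). Fractions too small for k-fold stratification
    are skipped with a warning entry.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if any(f2 <= f1 for f1, f2 in zip(fractions, fractions[1:])) or not all(
        0 < f <= 1 for f in fractions
    ):
        raise ValueError("fractions must be increasing and in (0, 1]")
    M = int(y.max()) + 1
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for frac in fractions:
        if frac >= 1.0:
            idx = np.arange(X.shape[0])
        else:
            idx = _stratified_subsample(y, frac, rng)
        counts = np.bincount(y[idx], minlength=M)
        if np.min(counts[counts > 0]) < k or idx.size < 10:
            rows.append({"fraction": frac, "n": int(idx.size),
                         "skipped": True})
            continue
        Xs, ys = X[idx], y[idx]
        train_scores, val_scores = [], []
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=seed % (2**31))
        for fold, (tr, te) in enumerate(skf.split(Xs, ys)):
            fold_cfg = replace(cfg or LaminarConfig(), seed=seed + fold)
            model, _ = train_laminar(Xs[tr], ys[tr], fold_cfg, evo_cfg, pso_cfg)
            pred_tr, _ = model.predict(Xs[tr])
            pred_te, _ = model.predict(Xs[te])
            train_scores.append(float(np.mean(pred_tr == ys[tr])))
            val_scores.append(float(np.mean(pred_te == ys[te])))
        rows.append(
            {
                "fraction": frac,
                "n": int(idx.size),
                "skipped": False,
                "train_accuracy": float(np.mean(train_scores)),
                "val_accuracy": float(np.mean(val_scores)),
            }
        )
    return rows


def _stratified_subsample(
    y: np.ndarray, frac: float, rng: np.random.Generator
) -> np.ndarray:
    idx: list[int] = []
    for c in np.unique(y):
        members = np.flatnonzero(y == c)
        take = max(1, int(round(frac * members.size)))
        idx.extend(rng.choice(members, size=take, replace=False).tolist())
    return np.sort(np.asarray(idx, dtype=int))
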