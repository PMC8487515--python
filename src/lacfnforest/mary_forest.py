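"""DFNForest: M-ary decomposition, FNT forests, cascading with augmentation.

A single flexible neural tree has one output in (0, 1), so an M-class problem
is first turned into B = ceil(log2 M) binary tasks: class c gets the B-bit
binary code of c, and tree b in a forest predicts bit b. Forests are stacked
into a cascade; level l consumes the original features concatenated with the
raw bit outputs of all earlier levels, and the cascade depth is chosen
automatically on a held-out validation split (stop when accuracy no longer
improves, keep the depth that maximised it). Decoding maps a raw output
vector to the nearest valid class code.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from .evolution import EvolutionConfig, PSOConfig, derive_rng, evolve_structure
from .fnt_core import (
    FlexibleNeuralTree,
    FunctionSet,
    evaluate_tree,
    tree_from_dict,
    tree_to_dict,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BinaryTaskCodebook:
    """Class index -> B-bit code, B = ceil(log2 M); codes are the plain binary
    representations (MSB first), so some codes are unused when M is not a
    power of two."""

    num_classes: int
    num_bits: int
    codes: np.ndarray  # (M, B) of 0/1

    def encode(self, class_index: int) -> np.ndarray:
        if not 0 <= class_index < self.num_classes:
            raise ValueError(f"class index {class_index} out of range")
        return self.codes[class_index]

    def encode_all(self, y: np.ndarray) -> np.ndarray:
        return self.codes[np.asarray(y, dtype=int)]

    def decode(self, outputs: np.ndarray) -> np.ndarray:
        """Nearest valid code by Euclidean distance; ties go to the lowest
        class index. Accepts one (B,) vector or an (n, B) batch."""
        o = np.atleast_2d(np.asarray(outputs, dtype=float))
        if o.shape[1] != self.num_bits:
            raise ValueError("output width does not match codebook")
        d2 = ((o[:, None, :] - self.codes[None, :, :]) ** 2).sum(axis=2)
        cls = np.argmin(d2, axis=1)  # argmin takes the first (lowest) index
        return cls if np.asarray(outputs).ndim == 2 else int(cls[0])


def build_codebook(num_classes: int) -> BinaryTaskCodebook:
    if num_classes < 2:
        raise ValueError("need at least 2 classes")
    B = max(1, math.ceil(math.log2(num_classes)))
    codes = np.array(
        [[(c >> (B - 1 - b)) & 1 for b in range(B)] for c in range(num_classes)],
        dtype=float,
    )
    return BinaryTaskCodebook(num_classes, B, codes)


def encode_label(cb: BinaryTaskCodebook, class_index: int) -> np.ndarray:
    return cb.encode(class_index)


def decode_outputs(cb: BinaryTaskCodebook, outputs: np.ndarray):
    return cb.decode(outputs)


@dataclass
class NeuralForest:
    """One cascade level: B trees, tree b trained on bit b."""

    trees: list[FlexibleNeuralTree]
    function_set: FunctionSet

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([evaluate_tree(t, X) for t in self.trees])


@dataclass
class DFNForestModel:
    """A trained cascade of forests for one M-class problem.

    Level l (1-based) sees ``base_input_dim + (l-1) * B`` columns: the
    original features plus every earlier level's raw bit outputs.
    """

    levels: list[NeuralForest]
    codebook: BinaryTaskCodebook
    function_set: FunctionSet
    base_input_dim: int
    val_accuracy_trace: list[float] = field(default_factory=list)

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Raw B-vector outputs of the last level, running the cascade with
        internal augmentation."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.base_input_dim:
            raise ValueError(
                f"input width {X.shape[1]}, model expects {self.base_input_dim}"
            )
        cur = X
        out = None
        for forest in self.levels:
            out = forest.predict(cur)
            cur = np.hstack([cur, out])
        return out

    def to_dict(self) -> dict:
        return {
            "base_input_dim": self.base_input_dim,
            "num_classes": self.codebook.num_classes,
            "function_set": {"arities": list(self.function_set.arities),
                             "name": self.function_set.name},
            "val_accuracy_trace": self.val_accuracy_trace,
            "levels": [[tree_to_dict(t) for t in lvl.trees]
                       for lvl in self.levels],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DFNForestModel":
        fs = FunctionSet(tuple(d["function_set"]["arities"]),
                         d["function_set"].get("name", ""))
        levels = [
            NeuralForest([tree_from_dict(t) for t in lvl], fs)
            for lvl in d["levels"]
        ]
        return cls(levels, build_codebook(int(d["num_classes"])), fs,
                   int(d["base_input_dim"]), list(d["val_accuracy_trace"]))


def augment_features(X_base: np.ndarray, forest_outputs: np.ndarray) -> np.ndarray:
    """Column-wise concatenation [X_base | outputs]."""
    X_base = np.asarray(X_base, dtype=float)
    forest_outputs = np.asarray(forest_outputs, dtype=float)
    if X_base.shape[0] != forest_outputs.shape[0]:
        raise ValueError("row counts of base matrix and outputs differ")
    return np.hstack([X_base, forest_outputs])


def train_level(
    X_aug: np.ndarray,
    y_bits: np.ndarray,
    fs: FunctionSet,
    evo_cfg: EvolutionConfig,
    pso_cfg: PSOConfig,
    rng_seed: int = 0,
) -> NeuralForest:
    """Evolve one FNT per bit column."""
    X_aug = np.asarray(X_aug, dtype=float)
    y_bits = np.atleast_2d(np.asarray(y_bits, dtype=float))
    trees = []
    for b in range(y_bits.shape[1]):
        col = y_bits[:, b]
        if col.min() == col.max():
            logger.warning(
                "bit %d is degenerate (all %g); training anyway", b, col[0]
            )
        rng = derive_rng(rng_seed, "bit", b)
        trees.append(evolve_structure(X_aug, col, fs, evo_cfg, pso_cfg, rng))
    return NeuralForest(trees, fs)


def train_cascade(
    X: np.ndarray,
    y: np.ndarray,
    fs: FunctionSet,
    evo_cfg: EvolutionConfig | None = None,
    pso_cfg: PSOConfig | None = None,
    val_fraction: float = 0.2,
    max_levels: int = 8,
    seed: int = 0,
    codebook: BinaryTaskCodebook | None = None,
) -> DFNForestModel:
    """Train a cascade, deepening while held-out accuracy strictly improves.

    An 80/20 stratified train/validation split (fixed by ``seed``) scores each
    level; training stops on the first non-improvement (patience 1) or at
    ``max_levels``, and the model keeps the prefix of levels up to the best
    recorded accuracy.
    """
    evo_cfg = evo_cfg or EvolutionConfig()
    pso_cfg = pso_cfg or PSOConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 samples to train a cascade")
    classes = np.unique(y)
    if classes.size < 2 and codebook is None:
        raise ValueError("need at least 2 classes present")
    cb = codebook or build_codebook(int(classes.max()) + 1)

    counts = np.bincount(y)
    strat = y if np.min(counts[counts > 0]) >= 2 and classes.size >= 2 else None
    if strat is not None and int(np.ceil(val_fraction * y.size)) < classes.size:
        strat = None  # validation split too small to hold every class
    X_tr, X_val, y_tr, y_val = train_test_split(
        X, y, test_size=val_fraction, random_state=seed % (2**31), stratify=strat
    )
    if X_val.shape[0] == 0:
        raise ValueError("validation split is empty")
    bits_tr = cb.encode_all(y_tr)

    levels: list[NeuralForest] = []
    trace: list[float] = []
    cur_tr, cur_val = X_tr, X_val
    best_acc, best_depth = -np.inf, 0
    for lvl in range(max_levels):
        forest = train_level(cur_tr, bits_tr, fs, evo_cfg, pso_cfg,
                             rng_seed=seed + 7919 * lvl)
        levels.append(forest)
        out_tr = forest.predict(cur_tr)
        out_val = forest.predict(cur_val)
        acc = float(np.mean(cb.decode(out_val) == y_val))
        trace.append(acc)
        if acc > best_acc:
            best_acc, best_depth = acc, lvl + 1
        elif lvl + 1 > best_depth:  # no strict increase: stop deepening
            break
        cur_tr = augment_features(cur_tr, out_tr)
        cur_val = augment_features(cur_val, out_val)

    return DFNForestModel(levels[:best_depth], cb, fs, X.shape[1], trace)


def predict_dfn(model: DFNForestModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(decoded class indices, raw last-level B-vector per sample)."""
    raw = model.forward(X)
    return model.codebook.decode(raw), raw
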