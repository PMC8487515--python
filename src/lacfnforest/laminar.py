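"""The laminar augmented cascading flexible neural forest (LACFNForest).

Several DFNForests with different grammars form one *layer*; layers are
stacked N deep (default 4) and widen arithmetically (K, K+1, ... forests) to
grow ensemble diversity with depth. After each layer an output-judgment rule
routes samples: those whose averaged bit outputs all fall inside the
confidence region [0, 0.1] u [0.9, 1] exit (set Y); uncertain samples (set X)
continue, carrying a densely augmented input — the original features
concatenated with *every* earlier layer's averaged outputs, after the
dense-block idea. The final layer classifies everything (threshold 0.5).
A sample's combined score is the triangular-weighted sum of the layer outputs
it traversed, w_i = i / (1 + 2 + ... + N), renormalised over the traversed
prefix for early exits; the class is the nearest codebook code.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .evolution import EvolutionConfig, PSOConfig
from .fnt_core import DEFAULT_FUNCTION_SETS, FunctionSet
from .mary_forest import (
    BinaryTaskCodebook,
    DFNForestModel,
    build_codebook,
    train_cascade,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfidenceRule:
    """The output-judgment intervals. A sample is confident at a non-final
    layer iff every bit of its averaged output lies in the union of the
    (closed) intervals; at the final layer everyone is classified."""

    intervals: tuple[tuple[float, float], ...] = ((0.0, 0.1), (0.9, 1.0))
    final_threshold: float = 0.5

    def __post_init__(self) -> None:
        ivs = tuple((float(a), float(b)) for a, b in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        for a, b in ivs:
            if not (0.0 <= a <= b <= 1.0):
                raise ValueError(f"interval [{a}, {b}] not within [0, 1]")
        for (a1, b1) in ivs:
            for (a2, b2) in ivs:
                if (a1, b1) < (a2, b2) and b1 >= a2:
                    raise ValueError("intervals must be pairwise disjoint")

    def contains(self, values: np.ndarray) -> np.ndarray:
        """Elementwise membership in the union of intervals."""
        v = np.asarray(values, dtype=float)
        inside = np.zeros(v.shape, dtype=bool)
        for a, b in self.intervals:
            inside |= (v >= a) & (v <= b)
        return inside


@dataclass(frozen=True)
class LaminarConfig:
    """Ensemble shape: N layers (default 4), K forests in the first layer
    (default 3), widening +1 per layer (arithmetic) or constant width, with
    the four grammars assigned round-robin across each layer's forests."""

    num_layers: int = 4
    k_base: int = 3
    function_sets: tuple[FunctionSet, ...] = DEFAULT_FUNCTION_SETS
    widening: str = "arithmetic"
    confidence: ConfidenceRule = ConfidenceRule()
    gate_mode: str = "all_bits"  # or "max_bit": only the largest bit gates
    augment_per_forest: bool = False  # B*width augmentation columns per layer
    max_cascade_levels: int = 8
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_layers < 1 or self.k_base < 1:
            raise ValueError("num_layers and k_base must be >= 1")
        if self.widening not in ("arithmetic", "constant"):
            raise ValueError("widening must be 'arithmetic' or 'constant'")
        if self.gate_mode not in ("all_bits", "max_bit"):
            raise ValueError("gate_mode must be 'all_bits' or 'max_bit'")

    def layer_width(self, layer_index: int) -> int:
        """Forest count of 1-based layer ``layer_index``."""
        if self.widening == "constant":
            return self.k_base
        return self.k_base + (layer_index - 1)


def layer_weights(num_layers: int) -> np.ndarray:
    """Triangular layer weights w_i = i / (N(N+1)/2); sum to 1 and strictly
    increase, so deeper (better-informed) layers count more."""
    if num_layers < 1:
        raise ValueError("need at least one layer")
    i = np.arange(1, num_layers + 1, dtype=float)
    return i / (num_layers * (num_layers + 1) / 2.0)


@dataclass
class LaminarLayer:
    forests: list[DFNForestModel]
    layer_index: int  # 1-based

    def predict(self, X_aug: np.ndarray) -> np.ndarray:
        """Per-bit arithmetic mean of the layer's DFNForest raw outputs."""
        outs = [f.forward(X_aug) for f in self.forests]
        return np.mean(outs, axis=0)

    def forest_outputs(self, X_aug: np.ndarray) -> np.ndarray:
        """Per-forest raw outputs side by side: (n, B * n_forests)."""
        return np.hstack([f.forward(X_aug) for f in self.forests])


def layer_predict(layer: LaminarLayer, X_aug: np.ndarray) -> np.ndarray:
    return layer.predict(X_aug)


def gate_samples(
    outputs: np.ndarray,
    rule: ConfidenceRule,
    is_final: bool,
    mode: str = "all_bits",
) -> tuple[np.ndarray, np.ndarray]:
    """Split sample indices into (Y: confident, X: uncertain).

    Non-final layers: under ``all_bits`` (default, the strictest rule) a
    sample is confident iff every bit lies inside the confidence region;
    under ``max_bit`` only its largest bit output must. Final layer:
    everyone is classified, so Y is all samples.
    """
    o = np.atleast_2d(np.asarray(outputs, dtype=float))
    n = o.shape[0]
    if is_final:
        return np.arange(n), np.array([], dtype=int)
    if mode == "max_bit":
        confident = rule.contains(o.max(axis=1))
    else:
        confident = rule.contains(o).all(axis=1)
    return np.flatnonzero(confident), np.flatnonzero(~confident)


def dense_augment(X0: np.ndarray, history: list[np.ndarray]) -> np.ndarray:
    """[X0 | out_1 | ... | out_l]: base features first, then each traversed
    layer's averaged B-vector outputs in order."""
    X0 = np.asarray(X0, dtype=float)
    for h in history:
        if np.asarray(h).shape[0] != X0.shape[0]:
            raise ValueError("history rows misaligned with base matrix")
    if not history:
        return X0
    return np.hstack([X0] + [np.asarray(h, dtype=float) for h in history])


@dataclass
class SampleRouting:
    """Training-time routing record: which layer each sample exited at and
    its averaged output at every layer it traversed."""

    exit_layer: np.ndarray  # (n,), 1-based
    layer_outputs: list[dict[int, np.ndarray]]  # per layer: sample -> B-vector

    def uncertain_counts(self) -> list[int]:
        """Size of set X entering each layer (layer 1 sees everyone)."""
        n = self.exit_layer.size
        counts = [n]
        for l in range(1, int(self.exit_layer.max())):
            counts.append(int(np.sum(self.exit_layer > l)))
        return counts


@dataclass
class LaminarModel:
    layers: list[LaminarLayer]
    codebook: BinaryTaskCodebook
    base_input_dim: int
    config: LaminarConfig
    layer_weights_: np.ndarray

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(class indices, combined B-vector y_f per sample).

        Each sample flows through layers until gated confident or the final
        layer; y_f is the traversed-prefix triangular-weighted mean of its
        layer outputs (weights renormalised to sum 1), and the class is the
        nearest codebook code.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.base_input_dim:
            raise ValueError(
                f"input width {X.shape[1] if X.ndim == 2 else 'n/a'}, "
                f"model expects {self.base_input_dim}"
            )
        n = X.shape[0]
        B = self.codebook.num_bits
        rule = self.config.confidence
        nominal_final = self.config.num_layers

        y_f = np.zeros((n, B))
        weight_sum = np.zeros(n)
        active = np.arange(n)
        history: list[np.ndarray] = []  # outputs for currently active samples
        for li, layer in enumerate(self.layers, start=1):
            X_aug = dense_augment(X[active], history)
            out = layer.predict(X_aug)
            w = self.layer_weights_[li - 1]
            y_f[active] += w * out
            weight_sum[active] += w
            is_final = li == nominal_final or li == len(self.layers)
            conf, unc = gate_samples(out, rule, is_final, self.config.gate_mode)
            if unc.size == 0:
                break
            aug_out = (layer.forest_outputs(X_aug)
                       if self.config.augment_per_forest else out)
            history = [h[unc] for h in history] + [aug_out[unc]]
            active = active[unc]
        # renormalise the traversed prefix so y_f is a convex combination
        y_f /= weight_sum[:, None]
        return self.codebook.decode(y_f), y_f

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "lacfnforest-model",
            "version": 1,
            "base_input_dim": self.base_input_dim,
            "num_classes": self.codebook.num_classes,
            "config": {
                "num_layers": self.config.num_layers,
                "k_base": self.config.k_base,
                "widening": self.config.widening,
                "gate_mode": self.config.gate_mode,
                "augment_per_forest": self.config.augment_per_forest,
                "confidence": {
                    "intervals": [list(iv) for iv in
                                  self.config.confidence.intervals],
                    "final_threshold": self.config.confidence.final_threshold,
                },
                "seed": self.config.seed,
            },
            "layer_weights": self.layer_weights_.tolist(),
            "layers": [
                {"layer_index": L.layer_index,
                 "forests": [f.to_dict() for f in L.forests]}
                for L in self.layers
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "LaminarModel":
        if d.get("format") != "lacfnforest-model":
            raise ValueError("not a laminar model record")
        cfgd = d["config"]
        cfg = LaminarConfig(
            num_layers=cfgd["num_layers"],
            k_base=cfgd["k_base"],
            widening=cfgd["widening"],
            gate_mode=cfgd.get("gate_mode", "all_bits"),
            augment_per_forest=cfgd.get("augment_per_forest", False),
            confidence=ConfidenceRule(
                tuple(tuple(iv) for iv in cfgd["confidence"]["intervals"]),
                cfgd["confidence"]["final_threshold"],
            ),
            seed=cfgd.get("seed", 0),
        )
        layers = [
            LaminarLayer([DFNForestModel.from_dict(f) for f in L["forests"]],
                         L["layer_index"])
            for L in d["layers"]
        ]
        return cls(layers, build_codebook(int(d["num_classes"])),
                   int(d["base_input_dim"]), cfg,
                   np.asarray(d["layer_weights"], dtype=float))

    @classmethod
    def from_json(cls, text: str) -> "LaminarModel":
        return cls.from_dict(json.loads(text))


def train_laminar(
    X: np.ndarray,
    y: np.ndarray,
    cfg: LaminarConfig | None = None,
    evo_cfg: EvolutionConfig | None = None,
    pso_cfg: PSOConfig | None = None,
) -> tuple[LaminarModel, SampleRouting]:
    """Train the full laminar ensemble.

    Layer l holds ``cfg.layer_width(l)`` DFNForests with grammars assigned
    round-robin; it trains only on the samples still uncertain after layer
    l-1's gating, on densely augmented inputs. Routing of the training
    samples is recorded and returned alongside the model.
    """
    cfg = cfg or LaminarConfig()
    evo_cfg = evo_cfg or EvolutionConfig()
    pso_cfg = pso_cfg or PSOConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = X.shape[0]
    M = int(y.max()) + 1
    if M < 2:
        raise ValueError("need at least 2 classes")
    cb = build_codebook(M)
    weights = layer_weights(cfg.num_layers)
    rule = cfg.confidence

    layers: list[LaminarLayer] = []
    exit_layer = np.zeros(n, dtype=int)
    layer_outputs: list[dict[int, np.ndarray]] = []
    active = np.arange(n)
    history: list[np.ndarray] = []

    for li in range(1, cfg.num_layers + 1):
        if active.size == 0:
            logger.info("all samples confident after layer %d; stopping", li - 1)
            break
        if li > 1 and active.size < 10:
            # too few uncertain samples to fit another layer; they exit at the
            # last trained layer (the final gate classifies everyone)
            logger.info(
                "only %d uncertain samples before layer %d; stopping",
                active.size, li,
            )
            break
        X_aug = dense_augment(X[active], history)
        y_act = y[active]
        if np.unique(y_act).size < 2:
            logger.warning(
                "layer %d sees a single class among uncertain samples; "
                "training without stratification", li
            )
        forests = []
        for fi in range(cfg.layer_width(li)):
            fs = cfg.function_sets[fi % len(cfg.function_sets)]
            forests.append(
                train_cascade(
                    X_aug, y_act, fs, evo_cfg, pso_cfg,
                    val_fraction=cfg.val_fraction,
                    max_levels=cfg.max_cascade_levels,
                    seed=cfg.seed + 104729 * li + 1299709 * fi,
                    codebook=cb,
                )
            )
        layer = LaminarLayer(forests, li)
        layers.append(layer)
        out = layer.predict(X_aug)
        layer_outputs.append({int(s): out[k] for k, s in enumerate(active)})
        is_final = li == cfg.num_layers
        conf, unc = gate_samples(out, rule, is_final, cfg.gate_mode)
        exit_layer[active[conf]] = li
        aug_out = layer.forest_outputs(X_aug) if cfg.augment_per_forest else out
        history = [h[unc] for h in history] + [aug_out[unc]]
        active = active[unc]

    exit_layer[exit_layer == 0] = len(layers)  # safety; final gate clears all
    model = LaminarModel(layers, cb, X.shape[1], cfg, weights)
    return model, SampleRouting(exit_layer, layer_outputs)


def predict_laminar(model: LaminarModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return model.predict(X)
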