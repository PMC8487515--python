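"""Flexible neural trees: representation, evaluation, fitness.

A flexible neural tree (FNT) is a tree-shaped neural network. Internal
("flexible neuron") nodes of arity M compute ``sigma(sum_j w_j * I_j + theta)``
over their M children; leaves emit a single input feature. The set of allowed
arities (the *function set*, e.g. ``{+2,+3,+4}``) together with the input
features (the *terminal set*) form the grammar alphabet from which structures
are evolved. Because any node may take a leaf as a child, cross-layer
connections between inputs and deep neurons arise naturally from the grammar.

Evaluation is vectorised over samples: every node maps an ``(n, d)`` matrix to
an ``(n,)`` output vector, so fitness over a whole training set is one
recursive pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

import numpy as np
from scipy.special import expit


class Activation(str, Enum):
    """Neuron activation. All experiments use the logistic sigmoid; the
    gaussian (unit width/centre) and relu variants are pluggable stubs."""

    LOGISTIC = "logistic"
    GAUSSIAN = "gaussian"
    RELU = "relu"

    def __call__(self, x: np.ndarray) -> np.ndarray:
        if self is Activation.LOGISTIC:
            return expit(x)
        if self is Activation.GAUSSIAN:
            return np.exp(-np.square(x))
        return np.maximum(0.0, x)


@dataclass(frozen=True)
class FunctionSet:
    """Allowed flexible-neuron arities, e.g. ``FunctionSet((2, 3, 4), "F1")``."""

    arities: tuple[int, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.arities:
            raise ValueError("function set must be non-empty")
        if any(a < 2 for a in self.arities):
            raise ValueError("all arities must be >= 2")
        object.__setattr__(self, "arities", tuple(sorted(set(self.arities))))


#: The four grammars used to diversify forests across laminar layers.
F1 = FunctionSet((2, 3, 4), "F1")
F2 = FunctionSet((2, 3, 5), "F2")
F3 = FunctionSet((2, 4, 5), "F3")
F4 = FunctionSet((3, 4, 5), "F4")
DEFAULT_FUNCTION_SETS: tuple[FunctionSet, ...] = (F1, F2, F3, F4)


@dataclass
class FNTNode:
    """One tree node: a flexible neuron (``kind="function"``) or an input
    feature leaf (``kind="leaf"``)."""

    kind: str
    feature_index: int = -1
    weights: np.ndarray | None = None
    bias: float = 0.0
    children: list["FNTNode"] = field(default_factory=list)

    @property
    def arity(self) -> int:
        return len(self.children)

    def validate(self, input_dim: int, arities: tuple[int, ...]) -> None:
        if self.kind == "leaf":
            if not (0 <= self.feature_index < input_dim):
                raise ValueError(
                    f"leaf feature index {self.feature_index} outside [0, {input_dim})"
                )
            if self.children:
                raise ValueError("leaf node must have no children")
            return
        if self.kind != "function":
            raise ValueError(f"unknown node kind {self.kind!r}")
        if self.arity not in arities:
            raise ValueError(f"function node arity {self.arity} not in {arities}")
        if self.weights is None or len(self.weights) != self.arity:
            raise ValueError("function node needs one weight per child")
        for c in self.children:
            c.validate(input_dim, arities)

    def copy(self) -> "FNTNode":
        if self.kind == "leaf":
            return FNTNode("leaf", feature_index=self.feature_index)
        return FNTNode(
            "function",
            weights=np.array(self.weights, dtype=float),
            bias=float(self.bias),
            children=[c.copy() for c in self.children],
        )


def leaf(feature_index: int) -> FNTNode:
    return FNTNode("leaf", feature_index=feature_index)


def neuron(weights, bias: float, children: list[FNTNode]) -> FNTNode:
    return FNTNode(
        "function", weights=np.asarray(weights, dtype=float), bias=float(bias),
        children=children,
    )


@dataclass
class FlexibleNeuralTree:
    """An evolved tree over ``input_dim`` features; the forest base learner.

    ``fitness`` caches the last RMSE assigned by the evolution loop (lower is
    better); it is metadata, not part of the function the tree computes.
    """

    root: FNTNode
    input_dim: int
    function_set: FunctionSet
    activation: Activation = Activation.LOGISTIC
    fitness: float | None = None

    def __post_init__(self) -> None:
        if self.root.kind != "function":
            raise ValueError("tree root must be a function node")
        self.root.validate(self.input_dim, self.function_set.arities)

    # -- structure ---------------------------------------------------------

    def nodes(self) -> Iterator[FNTNode]:
        """Pre-order traversal."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def depth(self) -> int:
        def _d(n: FNTNode) -> int:
            if not n.children:
                return 1
            return 1 + max(_d(c) for c in n.children)

        return _d(self.root)

    def n_nodes(self) -> int:
        return sum(1 for _ in self.nodes())

    def copy(self) -> "FlexibleNeuralTree":
        return FlexibleNeuralTree(
            self.root.copy(), self.input_dim, self.function_set,
            self.activation, self.fitness,
        )

    # -- parameters (flattened view used by the particle swarm) ------------

    def get_params(self) -> np.ndarray:
        """Flatten all weights and biases, pre-order, weights before bias."""
        parts: list[np.ndarray] = []
        for n in self._preorder_functions():
            parts.append(np.asarray(n.weights, dtype=float))
            parts.append(np.array([n.bias]))
        return np.concatenate(parts)

    def set_params(self, theta: np.ndarray) -> None:
        theta = np.asarray(theta, dtype=float)
        i = 0
        for n in self._preorder_functions():
            m = n.arity
            n.weights = theta[i : i + m].copy()
            n.bias = float(theta[i + m])
            i += m + 1
        if i != theta.size:
            raise ValueError(f"parameter vector length {theta.size}, expected {i}")
        self.fitness = None

    def n_params(self) -> int:
        return sum(n.arity + 1 for n in self._preorder_functions())

    def _preorder_functions(self) -> list[FNTNode]:
        return [n for n in self.nodes() if n.kind == "function"]


def evaluate_tree(tree: FlexibleNeuralTree, x: np.ndarray) -> float | np.ndarray:
    """Evaluate bottom-up: leaves emit features, neurons apply
    ``sigma(w . children + theta)``. Accepts one sample (``(d,)`` -> scalar)
    or a batch (``(n, d)`` -> ``(n,)``)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != tree.input_dim:
        raise ValueError(
            f"input has {X.shape[1]} features, tree expects {tree.input_dim}"
        )
    out = _eval_node(tree.root, X, tree.activation)
    return float(out[0]) if single else out


def _eval_node(node: FNTNode, X: np.ndarray, act: Activation) -> np.ndarray:
    if node.kind == "leaf":
        return X[:, node.feature_index]
    z = np.full(X.shape[0], node.bias)
    for w, child in zip(node.weights, node.children):
        z += w * _eval_node(child, X, act)
    return act(z)


def tree_fitness(tree: FlexibleNeuralTree, X: np.ndarray, y: np.ndarray) -> float:
    """Root-mean-square error between targets and tree outputs; the evolution
    objective (smaller is better)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("cannot score a tree on zero samples")
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y disagree on sample count")
    out = evaluate_tree(tree, X)
    return float(np.sqrt(np.mean(np.square(y - out))))


def used_features(tree: FlexibleNeuralTree) -> set[int]:
    """Feature indices the tree actually reads — evolved trees select a sparse
    subset of the inputs."""
    return {n.feature_index for n in tree.nodes() if n.kind == "leaf"}


# -- serialization ----------------------------------------------------------

def _node_to_dict(node: FNTNode) -> dict:
    if node.kind == "leaf":
        return {"kind": "leaf", "feature_index": node.feature_index}
    return {
        "kind": "function",
        "weights": [float(w) for w in node.weights],
        "bias": node.bias,
        "children": [_node_to_dict(c) for c in node.children],
    }


def _node_from_dict(d: dict) -> FNTNode:
    try:
        if d["kind"] == "leaf":
            return FNTNode("leaf", feature_index=int(d["feature_index"]))
        return FNTNode(
            "function",
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d["bias"]),
            children=[_node_from_dict(c) for c in d["children"]],
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed tree record: {exc}") from exc


def tree_to_dict(tree: FlexibleNeuralTree) -> dict:
    return {
        "input_dim": tree.input_dim,
        "function_set": {"arities": list(tree.function_set.arities),
                         "name": tree.function_set.name},
        "activation": tree.activation.value,
        "fitness": tree.fitness,
        "root": _node_to_dict(tree.root),
    }


def tree_from_dict(d: dict) -> FlexibleNeuralTree:
    try:
        fs = FunctionSet(tuple(d["function_set"]["arities"]),
                         d["function_set"].get("name", ""))
        return FlexibleNeuralTree(
            _node_from_dict(d["root"]),
            int(d["input_dim"]),
            fs,
            Activation(d.get("activation", "logistic")),
            d.get("fitness"),
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed tree record: {exc}") from exc


def serialize_tree(tree: FlexibleNeuralTree) -> str:
    """JSON text record; round-trips structure and parameters exactly."""
    return json.dumps(tree_to_dict(tree))


def deserialize_tree(text: str) -> FlexibleNeuralTree:
    try:
        d = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed tree record: {exc}") from exc
    return tree_from_dict(d)
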