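"""Synthetic expression-like data with known structure.

Real subtype-classification inputs are continuous expression matrices with
far more genes than samples (d of a few thousand, n of a few hundred), a few
classes separated by mean shifts on a minority of informative genes, plus
noise and scattered missing values. The generator emulates exactly that with
class-conditional Gaussians: each class gets a random +/- effect-size pattern
over the informative genes, all other genes are pure noise, and missingness
is injected uniformly at random. A log-normal mode produces positive,
pre-normalisation values to exercise the preprocessing path.

It makes no attempt to mimic real subtype biology or gene-gene correlation;
what it supports is controlled, seeded testing of every pipeline stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionMatrix, LabelVector
from .laminar import ConfidenceRule


@dataclass
class SyntheticSpec:
    n_samples: int = 200
    n_genes: int = 3000
    n_classes: int = 4
    n_informative: int = 30
    effect_size: float = 2.0  # class mean shift, in noise-SD units
    noise_sd: float = 1.0
    missing_rate: float = 0.02
    class_proportions: tuple[float, ...] | None = None
    lognormal: bool = False  # positive raw-scale values (pre-normalisation)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative cannot exceed n_genes")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.class_proportions is not None:
            p = np.asarray(self.class_proportions, dtype=float)
            if p.size != self.n_classes or not np.isclose(p.sum(), 1.0):
                raise ValueError("class_proportions must sum to 1, one per class")
        if self.n_samples < self.n_classes:
            raise ValueError("need at least one sample per class")


def generate_classification_data(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, LabelVector, dict]:
    """Draw a (matrix, labels, truth) triple.

    The truth record lists the informative gene ids, the per-class mean
    patterns, and the seed — enough to check that trained models concentrate
    on the informative genes.
    """
    rng = np.random.default_rng(spec.seed)
    n, d, M = spec.n_samples, spec.n_genes, spec.n_classes

    props = (
        np.asarray(spec.class_proportions, dtype=float)
        if spec.class_proportions is not None
        else np.full(M, 1.0 / M)
    )
    counts = np.floor(props * n).astype(int)
    while counts.sum() < n:  # distribute rounding remainder
        counts[int(np.argmin(counts / np.maximum(props, 1e-12)))] += 1
    y = np.repeat(np.arange(M), counts)
    rng.shuffle(y)

    info = np.sort(rng.choice(d, size=spec.n_informative, replace=False))
    # one random +/- effect pattern per class over the informative genes
    patterns = rng.choice([-1.0, 1.0], size=(M, spec.n_informative))
    means = np.zeros((M, d))
    means[:, info] = spec.effect_size * patterns

    values = means[y] + rng.normal(0.0, spec.noise_sd, size=(n, d))
    if spec.lognormal:
        values = np.exp(values)

    mask = np.zeros((n, d), dtype=bool)
    if spec.missing_rate > 0:
        mask = rng.random((n, d)) < spec.missing_rate
        values = values.copy()
        values[mask] = np.nan

    width_s = max(4, len(str(n)))
    width_g = max(5, len(str(d)))
    sample_ids = [f"S{i:0{width_s}d}" for i in range(n)]
    gene_ids = [f"G{j:0{width_g}d}" for j in range(d)]
    class_names = [f"subtype{c}" for c in range(M)]

    matrix = ExpressionMatrix(sample_ids, gene_ids, values, mask)
    labels = LabelVector(sample_ids, [class_names[c] for c in y], class_names)
    truth = {
        "informative_gene_ids": [gene_ids[j] for j in info],
        "informative_indices": info.tolist(),
        "class_patterns": patterns.tolist(),
        "effect_size": spec.effect_size,
        "seed": spec.seed,
    }
    return matrix, labels, truth


def worked_example_fixture() -> tuple[np.ndarray, ConfidenceRule]:
    """The canonical single-bit gating example: five first-layer outputs and
    the default confidence region [0, 0.1] u [0.9, 1] with final threshold
    0.5. Gating must send {0.07, 0.95} to the confident set Y and the other
    three to the uncertain set X."""
    outputs = np.array([0.07, 0.35, 0.52, 0.83, 0.95])
    return outputs, ConfidenceRule(((0.0, 0.1), (0.9, 1.0)), 0.5)
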