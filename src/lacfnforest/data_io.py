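"""Expression-matrix I/O and preprocessing.

The pipeline applied to raw expression tables is the standard one for
high-dimensional, small-sample transcriptomics: drop samples with excessive
missingness (strictly more than 20% missing by default), fill the remaining
gaps by k-nearest-neighbour imputation over samples, then z-score each gene,

    f_tilde = (f - E(f)) / sqrt(Var(f)),

with the population variance (divide by n), so every gene has mean 0 and unit
variance going into the classifier.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

#: Cell contents treated as missing (case-insensitive); empty cells also count.
NA_TOKENS = frozenset({"", "na", "nan", "null"})


class Orientation(str, Enum):
    SAMPLES_IN_ROWS = "samples-in-rows"
    GENES_IN_ROWS = "genes-in-rows"


class ZeroVariancePolicy(str, Enum):
    SET_ZERO = "set_zero"
    DROP_GENE = "drop_gene"


@dataclass
class PreprocessConfig:
    missingness_threshold: float = 0.20
    knn_k: int = 5
    zero_variance_policy: ZeroVariancePolicy = ZeroVariancePolicy.SET_ZERO

    def __post_init__(self) -> None:
        if not 0.0 <= self.missingness_threshold <= 1.0:
            raise ValueError("missingness_threshold must lie in [0, 1]")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        self.zero_variance_policy = ZeroVariancePolicy(self.zero_variance_policy)


@dataclass
class ExpressionMatrix:
    """Samples x genes numeric table with an explicit missing-value mask.

    ``values`` is ``(n, d)`` float; masked cells hold NaN. Canonical
    orientation is samples in rows (n << d in this domain, and rows per
    sample make cross-validation splits natural).
    """

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, d = self.values.shape
        if len(self.sample_ids) != n or len(self.gene_ids) != d:
            raise ValueError("ids do not match matrix shape")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.gene_ids)) != d:
            raise ValueError("duplicate gene ids")
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape mismatch")
        observed = self.values[~self.missing_mask]
        if observed.size and not np.all(np.isfinite(observed)):
            raise ValueError("non-finite value in an observed (unmasked) cell")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        vals = self.values.copy()
        vals[self.missing_mask] = np.nan
        return pd.DataFrame(vals, index=self.sample_ids, columns=self.gene_ids)


@dataclass
class LabelVector:
    """Per-sample class labels with an explicit ordered class universe."""

    sample_ids: list[str]
    labels: list[str]
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("sample_ids and labels must align")
        if not self.class_names:
            self.class_names = sorted(set(self.labels))
        unknown = set(self.labels) - set(self.class_names)
        if unknown:
            raise ValueError(f"labels not in class_names: {sorted(unknown)}")
        if len(self.class_names) < 2:
            raise ValueError("need at least 2 classes")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def as_indices(self) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.class_names)}
        return np.array([lut[l] for l in self.labels], dtype=int)

    def aligned_to(self, m: ExpressionMatrix) -> "LabelVector":
        """Reorder to match an expression matrix's samples (error on mismatch)."""
        lut = dict(zip(self.sample_ids, self.labels))
        missing = [s for s in m.sample_ids if s not in lut]
        if missing:
            raise ValueError(f"samples without labels: {missing[:5]}")
        return LabelVector(list(m.sample_ids), [lut[s] for s in m.sample_ids],
                           list(self.class_names))


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","


def read_expression_matrix(
    path: str | Path,
    orientation: Orientation | str = Orientation.SAMPLES_IN_ROWS,
) -> ExpressionMatrix:
    """Read a delimited expression table (header row + one id column).

    ``orientation`` declares how the file is laid out; the returned matrix is
    always samples-in-rows. Empty cells and the tokens NA/NaN/null
    (case-insensitive) are flagged missing; any other non-numeric cell is a
    parse error naming the offending row and column.
    """
    path = Path(path)
    orientation = Orientation(orientation)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty file")
    sep = _sep_for(path)
    header = text.splitlines()[0].split(sep)[1:]
    if len(set(header)) != len(header):
        raise ValueError(f"{path}: duplicate ids in header")
    df = pd.read_csv(io.StringIO(text), sep=sep, index_col=0,
                     dtype=str, keep_default_na=False)
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate ids in id column")
    if df.shape[1] == 0:
        raise ValueError(f"{path}: malformed header (no data columns)")
    if orientation is Orientation.GENES_IN_ROWS:
        df = df.T

    values = np.empty(df.shape, dtype=float)
    mask = np.zeros(df.shape, dtype=bool)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j].strip()
            if cell.lower() in NA_TOKENS:
                values[i, j] = np.nan
                mask[i, j] = True
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at sample "
                    f"{df.index[i]!r}, gene {df.columns[j]!r}"
                ) from None
    return ExpressionMatrix(
        [str(s) for s in df.index], [str(g) for g in df.columns], values, mask
    )


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Write samples-in-rows CSV/TSV; masked cells become 'NA'."""
    path = Path(path)
    m.to_dataframe().to_csv(path, sep=_sep_for(path), na_rep="NA",
                            index_label="sample_id")


def read_labels(path: str | Path) -> LabelVector:
    """Read a two-column (sample_id,label) CSV."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns sample_id,label")
    return LabelVector(df.iloc[:, 0].tolist(), df.iloc[:, 1].tolist())


def write_labels(lv: LabelVector, path: str | Path) -> None:
    pd.DataFrame({"sample_id": lv.sample_ids, "label": lv.labels}).to_csv(
        path, index=False
    )


def filter_samples_by_missingness(
    m: ExpressionMatrix, cfg: PreprocessConfig | None = None
) -> ExpressionMatrix:
    """Drop samples with strictly more than ``missingness_threshold`` of their
    genes missing (a sample at exactly the threshold is retained)."""
    cfg = cfg or PreprocessConfig()
    frac = m.missing_mask.mean(axis=1)
    keep = frac <= cfg.missingness_threshold
    if not keep.any():
        raise ValueError(
            "every sample exceeds the missingness threshold; dataset unusable"
        )
    idx = np.flatnonzero(keep)
    return ExpressionMatrix(
        [m.sample_ids[i] for i in idx], list(m.gene_ids),
        m.values[idx], m.missing_mask[idx],
    )


def impute_knn(
    m: ExpressionMatrix, cfg: PreprocessConfig | None = None
) -> ExpressionMatrix:
    """Fill missing cells with the gene-wise mean over the k nearest samples.

    Distance between two samples is Euclidean over their mutually observed
    genes, scaled by sqrt(d / n_shared) so samples sharing few genes are not
    spuriously close. Only neighbours observed for the target gene are
    candidates; k is clamped to the number available. Observed cells are
    never altered.
    """
    cfg = cfg or PreprocessConfig()
    if not m.missing_mask.any():
        return m
    X = m.values.copy()
    mask = m.missing_mask
    n, d = X.shape

    all_missing = np.flatnonzero(mask.all(axis=0))
    if all_missing.size:
        raise ValueError(
            f"gene(s) missing in every sample: "
            f"{[m.gene_ids[g] for g in all_missing[:5]]}"
        )

    obs = ~mask
    Xz = np.where(obs, X, 0.0)
    # pairwise squared distances over shared genes, scaled by coverage
    shared = obs.astype(float) @ obs.T.astype(float)
    sq = (
        (Xz**2 * obs) @ obs.T.astype(float)
        + obs.astype(float) @ (Xz**2 * obs).T
        - 2.0 * Xz @ Xz.T
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        dist2 = np.where(shared > 0, sq * (d / shared), np.inf)
    np.fill_diagonal(dist2, np.inf)

    out = X.copy()
    for i, j in zip(*np.nonzero(mask)):
        donors = np.flatnonzero(obs[:, j])
        order = donors[np.argsort(dist2[i, donors], kind="stable")]
        k = min(cfg.knn_k, order.size)
        if k == 0:
            raise ValueError(f"no donor sample observed for gene {m.gene_ids[j]!r}")
        out[i, j] = X[order[:k], j].mean()
    return ExpressionMatrix(
        list(m.sample_ids), list(m.gene_ids), out,
        np.zeros_like(mask, dtype=bool),
    )


def zscore_normalize(
    m: ExpressionMatrix, cfg: PreprocessConfig | None = None
) -> ExpressionMatrix:
    """Per-gene z-score with population variance: (f - mean) / std.

    Zero-variance genes are set to all-zero columns (``set_zero``, keeps the
    feature space stable across folds) or removed (``drop_gene``).
    """
    cfg = cfg or PreprocessConfig()
    if m.missing_mask.any():
        raise ValueError("normalize requires a fully imputed matrix")
    mu = m.values.mean(axis=0)
    sd = m.values.std(axis=0)  # population (ddof=0)
    const = sd == 0.0
    if cfg.zero_variance_policy is ZeroVariancePolicy.DROP_GENE:
        keep = np.flatnonzero(~const)
        vals = (m.values[:, keep] - mu[keep]) / sd[keep]
        return ExpressionMatrix(
            list(m.sample_ids), [m.gene_ids[g] for g in keep], vals,
            np.zeros_like(vals, dtype=bool),
        )
    safe_sd = np.where(const, 1.0, sd)
    vals = (m.values - mu) / safe_sd
    vals[:, const] = 0.0
    return ExpressionMatrix(
        list(m.sample_ids), list(m.gene_ids), vals,
        np.zeros_like(vals, dtype=bool),
    )


def preprocess(
    m: ExpressionMatrix, cfg: PreprocessConfig | None = None
) -> ExpressionMatrix:
    """filter -> impute -> normalize, the full pipeline."""
    cfg = cfg or PreprocessConfig()
    return zscore_normalize(impute_knn(filter_samples_by_missingness(m, cfg), cfg), cfg)
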