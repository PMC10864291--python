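"""Expression-matrix containers, delimited-text I/O and stratified partitioning.

The canonical in-memory orientation is samples x genes (rows = samples); readers
transpose gene-major files on load. Labels are arbitrary two-valued strings on
disk and are mapped to integer codes {0, 1} with the lexicographically smaller
string becoming 0, so the mapping is deterministic without configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "ExpressionDataset",
    "FoldPartition",
    "read_expression",
    "write_expression",
    "stratified_split",
    "stratified_kfold",
]


@dataclass
class ExpressionDataset:
    """A two-class expression matrix with sample and gene annotations.

    Parameters
    ----------
    values
        Real matrix of shape (n_samples, n_genes).
    gene_ids, sample_ids
        Unique identifiers for columns and rows respectively.
    labels
        Integer class codes in {0, 1}, one per sample.
    label_names
        Optional mapping from code to the original string label.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self, require_two_classes: bool = False) -> None:
        n, g = self.values.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValidationError(
                f"sample annotation length mismatch: {n} rows, "
                f"{len(self.sample_ids)} sample_ids, {len(self.labels)} labels"
            )
        if len(self.gene_ids) != g:
            raise ValidationError(
                f"gene annotation length mismatch: {g} columns, {len(self.gene_ids)} gene_ids"
            )
        if len(set(self.gene_ids)) != g:
            raise ValidationError("duplicate gene_ids")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample_ids")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("labels must be coded in {0, 1}")
        if require_two_classes and len(np.unique(self.labels)) != 2:
            raise ValidationError("exactly two label classes required")

    # -- convenience --------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def class_counts(self) -> dict[int, int]:
        codes, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(codes.tolist(), counts.tolist()))

    def subset_samples(self, indices: np.ndarray) -> "ExpressionDataset":
        indices = np.asarray(indices, dtype=int)
        return ExpressionDataset(
            values=self.values[indices],
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in indices],
            labels=self.labels[indices],
            label_names=dict(self.label_names),
        )

    def subset_genes(self, mask: np.ndarray) -> "ExpressionDataset":
        """Restrict to the genes where ``mask`` (bool or 0/1 vector) is set."""
        mask = np.asarray(mask).astype(bool)
        if mask.shape != (self.n_genes,):
            raise ValidationError(
                f"gene mask length {mask.shape} does not match gene count {self.n_genes}"
            )
        keep = np.flatnonzero(mask)
        return ExpressionDataset(
            values=self.values[:, keep],
            gene_ids=[self.gene_ids[i] for i in keep],
            sample_ids=list(self.sample_ids),
            labels=self.labels.copy(),
            label_names=dict(self.label_names),
        )


@dataclass
class FoldPartition:
    """Assignment of each sample to one of ``k`` stratified cross-validation folds."""

    fold_assignments: np.ndarray
    k: int
    seed: int

    def __post_init__(self) -> None:
        self.fold_assignments = np.asarray(self.fold_assignments, dtype=int)
        if self.k < 2:
            raise ValidationError("k must be >= 2")
        if self.fold_assignments.min(initial=0) < 0 or self.fold_assignments.max(initial=0) >= self.k:
            raise ValidationError("fold indices must lie in [0, k)")

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignments != fold)

    def iter_folds(self, ds: ExpressionDataset) -> Iterator[tuple[ExpressionDataset, ExpressionDataset]]:
        """Yield (train, test) dataset pairs for each fold in order."""
        for f in range(self.k):
            yield ds.subset_samples(self.train_indices(f)), ds.subset_samples(self.test_indices(f))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def _map_labels(raw: list[str]) -> tuple[np.ndarray, dict[int, str]]:
    classes = sorted(set(raw))
    if len(classes) != 2:
        raise ValidationError(
            f"expected exactly 2 label classes, found {len(classes)}: {classes[:5]}"
        )
    mapping = {classes[0]: 0, classes[1]: 1}
    codes = np.array([mapping[v] for v in raw], dtype=int)
    return codes, {0: classes[0], 1: classes[1]}


def _coerce_numeric(df: pd.DataFrame) -> np.ndarray:
    out = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            row = df.index[int(np.flatnonzero(bad.to_numpy())[0])]
            raise ParseError(
                f"non-numeric expression value at row '{row}', column '{col}': "
                f"{df[col][bad].iloc[0]!r}"
            )
        out[:, j] = converted.to_numpy()
    return out


def read_labels(path: str | Path) -> list[str]:
    """Read a one-label-per-line text file."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return [ln for ln in lines if ln]


def read_expression(
    path: str | Path,
    orientation: str = "genes_as_rows",
    label_source: str | Path | None = None,
    delimiter: str | None = None,
) -> ExpressionDataset:
    """Read a delimited expression matrix plus two-class labels.

    ``label_source`` is either a path to a one-column label file, or — when
    ``orientation="samples_as_rows"`` — the name of a label column inside the
    matrix file. The first column of the matrix file always holds identifiers.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    if orientation not in ("genes_as_rows", "samples_as_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    sep = _infer_delimiter(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows: pandas names the line
        raise ParseError(f"malformed delimited file {path}: {exc}") from exc

    label_col_values: list[str] | None = None
    if (
        orientation == "samples_as_rows"
        and label_source is not None
        and str(label_source) in df.columns
    ):
        label_col_values = [str(v) for v in df.pop(str(label_source)).tolist()]

    values = _coerce_numeric(df)
    if orientation == "genes_as_rows":
        gene_ids = [str(i) for i in df.index]
        sample_ids = [str(c) for c in df.columns]
        values = values.T
    else:
        sample_ids = [str(i) for i in df.index]
        gene_ids = [str(c) for c in df.columns]

    if label_col_values is not None:
        raw_labels = label_col_values
    elif label_source is not None:
        raw_labels = read_labels(label_source)
    else:
        raise ValidationError("label_source is required")
    if len(raw_labels) != len(sample_ids):
        raise ValidationError(
            f"label count {len(raw_labels)} does not match sample count {len(sample_ids)}"
        )
    labels, label_names = _map_labels(raw_labels)
    return ExpressionDataset(values, gene_ids, sample_ids, labels, label_names)


def write_expression(
    ds: ExpressionDataset,
    matrix_path: str | Path,
    labels_path: str | Path | None = None,
    orientation: str = "genes_as_rows",
    delimiter: str | None = None,
) -> None:
    """Write the matrix (and optionally labels) as delimited text.

    Floats are written with ``repr`` precision so a read-back round-trips
    exactly.
    """
    matrix_path = Path(matrix_path)
    sep = _infer_delimiter(matrix_path, delimiter)
    if orientation == "genes_as_rows":
        df = pd.DataFrame(ds.values.T, index=ds.gene_ids, columns=ds.sample_ids)
        df.index.name = "gene_id"
    elif orientation == "samples_as_rows":
        df = pd.DataFrame(ds.values, index=ds.sample_ids, columns=ds.gene_ids)
        df.index.name = "sample_id"
    else:
        raise ValidationError(f"unknown orientation {orientation!r}")
    df.to_csv(matrix_path, sep=sep)
    if labels_path is not None:
        names = ds.label_names or {0: "0", 1: "1"}
        Path(labels_path).write_text("\n".join(names[int(c)] for c in ds.labels) + "\n")


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------

def stratified_split(
    ds: ExpressionDataset, train_fraction: float, seed: int
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Stratified train/test split.

    Per class the train side receives ``floor(train_fraction * class_size)``
    samples; the remainder goes to test. Deterministic given ``seed``; sample
    order within each side follows the original dataset order.
    """
    if not (0.0 < train_fraction <= 1.0):
        raise ValidationError("train_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for code in sorted(np.unique(ds.labels)):
        members = np.flatnonzero(ds.labels == code)
        if members.size < 1:
            raise ValidationError(f"class {code} is empty")
        perm = rng.permutation(members)
        n_train = math.floor(train_fraction * members.size)
        train_idx.extend(perm[:n_train].tolist())
        test_idx.extend(perm[n_train:].tolist())
    return ds.subset_samples(np.sort(train_idx)), ds.subset_samples(np.sort(test_idx))


def stratified_kfold(ds: ExpressionDataset, k: int, seed: int) -> FoldPartition:
    """Stratified k-fold partition: per-class fold sizes differ by at most 1."""
    if k < 2:
        raise ValidationError("k must be >= 2")
    rng = np.random.default_rng(seed)
    assignments = np.full(ds.n_samples, -1, dtype=int)
    for code in sorted(np.unique(ds.labels)):
        members = np.flatnonzero(ds.labels == code)
        if members.size < k:
            raise ValidationError(
                f"class {code} has {members.size} samples, fewer than k={k}"
            )
        perm = rng.permutation(members)
        base, extra = divmod(members.size, k)
        start = 0
        for f in range(k):
            size = base + (1 if f < extra else 0)
            assignments[perm[start : start + size]] = f
            start += size
    return FoldPartition(assignments, k=k, seed=seed)
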