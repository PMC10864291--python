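"""Per-gene Z-score normalization with fit/apply separation.

Statistics are fitted on training data and then applied to both sides of a
split, so test samples never leak into the scaling. The standard deviation is
the population one (divisor n) by default; ``ddof=1`` switches to the sample
convention. Zero-variance genes are mapped to 0 rather than raising, since
constant genes carry no class information.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset
from .errors import ValidationError

__all__ = ["NormalizationStats", "zscore_fit", "zscore_apply", "zscore_fit_apply"]


@dataclass
class NormalizationStats:
    """Per-gene location/scale estimates used for Z-scoring."""

    gene_ids: list[str]
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        g = len(self.gene_ids)
        if self.mean.shape != (g,) or self.sd.shape != (g,):
            raise ValidationError("mean/sd length must equal gene count")
        if (self.sd < 0).any():
            raise ValidationError("standard deviations must be non-negative")

    def save(self, path: str | Path) -> None:
        df = pd.DataFrame({"gene_id": self.gene_ids, "mean": self.mean, "sd": self.sd})
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "NormalizationStats":
        df = pd.read_csv(path, sep="\t")
        return cls(
            gene_ids=[str(g) for g in df["gene_id"]],
            mean=df["mean"].to_numpy(float),
            sd=df["sd"].to_numpy(float),
        )


def zscore_fit(ds: ExpressionDataset, ddof: int = 0) -> NormalizationStats:
    """Estimate per-gene mean and standard deviation (population sd by default)."""
    if ds.n_samples < 2:
        raise ValidationError("z-score fitting needs at least 2 samples")
    mean = ds.values.mean(axis=0)
    sd = ds.values.std(axis=0, ddof=ddof)
    return NormalizationStats(list(ds.gene_ids), mean, sd)


def zscore_apply(ds: ExpressionDataset, stats: NormalizationStats) -> ExpressionDataset:
    """Transform each cell to (v - mean) / sd; zero-variance genes map to 0."""
    if list(ds.gene_ids) != list(stats.gene_ids):
        raise ValidationError("gene_ids of dataset and stats do not match in order")
    sd = stats.sd.copy()
    zero = sd == 0
    sd[zero] = 1.0
    values = (ds.values - stats.mean) / sd
    values[:, zero] = 0.0
    return ExpressionDataset(
        values=values,
        gene_ids=list(ds.gene_ids),
        sample_ids=list(ds.sample_ids),
        labels=ds.labels.copy(),
        label_names=dict(ds.label_names),
    )


def zscore_fit_apply(
    train: ExpressionDataset, *others: ExpressionDataset, ddof: int = 0
) -> tuple[ExpressionDataset, ...]:
    """Fit on ``train`` and apply the same statistics to train and all ``others``."""
    stats = zscore_fit(train, ddof=ddof)
    return tuple(zscore_apply(d, stats) for d in (train, *others))
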