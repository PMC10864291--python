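"""Seeded generator of two-class microarray-like datasets with planted signal.

The generator emulates the shape of a classic bulk lung-cancer microarray
cohort: two unbalanced classes (defaults 86 tumor vs 70 normal samples),
thousands of genes, and a small planted subset of informative genes whose
class-1 mean is shifted by ``effect_size`` standard deviations. Non-planted
genes are pure Gaussian noise, identical across classes. Informative genes
can share an equicorrelated Gaussian factor (``block_corr``), mimicking
co-regulated gene blocks. Baseline expression is 0 before normalization;
Z-scoring makes any constant baseline irrelevant downstream.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .datasets import ExpressionDataset, write_expression
from .errors import ValidationError

__all__ = ["SyntheticSpec", "generate", "write_synthetic"]


@dataclass
class SyntheticSpec:
    """Generative parameters for a planted two-class expression dataset.

    ``effect_size`` is the class-1 mean shift of each planted gene in units of
    ``noise_sd``; ``block_corr`` is the pairwise correlation within the
    planted block.
    """

    n_class0: int = 70
    n_class1: int = 86
    n_genes: int = 2000
    n_informative: int = 20
    effect_size: float = 1.0
    noise_sd: float = 1.0
    block_corr: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_class0, self.n_class1) < 1:
            raise ValidationError("class sizes must be positive")
        if self.n_genes < 1 or not (1 <= self.n_informative <= self.n_genes):
            raise ValidationError("need 1 <= n_informative <= n_genes")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if not (0.0 <= self.block_corr < 1.0):
            raise ValidationError("block_corr must lie in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        return cls(**d)


def generate(spec: SyntheticSpec) -> tuple[ExpressionDataset, np.ndarray]:
    """Draw one dataset; returns it with the 0/1 truth vector of planted genes.

    Deterministic given ``spec.seed``. Class-0 samples come first, then
    class-1; planted gene positions are a seeded draw without replacement.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_class0 + spec.n_class1
    g = spec.n_genes
    planted = np.sort(rng.choice(g, size=spec.n_informative, replace=False))
    truth = np.zeros(g, dtype=np.int8)
    truth[planted] = 1

    values = rng.normal(0.0, spec.noise_sd, size=(n, g))
    if spec.block_corr > 0:
        # equicorrelated block via a shared per-sample factor (Gaussian copula)
        z_common = rng.normal(0.0, 1.0, size=n)
        z_ind = rng.normal(0.0, 1.0, size=(n, spec.n_informative))
        block = np.sqrt(spec.block_corr) * z_common[:, None] + np.sqrt(
            1.0 - spec.block_corr
        ) * z_ind
        values[:, planted] = spec.noise_sd * block
    labels = np.concatenate(
        [np.zeros(spec.n_class0, dtype=int), np.ones(spec.n_class1, dtype=int)]
    )
    values[np.ix_(labels == 1, planted)] += spec.effect_size * spec.noise_sd

    sample_ids = [f"S{i:04d}" for i in range(n)]
    gene_ids = [f"G{j:05d}" for j in range(g)]
    ds = ExpressionDataset(
        values=values,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        labels=labels,
        label_names={0: "normal", 1: "tumor"},
    )
    return ds, truth


def write_synthetic(
    spec: SyntheticSpec, out_dir: str | Path
) -> tuple[ExpressionDataset, np.ndarray]:
    """Generate and write matrix/labels/truth plus a manifest with checksums."""
    import hashlib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds, truth = generate(spec)
    matrix = out / "expression.tsv"
    labels = out / "labels.txt"
    truth_path = out / "truth.txt"
    write_expression(ds, matrix, labels, orientation="genes_as_rows")
    truth_path.write_text("\n".join(str(int(b)) for b in truth) + "\n")
    manifest = {
        "spec": spec.to_dict(),
        "seed": spec.seed,
        "files": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in (matrix, labels, truth_path)
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return ds, truth
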