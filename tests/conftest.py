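import numpy as np
import pytest

from cuckoonet import ExpressionDataset, SyntheticSpec, generate


@pytest.fixture
def tiny_ds() -> ExpressionDataset:
    """Six samples, four genes, handcrafted values; classes 3/3."""
    values = np.array(
        [
            [1.0, 10.0, 0.0, 5.0],
            [2.0, 20.0, 0.0, 5.0],
            [3.0, 30.0, 0.0, 5.0],
            [4.0, 40.0, 1.0, 5.0],
            [5.0, 50.0, 1.0, 5.0],
            [6.0, 60.0, 1.0, 5.0],
        ]
    )
    return ExpressionDataset(
        values=values,
        gene_ids=["g1", "g2", "g3", "g4"],
        sample_ids=[f"s{i}" for i in range(6)],
        labels=np.array([0, 0, 0, 1, 1, 1]),
        label_names={0: "normal", 1: "tumor"},
    )


@pytest.fixture
def planted_ds():
    """Separable planted dataset: 20+20 samples, 30 genes, 6 informative."""
    spec = SyntheticSpec(
        n_class0=20, n_class1=20, n_genes=30, n_informative=6, effect_size=3.0, seed=7
    )
    return generate(spec)


@pytest.fixture
def kentridge_shaped_ds():
    """Class sizes matching the real cohort (86 tumor / 70 normal), few genes."""
    spec = SyntheticSpec(
        n_class0=70, n_class1=86, n_genes=50, n_informative=5, effect_size=1.0, seed=3
    )
    ds, _ = generate(spec)
    return ds
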