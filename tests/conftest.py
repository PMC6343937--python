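import numpy as np
import pandas as pd
import pytest

from sstrans.datasets import CONTROL, DISEASE, ExpressionDataset


def make_dataset(values, genes, samples, labels, species="mouse", name="toy"):
    """Build an ExpressionDataset from plain lists."""
    df = pd.DataFrame(np.asarray(values, dtype=float), index=genes, columns=samples)
    lab = pd.Series(labels, index=samples)
    return ExpressionDataset(values=df, labels=lab, species=species, name=name)


@pytest.fixture
def tiny_dataset():
    """3 genes x 4 samples, both classes present."""
    return make_dataset(
        [[1.0, 2.0, 3.0, 4.0],
         [4.0, 3.0, 2.0, 1.0],
         [0.5, 0.5, 2.5, 2.5]],
        genes=["Arg1", "Lcn2", "Xist"],
        samples=["s1", "s2", "s3", "s4"],
        labels=[CONTROL, CONTROL, DISEASE, DISEASE])


@pytest.fixture
def planted_dataset():
    """200 genes, first 20 informative with class-mean shift 2.0, n=40."""
    rng = np.random.default_rng(7)
    n_genes, n = 200, 40
    y = np.array([0] * 20 + [1] * 20)
    vals = rng.normal(size=(n_genes, n))
    vals[:20, :] += 2.0 * y[None, :]
    genes = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    samples = [f"s{i:02d}" for i in range(n)]
    labels = [CONTROL if v == 0 else DISEASE for v in y]
    return make_dataset(vals, genes, samples, labels), set(genes[:20])
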