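import numpy as np
import pandas as pd
import pytest

from cernet.io import ExpressionMatrix


def make_matrix(values: np.ndarray, classes, prefix="F", samples=None):
    """ExpressionMatrix helper: rows get ids F001.., classes cycles/maps."""
    n, s = values.shape
    ids = [f"{prefix}{i:03d}" for i in range(n)]
    if isinstance(classes, str):
        class_map = {f: classes for f in ids}
    else:
        class_map = {f: c for f, c in zip(ids, classes)}
    cols = samples or [f"S{j:03d}" for j in range(s)]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=ids, columns=cols),
        feature_class=class_map,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_matrices(rng):
    """Disjoint miRNA / lncRNA / mRNA matrices over shared samples."""
    n_samples = 20
    mi = make_matrix(rng.standard_normal((4, n_samples)), "miRNA", prefix="MI")
    lnc = make_matrix(rng.standard_normal((5, n_samples)), "lncRNA", prefix="LNC")
    m = make_matrix(rng.standard_normal((6, n_samples)), "mRNA", prefix="M")
    return mi, lnc, m
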