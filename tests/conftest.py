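import warnings

import numpy as np
import pandas as pd
import pytest

import rccsig as r


@pytest.fixture
def tiny_matrix():
    return r.ExpressionMatrix(
        gene_symbols=["TP53", "VHL", "MET"],
        sample_ids=["s1", "s2"],
        values=np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One microarray-like cohort at the default study conditions."""
    cfg = r.SyntheticConfig(seed=7)
    matrix, ann, markers = r.generate_cohort(cfg)
    return matrix, ann, markers


@pytest.fixture(scope="session")
def harmonized_cohort(default_cohort):
    """Default cohort, quantile-normalized, batch-adjusted and z-scored."""
    matrix, ann, markers = default_cohort
    q = r.quantile_normalize(matrix)
    adj, _ = r.combat_adjust(q, ann)
    z = r.zscore_genes(adj)
    labels = ann.labels_for(matrix.sample_ids)
    return z, labels, markers


@pytest.fixture(scope="session")
def trained_signature(harmonized_cohort):
    z, labels, markers = harmonized_cohort
    return r.select_signature(z, labels, k=10)


def separable_cohort(seed=0, n_per_class=12, n_classes=3, n_genes=30, delta=6.0):
    """Small, cleanly separable multi-class cohort for exactness checks."""
    rng = np.random.default_rng(seed)
    classes = [f"c{i}" for i in range(n_classes)]
    genes = [f"G{i:03d}" for i in range(n_genes)]
    labels, cols = [], []
    for ci, cls in enumerate(classes):
        mean = np.zeros(n_genes)
        mean[ci * 3:(ci + 1) * 3] = delta
        for _ in range(n_per_class):
            cols.append(mean + rng.normal(0, 0.5, n_genes))
            labels.append(cls)
    matrix = r.ExpressionMatrix(genes, [f"s{i}" for i in range(len(cols))],
                                np.array(cols).T)
    return matrix, np.array(labels, dtype=object)


@pytest.fixture
def no_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
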