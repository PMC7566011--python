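import numpy as np
import pandas as pd
import pytest

import treevote as tv
from treevote.synthetic import GroundTruth


@pytest.fixture(scope="session")
def small_dataset():
    """A small but fully structured synthetic cohort shared across tests."""
    return tv.simulate(
        n_genes=300,
        n_informative=10,
        n_redundant=20,
        n_major=120,
        n_minor=30,
        effect_size=2.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def preprocessed_small(small_dataset):
    matrix, _ = tv.preprocess(small_dataset.matrix, seed=1)
    return matrix


@pytest.fixture()
def make_truth():
    """Factory for a bare ground truth with random subtype assignments."""

    def _make(n_tumor, k=3, seed=0):
        rng = np.random.default_rng(seed)
        labs = rng.integers(1, k + 1, size=n_tumor)
        return GroundTruth(
            informative_gene_ids={"g1"},
            redundant_map={},
            subtype_of_sample={f"T{i:04d}": int(l) for i, l in enumerate(labs)},
            enriched_mutation_genes={},
            direction={},
            mutation_gene_ids=[f"m{i:03d}" for i in range(30)],
        )

    return _make


@pytest.fixture()
def labeled_matrix():
    """Tiny handmade labeled matrix for exact-value tests."""

    def _make(values, tumor_cols, gene_ids=None):
        values = np.asarray(values, dtype=float)
        n_genes, n_samples = values.shape
        gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
        sample_ids = [f"s{j}" for j in range(n_samples)]
        labels = pd.Series(
            ["tumor" if j in tumor_cols else "normal" for j in range(n_samples)],
            index=sample_ids,
        )
        return tv.ExpressionMatrix(
            pd.DataFrame(values, index=gene_ids, columns=sample_ids), labels
        )

    return _make
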