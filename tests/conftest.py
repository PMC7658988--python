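import numpy as np
import pytest

from chromclust import (
    CorrelationFilterParams,
    Embedding,
    QCParams,
    adjusted_rand_index,
    filter_cells,
    filter_features,
    normalize,
    planted_benchmark,
    run_pca,
)
from chromclust.reduce import correlation_threshold, filter_uncorrelated


@pytest.fixture
def two_blob_embedding() -> Embedding:
    """20 cells in two tight, well-separated blobs in 5-D score space."""
    rng = np.random.default_rng(42)
    blob1 = np.array([10.0, 0.0, 5.0, -3.0, 1.0]) + rng.normal(0, 0.05, size=(10, 5))
    blob2 = np.array([-8.0, 6.0, -5.0, 2.0, -4.0]) + rng.normal(0, 0.05, size=(10, 5))
    scores = np.vstack([blob1, blob2])
    ids = [f"cell{i}" for i in range(20)]
    return Embedding(scores, np.ones(5), ids, ["s1"] * 20)


@pytest.fixture(scope="session")
def benchmark400():
    """Planted four-population benchmark run through QC, PCA and filtering.

    400 cells (100 per population), 2000 bins, enrichment ratio 20 —
    processed once per session; downstream stages are cheap enough to
    recompute per test.
    """
    matrix, labels, ann, sets, profiles = planted_benchmark(seed=1234)
    params = QCParams()
    filtered, _ = filter_cells(matrix, params)
    filtered = filter_features(filtered, params)
    x = normalize(filtered)
    e = run_pca(x, 50)
    t = correlation_threshold(e, CorrelationFilterParams(seed=5), x)
    kept_ids, _ = filter_uncorrelated(e, t, 1.0)
    kept = [e.cell_ids.index(c) for c in kept_ids]
    e_kept = e.subset_cells(kept)
    x_kept = normalize(filtered.subset_cells(kept))
    truth = dict(zip(labels["cell_id"], labels["population"]))
    return {
        "matrix": filtered,
        "labels": labels,
        "annotation": ann,
        "gene_sets": sets,
        "profiles": profiles,
        "normalized": x_kept,
        "embedding": e_kept,
        "truth": [truth[c] for c in e_kept.cell_ids],
    }


def majority_population(truth, labels, cluster):
    """The most common ground-truth population inside one cluster."""
    members = [t for t, l in zip(truth, labels) if l == cluster]
    return max(set(members), key=members.count)


@pytest.fixture
def ari():
    return adjusted_rand_index
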