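"""Partition-quality and composition metrics for benchmarking clusterings."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2, fisher_exact
from sklearn.metrics import adjusted_rand_score

from .errors import ValidationError

__all__ = [
    "adjusted_rand_index",
    "assignment_scores",
    "composition_chisq",
    "fisher_exact_2x2",
]


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected agreement between two partitions of the same cells.

    1 for identical partitions, ~0 for independent ones; invariant to
    relabeling of either argument.
    """
    a, b = list(a), list(b)
    if len(a) != len(b):
        raise ValidationError(f"partitions differ in length ({len(a)} vs {len(b)})")
    return float(adjusted_rand_score(a, b))


def assignment_scores(samples, clusters) -> pd.DataFrame:
    """Fraction of each sample's cells landing in each cluster.

    Rows are samples, columns clusters; each row sums to 1.
    """
    samples, clusters = list(samples), list(clusters)
    if len(samples) != len(clusters):
        raise ValidationError("samples and clusters differ in length")
    table = pd.crosstab(pd.Series(samples, name="sample"), pd.Series(clusters, name="cluster"))
    return table.div(table.sum(axis=1), axis=0)


def composition_chisq(observed, expected_fractions) -> float:
    """Pearson chi-squared goodness-of-fit p-value, no continuity correction.

    Tests whether the sample composition of one cluster departs from the
    overall sample fractions; df = number of samples - 1.
    """
    obs = np.asarray(observed, dtype=float)
    frac = np.asarray(expected_fractions, dtype=float)
    if obs.shape != frac.shape:
        raise ValidationError("observed and expected_fractions differ in shape")
    if not np.isclose(frac.sum(), 1.0):
        raise ValidationError("expected fractions must sum to 1")
    total = obs.sum()
    if total <= 0:
        raise ValidationError("observed total must be positive")
    if np.any((frac == 0) & (obs > 0)):
        raise ValidationError("nonzero observation with zero expected fraction")
    keep = frac > 0
    expected = total * frac[keep]
    stat = float(np.sum((obs[keep] - expected) ** 2 / expected))
    df = keep.sum() - 1
    return float(chi2.sf(stat, df))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 contingency table.

    Two-sided rule: sum of probabilities of all tables with the same
    margins at most as probable as the observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t != np.floor(t)) or np.any(t < 0):
            raise ValidationError("counts must be nonnegative integers")
        t = t.astype(int)
    return float(fisher_exact(t, alternative="two-sided")[1])
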