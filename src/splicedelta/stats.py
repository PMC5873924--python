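"""Shared statistical primitives.

Every two-group comparison in the pipeline uses the same two-sided Welch
(unequal-variance) t-test.  With n = 3 biological replicates per group there
is no basis for assuming equal variances, and Welch is the robust default.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["welch_ttest", "welch_ttest_rows"]


def welch_ttest(a, b) -> tuple[float, float]:
    """Two-sided Welch t-test; returns (t, p).

    Degenerate inputs are resolved conservatively: if both groups have zero
    variance and equal means there is no evidence of a difference and p is 1;
    if both have zero variance but different means, p is 0 (an infinite t).
    """
    t, p = _welch(np.asarray(a, float)[None, :], np.asarray(b, float)[None, :])
    return float(t[0]), float(p[0])


def welch_ttest_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t-test for (n_features, n_replicates) matrices."""
    return _welch(np.asarray(a, float), np.asarray(b, float))


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("Welch t-test needs at least 2 replicates per group")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.asarray(t, float).copy()
    p = np.asarray(p, float).copy()
    # zero variance in both groups: scipy yields nan
    same = np.isnan(p) & np.isclose(a.mean(axis=1), b.mean(axis=1))
    diff = np.isnan(p) & ~same
    t[same], p[same] = 0.0, 1.0
    t[diff] = np.where(a.mean(axis=1)[diff] > b.mean(axis=1)[diff], np.inf, -np.inf)
    p[diff] = 0.0
    return t, p
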