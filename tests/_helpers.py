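"""Shared oracles for the test suite."""

import math

import numpy as np

from mdtfit.elicit import _bounds_from_choices

# closed-form mean of the uniform distribution on the n=3 ordering cone
# (expected order statistics of a flat Dirichlet): (11/18, 5/18, 2/18)
CONE3_MEAN = np.array([11 / 18, 5 / 18, 1 / 9])


def batch_means_se(X, n_batches=50):
    """MC standard error of a chain mean via batch means (handles autocorrelation)."""
    batches = np.array_split(X, n_batches)
    means = np.array([b.mean(axis=0) for b in batches])
    return means.std(axis=0, ddof=1) / np.sqrt(n_batches)


def n2_intervals(records):
    """Per-respondent censoring interval for the first component of an
    n=2 weight vector, replayed from the response records."""
    intervals = []
    for r in records:
        i, j = r.ranking
        if r.choices:
            b = _bounds_from_choices((i, j), r.choices[0])
            lo, hi = b.lower, b.upper
        else:
            lo, hi = 1.0, math.inf
        wi = (lo / (1 + lo), 1.0 if math.isinf(hi) else hi / (1 + hi))
        intervals.append(wi if i == 0 else (1 - wi[1], 1 - wi[0]))
    return np.array(intervals)
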