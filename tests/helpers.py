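"""Independent oracles used by the tests.

These deliberately re-derive quantities by brute force (exhaustive grids,
full enumeration) rather than calling the library code they check.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import gammaln


def loglogistic_grid_oracle(
    doses,
    n,
    k,
    c: float = 0.0,
    n_slopes: int = 401,
    n_centers: int = 1201,
    slope_range=(0.1, 10.0),
    center_range=(-1.0, 2.0),
):
    """Exhaustive grid search of the binomial log-likelihood.

    Model: deaths ~ Binomial(n, c + (1-c) / (1 + exp(-s*(log10 d - m)))).
    Returns (max log-likelihood, best slope, best log10 LD50).
    """
    doses = np.asarray(doses, dtype=float)
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    slopes = np.exp(np.linspace(np.log(slope_range[0]), np.log(slope_range[1]), n_slopes))
    centers = np.linspace(center_range[0], center_range[1], n_centers)
    x = np.log10(doses)
    S, M = np.meshgrid(slopes, centers, indexing="ij")
    z = S[..., None] * (x[None, None, :] - M[..., None])
    p = c + (1.0 - c) / (1.0 + np.exp(-z))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    ll = (k * np.log(p) + (n - k) * np.log1p(-p)).sum(axis=-1)
    ll += float((gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)).sum())
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    return float(ll[i, j]), float(slopes[i]), float(centers[j])


def exact_ranksum_p(a, b) -> float:
    """Two-sided rank-sum p-value by full enumeration of group assignments.

    Enumerates every C(n_a + n_b, n_a) split of the pooled sample and counts
    splits whose rank sum is at least as extreme (two-sided, by distance from
    the mean rank sum) as the observed one. Tie-free data only.
    """
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    assert len(set(pooled)) == len(pooled), "enumeration oracle requires tie-free data"
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    n_a = len(a)
    observed = sum(ranks[v] for v in a)
    mean = n_a * (len(pooled) + 1) / 2.0
    count = total = 0
    for combo in itertools.combinations(pooled, n_a):
        s = sum(ranks[v] for v in combo)
        total += 1
        if abs(s - mean) >= abs(observed - mean) - 1e-9:
            count += 1
    return count / total
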