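"""Independent oracles used by the tests.

Everything here is written from first principles (enumeration, closed
forms, dense numerical integration) and deliberately avoids the package's
own code paths, so agreement is evidence of correctness rather than
self-consistency.
"""

import math

import numpy as np
from scipy import stats


def brute_force_auc(values, labels) -> float:
    """AUC by enumerating every (positive, negative) pair."""
    values = np.asarray(values, float)
    labels = np.asarray(labels, int)
    pos = values[labels == 1]
    neg = values[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_force_roc_points(values, labels):
    """(threshold, se, fpr) for every candidate threshold, >=-positive."""
    values = np.asarray(values, float)
    labels = np.asarray(labels, int)
    pos = values[labels == 1]
    neg = values[labels == 0]
    points = []
    for t in [math.inf] + sorted(set(values), reverse=True):
        se = float(np.mean(pos >= t))
        fpr = float(np.mean(neg >= t))
        points.append((t, se, fpr))
    return points


def hand_cell_probability(pi, se, sp, cov_se, cov_sp, i, j, k) -> float:
    """One latent class cell probability evaluated term by term."""
    d = 1.0 if i == j else -1.0
    dis = (se[0] ** i * (1 - se[0]) ** (1 - i)
           * se[1] ** j * (1 - se[1]) ** (1 - j) + d * cov_se)
    dis *= se[2] ** k * (1 - se[2]) ** (1 - k)
    hea = ((1 - sp[0]) ** i * sp[0] ** (1 - i)
           * (1 - sp[1]) ** j * sp[1] ** (1 - j) + d * cov_sp)
    hea *= (1 - sp[2]) ** k * sp[2] ** (1 - k)
    return pi * dis + (1 - pi) * hea


def grid_posterior_median(counts_row, prior_ab, se, sp, cov_se, cov_sp,
                          n_grid=20001) -> float:
    """Posterior median of one population's prevalence by dense integration,
    with all test parameters fixed."""
    grid = np.linspace(1e-5, 1 - 1e-5, n_grid)
    ll = np.empty(n_grid)
    for g_idx, g in enumerate(grid):
        cells = [hand_cell_probability(g, se, sp, cov_se, cov_sp,
                                       (c >> 2) & 1, (c >> 1) & 1, c & 1)
                 for c in range(8)]
        ll[g_idx] = float(np.dot(counts_row, np.log(cells)))
    lp = ll + stats.beta.logpdf(grid, *prior_ab)
    w = np.exp(lp - lp.max())
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    return float(np.interp(0.5, cdf, grid))


def beta_cdf_integer(x: float, a: int, b: int) -> float:
    """Beta(a, b) CDF for integer parameters via the binomial-tail identity:
    F(x; a, b) = P(Binomial(a+b-1, x) >= a)."""
    n = a + b - 1
    return float(sum(math.comb(n, k) * x**k * (1 - x) ** (n - k)
                     for k in range(a, n + 1)))
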