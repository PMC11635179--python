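"""Independent brute-force oracles used only by the tests.

These re-derive every statistic from first principles (explicit pairwise
set enumeration, raw normal equations) without touching the package's
own computation paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_incidence_partition(presence) -> tuple[float, float, float]:
    """(β_SOR, β_SIM, β_SNE) by enumerating every time pair from raw sets."""
    sets = [frozenset(np.flatnonzero(row).tolist()) for row in np.asarray(presence, bool)]
    T = len(sets)
    sum_min = sum_max = 0
    for i, j in itertools.combinations(range(T), 2):
        b_ij = len(sets[i] - sets[j])
        b_ji = len(sets[j] - sets[i])
        sum_min += min(b_ij, b_ji)
        sum_max += max(b_ij, b_ji)
    pooled = frozenset().union(*sets) if sets else frozenset()
    excess = sum(len(s) for s in sets) - len(pooled)
    sor_den = 2 * excess + sum_min + sum_max
    sim_den = excess + sum_min
    sor = (sum_min + sum_max) / sor_den if sor_den else 0.0
    sim = sum_min / sim_den if sim_den else 0.0
    return sor, sim, sor - sim


def brute_bray_curtis_partition(x) -> tuple[float, float, float]:
    """(BC_total, BC_bal, BC_gra) by explicit pairwise enumeration."""
    x = np.asarray(x, float)
    T = x.shape[0]
    sum_a = sum_min = sum_max = 0.0
    for i, j in itertools.combinations(range(T), 2):
        a = float(np.minimum(x[i], x[j]).sum())
        b_ij = float(x[i].sum()) - a
        b_ji = float(x[j].sum()) - a
        sum_a += a
        sum_min += min(b_ij, b_ji)
        sum_max += max(b_ij, b_ji)
    tot_den = 2 * sum_a + sum_min + sum_max
    bal_den = sum_a + sum_min
    total = (sum_min + sum_max) / tot_den if tot_den else 0.0
    bal = sum_min / bal_den if bal_den else 0.0
    return total, bal, total - bal


def brute_ols(y, X):
    """Normal-equations OLS: (coefficients, residuals, loglik) with an
    intercept prepended."""
    y = np.asarray(y, float)
    n = y.size
    Xd = np.column_stack([np.ones(n), np.asarray(X, float)]) if np.size(X) \
        else np.ones((n, 1))
    beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
    resid = y - Xd @ beta
    sigma2 = resid @ resid / n                      # Gaussian MLE variance
    loglik = -n / 2 * (math.log(2 * math.pi * sigma2) + 1)
    return beta, resid, loglik


def brute_aicc(loglik: float, n: int, k: int) -> float:
    aic = -2 * loglik + 2 * k
    return aic + 2 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0 else math.inf
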