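"""Independent brute-force oracles used by the tests.

Deliberately written in plain Python loops and sets, sharing no code
with the package implementation.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np


def naive_rank_row(scores_row):
    """Label -> rank (1-based), descending score, ties by ascending index."""
    order = sorted(range(len(scores_row)), key=lambda j: (-scores_row[j], j))
    return {j: pos + 1 for pos, j in enumerate(order)}


def naive_metrics(Y, scores, Yhat):
    """All six measures via direct set/rank enumeration.

    Returns NaN for a ranking measure with no qualifying rows.
    """
    Y = [list(map(int, row)) for row in Y]
    Yhat = [list(map(int, row)) for row in Yhat]
    scores = [list(map(float, row)) for row in scores]
    n, L = len(Y), len(Y[0])
    ap, cov, rl, oe, acc, ham = [], [], [], [], [], []
    for i in range(n):
        pos = {j for j in range(L) if Y[i][j] == 1}
        neg = set(range(L)) - pos
        rank = naive_rank_row(scores[i])
        if pos:
            terms = []
            for q in pos:
                above = sum(1 for p in pos if rank[p] <= rank[q])
                terms.append(above / rank[q])
            ap.append(sum(terms) / len(pos))
            cov.append(max(rank[p] for p in pos) - 1)
            top = min(range(L), key=lambda j: rank[j])
            oe.append(0.0 if top in pos else 1.0)
        if pos and neg:
            bad = sum(
                1 for p in pos for q in neg if scores[i][p] <= scores[i][q]
            )
            rl.append(bad / (len(pos) * len(neg)))
        pred = {j for j in range(L) if Yhat[i][j] == 1}
        union = pred | pos
        acc.append(len(pred & pos) / len(union) if union else 1.0)
        ham.append(len(pred ^ pos) / L)
    mean = lambda xs: sum(xs) / len(xs) if xs else math.nan
    return {
        "average_precision": mean(ap),
        "coverage": mean(cov),
        "ranking_loss": mean(rl),
        "one_error": mean(oe),
        "accuracy": mean(acc),
        "hamming_loss": mean(ham),
    }


def naive_hsic(K, U):
    """Empirical HSIC by explicit double-centering and summation."""
    K = np.asarray(K, dtype=float)
    U = np.asarray(U, dtype=float)
    n = K.shape[0]
    H = np.eye(n) - np.ones((n, n)) / n
    M = H @ U @ H
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += K[i, j] * M[j, i]
    return total / n**2


def grid_search_simplex(a, nu1, step=0.01):
    """Exhaustive minimizer of -a.beta + nu1*||beta||^2 on the simplex grid."""
    a = np.asarray(a, dtype=float)
    P = len(a)
    steps = int(round(1.0 / step))
    best_beta, best_obj = None, np.inf
    if P == 1:
        return np.array([1.0])
    if P == 2:
        grid = (np.array([i, steps - i]) for i in range(steps + 1))
    elif P == 3:
        grid = (
            np.array([i, j, steps - i - j])
            for i in range(steps + 1)
            for j in range(steps + 1 - i)
        )
    else:
        raise ValueError("grid oracle supports P <= 3")
    for counts in grid:
        beta = counts / steps
        obj = -float(a @ beta) + nu1 * float(beta @ beta)
        if obj < best_obj:
            best_obj, best_beta = obj, beta
    return best_beta


def random_psd(rng, n, rank=None):
    A = rng.normal(size=(n, rank or n))
    return A @ A.T


def all_binary_matrices(n, L):
    """Every {0,1} matrix of shape (n, L)."""
    for bits in product((0, 1), repeat=n * L):
        yield np.array(bits, dtype=int).reshape(n, L)
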