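"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the incremental caching, vectorization, and library
shortcuts of the package code so they can serve as oracles.
"""

from itertools import combinations

import numpy as np


def nnls_by_enumeration(C: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Exact NNLS via exhaustive enumeration of active sets (small n_types only).

    For every support pattern, solve the unconstrained least squares on that
    support; among supports whose solution is nonnegative, return the one with
    the smallest residual.
    """
    n_t = C.shape[1]
    best = (np.inf, np.zeros(n_t))
    for k in range(n_t + 1):
        for support in combinations(range(n_t), k):
            d = np.zeros(n_t)
            if support:
                sol, *_ = np.linalg.lstsq(C[:, support], e, rcond=None)
                if (sol < -1e-12).any():
                    continue
                d[list(support)] = np.clip(sol, 0.0, None)
            resid = float(((e - C @ d) ** 2).sum())
            if resid < best[0] - 1e-15:
                best = (resid, d)
    return best[1]


def mrmr_stepwise(C_rows: np.ndarray, gene_ids: list[str], n: int) -> list[str]:
    """Greedy mRMR re-implemented without incremental caching.

    At each step, recompute relevance and redundancy from scratch for every
    remaining gene and pick the argmax (ties to the first gene id in sorted
    order).
    """
    order = sorted(range(len(gene_ids)), key=lambda i: gene_ids[i])
    rows = C_rows[order]
    ids = [gene_ids[i] for i in order]
    selected: list[int] = []
    for _ in range(n):
        best = None
        for i in range(len(ids)):
            if i in selected:
                continue
            F = float(np.var(rows[i], ddof=1))
            if selected:
                cs = []
                for j in selected:
                    a, b = rows[i], rows[j]
                    if a.std() == 0 or b.std() == 0:
                        cs.append(0.0)
                    else:
                        cs.append(abs(float(np.corrcoef(a, b)[0, 1])))
                redund = max(sum(cs) / len(cs), 1e-12)
            else:
                redund = 1.0
            v = F / redund
            if best is None or v > best[0] + 1e-15:
                best = (v, i)
        selected.append(best[1])
    return [ids[i] for i in selected]


def noise_scores_full_resolve(C: np.ndarray, E: np.ndarray) -> np.ndarray:
    """Sequential incremental-MSE gene noise scores via full lstsq re-solves."""
    n_g = C.shape[0]
    scores = np.empty(n_g)
    prev = float((E ** 2).sum())
    for i in range(n_g):
        rows = list(range(i + 1))
        D_hat, *_ = np.linalg.lstsq(C[rows], E[rows], rcond=None)
        mse = float(((E - C @ D_hat) ** 2).sum())
        scores[i] = mse - prev
        prev = mse
    return scores


def pearson_one_pass(x: np.ndarray, y: np.ndarray) -> float:
    """Direct one-pass Pearson correlation."""
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    num = n * sxy - sx * sy
    den = np.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return float(num / den)


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS coefficients (intercept first) by explicitly solving X'X b = X'y."""
    A = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(A.T @ A, A.T @ y)


def intersection_sorted_merge(a: list[str], b: list[str]) -> int:
    """Set intersection size via an explicit sorted merge."""
    sa, sb = sorted(set(a)), sorted(set(b))
    i = j = count = 0
    while i < len(sa) and j < len(sb):
        if sa[i] == sb[j]:
            count += 1
            i += 1
            j += 1
        elif sa[i] < sb[j]:
            i += 1
        else:
            j += 1
    return count
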