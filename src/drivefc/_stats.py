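"""Rank-correlation primitives shared by feature screening and model scoring.

Spearman's rho is computed as the Pearson correlation of ranks (average ranks
on ties).  The two-sided p-value of the no-correlation null uses the exact
permutation distribution for tie-free samples of size <= 9 and the classical
t approximation with n - 2 degrees of freedom otherwise.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

import numpy as np
from scipy import stats

EXACT_N_MAX = 9


@lru_cache(maxsize=None)
def _exact_abs_rho_table(n: int) -> np.ndarray:
    """Sorted |rho| over all n! rank permutations (tie-free null)."""
    base = np.arange(n, dtype=np.int64)
    perms = np.array(list(permutations(range(n))), dtype=np.int64)
    s = ((perms - base) ** 2).sum(axis=1)
    rho = 1.0 - 6.0 * s / (n * (n * n - 1))
    return np.sort(np.abs(rho))


def exact_spearman_pvalue(rho, n: int):
    """Two-sided exact p-value(s) for tie-free Spearman rho at sample size n."""
    if n < 2 or n > EXACT_N_MAX:
        raise ValueError(f"exact null tabulated only for 2 <= n <= {EXACT_N_MAX}")
    table = _exact_abs_rho_table(n)
    r = np.atleast_1d(np.asarray(rho, dtype=float))
    k = np.searchsorted(table, np.abs(r) - 1e-12, side="left")
    p = (table.size - k) / table.size
    return p if np.ndim(rho) else float(p[0])


def t_approx_spearman_pvalue(rho, n: int):
    """Two-sided t-approximation p-value(s) for Spearman rho."""
    if n < 4:
        raise ValueError("need n >= 4 for the t approximation")
    r = np.clip(np.atleast_1d(np.asarray(rho, dtype=float)), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.clip(p, 0.0, 1.0)
    return p if np.ndim(rho) else float(p[0])


def spearman_pvalue(rho, n: int, ties: bool = False):
    """Dispatch between the exact (small tie-free n) and t-approximate null."""
    if n <= EXACT_N_MAX and not ties:
        return exact_spearman_pvalue(rho, n)
    return t_approx_spearman_pvalue(rho, n)


def _has_column_ties(ranked: np.ndarray) -> np.ndarray:
    """Per-column tie flag for an (m, k) rank matrix."""
    srt = np.sort(ranked, axis=0)
    return (np.diff(srt, axis=0) == 0).any(axis=0)


def spearman_vector(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and two-sided p of each column of ``X`` against ``y``.

    Zero-variance columns (or a constant ``y``) yield rho = 0, p = 1.

    Parameters
    ----------
    X : (m, k) array
    y : (m,) array

    Returns
    -------
    rho, p : (k,) arrays
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    m = y.shape[0]
    if X.shape[0] != m:
        raise ValueError("X and y have mismatched lengths")
    if m < 3:
        raise ValueError("need at least 3 samples for a correlation")
    rx = stats.rankdata(X, axis=0)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean(axis=0)
    ryc = ry - ry.mean()
    denom_x = np.sqrt((rxc**2).sum(axis=0))
    denom_y = np.sqrt((ryc**2).sum())
    rho = np.zeros(X.shape[1])
    if denom_y > 0:
        ok = denom_x > 0
        rho[ok] = (rxc[:, ok].T @ ryc) / (denom_x[ok] * denom_y)
    rho = np.clip(rho, -1.0, 1.0)

    p = np.ones_like(rho)
    defined = (denom_x > 0) & (denom_y > 0)
    if defined.any():
        if m <= EXACT_N_MAX:
            col_ties = _has_column_ties(rx) | bool(
                (np.diff(np.sort(ry)) == 0).any()
            )
            exact_cols = defined & ~col_ties
            approx_cols = defined & col_ties
            if exact_cols.any():
                p[exact_cols] = exact_spearman_pvalue(rho[exact_cols], m)
            if approx_cols.any():
                p[approx_cols] = t_approx_spearman_pvalue(rho[approx_cols], m)
        else:
            p[defined] = t_approx_spearman_pvalue(rho[defined], m)
    return rho, p


def spearman_scalar(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho between two vectors; 0.0 when either side is constant."""
    rho, _ = spearman_vector(np.asarray(x, dtype=float).reshape(-1, 1), y)
    return float(rho[0])
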