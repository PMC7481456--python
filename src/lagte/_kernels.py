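"""Numba kernels for Chebyshev k-nearest-neighbor statistics on small clouds.

The conditional-mutual-information estimator used throughout the package
needs, for every point i, the distance eps_i to its k-th nearest neighbor
in a joint space and the number of points strictly within eps_i in marginal
subspaces.  The greedy candidate selection evaluates thousands of joint
spaces that differ from an already-characterized base space by one appended
(possibly row-permuted) coordinate, so the base pairwise distances are kept
as dense row-sorted matrices: the k-th-neighbor search walks each sorted
row and stops as soon as the base distance alone exceeds the current k-th
best joint distance, and marginal counts come from binary searches or
bounded walks over the same sorted rows.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def pairwise_chebyshev(Z):
    """Dense pairwise max-coordinate distance matrix of a (n, d) cloud."""
    n, d = Z.shape
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m = 0.0
            for c in range(d):
                v = abs(Z[i, c] - Z[j, c])
                if v > m:
                    m = v
            D[i, j] = m
            D[j, i] = m
    return D


@njit(cache=False)
def abs_diff_matrix(col):
    """Pairwise |c_i - c_j| for a single coordinate."""
    n = col.shape[0]
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = abs(col[i] - col[j])
            A[i, j] = v
            A[j, i] = v
    return A


@njit(cache=False)
def max_update(D, A):
    """In-place D := max(D, A) after a candidate is accepted."""
    n = D.shape[0]
    for i in range(n):
        for j in range(n):
            if A[i, j] > D[i, j]:
                D[i, j] = A[i, j]


@njit(cache=False)
def _kth_insert(best, k, v):
    # insertion into ascending best[:k]; caller checks v < best[k-1]
    pos = k - 1
    while pos > 0 and best[pos - 1] > v:
        best[pos] = best[pos - 1]
        pos -= 1
    best[pos] = v


@njit(cache=False)
def sum_log_kth(D, k):
    """Sum over rows of ln(eps_i); eps_i = k-th smallest off-diagonal entry.

    Returns (sum, n_zero); n_zero counts rows with a zero k-th neighbor
    distance (duplicate points, prevented by the jitter policy).
    """
    n = D.shape[0]
    best = np.empty(k)
    total = 0.0
    n_zero = 0
    for i in range(n):
        for t in range(k):
            best[t] = np.inf
        worst = np.inf
        for j in range(n):
            if j == i:
                continue
            v = D[i, j]
            if v < worst:
                _kth_insert(best, k, v)
                worst = best[k - 1]
        if worst <= 0.0:
            n_zero += 1
        else:
            total += np.log(worst)
    return total, n_zero


@njit(cache=False, fastmath=True)
def walk_kth_eps(Dvals, Didx, cvec, k, eps):
    """Per-row k-th neighbor distance of max(D_ij, |c_i - c_j|).

    Dvals/Didx hold each base row sorted ascending (self included at
    distance 0).  Since the joint distance is bounded below by the base
    distance, the walk stops once the sorted base distance reaches the
    current k-th best.  Fills ``eps``; returns the number of degenerate
    (zero) radii.
    """
    n = Dvals.shape[0]
    best = np.empty(k)
    n_zero = 0
    for i in range(n):
        ci = cvec[i]
        for t in range(k):
            best[t] = np.inf
        worst = np.inf
        filled = 0
        for m in range(n):
            j = Didx[i, m]
            if j == i:
                continue
            dij = Dvals[i, m]
            if dij >= worst:
                break
            a = abs(ci - cvec[j])
            v = dij if dij > a else a
            if v < worst:
                _kth_insert(best, k, v)
                if filled < k:
                    filled += 1
                if filled == k:
                    worst = best[k - 1]
        eps[i] = worst
        if worst <= 0.0 or not np.isfinite(worst):
            n_zero += 1
    return n_zero


@njit(cache=False)
def count_base_lt(Dvals, eps, counts):
    """Per-row count of off-diagonal base distances strictly below eps_i.

    Dvals rows are sorted ascending and include the self distance 0, which
    is excluded from the count.
    """
    n = Dvals.shape[0]
    for i in range(n):
        e = eps[i]
        lo, hi = 0, n
        while lo < hi:
            mid = (lo + hi) // 2
            if Dvals[i, mid] < e:
                lo = mid + 1
            else:
                hi = mid
        counts[i] = lo - 1  # exclude self


@njit(cache=False, fastmath=True)
def count_aug_lt(Dvals, Didx, cvec, eps, counts):
    """Per-row count of j != i with max(D_ij, |c_i - c_j|) < eps_i."""
    n = Dvals.shape[0]
    for i in range(n):
        e = eps[i]
        ci = cvec[i]
        c = 0
        for m in range(n):
            if Dvals[i, m] >= e:
                break
            j = Didx[i, m]
            if j == i:
                continue
            if abs(ci - cvec[j]) < e:
                c += 1
        counts[i] = c


@njit(cache=False)
def count_1d_lt(svals, cvec, eps, counts):
    """Per-row count of j != i with |c_i - c_j| < eps_i (svals = sorted c).

    The predicate |c_i - v| < eps is evaluated exactly (it is monotone in
    v on either side of c_i); forming interval endpoints c_i +- eps would
    round and misclassify neighbors sitting exactly at the shared radius.
    """
    n = svals.shape[0]
    for i in range(n):
        e = eps[i]
        ci = cvec[i]
        # first index with ci - svals[idx] < e
        lo, hi = 0, n
        while lo < hi:
            mid = (lo + hi) // 2
            if ci - svals[mid] < e:
                hi = mid
            else:
                lo = mid + 1
        left = lo
        # first index with svals[idx] - ci >= e
        lo, hi = left, n
        while lo < hi:
            mid = (lo + hi) // 2
            if svals[mid] - ci < e:
                lo = mid + 1
            else:
                hi = mid
        counts[i] = lo - left - 1  # exclude self
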