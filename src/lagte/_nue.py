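"""Greedy non-uniform embedding engine.

Implements the sequential candidate selection behind
:func:`lagte.embedding.select_candidates`: at each round the candidate with
the largest conditional-mutual-information gain

    gain(c) = I(y; c | S) = psi(k) - < psi(n_yS + 1) + psi(n_cS + 1)
                                      - psi(n_S + 1) >

(shared-radius estimator, see :mod:`lagte.estimators`) is proposed, then
gated against a permutation null of its own column.  The gate threshold
corrects for best-of-C selection (the proposed candidate is the maximum
over the remaining candidates): with C remaining candidates of the
winner's own process - the natural question being whether that process
informs the target, at level alpha per process - the acceptance level
per candidate is Sidak-adjusted to (1-alpha)^(1/C), and
the corresponding quantile of the permutation null is evaluated from a
moment fit (mean, SD and a Cornish-Fisher skewness adjustment) of the
``n_shuffles`` permuted gains, since that quantile is not resolvable as a
raw empirical percentile of 100 draws.  The uncorrected
empirical 95th-percentile gate of the toolbox lineage is available as
``gate="per-candidate"``.  An accepted candidate must additionally have a
positive gain.  The first failure terminates selection.

The engine keeps row-sorted pairwise Chebyshev distance matrices of the
current conditioning set and evaluates each one-column augmentation with
early-terminating walks.  Selection (a model-choice step) runs on at most
``BRUTE_FORCE_MAX_N`` evenly strided design rows; the TE value itself is
always computed on the full design (see
:mod:`lagte.transfer_entropy`).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import optimize, stats
from scipy.special import digamma, ndtri

from ._design import Design
from ._kernels import (
    abs_diff_matrix,
    count_1d_lt,
    count_aug_lt,
    count_base_lt,
    max_update,
    walk_kth_eps,
)
from .estimators import BRUTE_FORCE_MAX_N


class _DenseState:
    """Row-sorted distance-matrix backend for n <= BRUTE_FORCE_MAX_N."""

    def __init__(self, design: Design, k: int):
        self.k = k
        self.n = design.n_rows
        y = np.ascontiguousarray(design.target)
        self.D_yS = abs_diff_matrix(y)
        self.D_S = None                      # None while S is empty
        self.dim_S = 0
        self._psi = digamma(np.arange(1, self.n + 2))
        self._eps = np.empty(self.n)
        self._cnt = np.empty(self.n, dtype=np.int64)
        self._sort()

    def _sort_one(self, D):
        order = np.argsort(D, axis=1).astype(np.int32)
        vals = np.take_along_axis(D, order.astype(np.int64), axis=1)
        return np.ascontiguousarray(vals), np.ascontiguousarray(order)

    def _sort(self):
        self.vals_yS, self.idx_yS = self._sort_one(self.D_yS)
        if self.D_S is not None:
            self.vals_S, self.idx_S = self._sort_one(self.D_S)

    def gain(self, cvec: np.ndarray,
             sorted_c: np.ndarray | None = None) -> float:
        """I(y; c | S) for one candidate column."""
        cvec = np.ascontiguousarray(cvec)
        nz = walk_kth_eps(self.vals_yS, self.idx_yS, cvec, self.k, self._eps)
        if nz:
            raise ValueError(
                f"{nz} degenerate k-th neighbor radii; jitter policy failed")
        eps = self._eps
        psi = self._psi
        count_base_lt(self.vals_yS, eps, self._cnt)
        mean_terms = psi[self._cnt].mean()          # psi(n_yS + 1)
        if self.D_S is None:
            if sorted_c is None:
                sorted_c = np.sort(cvec)
            count_1d_lt(sorted_c, cvec, eps, self._cnt)
            mean_terms += psi[self._cnt].mean()     # psi(n_c + 1)
            mean_terms -= psi[self.n - 1]           # psi(n) ; n_S = n - 1
        else:
            count_aug_lt(self.vals_S, self.idx_S, cvec, eps, self._cnt)
            mean_terms += psi[self._cnt].mean()     # psi(n_cS + 1)
            count_base_lt(self.vals_S, eps, self._cnt)
            mean_terms -= psi[self._cnt].mean()     # psi(n_S + 1)
        return float(psi[self.k - 1] - mean_terms)  # psi[k-1] = digamma(k)

    def accept(self, cvec: np.ndarray) -> None:
        A = abs_diff_matrix(np.ascontiguousarray(cvec))
        max_update(self.D_yS, A)
        if self.D_S is None:
            self.D_S = A
        else:
            max_update(self.D_S, A)
        self.dim_S += 1
        self._sort()


@lru_cache(maxsize=256)
def _max_gate_z(alpha: float, n_candidates: int, n_shuffles: int) -> float:
    """Gaussian quantile multiplier controlling family-wise acceptance.

    Solves P(max of C iid normals > mu_hat + sd_hat * z) = alpha where
    mu_hat and sd_hat are moment estimates from B = n_shuffles draws, i.e.
    the Sidak-style best-of-C correction with an allowance for the
    sampling noise of the estimated threshold.
    """
    C, B = n_candidates, n_shuffles
    if C == 1 and B > 10 ** 6:
        return float(ndtri(1 - alpha))
    # quadrature nodes for mu_hat ~ N(0, 1/B) and sd_hat^2 ~ chi2_{B-1}/B
    xs, ws = np.polynomial.hermite_e.hermegauss(41)
    us = xs / np.sqrt(B)
    ws = ws / ws.sum()
    qs = (np.arange(1, 42) - 0.5) / 41
    ss = np.sqrt(stats.chi2.ppf(qs, B - 1) / B)

    def fwer(z):
        val = 0.0
        for u, w in zip(us, ws):
            val += w * np.mean(1 - stats.norm.cdf(u + ss * z) ** C)
        return val

    return float(optimize.brentq(lambda z: fwer(z) - alpha, 0.5, 8.0))


def _gate_threshold(null_gains: np.ndarray, alpha: float, n_remaining: int,
                    gate: str) -> float:
    if gate == "max-corrected":
        z = _max_gate_z(alpha, n_remaining, null_gains.size)
        # permutation nulls of the CMI gain are mildly right-skewed;
        # Cornish-Fisher adjustment of the Gaussian quantile
        centered = null_gains - null_gains.mean()
        sd = null_gains.std()
        if sd > 0:
            skew = np.mean(centered ** 3) / sd ** 3
            z = z + (z ** 2 - 1.0) * skew / 6.0
        return float(null_gains.mean() + sd * z)
    if gate == "per-candidate":
        return float(np.quantile(null_gains, 1.0 - alpha, method="higher"))
    raise ValueError(f"unknown gate {gate!r}")


def run_selection(design: Design, k: int, n_shuffles: int, alpha: float,
                  gate: str, rng: np.random.Generator):
    """Greedy gated selection on a prepared design.

    Returns (selected candidate indices in acceptance order, CMI gains).
    """
    n = design.n_rows
    if n <= k:
        raise ValueError(f"need more than k={k} rows, got {n}")
    if n > BRUTE_FORCE_MAX_N:
        # candidate choice on an evenly strided row subsample; the TE value
        # is still estimated from every row
        rows = np.linspace(0, n - 1, BRUTE_FORCE_MAX_N).round().astype(int)
        design = Design(target=design.target[rows],
                        columns=design.columns[rows],
                        candidates=design.candidates,
                        tau=design.tau, l_max=design.l_max)
    state = _DenseState(design, k)

    # tie-break order: lowest delay first, source process before target
    order = sorted(range(len(design.candidates)),
                   key=lambda i: design.candidates[i])
    cols = [np.ascontiguousarray(design.columns[:, i]) for i in order]
    sorted_cols = [np.sort(c) for c in cols]
    remaining = list(range(len(order)))
    selected: list[int] = []
    gains: list[float] = []
    while remaining:
        best_gain = -np.inf
        best = -1
        for pos in remaining:
            g = state.gain(cols[pos], sorted_cols[pos])
            if g > best_gain:
                best_gain = g
                best = pos
        col = cols[best]
        sorted_c = sorted_cols[best]
        null_gains = np.empty(n_shuffles)
        for b in range(n_shuffles):
            null_gains[b] = state.gain(rng.permuted(col), sorted_c)
        # the correction family is the winner's own process: the gate asks
        # "does this process inform the target", at level alpha per process
        proc = design.candidates[order[best]].process
        n_family = sum(1 for pos in remaining
                       if design.candidates[order[pos]].process == proc)
        threshold = _gate_threshold(null_gains, alpha, n_family, gate)
        if not (best_gain > threshold and best_gain > 0.0):
            break
        selected.append(order[best])
        gains.append(float(best_gain))
        remaining.remove(best)
        state.accept(col)
    return selected, gains
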