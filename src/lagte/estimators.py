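"""Nearest-neighbor entropy and conditional mutual information estimators.

Differential entropy uses the Kozachenko-Leonenko k-nearest-neighbor
estimator under the max-coordinate (Chebyshev) metric,

    H_hat = psi(n) - psi(k) + (d / n) * sum_i ln(2 * eps_i),

with ``eps_i`` the distance from point i to its k-th nearest neighbor.

Conditional mutual information (and hence transfer entropy) is an
entropy *combination*: every term is a Kozachenko-Leonenko entropy
evaluated with the shared radius eps_i taken from the joint space, which
turns the combination into the digamma neighbor-count form

    I(t; S | C) = psi(k) - < psi(n_tC + 1) + psi(n_SC + 1) - psi(n_C + 1) >

(n_* = points strictly within eps_i in the marginal subspace; with C empty
this is the Kraskov-Stoegbauer-Grassberger mutual information).  Sharing
the radius is what makes the dimension-dependent biases of the four terms
cancel, which matters greatly on the ~300-sample segments this package is
designed for.

Small clouds are handled by dense brute-force kernels (see
:mod:`lagte._kernels`); large clouds fall back to a cKDTree index.

A linear-Gaussian closed-form transfer entropy (regression residual
variances) is provided as an independent oracle for testing kNN estimates
on linear systems; it is not a user-facing estimator option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

from ._kernels import pairwise_chebyshev, sum_log_kth

__all__ = [
    "EstimatorParams",
    "knn_entropy",
    "cmi_knn",
    "gaussian_te_oracle",
]

#: clouds up to this many points use the dense brute-force kernels
BRUTE_FORCE_MAX_N = 2000

#: relative jitter amplitude (fraction of the per-coordinate sample SD)
JITTER_SCALE = 1e-10


@dataclass
class EstimatorParams:
    """Settings of the nearest-neighbor estimator.

    k : neighbor count (10, the customary default of nearest-neighbor
        transfer-entropy toolboxes; exposed here).
    metric : only the max-coordinate ("chebyshev") metric is supported.
    clip_negative : report max(0, value) for quantities that are
        non-negative by definition (estimator noise is not).
    """

    k: int = 10
    metric: str = "chebyshev"
    clip_negative: bool = True

    def __post_init__(self):
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.metric != "chebyshev":
            raise ValueError("only the 'chebyshev' metric is supported")


def _as_cloud(points) -> np.ndarray:
    Z = np.asarray(points, dtype=np.float64)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.ndim != 2:
        raise ValueError("point cloud must be a (n, d) array")
    if not np.all(np.isfinite(Z)):
        raise ValueError("point cloud contains non-finite coordinates")
    return Z


def _check_degenerate(Z: np.ndarray) -> None:
    sds = Z.std(axis=0)
    bad = np.flatnonzero(sds == 0.0)
    if bad.size:
        raise ValueError(
            f"degenerate (constant) coordinate(s) {bad.tolist()}: "
            "nearest-neighbor distances are ill-defined"
        )


def apply_jitter(Z: np.ndarray, rng: np.random.Generator | None) -> np.ndarray:
    """Deterministic tie-breaking jitter, amplitude 1e-10 x per-column SD.

    Tied Chebyshev distances (e.g. from repeated values in short series)
    break the k-th-neighbor count logic; a seeded jitter far below any
    physical scale removes ties without affecting estimates.
    """
    if rng is None:
        return Z
    sds = Z.std(axis=0)
    return Z + rng.uniform(-1.0, 1.0, size=Z.shape) * (JITTER_SCALE * sds)


def _kl_entropy(Z: np.ndarray, k: int) -> float:
    n, d = Z.shape
    if n <= k:
        raise ValueError(f"need more than k={k} points, got n={n}")
    if n <= BRUTE_FORCE_MAX_N:
        D = pairwise_chebyshev(np.ascontiguousarray(Z))
        total, n_zero = sum_log_kth(D, k)
    else:
        eps = cKDTree(Z).query(Z, k=k + 1, p=np.inf)[0][:, k]
        n_zero = int(np.sum(eps <= 0.0))
        total = float(np.sum(np.log(eps[eps > 0.0])))
    if n_zero:
        raise ValueError(
            f"{n_zero} duplicate points at the k-th neighbor distance; "
            "apply the jitter policy before estimation"
        )
    return float(digamma(n) - digamma(k) + d * np.log(2.0) + (d / n) * total)


def knn_entropy(cloud, params: EstimatorParams | None = None,
                rng: np.random.Generator | None = None) -> float:
    """Differential entropy (nats) of a sample cloud.

    Parameters
    ----------
    cloud : (n,) or (n, d) array of points.
    params : estimator settings; defaults to ``EstimatorParams()``.
    rng : optional generator driving the deterministic tie-break jitter.
        Pass ``None`` for data that is already jittered or tie-free.
    """
    params = params or EstimatorParams()
    Z = _as_cloud(cloud)
    _check_degenerate(Z)
    Z = apply_jitter(Z, rng)
    return _kl_entropy(Z, params.k)


def _joint_radius_and_counts(Z: np.ndarray, subspaces, k: int):
    """Shared k-th neighbor radii of Z and strict-inequality neighbor
    counts of each subspace (list of column-index lists; None = full space).

    Returns (eps, log-radius mean, list of count arrays).
    """
    n = Z.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} points, got n={n}")
    counts = []
    if n <= BRUTE_FORCE_MAX_N:
        D = pairwise_chebyshev(np.ascontiguousarray(Z))
        Dk = D.copy()
        np.fill_diagonal(Dk, np.inf)
        eps = np.partition(Dk, k - 1, axis=1)[:, k - 1]
        if np.any(eps <= 0):
            raise ValueError("duplicate points: zero k-th neighbor radius")
        for cols in subspaces:
            if cols is None:
                Dsub = D
            else:
                Dsub = pairwise_chebyshev(np.ascontiguousarray(Z[:, cols]))
            counts.append((Dsub < eps[:, None]).sum(axis=1) - 1)
    else:
        eps = cKDTree(Z).query(Z, k=k + 1, p=np.inf)[0][:, k]
        if np.any(eps <= 0):
            raise ValueError("duplicate points: zero k-th neighbor radius")
        r = np.nextafter(eps, 0.0)  # strict inequality at the boundary
        for cols in subspaces:
            sub = Z if cols is None else np.ascontiguousarray(Z[:, cols])
            tree = cKDTree(sub)
            counts.append(
                tree.query_ball_point(sub, r, p=np.inf,
                                      return_length=True) - 1)
    return eps, float(np.mean(np.log(2.0 * eps))), counts


def _fp_cmi_core(t: np.ndarray, S: np.ndarray, C: np.ndarray | None,
                 k: int) -> float:
    """Shared-radius CMI I(t; S | C) on pre-jittered columns (nats)."""
    n = t.shape[0]
    blocks = [t, S] + ([C] if C is not None else [])
    Z = np.hstack(blocks)
    d_t, d_s = t.shape[1], S.shape[1]
    cols_tC = list(range(d_t)) + (
        list(range(d_t + d_s, Z.shape[1])) if C is not None else [])
    cols_SC = list(range(d_t, Z.shape[1]))
    subspaces = [cols_tC, cols_SC]
    if C is not None:
        subspaces.append(list(range(d_t + d_s, Z.shape[1])))
    _, _, counts = _joint_radius_and_counts(Z, subspaces, k)
    n_tC, n_SC = counts[0], counts[1]
    n_C = counts[2] if C is not None else np.full(n, n - 1)
    return float(digamma(k)
                 - np.mean(digamma(n_tC + 1) + digamma(n_SC + 1)
                           - digamma(n_C + 1)))


def cmi_knn(target, source_block, cond_block=None,
            params: EstimatorParams | None = None,
            rng: np.random.Generator | None = None) -> float:
    """Conditional mutual information I(target; source | cond) in nats.

    Estimated as the shared-radius entropy combination
    ``H(t,C) - H(C) - H(t,S,C) + H(S,C)`` (see module docstring); with an
    empty condition block this reduces to mutual information.  The raw
    combination may be slightly negative; it is clipped at zero when
    ``params.clip_negative`` (pass ``clip_negative=False`` to study the
    raw estimator noise).
    """
    params = params or EstimatorParams()
    t = _as_cloud(target)
    if t.shape[1] != 1:
        raise ValueError("target must be one-dimensional")
    S = _as_cloud(source_block)
    C = None
    if cond_block is not None:
        C = _as_cloud(cond_block)
        if C.shape[1] == 0:
            C = None
    if S.shape[0] != t.shape[0] or (C is not None and C.shape[0] != t.shape[0]):
        raise ValueError("target, source and condition blocks must share n")
    full = np.hstack([t, S] + ([C] if C is not None else []))
    _check_degenerate(full)
    full = apply_jitter(full, rng)
    t_j = full[:, :1]
    S_j = full[:, 1:1 + S.shape[1]]
    C_j = full[:, 1 + S.shape[1]:] if C is not None else None
    raw = _fp_cmi_core(t_j, S_j, C_j, params.k)
    if params.clip_negative:
        return max(0.0, raw)
    return raw


def _lag_matrix(series: np.ndarray, lags, n_rows: int, max_lag: int) -> np.ndarray:
    cols = [series[max_lag - lag: max_lag - lag + n_rows] for lag in sorted(lags)]
    if not cols:
        return np.empty((n_rows, 0))
    return np.column_stack(cols)


def gaussian_te_oracle(x, y, source_lags, target_lags) -> float:
    """Linear-Gaussian transfer entropy X->Y via regression residual variances.

    TE = 0.5 * ln(sigma^2_restricted / sigma^2_full), where the restricted
    model predicts y_n from its own lagged values (``target_lags``) and the
    full model adds the lagged source values (``source_lags``).  Exact for
    jointly Gaussian (linear) systems; used as an independent oracle when
    testing the kNN pipeline.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    source_lags = sorted(int(l) for l in source_lags)
    target_lags = sorted(int(l) for l in target_lags)
    if not source_lags:
        raise ValueError("source_lags must be non-empty")
    if any(l < 1 for l in source_lags + target_lags):
        raise ValueError("lags must be >= 1")
    max_lag = max(source_lags + target_lags)
    n_rows = y.size - max_lag
    if n_rows < 10 + len(source_lags) + len(target_lags):
        raise ValueError("series too short for the requested lag design")
    target = y[max_lag:]
    own = _lag_matrix(y, target_lags, n_rows, max_lag)
    src = _lag_matrix(x, source_lags, n_rows, max_lag)

    def _resid_var(design: np.ndarray) -> float:
        if design.shape[1] == 0:
            return float(np.var(target))
        X = np.column_stack([np.ones(n_rows), design])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise np.linalg.LinAlgError("singular regression design")
        beta, *_ = np.linalg.lstsq(X, target, rcond=None)
        r = target - X @ beta
        return float(np.var(r))

    var_restricted = _resid_var(own)
    var_full = _resid_var(np.column_stack([own, src]) if own.size else src)
    return 0.5 * float(np.log(var_restricted / var_full))
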