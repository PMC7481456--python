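"""Lagged transfer entropy with time-shift surrogate significance.

Transfer entropy from a source process X to a target Y is the information
the past of X carries about the present of Y beyond Y's own past.  With a
selected conditioning vector V_k = [V_k^X, V_k^Y] (see
:mod:`lagte.embedding`) it is computed as the entropy combination

    TE_{X->Y} = H(y_n, V_k^Y) - H(V_k^Y) - H(y_n, V_k) + H(V_k)

in nats.  The *lagged* variant shifts the Y-labelled (driven) series back by
``tau`` samples and evaluates both directions on the shifted pair: for
X->Y the target sample moves to y_{n-tau} while the source past stays
anchored at n-1 (resolving instantaneous versus delayed influence on a
per-sample time scale); for Y->X the source past is deferred by ``tau``
so that it never overlaps the target's future.  ``tau = 0`` is standard
TE in both directions.

Significance is assessed against time-shift surrogates: the source series
is circularly shifted by a random offset in [1, max_shift], which destroys
the directed alignment while preserving both marginals, and TE is
recomputed on each shifted pair with the observed conditioning vector.
The embedding is deliberately NOT re-selected per surrogate: a circular
shift merely relabels candidate delays, so a re-run selection would
rediscover the same alignment (delay j of the shifted source is delay
j + shift of the original) and tie the observed value instead of nulling
it.  A value is significant when it strictly exceeds the empirical 95th
percentile of the surrogate distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._design import (
    SOURCE,
    BivariateSeries,
    build_design,
    direction_arrays,
    shift_role,
)
from ._nue import run_selection
from ._rng import substream
from .embedding import EmbeddingVector, SelectionPolicy
from .estimators import EstimatorParams, _fp_cmi_core, _joint_radius_and_counts

__all__ = [
    "BivariateSeries",
    "TEEstimate",
    "SurrogateResult",
    "LagProfile",
    "DIRECTIONS",
    "shift_align",
    "transfer_entropy",
    "surrogate_test",
    "lag_profile",
]

DIRECTIONS = ("x->y", "y->x")


@dataclass
class TEEstimate:
    """One directed, lagged transfer entropy value (nats)."""

    direction: str
    lag: int
    value: float            # clipped at 0 when params.clip_negative
    raw_value: float
    embedding: EmbeddingVector
    params: EstimatorParams


@dataclass
class SurrogateResult:
    """Time-shift surrogate null distribution for one TE estimate."""

    n_surrogates: int
    max_shift: int
    surrogate_values: np.ndarray
    threshold: float        # empirical 95th percentile (no interpolation)
    significant: bool       # observed value strictly above the threshold


@dataclass
class LagProfile:
    """Complete per-lag, per-direction grid of TE estimates."""

    estimates: dict = field(default_factory=dict)    # (direction, lag) -> TEEstimate
    surrogates: dict = field(default_factory=dict)   # (direction, lag) -> SurrogateResult | None
    tau_max: int = 15

    def to_frame(self, segment_id: str = "segment-0") -> pd.DataFrame:
        """Long-format results table, one row per (direction, lag)."""
        rows = []
        for (direction, lag), est in sorted(self.estimates.items()):
            surr = self.surrogates.get((direction, lag))
            rows.append({
                "segment_id": segment_id,
                "direction": direction,
                "lag": lag,
                "value": est.value,
                "raw_value": est.raw_value,
                "threshold": surr.threshold if surr else np.nan,
                "significant": surr.significant if surr else pd.NA,
                "n_candidates_source": len(est.embedding.source_part),
                "n_candidates_target": len(est.embedding.target_part),
            })
        return pd.DataFrame(rows)


def shift_align(pair: BivariateSeries, tau: int, l_max: int = 10,
                direction: str = "x->y", min_rows: int = 50):
    """Lag-shifted embedded design (no jitter), as plain arrays.

    Returns ``(target, source_past, target_past)``.  For "x->y" row n
    carries the target sample y_{n-tau}, the source past
    x_{n-1..n-L_max} and the target past y_{n-tau-1..n-tau-L_max}; for
    "y->x" the lag defers the source instead (target x_n, source past
    y_{n-tau-1..n-tau-L_max}, target past x_{n-1..n-L_max}).  The row
    count is ``N - tau - l_max`` either way.
    """
    source, target = direction_arrays(pair, direction)
    design = build_design(source, target, tau, l_max, None, min_rows,
                          shift_role(direction))
    n_src = sum(1 for c in design.candidates if c.process == SOURCE)
    return (design.target,
            design.columns[:, :n_src],
            design.columns[:, n_src:])


def _design_blocks(design, embedding: EmbeddingVector):
    y = design.target[:, None]
    v_src = np.column_stack([design.col(c) for c in embedding.source_part]) \
        if embedding.source_part else None
    v_tgt = np.column_stack([design.col(c) for c in embedding.target_part]) \
        if embedding.target_part else None
    return y, v_src, v_tgt


def _te_from_design(design, embedding: EmbeddingVector,
                    params: EstimatorParams) -> tuple[float, float]:
    """(raw, clipped) TE from a jittered design and a conditioning vector.

    Realizes TE = H(y,V^Y) - H(V^Y) - H(y,V) + H(V) with every entropy
    term sharing the joint-space k-th neighbor radius, which reduces the
    combination to I(y; V^X | V^Y) in digamma neighbor-count form.
    """
    if not embedding.source_part:
        return 0.0, 0.0
    y, v_src, v_tgt = _design_blocks(design, embedding)
    raw = _fp_cmi_core(y, v_src, v_tgt, params.k)
    value = max(0.0, raw) if params.clip_negative else raw
    return raw, value


def te_decomposition_terms(design, embedding: EmbeddingVector, k: int):
    """The four shared-radius entropy terms of the conditioning-vector form.

    Returns (H(y,V^Y), H(V^Y), H(y,V), H(V)) in nats, each a
    Kozachenko-Leonenko entropy evaluated at the joint-space radius; their
    combination H(y,V^Y) - H(V^Y) - H(y,V) + H(V) equals the direct CMI
    formulation of :func:`_te_from_design` up to floating-point error.
    """
    from scipy.special import digamma

    y, v_src, v_tgt = _design_blocks(design, embedding)
    if v_src is None:
        raise ValueError("decomposition needs >= 1 source candidate")
    blocks = [y, v_src] + ([v_tgt] if v_tgt is not None else [])
    Z = np.hstack(blocks)
    n = Z.shape[0]
    d_src = v_src.shape[1]
    cols_tgt = list(range(1 + d_src, Z.shape[1]))
    # subspace column sets; an empty V^Y contributes H = 0
    subspaces = [
        [0] + cols_tgt,                       # (y, V^Y)
        cols_tgt,                             # V^Y
        None,                                 # (y, V) = full space
        list(range(1, Z.shape[1])),           # V
    ]
    queried = [s for s in subspaces if s is None or len(s) > 0]
    _, mean_log_2eps, counts = _joint_radius_and_counts(Z, queried, k)
    counts_iter = iter(counts)
    psi_n = digamma(n)
    dims = [1 + len(cols_tgt), len(cols_tgt), Z.shape[1], Z.shape[1] - 1]
    out = []
    for dim, s in zip(dims, subspaces):
        if s is not None and len(s) == 0:
            out.append(0.0)
            continue
        cnt = next(counts_iter)
        out.append(float(psi_n - np.mean(digamma(cnt + 1))
                         + dim * mean_log_2eps))
    return tuple(out)


def _analyze(source: np.ndarray, target: np.ndarray, tau: int,
             policy: SelectionPolicy, params: EstimatorParams,
             jitter_rng, shuffle_rng,
             embedding: EmbeddingVector | None, shifted: str = "target"):
    """Selection (unless an embedding is supplied) + TE on one direction."""
    design = build_design(source, target, tau, policy.l_max, jitter_rng,
                          policy.min_rows, shifted)
    if embedding is None:
        idx, gains = run_selection(design, params.k, policy.n_shuffles,
                                   policy.alpha, policy.gate, shuffle_rng)
        embedding = EmbeddingVector([design.candidates[i] for i in idx],
                                    gains, policy.l_max)
    raw, value = _te_from_design(design, embedding, params)
    return embedding, raw, value


def transfer_entropy(pair: BivariateSeries, direction: str = "x->y",
                     lag: int = 0,
                     embedding: EmbeddingVector | None = None,
                     policy: SelectionPolicy | None = None,
                     params: EstimatorParams | None = None,
                     seed: int = 0) -> TEEstimate:
    """Lagged TE for one direction; selects the embedding unless given one.

    The reported ``value`` is clipped at zero (TE is non-negative by
    definition); ``raw_value`` keeps the unclipped entropy combination.  An
    embedding with no source-side candidates yields exactly zero.
    """
    policy = policy or SelectionPolicy()
    params = params or EstimatorParams()
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    pair = pair.zscored()
    source, target = direction_arrays(pair, direction)
    emb, raw, value = _analyze(
        source, target, lag, policy, params,
        substream(seed, "jitter", direction, lag),
        substream(seed, "shuffles", direction, lag),
        embedding, shift_role(direction),
    )
    return TEEstimate(direction, lag, value, raw, emb, params)


def surrogate_test(pair: BivariateSeries, direction: str = "x->y",
                   lag: int = 0,
                   embedding: EmbeddingVector | None = None,
                   policy: SelectionPolicy | None = None,
                   params: EstimatorParams | None = None,
                   n_surrogates: int = 100, max_shift: int = 20,
                   seed: int = 0) -> tuple[TEEstimate, SurrogateResult]:
    """Time-shift surrogate significance test of one lagged TE value.

    Each surrogate circularly shifts the source series by an integer drawn
    uniformly from [1, max_shift] and recomputes TE with the observed
    conditioning vector (see the module docstring for why selection is
    not re-run per surrogate).  ``embedding`` overrides the observed
    value's conditioning vector; when None it is selected here.
    """
    policy = policy or SelectionPolicy()
    params = params or EstimatorParams()
    if max_shift < 1:
        raise ValueError("max_shift must be >= 1")
    if len(pair) <= 2 * max_shift:
        raise ValueError("series too short for the requested max_shift")
    pair = pair.zscored()
    if pair.x.std() == 0 or pair.y.std() == 0:
        raise ValueError("degenerate (constant) series")
    observed = transfer_entropy(pair, direction, lag, embedding, policy,
                                params, seed)
    source, target = direction_arrays(pair, direction)
    shift_rng = substream(seed, "shifts", direction, lag)
    shifts = shift_rng.integers(1, max_shift + 1, size=n_surrogates)
    values = np.empty(n_surrogates)
    for s, shift in enumerate(shifts):
        shifted = np.roll(source, int(shift))
        _, _, values[s] = _analyze(
            shifted, target, lag, policy, params,
            substream(seed, "surrogate-jitter", direction, lag, s),
            substream(seed, "surrogate-shuffles", direction, lag, s),
            observed.embedding, shift_role(direction),
        )
    threshold = float(np.quantile(values, 0.95, method="higher"))
    result = SurrogateResult(n_surrogates, max_shift, values, threshold,
                             bool(observed.value > threshold))
    return observed, result


def lag_profile(pair: BivariateSeries, tau_max: int = 15,
                policy: SelectionPolicy | None = None,
                params: EstimatorParams | None = None,
                seed: int = 0, surrogates: bool = True,
                n_surrogates: int = 100, max_shift: int = 20) -> LagProfile:
    """TE over the full lag grid (0..tau_max), both directions.

    The embedding is re-selected per (direction, lag); the lag-0 cell is
    bit-identical to a direct :func:`transfer_entropy` call with the same
    seed.  Surrogate testing of every cell is expensive (each surrogate
    repeats candidate selection) and can be disabled.
    """
    policy = policy or SelectionPolicy()
    params = params or EstimatorParams()
    if not tau_max < len(pair) / 4:
        raise ValueError("tau_max must be below N/4")
    profile = LagProfile(tau_max=tau_max)
    for direction in DIRECTIONS:
        for tau in range(tau_max + 1):
            if surrogates:
                est, surr = surrogate_test(
                    pair, direction, tau, None, policy, params,
                    n_surrogates, max_shift, seed)
            else:
                est = transfer_entropy(pair, direction, tau, None, policy,
                                       params, seed)
                surr = None
            profile.estimates[(direction, tau)] = est
            profile.surrogates[(direction, tau)] = surr
    return profile
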