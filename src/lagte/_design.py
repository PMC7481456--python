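"""Lagged embedding designs shared by candidate selection and TE estimation.

A *design* aligns the target sample with the candidate past states of both
processes for one (direction, lag) analysis.  The lag ``tau`` always
shifts the Y-labelled series (the driven process) back in time, and both
directional TEs are computed on the shifted pair, so that the source
candidates of either direction never reach into the target's future.  With
maximum candidate delay ``L`` and 1-based n = tau+L+1 .. N:

    direction X->Y (target y):
        target          y[n - tau]
        source delay j  x[n - j]             j = 1..L
        target delay j  y[n - tau - j]       j = 1..L

    direction Y->X (target x):
        target          x[n]
        source delay j  y[n - tau - j]       j = 1..L
        target delay j  x[n - j]             j = 1..L

For X->Y the source past stays anchored at n-1 while the target is shifted
back, capturing instantaneous and anticipated effects; for Y->X the lag
defers the source past instead.  ``tau = 0`` reproduces the standard TE
design in both directions and the usable row count is ``N - tau - L`` for
every lag.

The design matrix is jittered once (deterministically, from the run seed)
so that every entropy term computed from it shares identical coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimators import apply_jitter

SOURCE = "source"
TARGET = "target"


@dataclass(frozen=True, order=True)
class Candidate:
    """One lagged past state eligible for the conditioning vector.

    ``process`` is "source" or "target"; ``delay`` is in samples (>= 1)
    relative to the (possibly lag-shifted) target sample.  Ordering is by
    delay first, source before target, matching the selection tie-break.
    """

    delay: int
    process: str

    def __post_init__(self):
        if self.process not in (SOURCE, TARGET):
            raise ValueError(f"unknown process {self.process!r}")
        if self.delay < 1:
            raise ValueError("candidate delay must be >= 1")


@dataclass
class BivariateSeries:
    """Aligned sample vectors of the two processes under analysis.

    ``x`` is the source-labelled process (RR or simulated X), ``y`` the
    target-labelled one (RESP or simulated Y); direction strings such as
    "x->y" refer to these labels.  Analysis routines z-normalize defensively.
    """

    x: np.ndarray
    y: np.ndarray
    label_x: str = "x"
    label_y: str = "y"

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.x.size != self.y.size:
            raise ValueError("x and y must have equal length")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("series contain non-finite values")

    def __len__(self) -> int:
        return self.x.size

    def zscored(self) -> "BivariateSeries":
        """Population z-normalization of both channels (idempotent)."""
        def _z(v):
            sd = v.std()
            if sd == 0:
                raise ValueError("cannot z-normalize a constant series")
            return (v - v.mean()) / sd
        return BivariateSeries(_z(self.x), _z(self.y),
                               self.label_x, self.label_y)


def direction_arrays(pair: BivariateSeries, direction: str):
    """Map a direction string to (source, target) arrays.

    "x->y" targets ``pair.y``; "y->x" targets ``pair.x``.
    """
    if direction == "x->y":
        return pair.x, pair.y
    if direction == "y->x":
        return pair.y, pair.x
    raise ValueError(f"direction must be 'x->y' or 'y->x', got {direction!r}")


def shift_role(direction: str) -> str:
    """Which design role carries the lag shift for a direction.

    The lag always shifts the Y-labelled series: it is the (shifted)
    target of "x->y" and the (deferred) source of "y->x".
    """
    return {"x->y": "target", "y->x": "source"}[direction]


def candidate_list(l_max: int) -> list[Candidate]:
    """The full candidate set Omega: delays 1..L_max for each process."""
    if l_max < 1:
        raise ValueError("l_max must be >= 1")
    out = [Candidate(d, SOURCE) for d in range(1, l_max + 1)]
    out += [Candidate(d, TARGET) for d in range(1, l_max + 1)]
    return out


@dataclass
class Design:
    """Jittered, aligned design for one (direction, lag) analysis."""

    target: np.ndarray            # (n_rows,) target samples
    columns: np.ndarray           # (n_rows, 2 L) candidate columns
    candidates: list[Candidate] = field(default_factory=list)
    tau: int = 0
    l_max: int = 10

    @property
    def n_rows(self) -> int:
        return self.target.size

    def col(self, cand: Candidate) -> np.ndarray:
        return self.columns[:, self.candidates.index(cand)]


def build_design(source: np.ndarray, target: np.ndarray, tau: int, l_max: int,
                 jitter_rng: np.random.Generator | None = None,
                 min_rows: int = 50, shifted: str = "target") -> Design:
    """Assemble the lag-shifted design matrix for one direction.

    ``shifted`` names the role carrying the lag shift: "target"
    (the X->Y layout: target sample shifted back, source past anchored at
    n-1) or "source" (the Y->X layout: target at n, source past deferred
    by ``tau``).  Raises if fewer than ``min_rows`` usable rows remain.
    """
    if tau < 0:
        raise ValueError("lag must be >= 0")
    if shifted not in ("target", "source"):
        raise ValueError(f"shifted must be 'target' or 'source', got {shifted!r}")
    N = target.size
    n_rows = N - tau - l_max
    if n_rows < min_rows:
        raise ValueError(
            f"series too short: {n_rows} usable rows after truncation "
            f"(N={N}, tau={tau}, L_max={l_max}); need >= {min_rows}"
        )
    cands = candidate_list(l_max)
    # 1-based n runs over tau+L+1 .. N; 0-based anchor i = n-1
    i = np.arange(tau + l_max, N)
    src_shift = tau if shifted == "source" else 0
    tgt_shift = tau if shifted == "target" else 0
    cols = np.empty((n_rows, 2 * l_max))
    for idx, cand in enumerate(cands):
        if cand.process == SOURCE:
            cols[:, idx] = source[i - src_shift - cand.delay]
        else:
            cols[:, idx] = target[i - tgt_shift - cand.delay]
    full = np.column_stack([target[i - tgt_shift], cols])
    full = apply_jitter(full, jitter_rng)
    return Design(target=full[:, 0], columns=full[:, 1:],
                  candidates=cands, tau=tau, l_max=l_max)
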