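"""Non-uniform embedding: greedy, significance-gated candidate selection.

Instead of a fixed uniform delay vector, the conditioning set for transfer
entropy is assembled candidate by candidate from the pooled past states of
both processes, Omega = {X_{n-1},...,X_{n-Lmax}, Y_{n-1},...,Y_{n-Lmax}}.
Each round proposes the candidate whose inclusion yields the largest
conditional-mutual-information gain; a permutation gate (see
:mod:`lagte._nue`) decides whether the gain is distinguishable from chance,
and the first failure terminates selection.  The result is an ordered
conditioning vector V_k = [V_k^X, V_k^Y].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._design import (
    SOURCE,
    TARGET,
    BivariateSeries,
    Candidate,
    build_design,
    candidate_list,
    direction_arrays,
    shift_role,
)
from ._nue import run_selection
from ._rng import substream
from .estimators import EstimatorParams

__all__ = [
    "Candidate",
    "EmbeddingVector",
    "SelectionPolicy",
    "build_candidate_set",
    "select_candidates",
    "candidate_frequency",
]


@dataclass
class SelectionPolicy:
    """Candidate-selection settings.

    l_max : maximum candidate delay per process (default 10).
    n_shuffles : permutations behind the significance gate.
    alpha : gate significance level.
    gate : "max-corrected" (default; threshold adjusted for best-of-C
        candidate selection so that null series yield empty embeddings at
        rate ~1-alpha) or "per-candidate" (uncorrected empirical
        95th-percentile gate).
    seed : default seed when the caller passes none.
    min_rows : minimum usable sample count after lag/delay truncation.
    """

    l_max: int = 10
    n_shuffles: int = 100
    alpha: float = 0.05
    gate: str = "max-corrected"
    seed: int | None = None
    min_rows: int = 50

    def __post_init__(self):
        if self.l_max < 1:
            raise ValueError("l_max must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")


@dataclass
class EmbeddingVector:
    """Ordered conditioning vector produced by the greedy selection.

    ``selected`` lists accepted candidates in acceptance order;
    ``selection_scores`` the CMI gain (nats) at each acceptance.  The
    source/target partitions are the V_k^X and V_k^Y views.
    """

    selected: list[Candidate] = field(default_factory=list)
    selection_scores: list[float] = field(default_factory=list)
    l_max: int = 10

    @property
    def source_part(self) -> list[Candidate]:
        return [c for c in self.selected if c.process == SOURCE]

    @property
    def target_part(self) -> list[Candidate]:
        return [c for c in self.selected if c.process == TARGET]

    def __len__(self) -> int:
        return len(self.selected)


def build_candidate_set(policy: SelectionPolicy | None = None) -> list[Candidate]:
    """The initial candidate set: delays 1..L_max for each process."""
    policy = policy or SelectionPolicy()
    return candidate_list(policy.l_max)


def _target_to_direction(target_process: str) -> str:
    if target_process in ("y", TARGET):
        return "x->y"
    if target_process == "x":
        return "y->x"
    raise ValueError(f"target_process must be 'x' or 'y', got {target_process!r}")


def select_candidates(pair: BivariateSeries, target_process: str = "y",
                      lag: int = 0,
                      policy: SelectionPolicy | None = None,
                      params: EstimatorParams | None = None,
                      seed: int | None = None) -> EmbeddingVector:
    """Greedy gated candidate selection for one (target, lag) analysis.

    ``target_process`` names the process being predicted ("y" corresponds
    to the X->Y direction).  Selection is reproducible bit-for-bit given
    (pair, policy, seed).
    """
    policy = policy or SelectionPolicy()
    params = params or EstimatorParams()
    direction = _target_to_direction(target_process)
    if seed is None:
        seed = policy.seed if policy.seed is not None else 0
    pair = pair.zscored()
    source, target = direction_arrays(pair, direction)
    design = build_design(source, target, lag, policy.l_max,
                          substream(seed, "jitter", direction, lag),
                          policy.min_rows, shift_role(direction))
    shuffle_rng = substream(seed, "shuffles", direction, lag)
    idx, gains = run_selection(design, params.k, policy.n_shuffles,
                               policy.alpha, policy.gate, shuffle_rng)
    return EmbeddingVector([design.candidates[i] for i in idx], gains,
                           policy.l_max)


def candidate_frequency(runs: list[EmbeddingVector],
                        l_max: int | None = None) -> pd.DataFrame:
    """Selection fraction of every candidate over a collection of runs.

    Returns a long-format table (process, delay, fraction) covering all
    2*L_max candidates, fractions in [0, 1].
    """
    if not runs:
        raise ValueError("need at least one embedding run")
    if l_max is None:
        l_max = max(r.l_max for r in runs)
    counts = {(c.process, c.delay): 0 for c in candidate_list(l_max)}
    for run in runs:
        for cand in run.selected:
            counts[(cand.process, cand.delay)] += 1
    rows = [
        {"process": p, "delay": d, "fraction": counts[(p, d)] / len(runs)}
        for (p, d) in sorted(counts, key=lambda t: (t[0] != SOURCE, t[1]))
    ]
    return pd.DataFrame(rows)
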