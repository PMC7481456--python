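"""Statistical designs around the lagged-TE estimates.

Three designs are covered: the simulation validation study (one-way ANOVA
of TE against the 16-level lag factor over replicate realizations of the
coupled-AR system, with Bonferroni pairwise lag comparisons), a
cohort-style two-factor ANCOVA (lag x gestational-age group with sex, mode
of delivery and hours of life as covariates, Type-II sums of squares), and
Sobel partial mediation (sleep state -> breathing rate -> TE).  A
synthetic-cohort generator with injectable group effects provides the
parameter-recovery test surface, since the clinical cohort itself is not
publicly deposited.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from ._rng import substream
from .embedding import SelectionPolicy, candidate_frequency
from .estimators import EstimatorParams
from .simulate import ARSimSpec, simulate_coupled_ar
from .transfer_entropy import DIRECTIONS, transfer_entropy

__all__ = [
    "ValidationResult",
    "MediationResult",
    "validation_experiment",
    "lag_anova",
    "pairwise_lag_tests",
    "cohort_model",
    "make_synthetic_cohort",
    "sobel_mediation",
]

GA_GROUPS = ("LPT", "ET", "FT")


@dataclass
class ValidationResult:
    """Replicate-level TE table and the per-direction lag ANOVAs."""

    table: pd.DataFrame                  # replicate, direction, lag, value...
    anova: pd.DataFrame                  # direction, F, p
    pairwise: pd.DataFrame               # direction, lag_a, lag_b, p_adj
    embeddings: dict                     # (direction, lag) -> [EmbeddingVector]

    def candidate_table(self, direction: str = "x->y",
                        lag: int = 0) -> pd.DataFrame:
        return candidate_frequency(self.embeddings[(direction, lag)])


def validation_experiment(n_reps: int = 100, lags=range(16),
                          spec: ARSimSpec | None = None,
                          policy: SelectionPolicy | None = None,
                          params: EstimatorParams | None = None,
                          seed: int = 0,
                          progress: bool = False) -> ValidationResult:
    """The coupled-AR validation study.

    Simulates ``n_reps`` independent realizations (N from ``spec``, default
    300) and computes lagged TE in both directions at every requested lag,
    re-selecting the embedding per (replicate, direction, lag).  Reports
    the one-way ANOVA of TE against the lag factor per direction and
    Bonferroni-adjusted pairwise lag comparisons.
    """
    if n_reps < 10:
        raise ValueError("need at least 10 replicates")
    spec = spec or ARSimSpec()
    policy = policy or SelectionPolicy()
    params = params or EstimatorParams()
    lags = list(lags)
    rows = []
    embeddings = {(d, lag): [] for d in DIRECTIONS for lag in lags}
    for rep in range(n_reps):
        rep_seed = int(substream(seed, "validation", rep).integers(2 ** 31))
        pair = simulate_coupled_ar(spec, seed=rep_seed)
        for direction in DIRECTIONS:
            for lag in lags:
                est = transfer_entropy(pair, direction, lag, None, policy,
                                       params, seed=rep_seed)
                rows.append({
                    "replicate": rep, "direction": direction, "lag": lag,
                    "value": est.value, "raw_value": est.raw_value,
                    "n_candidates_source": len(est.embedding.source_part),
                    "n_candidates_target": len(est.embedding.target_part),
                })
                embeddings[(direction, lag)].append(est.embedding)
        if progress and (rep + 1) % 10 == 0:
            print(f"  replicate {rep + 1}/{n_reps}", flush=True)
    table = pd.DataFrame(rows)
    return ValidationResult(table, lag_anova(table),
                            pairwise_lag_tests(table), embeddings)


def lag_anova(table: pd.DataFrame) -> pd.DataFrame:
    """One-way ANOVA of TE against the lag factor, per direction."""
    rows = []
    for direction in table.direction.unique():
        sub = table[table.direction == direction]
        lags = sorted(sub.lag.unique())
        groups = [sub.value[sub.lag == lag].to_numpy() for lag in lags]
        if np.ptp(sub.value.to_numpy()) == 0:
            f, p = 0.0, 1.0        # degenerate constant response
        else:
            f, p = stats.f_oneway(*groups)
        rows.append({"direction": direction, "F": float(f), "p": float(p)})
    return pd.DataFrame(rows)


def pairwise_lag_tests(table: pd.DataFrame,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni-adjusted pairwise lag comparisons per direction.

    Two-sample t tests over all lag pairs; the Bonferroni family is the
    full set of pairwise comparisons within one direction.
    """
    out = []
    for direction in table.direction.unique():
        sub = table[table.direction == direction]
        lags = sorted(sub.lag.unique())
        n_pairs = len(lags) * (len(lags) - 1) // 2
        for a, b in itertools.combinations(lags, 2):
            va = sub.value[sub.lag == a].to_numpy()
            vb = sub.value[sub.lag == b].to_numpy()
            t, p = stats.ttest_ind(va, vb)
            p_adj = min(1.0, float(p) * n_pairs)
            out.append({"direction": direction, "lag_a": a, "lag_b": b,
                        "t": float(t), "p_adj": p_adj,
                        "significant": p_adj < alpha})
    return pd.DataFrame(out)


def cohort_model(table: pd.DataFrame, sleep_state: str | None = None,
                 alpha: float = 0.05):
    """Two-factor ANCOVA of TE on lag and GA group with covariates.

    ``table`` rows need value, lag, group, sex, mode_of_delivery,
    hours_of_life (and sleep_state when filtering).  Returns
    (anova table, pairwise group contrasts).  Type-II sums of squares;
    group contrasts are Bonferroni-adjusted over the three pairs.
    """
    df = table.copy()
    if sleep_state is not None:
        df = df[df.sleep_state == sleep_state]
    if df.group.nunique() < 2 or df.lag.nunique() < 2:
        raise ValueError("need >= 2 groups and >= 2 lags")
    model = smf.ols(
        "value ~ C(lag) * C(group) + sex + mode_of_delivery + hours_of_life",
        data=df).fit()
    if model.df_resid < 1 or np.linalg.matrix_rank(model.model.exog) < \
            model.model.exog.shape[1]:
        raise ValueError("rank-deficient design: lag x group interaction "
                         "cells are not all populated")
    aov = anova_lm(model, typ=2).rename_axis("term").reset_index()

    groups = sorted(df.group.unique())
    pairs = list(itertools.combinations(groups, 2))
    rows = []
    for a, b in pairs:
        sub = df[df.group.isin([a, b])]
        adj = smf.ols("value ~ C(lag) + C(group) + sex + mode_of_delivery "
                      "+ hours_of_life", data=sub).fit()
        name = [c for c in adj.params.index if c.startswith("C(group)")][0]
        t = adj.tvalues[name]
        p_adj = min(1.0, float(adj.pvalues[name]) * len(pairs))
        rows.append({"group_a": a, "group_b": b,
                     "estimate": float(adj.params[name]), "t": float(t),
                     "p_adj": p_adj, "significant": p_adj < alpha})
    return aov, pd.DataFrame(rows)


def make_synthetic_cohort(n_per_group: int = 40, lags=range(4),
                          group_effect: float = 1.0,
                          interaction: float = 0.0,
                          noise_sd: float = 0.1, seed: int = 0,
                          sleep_states=("AS", "QS")) -> pd.DataFrame:
    """Synthetic cohort with a graded LPT < ET < FT group effect.

    ``group_effect`` is the shift between adjacent GA groups in units of
    the residual (pooled) SD; ``interaction`` adds a lag x group slope.
    Covariates are drawn independently of the outcome.
    """
    rng = substream(seed, "synthetic-cohort")
    rows = []
    lags = list(lags)
    base_lag = {lag: 0.3 - 0.02 * i for i, lag in enumerate(lags)}
    for gi, group in enumerate(GA_GROUPS):
        for unit in range(n_per_group):
            sex = int(rng.integers(0, 2))
            mod = int(rng.integers(0, 2))
            hol = float(rng.uniform(12, 84))
            state = sleep_states[unit % len(sleep_states)]
            for lag in lags:
                mu = (base_lag[lag] + group_effect * noise_sd * gi
                      + interaction * noise_sd * gi * lag)
                rows.append({
                    "unit": f"{group}-{unit}", "group": group, "lag": lag,
                    "sleep_state": state, "sex": sex,
                    "mode_of_delivery": mod, "hours_of_life": hol,
                    "value": float(mu + rng.normal(0, noise_sd)),
                })
    return pd.DataFrame(rows)


@dataclass
class MediationResult:
    """Sobel partial-mediation decomposition IV -> M -> DV."""

    a: float                 # M ~ IV slope
    b: float                 # DV ~ M slope (adjusting for IV)
    c: float                 # total effect, DV ~ IV
    c_prime: float           # direct effect, DV ~ IV + M
    se_a: float
    se_b: float
    z: float                 # Sobel z of the indirect path a*b
    p: float
    proportion_mediated: float   # (c - c') / c

    def to_json(self) -> str:
        import dataclasses
        import json
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def sobel_mediation(iv, mediator, dv) -> MediationResult:
    """Sobel test of the indirect path IV -> mediator -> DV.

    z = a*b / sqrt(b^2 se_a^2 + a^2 se_b^2); the proportion mediated is
    (c - c') / c, the relative drop of the IV effect once the mediator
    enters the model.
    """
    iv = np.asarray(iv, dtype=float)
    m = np.asarray(mediator, dtype=float)
    dv = np.asarray(dv, dtype=float)
    if not iv.size == m.size == dv.size:
        raise ValueError("iv, mediator and dv must have equal length")
    if iv.size < 30:
        raise ValueError("need at least 30 units for mediation analysis")
    for name, v in (("iv", iv), ("mediator", m), ("dv", dv)):
        if v.std() == 0:
            raise ValueError(f"{name} has zero variance")
    X_iv = sm.add_constant(iv)
    fit_a = sm.OLS(m, X_iv).fit()
    a, se_a = float(fit_a.params[1]), float(fit_a.bse[1])
    fit_c = sm.OLS(dv, X_iv).fit()
    c = float(fit_c.params[1])
    X_full = sm.add_constant(np.column_stack([iv, m]))
    fit_b = sm.OLS(dv, X_full).fit()
    c_prime = float(fit_b.params[1])
    b, se_b = float(fit_b.params[2]), float(fit_b.bse[2])
    denom = np.sqrt(b ** 2 * se_a ** 2 + a ** 2 * se_b ** 2)
    z = a * b / denom if denom > 0 else 0.0
    p = 2 * (1 - stats.norm.cdf(abs(z)))
    prop = (c - c_prime) / c if c != 0 else np.nan
    return MediationResult(a, b, c, c_prime, se_a, se_b, float(z), float(p),
                           float(prop))
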