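"""Survival evaluation of the frailty index.

Three views of predictive performance, all over a configurable follow-up
horizon (183 days for 6 months, 365 for 1 year by default):

* Kaplan-Meier product-limit curves per score group with the unweighted
  k-sample log-rank test;
* a Cox proportional-hazards model with dummy terms for score groups 2-6
  (group 1 reference), adjusted for age (per year) and gender (female vs
  male reference), Efron handling of tied event days, Wald 95% CIs;
* fixed-horizon ROC analysis: death by the horizon is the binary outcome,
  patients censored before the horizon are excluded (and counted), AUC is
  computed through the rank (Mann-Whitney) identity with midrank tie
  handling and its standard error with the DeLong estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "KMEstimate",
    "CoxTerm",
    "CoxResult",
    "ROCResult",
    "km_by_group",
    "cox_groups",
    "roc_at_horizon",
    "per_parameter_auc",
    "HORIZON_6M",
    "HORIZON_12M",
]

HORIZON_6M = 183
HORIZON_12M = 365


@dataclass(frozen=True)
class KMEstimate:
    group: int
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    logrank_p: float  # shared across groups


@dataclass(frozen=True)
class CoxTerm:
    name: str
    coef: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float


@dataclass(frozen=True)
class CoxResult:
    terms: tuple[CoxTerm, ...]
    horizon_days: int
    n: int
    n_events: int
    dropped: tuple[str, ...] = field(default_factory=tuple)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "term": t.name,
                    "coef": t.coef,
                    "se": t.se,
                    "hr": t.hr,
                    "ci_low": t.ci_low,
                    "ci_high": t.ci_high,
                    "p": t.p,
                }
                for t in self.terms
            ]
        )


@dataclass(frozen=True)
class ROCResult:
    horizon_days: int
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    auc_se: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int
    n_excluded: int = 0

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])


def _apply_horizon(time_days, event, horizon_days: float):
    t = np.asarray(time_days, dtype=float)
    e = np.asarray(event, dtype=int)
    t_h = np.minimum(t, horizon_days)
    e_h = ((e == 1) & (t <= horizon_days)).astype(int)
    return t_h, e_h


def km_by_group(
    cohort: pd.DataFrame,
    horizon_days: int = HORIZON_12M,
) -> tuple[list[KMEstimate], float]:
    """Product-limit curves per score group plus the k-sample log-rank p.

    ``cohort`` needs ``time_days``, ``event`` and ``group`` columns.
    Follow-up is administratively censored at the horizon.  Empty groups are
    simply absent; a single populated group makes the log-rank undefined and
    raises.
    """
    t, e = _apply_horizon(cohort["time_days"], cohort["event"], horizon_days)
    groups = np.asarray(cohort["group"], dtype=int)
    present = np.unique(groups)
    if present.size < 2:
        raise ValueError("log-rank requires at least two populated score groups")

    if e.sum() == 0:
        logrank_p = 1.0
    else:
        res = multivariate_logrank_test(t, groups, e)
        logrank_p = float(res.p_value)

    estimates = []
    for g in present:
        mask = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], event_observed=e[mask])
        table = kmf.event_table
        sf = kmf.survival_function_
        estimates.append(
            KMEstimate(
                group=int(g),
                times=sf.index.to_numpy(dtype=float),
                survival=sf.iloc[:, 0].to_numpy(dtype=float),
                at_risk=table["at_risk"].to_numpy(dtype=float),
                events=table["observed"].to_numpy(dtype=float),
                logrank_p=logrank_p,
            )
        )
    return estimates, logrank_p


def cox_groups(
    cohort: pd.DataFrame,
    horizon_days: int = HORIZON_12M,
    reference_group: int = 1,
) -> CoxResult:
    """Cox PH fit of score-group dummies adjusted for age and gender.

    Terms are ``group[k]`` for each populated non-reference group, ``age``
    (per year) and ``gender[2]`` (female indicator; male is the reference
    level).  Ties are handled with Efron's approximation (the lifelines
    default); CIs are 95% Wald on the log-hazard scale.
    """
    t, e = _apply_horizon(cohort["time_days"], cohort["event"], horizon_days)
    groups = np.asarray(cohort["group"], dtype=int)
    present = sorted(np.unique(groups))
    if len(present) < 2:
        raise ValueError("Cox model requires at least two populated score groups")
    if e.sum() == 0:
        raise ValueError("Cox model requires at least one event before the horizon")

    df = pd.DataFrame({"time": t, "event": e})
    dropped = []
    term_names = []
    for g in present:
        if g == reference_group:
            continue
        name = f"group[{g}]"
        mask = groups == g
        if e[mask].sum() == 0:
            # no events in the group: the dummy's partial likelihood is
            # monotone (no finite MLE), so the term is dropped
            warnings.warn(f"score {name} has no events before day {horizon_days}; term dropped",
                          stacklevel=2)
            dropped.append(name)
            continue
        df[name] = mask.astype(float)
        term_names.append(name)
    df["age"] = np.asarray(cohort["age"], dtype=float)
    df["gender[2]"] = (cohort["sex"].astype(str) == "female").to_numpy(dtype=float)
    for adj in ("age", "gender[2]"):
        if df[adj].nunique() <= 1:  # constant covariate: singular information
            warnings.warn(f"adjustment covariate {adj} is constant; term dropped",
                          stacklevel=2)
            df = df.drop(columns=[adj])
            dropped.append(adj)
        else:
            term_names.append(adj)

    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")  # Efron ties
    summary = cph.summary

    terms = []
    for name in term_names:
        row = summary.loc[name]
        terms.append(
            CoxTerm(
                name=name,
                coef=float(row["coef"]),
                se=float(row["se(coef)"]),
                hr=float(row["exp(coef)"]),
                ci_low=float(row["exp(coef) lower 95%"]),
                ci_high=float(row["exp(coef) upper 95%"]),
                p=float(row["p"]),
            )
        )
    return CoxResult(
        terms=tuple(terms),
        horizon_days=horizon_days,
        n=len(df),
        n_events=int(e.sum()),
        dropped=tuple(dropped),
    )


def _auc_rank(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC through the Mann-Whitney identity U / (n_pos * n_neg), midranks."""
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    m = pos.size
    u = ranks[:m].sum() - m * (m + 1) / 2.0
    return float(u / (m * neg.size))


def _delong_se(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong standard error of the empirical AUC (midrank tie handling)."""
    m, n = pos.size, neg.size
    cmp_matrix = (pos[:, None] > neg[None, :]).astype(float)
    cmp_matrix += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp_matrix.mean(axis=1)  # structural components per positive
    v01 = cmp_matrix.mean(axis=0)  # per negative
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(np.sqrt(s10 / m + s01 / n))


def roc_at_horizon(
    scores,
    time_days,
    event,
    horizon_days: int = HORIZON_12M,
) -> ROCResult:
    """Fixed-horizon ROC of a continuous (or binary) score.

    Positives died on or before the horizon; negatives have follow-up
    reaching the horizon alive.  Patients censored before the horizon are
    excluded and counted in ``n_excluded``.  Patients with a missing score
    are likewise excluded.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time_days, dtype=float)
    e = np.asarray(event, dtype=int)
    measured = ~np.isnan(s)
    pos_mask = (e == 1) & (t <= horizon_days)
    neg_mask = (t >= horizon_days) & ~pos_mask
    usable = (pos_mask | neg_mask) & measured
    n_excluded = int((~usable).sum())

    pos = s[pos_mask & measured]
    neg = s[neg_mask & measured]
    if pos.size == 0 or neg.size == 0:
        raise ValueError(
            f"horizon {horizon_days} d leaves {pos.size} positives and {neg.size} negatives"
        )

    auc = _auc_rank(pos, neg)
    se = _delong_se(pos, neg)
    fpr, tpr, _ = roc_curve(
        np.concatenate([np.ones(pos.size), np.zeros(neg.size)]),
        np.concatenate([pos, neg]),
    )
    ci = (max(0.0, auc - 1.959963984540054 * se), min(1.0, auc + 1.959963984540054 * se))
    return ROCResult(
        horizon_days=horizon_days,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        auc_se=se,
        ci95=ci,
        n_pos=pos.size,
        n_neg=neg.size,
        n_excluded=n_excluded,
    )


def per_parameter_auc(
    deficit_matrix: pd.DataFrame,
    time_days,
    event,
    horizons=(HORIZON_6M, HORIZON_12M),
) -> pd.DataFrame:
    """Discrimination of each analyte's 0/1 code at each horizon.

    One row per analyte x horizon with AUC, DeLong SE, Wald 95% CI and the
    two-sided p against AUC = 0.5.  For a binary marker the AUC equals
    (sensitivity + specificity) / 2.  Analytes that are untestable at a
    horizon (all missing in one outcome group, or constant) are flagged in
    the ``testable`` column; constant analytes still get AUC 0.5.
    """
    t = np.asarray(time_days, dtype=float)
    e = np.asarray(event, dtype=int)
    rows = []
    for horizon in horizons:
        for analyte in deficit_matrix.columns:
            codes = deficit_matrix[analyte].to_numpy(dtype=float)
            row = {"analyte_id": analyte, "horizon_days": int(horizon)}
            try:
                roc = roc_at_horizon(codes, t, e, horizon_days=horizon)
            except ValueError:
                rows.append(
                    {**row, "auc": np.nan, "se": np.nan, "ci_low": np.nan,
                     "ci_high": np.nan, "p": np.nan, "n_pos": 0, "n_neg": 0,
                     "testable": False}
                )
                continue
            constant = roc.auc_se == 0.0
            if constant:
                p = np.nan
            else:
                z = (roc.auc - 0.5) / roc.auc_se
                p = float(2 * stats.norm.sf(abs(z)))
            rows.append(
                {
                    **row,
                    "auc": roc.auc,
                    "se": roc.auc_se,
                    "ci_low": roc.ci95[0],
                    "ci_high": roc.ci95[1],
                    "p": p,
                    "n_pos": roc.n_pos,
                    "n_neg": roc.n_neg,
                    "testable": not constant,
                }
            )
    out = pd.DataFrame(rows)
    n_flagged = int((~out["testable"]).sum())
    if n_flagged:
        warnings.warn(f"{n_flagged} analyte/horizon rows untestable or constant", stacklevel=2)
    return out
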