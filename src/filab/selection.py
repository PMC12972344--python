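"""Panel reduction by volcano ranking of coded deficits.

Each analyte's 0/1 deficit codes are compared between patients who died
within the outcome horizon and those who survived it, with a two-sided
Mann-Whitney U test.  Binary data are maximally tied, so the exact null
distribution of U collapses onto the hypergeometric distribution of the
deficit count in one group; that exact computation is used for small
samples, and the tie-corrected normal approximation (with continuity
correction) otherwise.  Raw p-values are adjusted for multiplicity
(Benjamini-Hochberg by default) and each analyte gets volcano coordinates:
the decedent-survivor difference in deficit prevalence on the x-axis and
-log10 of the adjusted p-value on the y-axis.

Panel selection takes all significant analytes first, then fills the
remaining slots with the analytes showing the strongest tendency towards
significance (smallest adjusted p among the non-significant), with optional
force-include / force-exclude overrides for judgment calls the statistics
alone cannot make (e.g. organ-system coverage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "VolcanoRow",
    "SelectionResult",
    "mannwhitney_binary",
    "adjust_pvalues",
    "volcano_table",
    "select_panel",
]

#: Combined sample size at or below which the exact null distribution is used.
EXACT_THRESHOLD = 20

_ADJUST_METHODS = {"bh_fdr": "fdr_bh", "holm": "holm", "bonferroni": "bonferroni"}


@dataclass(frozen=True)
class VolcanoRow:
    analyte_id: str
    prop_dead: float
    prop_alive: float
    effect: float
    p_raw: float
    p_adj: float
    significant: bool
    neg_log10_p_adj: float


@dataclass(frozen=True)
class SelectionResult:
    selected: tuple[str, ...]
    n_significant: int
    n_trending: int
    alpha: float
    target_size: int
    overrides_applied: tuple[str, ...] = field(default_factory=tuple)


def _validate_binary(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError(f"group {name} is empty after dropping missing codes")
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError(f"group {name} contains values outside {{0, 1}}")
    return x


def _u_statistic_binary(k1: float, n1: int, n2: int, k_total: float) -> float:
    """Mann-Whitney U of group 1 from its deficit count, via midranks."""
    n = n1 + n2
    n_zero = n - k_total
    rank_zero = (n_zero + 1) / 2.0
    rank_one = n_zero + (k_total + 1) / 2.0
    r1 = (n1 - k1) * rank_zero + k1 * rank_one
    return r1 - n1 * (n1 + 1) / 2.0


def mannwhitney_binary(
    codes_a,
    codes_b,
    exact_threshold: int = EXACT_THRESHOLD,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test for two samples of 0/1 codes.

    Returns ``(U, p)`` with U the statistic of ``codes_a`` (midrank
    convention).  For combined n <= ``exact_threshold`` the p-value is exact:
    with only two distinct values the permutation distribution of U is a
    deterministic function of the hypergeometric count of ones in group a,
    so the exact two-sided p sums hypergeometric probabilities of counts at
    least as extreme as observed.  For larger samples the tie-corrected
    normal approximation with continuity correction is used.  Missing codes
    (NaN) are dropped before testing.
    """
    a = _validate_binary(codes_a, "a")
    b = _validate_binary(codes_b, "b")
    n1, n2 = a.size, b.size
    n = n1 + n2
    k1 = float(a.sum())
    k_total = k1 + float(b.sum())
    u_obs = _u_statistic_binary(k1, n1, n2, k_total)

    if k_total == 0 or k_total == n:
        return u_obs, 1.0  # constant data: no difference possible

    if n <= exact_threshold:
        mean_k = n1 * k_total / n
        k_min = int(max(0, k_total - n2))
        k_max = int(min(n1, k_total))
        ks = np.arange(k_min, k_max + 1)
        pmf = stats.hypergeom.pmf(ks, n, int(k_total), n1)
        extreme = np.abs(ks - mean_k) >= abs(k1 - mean_k) - 1e-12
        p = float(min(1.0, pmf[extreme].sum()))
        if p > 1 - 1e-9:
            p = 1.0
        return u_obs, max(p, np.finfo(float).tiny)

    # tie-corrected normal approximation; with only two distinct values U
    # moves on a lattice of step n/2, so the continuity correction is n/4
    mu = n1 * n2 / 2.0
    tie_term = sum(t**3 - t for t in (n - k_total, k_total))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return u_obs, 1.0
    z = max(0.0, abs(u_obs - mu) - n / 4.0) / np.sqrt(var)
    p = float(min(1.0, 2 * stats.norm.sf(z)))
    return u_obs, p


def adjust_pvalues(p_raw, method: str = "bh_fdr") -> np.ndarray:
    """Multiplicity-adjusted p-values, clipped at 1.

    ``method`` is one of ``bh_fdr`` (Benjamini-Hochberg step-up, the
    default), ``holm`` (step-down) or ``bonferroni``.
    """
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in _ADJUST_METHODS:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=_ADJUST_METHODS[method])[1]


def volcano_table(
    deficit_matrix: pd.DataFrame,
    outcome,
    alpha: float = 0.05,
    method: str = "bh_fdr",
) -> tuple[pd.DataFrame, list[str]]:
    """Per-analyte volcano rows from a patients x analytes code matrix.

    ``outcome`` is a boolean/0-1 vector (died within horizon) aligned with
    the matrix rows.  Returns ``(table, untestable)`` where ``table`` has one
    row per testable analyte (columns mirroring :class:`VolcanoRow`) and
    ``untestable`` lists analytes with no non-missing codes in one of the
    outcome groups.  Adjustment is applied across all testable analytes.
    """
    outcome = np.asarray(outcome, dtype=bool)
    if outcome.shape[0] != len(deficit_matrix):
        raise ValueError("outcome and deficit matrix are not aligned")
    n_dead = int(outcome.sum())
    n_alive = int((~outcome).sum())
    if n_dead < 2 or n_alive < 2:
        raise ValueError(
            f"degenerate outcome: {n_dead} decedents vs {n_alive} survivors "
            "(need at least 2 in each)"
        )

    rows, untestable = [], []
    for analyte in deficit_matrix.columns:
        codes = deficit_matrix[analyte].to_numpy(dtype=float)
        dead = codes[outcome]
        alive = codes[~outcome]
        dead = dead[~np.isnan(dead)]
        alive = alive[~np.isnan(alive)]
        if dead.size == 0 or alive.size == 0:
            untestable.append(analyte)
            continue
        _, p = mannwhitney_binary(dead, alive)
        prop_dead = float(dead.mean())
        prop_alive = float(alive.mean())
        rows.append(
            {
                "analyte_id": analyte,
                "prop_dead": prop_dead,
                "prop_alive": prop_alive,
                "effect": prop_dead - prop_alive,
                "p_raw": p,
            }
        )
    if not rows:
        raise ValueError("no testable analytes")
    table = pd.DataFrame(rows)
    table["p_adj"] = adjust_pvalues(table["p_raw"].to_numpy(), method=method)
    table["significant"] = table["p_adj"] < alpha
    table["neg_log10_p_adj"] = -np.log10(np.maximum(table["p_adj"], np.finfo(float).tiny))
    return table, untestable


def _rank_order(table: pd.DataFrame) -> pd.DataFrame:
    # deterministic: p_adj, then p_raw, then larger |effect|, then analyte_id
    t = table.copy()
    t["_abs_effect"] = -t["effect"].abs()
    t = t.sort_values(
        ["p_adj", "p_raw", "_abs_effect", "analyte_id"],
        kind="mergesort",
    ).drop(columns="_abs_effect")
    return t


def select_panel(
    volcano: pd.DataFrame,
    target_size: int = 21,
    alpha: float = 0.05,
    force_include: list[str] | None = None,
    force_exclude: list[str] | None = None,
) -> SelectionResult:
    """Reduce a panel to ``target_size`` analytes from a volcano table.

    All significant analytes (adjusted p < ``alpha``) are taken first in
    ascending adjusted-p order; remaining slots are filled by the
    non-significant analytes with a descending tendency towards significance
    (again ascending adjusted p).  ``force_include`` entries displace the
    lowest-ranked fills and ``force_exclude`` entries are never selected;
    applied overrides are reported.
    """
    force_include = list(force_include or [])
    force_exclude = list(force_exclude or [])
    known = set(volcano["analyte_id"])
    for a in force_include + force_exclude:
        if a not in known:
            raise KeyError(f"override analyte {a!r} not in volcano table")
    if target_size > len(known) - len(set(force_exclude) - set(force_include)):
        raise ValueError(
            f"target_size {target_size} exceeds the {len(known)} testable analytes "
            "remaining after exclusions"
        )

    ranked = _rank_order(volcano)
    ranked = ranked[~ranked["analyte_id"].isin(force_exclude)]
    order = list(ranked["analyte_id"])

    selected = order[:target_size]
    overrides: list[str] = []
    for a in force_include:
        if a in selected:
            continue
        # displace the lowest-ranked selection that is not itself forced
        for victim in reversed(selected):
            if victim not in force_include:
                selected.remove(victim)
                break
        else:
            raise ValueError("force_include list exceeds target_size")
        selected.append(a)
        overrides.append(f"force_include:{a}")
    overrides.extend(f"force_exclude:{a}" for a in force_exclude)

    sig = set(ranked.loc[ranked["significant"], "analyte_id"])
    selected_ranked = [a for a in order if a in selected]
    # forced analytes outside the ranking order go last
    selected_final = selected_ranked + [a for a in selected if a not in selected_ranked]
    n_significant = sum(a in sig for a in selected_final)
    return SelectionResult(
        selected=tuple(selected_final),
        n_significant=n_significant,
        n_trending=len(selected_final) - n_significant,
        alpha=alpha,
        target_size=target_size,
        overrides_applied=tuple(overrides),
    )
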