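"""Model/Results interface tying the pipeline together.

:class:`FrailtyLabModel` is built from a cohort table and a reference
panel; :meth:`FrailtyLabModel.fit` runs scoring, optional volcano-based
panel reduction, and the survival evaluation, returning a
:class:`FrailtyLabResults` that carries the score table, the volcano and
selection outputs, Kaplan-Meier/log-rank, Cox terms, and fixed-horizon
ROC/AUC results, with a ``summary()`` in the spirit of statsmodels results.

    >>> from filab import FrailtyLabModel, GeneratorConfig, generate_cohort
    >>> cohort, _ = generate_cohort(GeneratorConfig(seed=1))
    >>> res = FrailtyLabModel(cohort).fit(selection={"target_size": 21})
    >>> print(res.summary())                       # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import scoring, selection as sel, survival as surv
from .io import read_cohort
from .panels import ReferencePanel, load_filab21, load_filab44

__all__ = ["FrailtyLabModel", "FrailtyLabResults"]


@dataclass
class FrailtyLabResults:
    """Everything the fitted pipeline produced."""

    panel_id: str
    scores: pd.DataFrame
    excluded: pd.DataFrame
    score_summary: dict[str, float]
    horizons: tuple[int, ...]
    roc: dict[int, surv.ROCResult]
    cox: dict[int, surv.CoxResult]
    km: list[surv.KMEstimate]
    logrank_p: float
    per_parameter: pd.DataFrame
    volcano: pd.DataFrame | None = None
    selection: sel.SelectionResult | None = None
    selected_panel: ReferencePanel | None = None
    initial_scores: pd.DataFrame | None = None
    untestable: tuple[str, ...] = field(default_factory=tuple)

    @property
    def auc(self) -> dict[int, float]:
        return {h: r.auc for h, r in self.roc.items()}

    def summary(self) -> str:
        lines = []
        s = self.score_summary
        lines.append("Laboratory-based frailty index — fit summary")
        lines.append("=" * 60)
        lines.append(f"panel: {self.panel_id}   patients scored: {len(self.scores)}"
                     f"   excluded: {len(self.excluded)}")
        if s:
            lines.append(
                f"score: mean {s['mean']:.3f}  median {s['median']:.3f}  "
                f"min {s['min']:.2f}  max {s['max']:.2f}"
            )
            lines.append(
                f"percentiles: 1st {s['p1']:.2f}  5th {s['p5']:.2f}  "
                f"95th {s['p95']:.2f}  99th {s['p99']:.2f}"
            )
        if self.selection is not None:
            lines.append(
                f"panel selection: {self.selection.n_significant} significant + "
                f"{self.selection.n_trending} trending -> {len(self.selection.selected)} analytes"
            )
        lines.append(f"log-rank across score groups: p = {self.logrank_p:.3g}")
        for h in self.horizons:
            r = self.roc[h]
            lines.append(
                f"AUC @ {h} d: {r.auc:.4f} (SE {r.auc_se:.4f}, "
                f"95% CI {r.ci95[0]:.4f}-{r.ci95[1]:.4f}; "
                f"{r.n_pos} deaths / {r.n_neg} survivors)"
            )
        for h in self.horizons:
            lines.append(f"Cox PH terms @ {h} d (reference: group 1, male):")
            frame = self.cox[h].to_frame()
            for _, row in frame.iterrows():
                lines.append(
                    f"  {row['term']:<10} HR {row['hr']:7.3f}  "
                    f"95% CI {row['ci_low']:.3f}-{row['ci_high']:.3f}  p {row['p']:.4f}"
                )
        return "\n".join(lines)

    # -- plotting ---------------------------------------------------------
    def plot_km(self, ax=None):
        """Kaplan-Meier survival curves per score group (step functions)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for est in self.km:
            ax.step(est.times, est.survival, where="post", label=f"group {est.group}")
        ax.set_xlabel("days since surgery")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.02)
        ax.legend(title=f"log-rank p = {self.logrank_p:.2g}")
        return ax

    def plot_roc(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for h in self.horizons:
            r = self.roc[h]
            ax.plot(r.fpr, r.tpr, label=f"{h} d (AUC {r.auc:.3f})")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
        return ax

    def plot_volcano(self, ax=None):
        """Effect (prevalence difference) vs -log10 adjusted p, selected labelled."""
        import matplotlib.pyplot as plt

        if self.volcano is None:
            raise ValueError("no selection stage was run")
        if ax is None:
            _, ax = plt.subplots()
        v = self.volcano
        chosen = set(self.selection.selected) if self.selection else set()
        in_sel = v["analyte_id"].isin(chosen)
        ax.scatter(v.loc[~in_sel, "effect"], v.loc[~in_sel, "neg_log10_p_adj"],
                   c="grey", s=18, label="not selected")
        ax.scatter(v.loc[in_sel, "effect"], v.loc[in_sel, "neg_log10_p_adj"],
                   c="crimson", s=24, label="selected")
        for _, row in v[in_sel].iterrows():
            ax.annotate(row["analyte_id"], (row["effect"], row["neg_log10_p_adj"]),
                        fontsize=6, xytext=(2, 2), textcoords="offset points")
        ax.axhline(-np.log10(0.05), ls=":", c="k", lw=0.8)
        ax.set_xlabel("deficit prevalence difference (dead - alive)")
        ax.set_ylabel("-log10 adjusted p")
        ax.legend()
        return ax


class FrailtyLabModel:
    """Frailty-index pipeline over one cohort.

    Parameters
    ----------
    cohort : DataFrame with ``patient_id, age, sex, time_days, event`` and
        one column per measured analyte (canonical analyte ids, NaN/empty =
        not measured).
    panel : reference panel to score against; default is the packaged
        44-analyte admission panel.
    min_available_fraction : availability threshold below which a patient is
        excluded instead of scored (default 0.70).
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        panel: ReferencePanel | None = None,
        min_available_fraction: float = scoring.MIN_AVAILABLE_FRACTION,
    ):
        if cohort.empty:
            raise ValueError("empty cohort")
        for col in ("patient_id", "age", "sex", "time_days", "event"):
            if col not in cohort.columns:
                raise ValueError(f"cohort lacks required column {col!r}")
        self.cohort = cohort.reset_index(drop=True)
        self.panel = panel if panel is not None else load_filab44()
        self.min_available_fraction = min_available_fraction

    @classmethod
    def from_csv(cls, path, panel: ReferencePanel | None = None, **kwargs) -> "FrailtyLabModel":
        panel = panel if panel is not None else load_filab44()
        return cls(read_cohort(path, panel=panel), panel=panel, **kwargs)

    # convenience constructors for the packaged panels
    @classmethod
    def filab21(cls, cohort: pd.DataFrame, **kwargs) -> "FrailtyLabModel":
        return cls(cohort, panel=load_filab21(), **kwargs)

    def _score(self, panel: ReferencePanel):
        return scoring.score_cohort(
            self.cohort, panel, min_available_fraction=self.min_available_fraction
        )

    def fit(
        self,
        horizons: Sequence[int] = (surv.HORIZON_6M, surv.HORIZON_12M),
        selection: Mapping | bool | None = None,
        alpha: float = 0.05,
        adjust_method: str = "bh_fdr",
        selection_horizon: int = surv.HORIZON_12M,
    ) -> FrailtyLabResults:
        """Run scoring, optional panel reduction and survival evaluation.

        ``selection`` may be None/False (score with ``self.panel`` as is),
        True (reduce with defaults: target size 21, alpha 0.05, BH), or a
        mapping with ``target_size``, ``alpha``, ``method``,
        ``force_include``, ``force_exclude`` keys.  The selection outcome is
        death within ``selection_horizon`` days.
        """
        horizons = tuple(int(h) for h in horizons)
        panel = self.panel
        scores, excluded, summary = self._score(panel)
        if scores.empty:
            raise ValueError("no patients passed the availability filter")

        volcano = None
        sel_result = None
        selected_panel = None
        initial_scores = None
        untestable: tuple[str, ...] = ()

        if selection:
            opts = dict(selection) if isinstance(selection, Mapping) else {}
            included = self.cohort["patient_id"].isin(scores["patient_id"])
            sub = self.cohort[included]
            codes = scoring.code_cohort_matrix(sub, panel)
            died = (sub["event"].to_numpy(dtype=int) == 1) & (
                sub["time_days"].to_numpy(dtype=float) <= selection_horizon
            )
            volcano, untest = sel.volcano_table(
                codes, died,
                alpha=opts.get("alpha", alpha),
                method=opts.get("method", adjust_method),
            )
            untestable = tuple(untest)
            sel_result = sel.select_panel(
                volcano,
                target_size=opts.get("target_size", 21),
                alpha=opts.get("alpha", alpha),
                force_include=opts.get("force_include"),
                force_exclude=opts.get("force_exclude"),
            )
            selected_panel = panel.subset(
                sel_result.selected, panel_id=f"{panel.panel_id}_selected{len(sel_result.selected)}"
            )
            initial_scores = scores
            panel = selected_panel
            scores, excluded, summary = self._score(panel)

        merged = scores.merge(
            self.cohort[["patient_id", "age", "sex", "time_days", "event"]],
            on="patient_id",
        )
        km, logrank_p = surv.km_by_group(merged, horizon_days=max(horizons))
        codes = scoring.code_cohort_matrix(
            self.cohort[self.cohort["patient_id"].isin(scores["patient_id"])], panel
        )
        roc = {}
        cox = {}
        for h in horizons:
            roc[h] = surv.roc_at_horizon(
                merged["value"], merged["time_days"], merged["event"], horizon_days=h
            )
            cox[h] = surv.cox_groups(merged, horizon_days=h)
        sub = self.cohort[self.cohort["patient_id"].isin(scores["patient_id"])]
        per_param = surv.per_parameter_auc(
            codes, sub["time_days"], sub["event"], horizons=horizons
        )

        return FrailtyLabResults(
            panel_id=panel.panel_id,
            scores=scores,
            excluded=excluded,
            score_summary=summary,
            horizons=horizons,
            roc=roc,
            cox=cox,
            km=km,
            logrank_p=logrank_p,
            per_parameter=per_param,
            volcano=volcano,
            selection=sel_result,
            selected_panel=selected_panel,
            initial_scores=initial_scores,
            untestable=untestable,
        )
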