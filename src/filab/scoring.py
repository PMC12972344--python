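"""Deficit-accumulation scoring.

The frailty index of a patient is the fraction of measured panel analytes
that are outside their reference range:

    FI = n_deficits / n_available

Missing analytes reduce the denominator rather than being imputed, so the
score stays a proportion of what was actually measured.  Patients with fewer
than 70% of the panel available (configurable) are excluded from downstream
analysis rather than scored.  Scores are binned into six groups at the
one-decimal edges 0.1 ... 0.5 (right-closed), the grouping used by the
survival analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .panels import ReferencePanel, Sex

__all__ = [
    "PatientRecord",
    "DeficitVector",
    "FrailtyIndex",
    "GROUP_EDGES",
    "code_patient",
    "code_cohort_matrix",
    "compute_index",
    "assign_group",
    "score_cohort",
]

#: Right edges of score groups 1..5; everything above the last edge is group 6.
GROUP_EDGES: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5)

#: Default minimum fraction of the panel that must be measured for inclusion.
MIN_AVAILABLE_FRACTION = 0.70


@dataclass(frozen=True)
class PatientRecord:
    """Demographics, admission labs and follow-up for one patient.

    ``labs`` maps analyte_id -> value; absent keys (or NaN values) are
    treated as not measured.  ``time_days`` counts from surgery to death or
    censoring; ``event`` is 1 for death, 0 for censoring.
    """

    patient_id: str
    age: float
    sex: Sex
    labs: Mapping[str, float]
    time_days: float = np.nan
    event: int = 0

    def __post_init__(self) -> None:
        if not np.isnan(self.time_days) and self.time_days < 0:
            raise ValueError(f"{self.patient_id}: negative time_days")
        if self.event not in (0, 1):
            raise ValueError(f"{self.patient_id}: event must be 0 or 1")


@dataclass(frozen=True)
class DeficitVector:
    """Per-analyte ternary coding (0 normal, 1 deficit, None missing)."""

    patient_id: str
    panel_id: str
    codes: Mapping[str, int | None]
    n_available: int
    n_deficits: int

    def __post_init__(self) -> None:
        avail = sum(c is not None for c in self.codes.values())
        defic = sum(c == 1 for c in self.codes.values())
        if avail != self.n_available or defic != self.n_deficits:
            raise ValueError("DeficitVector counts inconsistent with codes")


@dataclass(frozen=True)
class FrailtyIndex:
    """The score and its bookkeeping; ``group`` is None when excluded."""

    patient_id: str
    panel_id: str
    value: float | None
    n_deficits: int
    n_available: int
    group: int | None
    excluded_reason: str | None = None

    @property
    def excluded(self) -> bool:
        return self.excluded_reason is not None


def code_patient(patient: PatientRecord, panel: ReferencePanel) -> DeficitVector:
    """Code every panel analyte for one patient.

    Labs not in the panel are ignored; panel analytes absent from the
    patient's labs (or NaN) are coded missing.
    """
    codes: dict[str, int | None] = {}
    for analyte in panel.analyte_order:
        value = patient.labs.get(analyte)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            codes[analyte] = None
        else:
            codes[analyte] = panel.interval_for(analyte, patient.sex).code(
                float(value), age=patient.age
            )
    n_available = sum(c is not None for c in codes.values())
    n_deficits = sum(c == 1 for c in codes.values())
    return DeficitVector(
        patient_id=patient.patient_id,
        panel_id=panel.panel_id,
        codes=codes,
        n_available=n_available,
        n_deficits=n_deficits,
    )


def code_cohort_matrix(cohort: pd.DataFrame, panel: ReferencePanel) -> pd.DataFrame:
    """Vectorised deficit coding of a cohort table.

    ``cohort`` needs ``sex`` and ``age`` columns plus one column per measured
    analyte.  Returns a patients x analytes frame of float codes (0.0 / 1.0,
    NaN for missing), columns in panel order, indexed like ``cohort``.
    """
    n = len(cohort)
    sex = cohort["sex"].astype(str).to_numpy()
    age = cohort["age"].to_numpy(dtype=float)
    out = pd.DataFrame(
        np.full((n, panel.n_analytes), np.nan),
        index=cohort.index,
        columns=list(panel.analyte_order),
    )
    for analyte in panel.analyte_order:
        if analyte not in cohort.columns:
            continue
        values = pd.to_numeric(cohort[analyte], errors="coerce").to_numpy(dtype=float)
        codes = np.full(n, np.nan)
        for s in Sex:
            mask = (sex == s.value) & ~np.isnan(values)
            if not mask.any():
                continue
            iv = panel.interval_for(analyte, s)
            v = values[mask]
            if iv.age_override is not None:
                # age-conditioned bounds are rare; fall back to scalar coding
                codes[mask] = [iv.code(x, age=a) for x, a in zip(v, age[mask])]
                continue
            lo, hi = iv.lower, iv.upper
            if iv.rule_kind.value == "two_sided":
                deficit = (v < lo) | (v > hi)
            elif iv.rule_kind.value == "upper_only":
                deficit = v >= hi
            else:
                deficit = v <= lo
            codes[mask] = deficit.astype(float)
        out[analyte] = codes
    return out


def compute_index(
    dv: DeficitVector,
    min_available_fraction: float = MIN_AVAILABLE_FRACTION,
) -> FrailtyIndex:
    """Score a deficit vector with the reduced-denominator rule.

    The denominator is the number of analytes actually measured.  If fewer
    than ``min_available_fraction`` of the panel is available the patient is
    flagged excluded (no score is emitted downstream); an all-missing vector
    is always excluded, never a division by zero.
    """
    panel_size = len(dv.codes)
    if panel_size == 0:
        raise ValueError("empty deficit vector")
    if dv.n_available == 0 or dv.n_available / panel_size < min_available_fraction:
        return FrailtyIndex(
            patient_id=dv.patient_id,
            panel_id=dv.panel_id,
            value=None,
            n_deficits=dv.n_deficits,
            n_available=dv.n_available,
            group=None,
            excluded_reason=(
                f"only {dv.n_available}/{panel_size} panel analytes available "
                f"(< {min_available_fraction:.0%})"
            ),
        )
    value = dv.n_deficits / dv.n_available
    return FrailtyIndex(
        patient_id=dv.patient_id,
        panel_id=dv.panel_id,
        value=value,
        n_deficits=dv.n_deficits,
        n_available=dv.n_available,
        group=assign_group(value),
    )


def assign_group(value: float) -> int:
    """Map a score in [0, 1] to groups 1..6.

    Bins are right-closed at the one-decimal edges: [0, 0.1], (0.1, 0.2],
    (0.2, 0.3], (0.3, 0.4], (0.4, 0.5], (0.5, 1].
    """
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"score must lie in [0, 1], got {value!r}")
    return 1 + int(np.searchsorted(GROUP_EDGES, value, side="left"))


def _percentiles(values: np.ndarray) -> dict[str, float]:
    # linear interpolation between order statistics
    p = np.percentile(values, [1, 5, 95, 99], method="linear")
    return {"p1": p[0], "p5": p[1], "p95": p[2], "p99": p[3]}


def score_cohort(
    cohort: pd.DataFrame | Iterable[PatientRecord],
    panel: ReferencePanel,
    min_available_fraction: float = MIN_AVAILABLE_FRACTION,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Score a whole cohort against a panel.

    Accepts either the cohort table (``patient_id, age, sex, time_days,
    event`` + analyte columns) or an iterable of :class:`PatientRecord`.
    Returns ``(scores, excluded, summary)``: one score row per included
    patient, the excluded patients with reasons, and summary statistics of
    the score distribution (mean, median, min, max and the 1st/5th/95th/99th
    percentiles).
    """
    if not isinstance(cohort, pd.DataFrame):
        records = list(cohort)
        if not records:
            raise ValueError("empty cohort")
        cohort = pd.DataFrame(
            [
                {
                    "patient_id": r.patient_id,
                    "age": r.age,
                    "sex": Sex(r.sex).value,
                    "time_days": r.time_days,
                    "event": r.event,
                    **dict(r.labs),
                }
                for r in records
            ]
        )
    if cohort.empty:
        raise ValueError("empty cohort")

    codes = code_cohort_matrix(cohort, panel)
    mat = codes.to_numpy()
    n_available = (~np.isnan(mat)).sum(axis=1)
    n_deficits = np.nansum(mat, axis=1).astype(int)

    rows, excluded = [], []
    for i, (_, patient) in enumerate(cohort.iterrows()):
        base = {
            "patient_id": patient["patient_id"],
            "panel_id": panel.panel_id,
            "n_deficits": int(n_deficits[i]),
            "n_available": int(n_available[i]),
        }
        if n_available[i] == 0 or n_available[i] / panel.n_analytes < min_available_fraction:
            excluded.append(
                {
                    **base,
                    "excluded_reason": (
                        f"only {n_available[i]}/{panel.n_analytes} panel analytes available"
                    ),
                }
            )
            continue
        value = n_deficits[i] / n_available[i]
        rows.append({**base, "value": value, "group": assign_group(value)})

    scores = pd.DataFrame(
        rows, columns=["patient_id", "panel_id", "n_deficits", "n_available", "value", "group"]
    )
    excluded_df = pd.DataFrame(
        excluded,
        columns=["patient_id", "panel_id", "n_deficits", "n_available", "excluded_reason"],
    )
    if scores.empty:
        warnings.warn("no patients passed the availability filter", stacklevel=2)
        summary: dict[str, float] = {}
    else:
        v = scores["value"].to_numpy()
        summary = {
            "n": float(len(v)),
            "mean": float(np.mean(v)),
            "median": float(np.median(v)),
            "min": float(np.min(v)),
            "max": float(np.max(v)),
            **{k: float(x) for k, x in _percentiles(v).items()},
        }
    return scores, excluded_df, summary
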