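"""Synthetic cohorts with the structure the frailty analysis assumes.

The default generator emulates an elderly hip-fracture cohort: ~235
patients aged >= 70 (about two thirds women), admission blood panels whose
deficit probabilities rise with a latent frailty, sparse missingness for a
few rarely-ordered assays, and one-year follow-up with ~38% mortality whose
hazard grows with the true deficit burden.

Generative model, per patient i with latent frailty f_i ~ Beta(a, b):

* deficit code of analyte j:  d_ij ~ Bernoulli( expit( logit(p0_j) + lambda_j * f_i ) )
* lab value: drawn uniformly inside the sex-specific reference interval if
  d_ij = 0, uniformly in a bounded band outside it (side chosen at random
  for two-sided rules) if d_ij = 1 — so re-coding the values reproduces the
  true codes exactly;
* missingness: each analyte is dropped independently at its missing rate;
* survival: T_i ~ Exponential( rate0 * exp( beta_frailty * dbar_i ) ) with
  dbar_i the patient's true deficit fraction over the whole panel,
  administratively censored at 365 days.

A second generator, :func:`generate_planted_cohort`, plants an *exact*
decedent-survivor difference in deficit prevalence by drawing the one-year
death flag first; it is the tool for studying the panel-selection stage,
where the quantity of interest is that prevalence difference itself.

Ground truth (latent frailties, true codes, planted loadings) is returned
alongside every cohort for parameter-recovery studies and is never consumed
by the analysis pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy.special import expit, logit

from .panels import ReferenceInterval, ReferencePanel, RuleKind, Sex, load_filab21, load_filab44
from .scoring import code_cohort_matrix
from .selection import volcano_table

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_planted_cohort",
    "recover_parameters",
]

#: Analytes measured only in a minority of patients in routine admissions.
SPARSE_ANALYTES = ("vitamin_d_125", "cholinesterase", "bone_alkaline_phosphatase")

#: Analytes carrying frailty signal by default: the reduced 21-item panel.
def _default_loadings() -> dict[str, float]:
    return {a: 2.5 for a in load_filab21().analyte_order}


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-generator settings; defaults emulate the reference cohort.

    ``baseline_rate`` (per day) was calibrated once against the 38.3%
    one-year mortality target under the default frailty and loading
    settings; ``beta_frailty`` is the log-hazard increase per unit true
    deficit fraction.
    """

    n_patients: int = 235
    seed: int = 0
    age_mean: float = 83.65
    age_sd: float = 6.3
    age_min: float = 70.0
    prop_female: float = 0.67
    panel: ReferencePanel | None = None  # None -> packaged 44-analyte panel
    baseline_prevalence: float | dict[str, float] = 0.15
    effect_analytes: dict[str, float] = field(default_factory=_default_loadings)
    frailty_a: float = 2.0
    frailty_b: float = 3.3
    baseline_rate: float = 5.0e-4
    beta_frailty: float = 4.0
    admin_censor_days: float = 365.0
    missing_rate: float = 0.02
    sparse_analytes: dict[str, float] = field(
        default_factory=lambda: {a: 0.7 for a in SPARSE_ANALYTES}
    )
    generate_values: bool = True  # skip continuous lab draws for pure simulation studies

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if not 0 <= self.prop_female <= 1:
            raise ValueError("prop_female must lie in [0, 1]")
        prevs = (
            [self.baseline_prevalence]
            if np.isscalar(self.baseline_prevalence)
            else list(self.baseline_prevalence.values())
        )
        if any(not 0 < p < 1 for p in prevs):
            raise ValueError("baseline prevalences must lie in (0, 1)")
        if self.baseline_rate <= 0 or self.frailty_a <= 0 or self.frailty_b <= 0:
            raise ValueError("rates and Beta parameters must be positive")
        if self.admin_censor_days <= 0:
            raise ValueError("admin_censor_days must be positive")
        rates = [self.missing_rate, *self.sparse_analytes.values()]
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("missing rates must lie in [0, 1]")

    def resolved_panel(self) -> ReferencePanel:
        return self.panel if self.panel is not None else load_filab44()

    def prevalence_of(self, analyte: str) -> float:
        if np.isscalar(self.baseline_prevalence):
            return float(self.baseline_prevalence)
        return float(self.baseline_prevalence[analyte])


@dataclass(frozen=True)
class GroundTruth:
    """Generator internals kept for recovery tests only."""

    frailty: np.ndarray
    loadings: dict[str, float]
    beta_frailty: float
    baseline_rate: float
    true_codes: pd.DataFrame  # pre-missingness 0/1 codes
    raw_times: np.ndarray  # uncensored survival times
    config: GeneratorConfig


def _draw_in(a: np.ndarray | float, b: np.ndarray | float, u: np.ndarray, closed: str):
    """Map uniforms u in [0, 1) onto [a, b) ('left') or (a, b] ('right')."""
    if closed == "left":
        return a + (b - a) * u
    return a + (b - a) * (1.0 - u)


def _draw_values(iv: ReferenceInterval, deficit: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Continuous values consistent with the 0/1 codes under interval ``iv``.

    Band widths outside the normal region are 50% of the interval width
    (two-sided) or of the cutoff (one-sided); magnitudes are arbitrary and
    never affect coding.  Lower bands are clipped at 0 where the normal
    region is positive.
    """
    n = deficit.size
    u = rng.random(n)
    out = np.empty(n)
    lo, hi = iv.lower, iv.upper
    if iv.rule_kind == RuleKind.two_sided:
        width = hi - lo
        normal = ~deficit.astype(bool)
        # normal: uniform on [lo, hi], boundaries inclusive-normal either way
        out[normal] = lo + width * u[normal]
        side_high = rng.random(n) < 0.5
        high = deficit.astype(bool) & side_high
        low = deficit.astype(bool) & ~side_high
        out[high] = _draw_in(hi, hi + 0.5 * width, u[high], "right")  # (hi, hi + w/2]
        band_lo = max(0.0, lo - 0.5 * width) if lo > 0 else lo - 0.5 * width
        out[low] = _draw_in(band_lo, lo, u[low], "left")  # [band_lo, lo)
    elif iv.rule_kind == RuleKind.upper_only:
        band = 0.5 * hi
        normal = ~deficit.astype(bool)
        out[normal] = _draw_in(max(0.0, hi - band), hi, u[normal], "left")  # [.., hi)
        out[~normal] = _draw_in(hi, hi + band, u[~normal], "left")  # [hi, ..)
    else:  # lower_only: normal iff value > lo
        band = 0.5 * lo
        normal = ~deficit.astype(bool)
        out[normal] = _draw_in(lo, lo + band, u[normal], "right")  # (lo, ..]
        out[~normal] = _draw_in(max(0.0, lo - band), lo, u[~normal], "right")  # (.., lo]
    return out


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw one cohort table plus its ground truth.

    The returned table has the pipeline's cohort schema (``patient_id, age,
    sex, time_days, event`` + one column per panel analyte, NaN = not
    measured).  Identical config and seed give identical cohorts.
    """
    panel = config.resolved_panel()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    female = rng.random(n) < config.prop_female
    sex = np.where(female, Sex.female.value, Sex.male.value)
    age = np.maximum(config.age_min, rng.normal(config.age_mean, config.age_sd, n))
    frailty = rng.beta(config.frailty_a, config.frailty_b, n)

    true_codes = {}
    values = {}
    for analyte in panel.analyte_order:
        p0 = config.prevalence_of(analyte)
        loading = config.effect_analytes.get(analyte, 0.0)
        p = expit(logit(p0) + loading * frailty)
        deficit = (rng.random(n) < p).astype(int)
        true_codes[analyte] = deficit
        if config.generate_values:
            col = np.empty(n)
            for s in Sex:
                mask = sex == s.value
                if mask.any():
                    col[mask] = _draw_values(
                        panel.interval_for(analyte, s), deficit[mask], rng
                    )
            values[analyte] = col

    true_codes_df = pd.DataFrame(true_codes)
    dbar = true_codes_df.to_numpy().mean(axis=1)
    rate = config.baseline_rate * np.exp(config.beta_frailty * dbar)
    raw_times = rng.exponential(1.0 / rate)
    time_days = np.minimum(raw_times, config.admin_censor_days)
    event = (raw_times <= config.admin_censor_days).astype(int)

    cohort = pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "age": np.round(age, 1),
            "sex": sex,
            "time_days": np.round(time_days, 1),
            "event": event,
        }
    )
    for analyte in panel.analyte_order:
        if config.generate_values:
            col = values[analyte]
        else:
            col = true_codes_df[analyte].to_numpy(dtype=float)
        missing_p = config.sparse_analytes.get(analyte, config.missing_rate)
        drop = rng.random(n) < missing_p
        cohort[analyte] = np.where(drop, np.nan, col)

    truth = GroundTruth(
        frailty=frailty,
        loadings=dict(config.effect_analytes),
        beta_frailty=config.beta_frailty,
        baseline_rate=config.baseline_rate,
        true_codes=true_codes_df,
        raw_times=raw_times,
        config=config,
    )
    return cohort, truth


def generate_planted_cohort(
    n_patients: int = 2000,
    planted: tuple[str, ...] | list[str] | None = None,
    delta: float = 0.30,
    mortality: float = 0.383,
    baseline_prevalence: float = 0.20,
    panel: ReferencePanel | None = None,
    seed: int = 0,
    generate_values: bool = True,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Cohort with an exact planted decedent-survivor prevalence difference.

    The one-year death flag is drawn first (Bernoulli ``mortality``); the
    planted analytes then have deficit probability ``baseline_prevalence``
    among survivors and ``baseline_prevalence + delta`` among decedents,
    while the remaining analytes are null.  Decedents die uniformly within
    the year; survivors are administratively censored at day 365.  No
    missingness is applied.
    """
    panel = panel if panel is not None else load_filab44()
    if planted is None:
        planted = tuple(load_filab21().analyte_order[:13])
    unknown = [a for a in planted if a not in panel.analyte_order]
    if unknown:
        raise KeyError(f"planted analytes not in panel: {unknown}")
    if not (0.0 < baseline_prevalence < 1.0 and 0.0 <= baseline_prevalence + delta <= 1.0):
        raise ValueError("prevalences out of range")

    rng = np.random.default_rng(seed)
    n = n_patients
    died = rng.random(n) < mortality
    female = rng.random(n) < 0.67
    sex = np.where(female, Sex.female.value, Sex.male.value)
    age = np.maximum(70.0, rng.normal(83.65, 6.3, n))

    true_codes = {}
    cohort = pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "age": np.round(age, 1),
            "sex": sex,
            "time_days": np.round(np.where(died, rng.uniform(1, 365, n), 365.0), 1),
            "event": died.astype(int),
        }
    )
    for analyte in panel.analyte_order:
        p = np.where(
            died, baseline_prevalence + (delta if analyte in planted else 0.0),
            baseline_prevalence,
        )
        deficit = (rng.random(n) < p).astype(int)
        true_codes[analyte] = deficit
        if generate_values:
            col = np.empty(n)
            for s in Sex:
                mask = sex == s.value
                if mask.any():
                    col[mask] = _draw_values(panel.interval_for(analyte, s), deficit[mask], rng)
            cohort[analyte] = col
        else:
            cohort[analyte] = deficit.astype(float)

    loadings = {a: delta for a in planted}
    config = GeneratorConfig(
        n_patients=n, seed=seed, panel=panel, baseline_prevalence=baseline_prevalence,
        effect_analytes=loadings, beta_frailty=0.0, generate_values=generate_values,
    )
    truth = GroundTruth(
        frailty=died.astype(float),
        loadings=loadings,
        beta_frailty=0.0,
        baseline_rate=np.nan,
        true_codes=pd.DataFrame(true_codes),
        raw_times=cohort["time_days"].to_numpy(dtype=float),
        config=config,
    )
    return cohort, truth


def recover_parameters(
    cohort: pd.DataFrame,
    truth: GroundTruth,
    alpha: float = 0.05,
) -> dict:
    """Check the generator's parameters against what the pipeline estimates.

    Reports (a) the Cox log-hazard coefficient of the true deficit fraction
    (estimate, SE, bias against the planted value and whether the Wald 95%
    CI covers it), (b) precision/recall of the volcano's significant set
    against the planted effect analytes, and (c) the empirical one-year
    mortality.
    """
    if len(cohort) != len(truth.true_codes):
        raise ValueError("cohort and ground truth do not match")
    dbar = truth.true_codes.to_numpy().mean(axis=1)

    df = pd.DataFrame(
        {
            "time": cohort["time_days"].to_numpy(dtype=float),
            "event": cohort["event"].to_numpy(dtype=int),
            "dbar": dbar,
        }
    )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    row = cph.summary.loc["dbar"]
    beta_hat = float(row["coef"])
    ci = (float(row["coef lower 95%"]), float(row["coef upper 95%"]))
    cox = {
        "beta_true": truth.beta_frailty,
        "beta_hat": beta_hat,
        "se": float(row["se(coef)"]),
        "ci": ci,
        "bias": beta_hat - truth.beta_frailty,
        "covered": ci[0] <= truth.beta_frailty <= ci[1],
    }

    panel = truth.config.resolved_panel()
    if truth.config.generate_values:
        codes = code_cohort_matrix(cohort, panel)
    else:
        # cohort columns already hold the 0/1 codes (NaN where dropped)
        codes = cohort[list(panel.analyte_order)]
    died = (cohort["event"].to_numpy(dtype=int) == 1) & (
        cohort["time_days"].to_numpy(dtype=float) <= 365
    )
    table, _ = volcano_table(codes, died, alpha=alpha)
    hits = set(table.loc[table["significant"], "analyte_id"])
    planted = {a for a, lam in truth.loadings.items() if lam != 0}
    precision = len(hits & planted) / len(hits) if hits else np.nan
    recall = len(hits & planted) / len(planted) if planted else np.nan

    return {
        "cox": cox,
        "volcano": {
            "n_significant": len(hits),
            "precision": precision,
            "recall": recall,
        },
        "mortality_1y": float(died.mean()),
    }
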