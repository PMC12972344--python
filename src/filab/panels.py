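"""Laboratory reference panels and deficit coding.

A deficit-accumulation frailty index built from blood work starts from a
*reference panel*: for every analyte and sex, a normality rule.  Rules come
in three kinds:

* ``two_sided`` — a reference interval ``[lower, upper]``; values inside the
  interval (boundaries included) are normal.
* ``upper_only`` — a one-sided cutoff printed as ``< upper``; normal iff the
  value is strictly below the cutoff.
* ``lower_only`` — a one-sided cutoff printed as ``> lower``; normal iff the
  value is strictly above the cutoff.

A value violating its applicable rule is a *deficit* and codes 1; a value
satisfying it codes 0.  The package ships two panels as CSV fixtures:
``filab44`` (the full 44-analyte admission panel) and ``filab21`` (the
reduced 21-analyte panel).  eGFR is shipped as a ``lower_only`` rule at
45 ml/min, the CKD-stage-3a boundary appropriate for a cohort aged >= 70;
an :class:`AgeOverride` mechanism is available to configure a different
cutoff below a minimum age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Sex",
    "RuleKind",
    "AgeOverride",
    "ReferenceInterval",
    "ReferencePanel",
    "PanelError",
    "MalformedRowError",
    "DuplicateEntryError",
    "load_reference_panel",
    "load_filab44",
    "load_filab21",
    "code_value",
]


class Sex(str, Enum):
    female = "female"
    male = "male"


class RuleKind(str, Enum):
    two_sided = "two_sided"
    upper_only = "upper_only"
    lower_only = "lower_only"


class PanelError(ValueError):
    """Base class for panel-definition problems."""


class MalformedRowError(PanelError):
    """A panel row has missing or inconsistent rule fields."""


class DuplicateEntryError(PanelError):
    """The same (analyte, sex) pair appears more than once."""


@dataclass(frozen=True)
class AgeOverride:
    """Replacement bounds that apply from ``min_age`` (years) upward."""

    min_age: float
    lower: float | None = None
    upper: float | None = None


@dataclass(frozen=True)
class ReferenceInterval:
    """One analyte's normality rule for one sex."""

    analyte_id: str
    display_name: str
    units: str
    sex: Sex
    rule_kind: RuleKind
    lower: float | None = None
    upper: float | None = None
    age_override: AgeOverride | None = None
    note: str = ""

    def __post_init__(self) -> None:
        k = self.rule_kind
        if k == RuleKind.two_sided:
            if self.lower is None or self.upper is None:
                raise MalformedRowError(
                    f"{self.analyte_id}/{self.sex.value}: two_sided rule needs both bounds"
                )
            if not self.lower < self.upper:
                raise MalformedRowError(
                    f"{self.analyte_id}/{self.sex.value}: lower must be < upper"
                )
        elif k == RuleKind.upper_only:
            if self.upper is None or self.lower is not None:
                raise MalformedRowError(
                    f"{self.analyte_id}/{self.sex.value}: upper_only rule needs exactly an upper bound"
                )
        elif k == RuleKind.lower_only:
            if self.lower is None or self.upper is not None:
                raise MalformedRowError(
                    f"{self.analyte_id}/{self.sex.value}: lower_only rule needs exactly a lower bound"
                )

    def bounds_at_age(self, age: float | None) -> tuple[float | None, float | None]:
        """Effective (lower, upper) after applying any age override."""
        lo, hi = self.lower, self.upper
        ov = self.age_override
        if ov is not None and age is not None and age >= ov.min_age:
            lo = ov.lower if ov.lower is not None else lo
            hi = ov.upper if ov.upper is not None else hi
        return lo, hi

    def code(self, value: float, age: float | None = None) -> int:
        """Return 1 if ``value`` is a deficit under this rule, else 0.

        Two-sided rules treat the boundaries as normal; one-sided rules
        follow the printed strict relation (``< upper`` / ``> lower``).
        """
        if not math.isfinite(value):
            raise ValueError(f"{self.analyte_id}: value must be finite, got {value!r}")
        lo, hi = self.bounds_at_age(age)
        if self.rule_kind == RuleKind.two_sided:
            return 0 if lo <= value <= hi else 1
        if self.rule_kind == RuleKind.upper_only:
            return 0 if value < hi else 1
        return 0 if value > lo else 1


@dataclass(frozen=True)
class ReferencePanel:
    """A validated set of reference intervals covering both sexes.

    ``analyte_order`` is the stable analyte ordering used everywhere
    downstream (deficit vectors, volcano tables, reports).
    """

    panel_id: str
    intervals: Mapping[tuple[str, Sex], ReferenceInterval]
    analyte_order: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for analyte in self.analyte_order:
            for sex in Sex:
                if (analyte, sex) not in self.intervals:
                    raise MalformedRowError(
                        f"panel {self.panel_id!r}: missing {sex.value} interval for {analyte!r}"
                    )

    @property
    def n_analytes(self) -> int:
        return len(self.analyte_order)

    def __contains__(self, analyte_id: str) -> bool:
        return analyte_id in self.analyte_order

    def interval_for(self, analyte_id: str, sex: Sex | str) -> ReferenceInterval:
        sex = Sex(sex)
        try:
            return self.intervals[(analyte_id, sex)]
        except KeyError:
            raise KeyError(
                f"panel {self.panel_id!r} has no {sex.value} interval for analyte {analyte_id!r}"
            ) from None

    def subset(self, analyte_ids: Iterable[str], panel_id: str) -> "ReferencePanel":
        """A new panel restricted to ``analyte_ids`` (order preserved as given)."""
        ids = tuple(analyte_ids)
        missing = [a for a in ids if a not in self.analyte_order]
        if missing:
            raise KeyError(f"analytes not in panel {self.panel_id!r}: {missing}")
        intervals = {
            (a, s): self.intervals[(a, s)] for a in ids for s in Sex
        }
        return ReferencePanel(panel_id=panel_id, intervals=intervals, analyte_order=ids)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.analyte_order:
            for s in Sex:
                iv = self.intervals[(a, s)]
                rows.append(
                    {
                        "analyte_id": iv.analyte_id,
                        "display_name": iv.display_name,
                        "units": iv.units,
                        "sex": iv.sex.value,
                        "rule_kind": iv.rule_kind.value,
                        "lower": iv.lower,
                        "upper": iv.upper,
                    }
                )
        return pd.DataFrame(rows)


def _parse_bound(raw, analyte: str, which: str) -> float | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
        return None
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise MalformedRowError(f"{analyte}: cannot parse {which} bound {raw!r}") from None


def load_reference_panel(source, panel_id: str | None = None) -> ReferencePanel:
    """Load and validate a panel from a CSV definition.

    ``source`` is a path or file-like object with columns ``analyte_id,
    display_name, units, sex, rule_kind, lower, upper`` (an optional ``note``
    column is carried through).  One row per analyte x sex; an empty cell
    means an absent bound.  Raises :class:`DuplicateEntryError` on repeated
    (analyte, sex) pairs and :class:`MalformedRowError` on inconsistent rule
    fields, naming the offending analyte.
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    required = {"analyte_id", "sex", "rule_kind", "lower", "upper"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise MalformedRowError(f"panel definition lacks columns: {sorted(missing_cols)}")

    intervals: dict[tuple[str, Sex], ReferenceInterval] = {}
    order: list[str] = []
    for _, row in df.iterrows():
        analyte = str(row["analyte_id"]).strip()
        if not analyte:
            raise MalformedRowError("panel row with empty analyte_id")
        try:
            sex = Sex(str(row["sex"]).strip())
        except ValueError:
            raise MalformedRowError(f"{analyte}: unknown sex {row['sex']!r}") from None
        try:
            kind = RuleKind(str(row["rule_kind"]).strip())
        except ValueError:
            raise MalformedRowError(f"{analyte}: unknown rule_kind {row['rule_kind']!r}") from None
        iv = ReferenceInterval(
            analyte_id=analyte,
            display_name=str(row.get("display_name", analyte)),
            units=str(row.get("units", "")),
            sex=sex,
            rule_kind=kind,
            lower=_parse_bound(row["lower"], analyte, "lower"),
            upper=_parse_bound(row["upper"], analyte, "upper"),
            note=str(row["note"]) if "note" in df.columns else "",
        )
        key = (analyte, sex)
        if key in intervals:
            raise DuplicateEntryError(f"duplicate panel entry for {analyte!r} / {sex.value}")
        intervals[key] = iv
        if analyte not in order:
            order.append(analyte)

    if panel_id is None:
        panel_id = getattr(source, "name", None) or "custom"
        panel_id = str(panel_id).rsplit("/", 1)[-1].removesuffix(".csv")
    return ReferencePanel(panel_id=panel_id, intervals=intervals, analyte_order=tuple(order))


def _load_packaged(name: str) -> ReferencePanel:
    ref = resources.files("filab.data").joinpath(f"{name}.csv")
    with resources.as_file(ref) as path:
        return load_reference_panel(path, panel_id=name)


def load_filab44() -> ReferencePanel:
    """The packaged 44-analyte admission panel."""
    return _load_packaged("filab44")


def load_filab21() -> ReferencePanel:
    """The packaged reduced 21-analyte panel (subset of the 44)."""
    return _load_packaged("filab21")


def code_value(
    analyte_id: str,
    value: float,
    sex: Sex | str,
    age: float,
    panel: ReferencePanel,
) -> int:
    """Code a single laboratory value against a panel: 0 normal, 1 deficit."""
    if analyte_id not in panel:
        raise KeyError(f"unknown analyte {analyte_id!r} for panel {panel.panel_id!r}")
    return panel.interval_for(analyte_id, sex).code(value, age=age)
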