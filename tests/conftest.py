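import numpy as np
import pandas as pd
import pytest

from filab import GeneratorConfig, generate_cohort, load_filab21, load_filab44


@pytest.fixture(scope="session")
def panel44():
    return load_filab44()


@pytest.fixture(scope="session")
def panel21():
    return load_filab21()


@pytest.fixture(scope="session")
def default_cohort():
    """One default-sized synthetic cohort shared across read-only tests."""
    cohort, truth = generate_cohort(GeneratorConfig(seed=11))
    return cohort, truth


def normal_value(interval):
    """A value guaranteed inside the normal region of a reference rule."""
    if interval.rule_kind.value == "two_sided":
        return 0.5 * (interval.lower + interval.upper)
    if interval.rule_kind.value == "upper_only":
        return 0.5 * interval.upper
    return interval.lower * 1.5 + 1.0


def deficit_value(interval):
    """A value guaranteed outside the normal region of a reference rule."""
    if interval.rule_kind.value == "two_sided":
        return interval.upper + 1.0
    if interval.rule_kind.value == "upper_only":
        return interval.upper + 1.0
    return max(0.0, interval.lower - 1.0)


def patient_row(panel, sex="female", age=83.0, fill=normal_value, patient_id="P1",
                time_days=365.0, event=0):
    """A one-row cohort frame with every panel analyte set by ``fill``."""
    labs = {a: fill(panel.interval_for(a, sex)) for a in panel.analyte_order}
    return pd.DataFrame(
        [{"patient_id": patient_id, "age": age, "sex": sex,
          "time_days": time_days, "event": event, **labs}]
    )
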