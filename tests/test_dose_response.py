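"""Resistance index, treatment means, fold-changes and dose correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from soilpah.dose_response import (
    dose_response_summary,
    fold_change,
    pearson_dose_correlation,
    resistance_index,
    resistance_table,
    treatment_mean,
)
from soilpah.exceptions import (
    EmptyGroupError,
    InvalidControlError,
    UndefinedCorrelationError,
)


@pytest.mark.parametrize(
    "c0, p, expected",
    [
        (5.0, 5.0, 1.0),  # no disturbance
        (5.0, 0.0, 0.0),  # 100 % impact
        (8.63, 7.16, 0.709),  # pyrene dehydrogenases, 4000 mg/kg
        (2.76, 1.63, 0.419),  # pyrene urease, 2000 mg/kg
        (2.76, 1.14, 0.260),  # pyrene urease, 4000 mg/kg
        (8.62, 8.93, 0.9306),  # stimulation: |D0| = 0.31
    ],
)
def test_resistance_index_examples(c0, p, expected):
    assert resistance_index(c0, p) == pytest.approx(expected, abs=5e-4)


def test_resistance_index_rejects_nonpositive_control():
    with pytest.raises(InvalidControlError):
        resistance_index(0.0, 1.0)
    with pytest.raises(InvalidControlError):
        resistance_index(-2.0, 1.0)


@given(
    c0=st.floats(min_value=0.1, max_value=100.0),
    delta=st.floats(min_value=0.0, max_value=100.0),
)
def test_resistance_symmetric_in_disturbance_sign(c0, delta):
    delta = min(delta, c0)  # keep the inhibited side non-negative
    assert resistance_index(c0, c0 + delta) == pytest.approx(
        resistance_index(c0, c0 - delta), abs=1e-12
    )


@given(
    c0=st.floats(min_value=0.1, max_value=100.0),
    d1=st.floats(min_value=0.0, max_value=50.0),
    d2=st.floats(min_value=0.0, max_value=50.0),
)
def test_resistance_strictly_decreasing_in_disturbance(c0, d1, d2):
    lo, hi = sorted((d1, d2))
    rs_small = resistance_index(c0, c0 + lo)
    rs_large = resistance_index(c0, c0 + hi)
    if hi - lo > 1e-9 * (c0 + hi):  # strict once the gap is resolvable in float
        assert rs_large < rs_small
    else:
        assert rs_large <= rs_small
    assert -1.0 < rs_large <= 1.0
    assert (rs_small == 1.0) == (c0 + lo == c0)  # RS = 1 iff no effective change


def test_treatment_means_match_printed_average_rows(activity_fixture_records):
    records = activity_fixture_records
    # column means over the four dose-level means, control included
    assert treatment_mean(records, "organotrophic_count", "naphthalene") == pytest.approx(30.02)
    assert treatment_mean(records, "urease", "anthracene") == pytest.approx(1.86)
    assert treatment_mean(records, "dehydrogenases", "anthracene") == pytest.approx(8.40)
    # single cell
    assert treatment_mean(records, "organotrophic_count", "pyrene", 4000) == pytest.approx(52.79)
    with pytest.raises(EmptyGroupError):
        treatment_mean(records, "urease", "pyrene", 3000)


def test_fold_change_statements(activity_fixture_records):
    records = activity_fixture_records
    control = treatment_mean(records, "organotrophic_count", "pyrene", 0)
    col = treatment_mean(records, "organotrophic_count", "pyrene")
    assert fold_change(col, control) == pytest.approx(2.157, abs=5e-4)
    assert fold_change(
        treatment_mean(records, "organotrophic_count", "pyrene", 4000), control
    ) == pytest.approx(2.893, abs=5e-4)
    assert fold_change(3.3, 3.3) == 1.0
    with pytest.raises(InvalidControlError):
        fold_change(1.0, 0.0)


def _records(doses, values, analyte="urease", hydrocarbon="pyrene"):
    return pd.DataFrame(
        {
            "analyte": analyte,
            "hydrocarbon": hydrocarbon,
            "dose_mg_per_kg": doses,
            "replicate": 1,
            "value": values,
        }
    )


def test_pearson_correlation_exact_linear_cases():
    doses = [0, 1000, 2000, 4000]
    up = _records(doses, [1.0, 2.0, 3.0, 5.0])  # exactly linear in dose
    down = _records(doses, [5.0, 4.0, 3.0, 1.0])
    assert pearson_dose_correlation(up, "urease", "pyrene") == pytest.approx(1.0)
    assert pearson_dose_correlation(down, "urease", "pyrene") == pytest.approx(-1.0)
    with pytest.raises(UndefinedCorrelationError):
        pearson_dose_correlation(_records(doses, [2.0] * 4), "urease", "pyrene")
    with pytest.raises(UndefinedCorrelationError):
        pearson_dose_correlation(_records([0, 1000], [1.0, 2.0]), "urease", "pyrene")


def test_pearson_on_printed_naphthalene_counts(activity_fixture_records):
    """Mean-level r over the printed count means; frozen brute-force value."""
    r = pearson_dose_correlation(
        activity_fixture_records, "organotrophic_count", "naphthalene", level="mean"
    )
    assert r == pytest.approx(0.988, abs=5e-4)


def test_resistance_table_mean_level(activity_fixture_records):
    table = resistance_table(activity_fixture_records)
    cell = table.query(
        "analyte == 'dehydrogenases' and hydrocarbon == 'pyrene' and dose_mg_per_kg == 4000"
    ).iloc[0]
    assert cell["c0"] == pytest.approx(8.63)
    assert cell["p_t0"] == pytest.approx(7.16)
    assert cell["d0"] == pytest.approx(1.47)
    assert cell["rs"] == pytest.approx(0.709, abs=5e-4)
    assert table["rs"].between(-1, 1).all()


def test_resistance_table_replicate_level_matches_mean_at_zero_noise():
    doses = [0, 1000, 0, 1000, 0, 1000]
    reps = [1, 1, 2, 2, 3, 3]
    df = pd.DataFrame(
        {
            "analyte": "urease",
            "hydrocarbon": "pyrene",
            "dose_mg_per_kg": doses,
            "replicate": reps,
            "value": [2.0, 1.0] * 3,
        }
    )
    mean_rs = resistance_table(df, level="mean")["rs"].iloc[0]
    rep_rs = resistance_table(df, level="replicate")["rs"].iloc[0]
    assert rep_rs == pytest.approx(mean_rs)


def test_dose_response_summary_structure(activity_fixture_records):
    summary = dose_response_summary(activity_fixture_records)
    pyr = summary.query("analyte == 'organotrophic_count' and hydrocarbon == 'pyrene'")
    assert pyr.query("dose_mg_per_kg == 0")["fold_change_vs_control"].iloc[0] == pytest.approx(1.0)
    assert pyr["column_mean_fold_change"].iloc[0] == pytest.approx(2.157, abs=5e-4)
    assert summary["pearson_r"].abs().max() <= 1.0 + 1e-12
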