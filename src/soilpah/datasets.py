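"""Packaged reference tables.

These CSVs transcribe the published treatment-mean tables of the study the
package reproduces: organotrophic bacteria counts, dehydrogenase and urease
activities (4 PAHs x 4 doses, means of 3 replicates), the printed soil
resistance grid, the Phytotoxkit inhibition percentages, the culture-media
group counts, and the printed column averages / correlation coefficients.
They contain printed means only — no replicate-level values were published.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .exceptions import FixtureError

_FILES = {
    "organotrophic_count": "organotrophic_counts.csv",
    "dehydrogenases": "dehydrogenases.csv",
    "urease": "urease.csv",
    "resistance_printed": "resistance_printed.csv",
    "phytotox_inhibition": "phytotox_inhibition.csv",
    "media_counts": "media_counts.csv",
    "printed_summaries": "printed_summaries.csv",
}


def _read(name: str) -> pd.DataFrame:
    try:
        ref = resources.files("soilpah.data").joinpath(_FILES[name])
        with ref.open("r", encoding="utf-8") as fh:
            df = pd.read_csv(fh)
    except (KeyError, FileNotFoundError) as exc:
        raise FixtureError(
            f"packaged table {name!r} unavailable; reinstall the package with its data files"
        ) from exc
    if len(df) == 0:
        raise FixtureError(f"packaged table {name!r} is empty")
    return df


def load_activity_table(analyte: str) -> pd.DataFrame:
    """Printed treatment means for one analyte, as tidy activity records.

    Returns the standard record schema (``replicate`` = 1: each printed
    value is the mean of 3 plates) plus the printed homogeneous-group
    letters.
    """
    if analyte not in ("organotrophic_count", "dehydrogenases", "urease"):
        raise FixtureError(f"no packaged activity table for analyte {analyte!r}")
    df = _read(analyte)
    df = df.assign(replicate=1)
    return df[["analyte", "hydrocarbon", "dose_mg_per_kg", "replicate", "value", "letters"]]


def load_all_activity_tables() -> pd.DataFrame:
    return pd.concat(
        [load_activity_table(a) for a in ("organotrophic_count", "dehydrogenases", "urease")],
        ignore_index=True,
    )


def load_resistance_printed() -> pd.DataFrame:
    """The published soil-resistance grid (RS per enzyme x PAH x dose)."""
    return _read("resistance_printed")


def load_phytotox_inhibition() -> pd.DataFrame:
    """Published SG/RI inhibition percentages, one row per species x PAH x metric."""
    long = _read("phytotox_inhibition")
    wide = long.pivot(index=["species", "hydrocarbon"], columns="metric", values="value")
    wide = wide.rename(columns={"sg": "sg_percent", "ri": "ri_percent"}).reset_index()
    wide.columns.name = None
    return wide


def load_media_counts() -> pd.DataFrame:
    """Published culture-media group counts (control + four PAHs at 4000 mg/kg)."""
    return _read("media_counts")


def load_printed_summaries() -> pd.DataFrame:
    """Printed column averages and dose-correlation coefficients."""
    return _read("printed_summaries")
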