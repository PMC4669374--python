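"""Plate observations: CFU conversion and daily colony-appearance series.

Organotrophic bacteria are counted on dilution plates and expressed as
colony-forming units (CFU) per kilogram of soil dry matter:

    cfu = a * n * (100 / %DM) * 10^3

where ``a`` is the number of colonies on the plate, ``n`` the inverse of the
dilution factor (e.g. 1e5 for a 10^-5 dilution), ``%DM`` the soil dry-matter
percentage and 10^3 converts from gram to kilogram basis.

New colonies are also recorded daily over a fixed observation window
(default 10 days); the resulting per-plate vector of daily appearance counts
is the input to the community indices (CD, EP).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import require_columns
from .exceptions import EmptySeriesError, InvalidInputError

#: The four model PAHs used as contamination treatments.
HYDROCARBONS: tuple[str, ...] = ("naphthalene", "phenanthrene", "anthracene", "pyrene")

#: Contamination doses in mg per kg of soil dry matter; 0 is the shared control.
DOSES: tuple[int, ...] = (0, 1000, 2000, 4000)

#: Default length of the colony-observation window, in days.
DEFAULT_DAYS = 10

SERIES_COLUMNS = ["sample_id", "hydrocarbon", "dose_mg_per_kg", "replicate", "day", "new_colonies"]


@dataclass(frozen=True)
class TreatmentKey:
    """One experimental treatment: a PAH and a dose (0 = uncontaminated control)."""

    hydrocarbon: str
    dose_mg_per_kg: int

    def __post_init__(self) -> None:
        # "control" is accepted at dose 0 for assays (Phytotoxkit) where the
        # uncontaminated soil is shared across the four PAH treatments.
        allowed = HYDROCARBONS + (("control",) if self.dose_mg_per_kg == 0 else ())
        if self.hydrocarbon not in allowed:
            raise InvalidInputError(
                f"unknown hydrocarbon {self.hydrocarbon!r}; expected one of {HYDROCARBONS}"
            )
        if self.dose_mg_per_kg < 0:
            raise InvalidInputError("dose_mg_per_kg must be >= 0")


@dataclass(frozen=True)
class PlateObservation:
    """A single dilution-plate count with its dry-matter context."""

    colonies_counted: int
    dilution_inverse: float
    dry_matter_percent: float

    def __post_init__(self) -> None:
        if self.colonies_counted < 0:
            raise InvalidInputError("colonies_counted must be >= 0")
        if not self.dilution_inverse > 0:
            raise InvalidInputError("dilution_inverse must be > 0")
        if not (0 < self.dry_matter_percent <= 100):
            raise InvalidInputError("dry_matter_percent must be in (0, 100]")


def cfu_count(obs: PlateObservation) -> float:
    """CFU per kg soil dry matter for one plate observation.

    Linear in both the colony count and the dilution inverse; zero exactly
    when no colonies were counted.
    """
    return obs.colonies_counted * obs.dilution_inverse * (100.0 / obs.dry_matter_percent) * 1e3


@dataclass(frozen=True)
class ColonyAppearanceSeries:
    """Daily counts of newly appeared colonies on one plate over ``D`` days."""

    sample_id: str
    treatment: TreatmentKey
    replicate: int
    daily_new_colonies: tuple[int, ...]

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.daily_new_colonies)
        object.__setattr__(self, "daily_new_colonies", counts)
        if self.replicate < 1:
            raise InvalidInputError("replicate must be a positive integer")
        if any(c < 0 for c in counts):
            raise InvalidInputError("daily colony counts must be >= 0")
        if len(counts) == 0:
            raise InvalidInputError("daily_new_colonies must have length >= 1")

    @property
    def days(self) -> int:
        return len(self.daily_new_colonies)

    @property
    def total(self) -> int:
        return int(sum(self.daily_new_colonies))


def daily_fractions(series: ColonyAppearanceSeries | Sequence[int]) -> np.ndarray:
    """Per-day proportions p_i = N_i / sum(N); sums to 1 for any non-empty series."""
    counts = np.asarray(
        series.daily_new_colonies if isinstance(series, ColonyAppearanceSeries) else series,
        dtype=float,
    )
    if counts.ndim != 1 or counts.size == 0:
        raise InvalidInputError("expected a one-dimensional, non-empty count vector")
    if np.any(counts < 0):
        raise InvalidInputError("daily colony counts must be >= 0")
    total = counts.sum()
    if total <= 0:
        raise EmptySeriesError("all-zero colony series: daily fractions (and CD/EP) undefined")
    return counts / total


def read_colony_series_csv(path: str | Path, days: int = DEFAULT_DAYS) -> list[ColonyAppearanceSeries]:
    """Read long-format colony series (one row per plate x day).

    Days absent from the file are treated as zero new colonies; days beyond
    the window raise a schema error.
    """
    df = pd.read_csv(path)
    require_columns(df, SERIES_COLUMNS, source=str(path))
    if len(df) and df["day"].max() > days:
        raise InvalidInputError(
            f"{path}: day {int(df['day'].max())} exceeds the {days}-day observation window"
        )
    out: list[ColonyAppearanceSeries] = []
    keys = ["sample_id", "hydrocarbon", "dose_mg_per_kg", "replicate"]
    for (sid, hc, dose, rep), grp in df.groupby(keys, sort=True):
        counts = np.zeros(days, dtype=int)
        for _, row in grp.iterrows():
            counts[int(row["day"]) - 1] += int(row["new_colonies"])
        out.append(
            ColonyAppearanceSeries(
                sample_id=str(sid),
                treatment=TreatmentKey(str(hc), int(dose)),
                replicate=int(rep),
                daily_new_colonies=tuple(counts),
            )
        )
    return out


def write_colony_series_csv(series: Iterable[ColonyAppearanceSeries], path: str | Path) -> None:
    """Write series in the same long format accepted by the reader."""
    rows = []
    for s in series:
        for day, n in enumerate(s.daily_new_colonies, start=1):
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "hydrocarbon": s.treatment.hydrocarbon,
                    "dose_mg_per_kg": s.treatment.dose_mg_per_kg,
                    "replicate": s.replicate,
                    "day": day,
                    "new_colonies": n,
                }
            )
    pd.DataFrame(rows, columns=SERIES_COLUMNS).to_csv(path, index=False)
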