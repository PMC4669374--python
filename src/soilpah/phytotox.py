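"""Phytotoxkit scoring: inhibition of seed germination (SG) and root growth (RI).

Trials expose seeds of three indicator plants (garden cress *Lepidium
sativum*, sweet sorghum *Sorghum saccharatum*, white mustard *Sinapis
alba*) to control soil and to soil contaminated with a single PAH dose
(4000 mg kg-1 DM), 10 seeds per plate and 3 plates per condition.  Both
endpoints are percent inhibition relative to the uncontaminated control:

    SG or RI = (A - B) / A * 100

with A the control metric and B the treated metric.  The germination
metric is the total number of germinated seeds over the plates; the root
metric is the mean root length of the germinated seeds.  Negative values
mean the PAH *stimulated* the endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from ._util import require_columns
from .exceptions import EmptyGroupError, IncompleteDesignError, InvalidControlError, InvalidInputError
from .plate_counts import HYDROCARBONS, TreatmentKey

SPECIES: tuple[str, ...] = ("Lepidium_sativum", "Sorghum_saccharatum", "Sinapis_alba")

TRIAL_COLUMNS = [
    "species",
    "hydrocarbon",
    "dose_mg_per_kg",
    "replicate",
    "seeds_sown",
    "seeds_germinated",
    "root_length_mm",
]

#: Phytotoxkit exposure dose, mg PAH per kg soil dry matter.
TRIAL_DOSE = 4000


@dataclass(frozen=True)
class PhytotoxTrial:
    """One plate: germination outcome and root lengths of germinated seeds."""

    species: str
    treatment: TreatmentKey
    replicate: int
    seeds_sown: int
    seeds_germinated: int
    root_lengths_mm: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise InvalidInputError(f"unknown species {self.species!r}; expected one of {SPECIES}")
        if self.seeds_sown <= 0:
            raise InvalidInputError("seeds_sown must be positive")
        if not (0 <= self.seeds_germinated <= self.seeds_sown):
            raise InvalidInputError("seeds_germinated must be in [0, seeds_sown]")
        lengths = tuple(float(x) for x in self.root_lengths_mm)
        object.__setattr__(self, "root_lengths_mm", lengths)
        if any(x < 0 for x in lengths):
            raise InvalidInputError("root lengths must be >= 0")
        if len(lengths) > self.seeds_germinated:
            raise InvalidInputError("root lengths recorded for more seeds than germinated")


def inhibition_percent(a: float, b: float) -> float:
    """Percent inhibition (A - B)/A * 100; negative values mean stimulation."""
    if not a > 0:
        raise InvalidControlError(f"control metric must be > 0, got {a!r}")
    return (a - b) / a * 100.0


def trials_to_inhibition(trials: Iterable[PhytotoxTrial]) -> pd.DataFrame:
    """SG/RI per species x hydrocarbon from control (dose 0) and treated plates.

    A and B pool the replicate plates: germination as the summed count of
    germinated seeds, root growth as the mean root length over all
    germinated seeds.
    """
    trials = list(trials)
    rows = []
    for species in sorted({t.species for t in trials}, key=SPECIES.index):
        controls = [t for t in trials if t.species == species and t.treatment.dose_mg_per_kg == 0]
        if not controls:
            raise EmptyGroupError(f"no control (dose 0) trials for {species}")
        a_germ = sum(t.seeds_germinated for t in controls)
        ctrl_lengths = [x for t in controls for x in t.root_lengths_mm]
        a_root = float(np.mean(ctrl_lengths)) if ctrl_lengths else 0.0
        treated = [t for t in trials if t.species == species and t.treatment.dose_mg_per_kg > 0]
        for hc in sorted({t.treatment.hydrocarbon for t in treated}, key=HYDROCARBONS.index):
            cell = [t for t in treated if t.treatment.hydrocarbon == hc]
            b_germ = sum(t.seeds_germinated for t in cell)
            lengths = [x for t in cell for x in t.root_lengths_mm]
            b_root = float(np.mean(lengths)) if lengths else 0.0
            rows.append(
                {
                    "species": species,
                    "hydrocarbon": hc,
                    "sg_percent": inhibition_percent(a_germ, b_germ),
                    "ri_percent": inhibition_percent(a_root, b_root),
                    "control_germinated": a_germ,
                    "treated_germinated": b_germ,
                    "control_root_mm": a_root,
                    "treated_root_mm": b_root,
                }
            )
    return pd.DataFrame(rows)


def _metric_column(metric: str) -> str:
    if metric not in ("sg", "ri"):
        raise ValueError("metric must be 'sg' or 'ri'")
    return f"{metric}_percent"


def species_mean_inhibition(results: pd.DataFrame, species: str, metric: str = "ri") -> float:
    """Mean inhibition for one species over the four hydrocarbons."""
    col = _metric_column(metric)
    sel = results[results["species"] == species]
    present = set(sel["hydrocarbon"])
    if present != set(HYDROCARBONS):
        raise IncompleteDesignError(
            f"{species}: expected all of {HYDROCARBONS}, missing {sorted(set(HYDROCARBONS) - present)}"
        )
    return float(sel[col].mean())


def hydrocarbon_mean_inhibition(results: pd.DataFrame, hydrocarbon: str, metric: str = "sg") -> float:
    """Mean inhibition for one hydrocarbon over the three plant species."""
    col = _metric_column(metric)
    sel = results[results["hydrocarbon"] == hydrocarbon]
    present = set(sel["species"])
    if present != set(SPECIES):
        raise IncompleteDesignError(
            f"{hydrocarbon}: expected all of {SPECIES}, missing {sorted(set(SPECIES) - present)}"
        )
    return float(sel[col].mean())


def read_phytotox_csv(path) -> list[PhytotoxTrial]:
    """Read trials from CSV, accepting per-seed rows or per-plate aggregates.

    Per-seed rows repeat the plate metadata and carry one root length each;
    a per-plate aggregate is a single row whose ``root_length_mm`` is the
    plate's mean root length (it is then expanded to the germinated count
    so downstream pooling weights plates by their seed numbers).
    """
    df = pd.read_csv(path)
    require_columns(df, TRIAL_COLUMNS, source=str(path))
    trials = []
    keys = ["species", "hydrocarbon", "dose_mg_per_kg", "replicate"]
    for (species, hc, dose, rep), grp in df.groupby(keys, sort=True):
        sown = int(grp["seeds_sown"].iloc[0])
        germinated = int(grp["seeds_germinated"].iloc[0])
        lengths = grp["root_length_mm"].dropna().to_list()
        if len(lengths) == 1 and germinated > 1:  # per-plate aggregate row
            lengths = lengths * germinated
        trials.append(
            PhytotoxTrial(
                species=str(species),
                treatment=TreatmentKey(str(hc), int(dose)),
                replicate=int(rep),
                seeds_sown=sown,
                seeds_germinated=germinated,
                root_lengths_mm=tuple(float(x) for x in lengths),
            )
        )
    return trials


def write_phytotox_csv(trials: Iterable[PhytotoxTrial], path) -> None:
    rows = []
    for t in trials:
        if t.root_lengths_mm:
            for x in t.root_lengths_mm:
                rows.append(_trial_row(t, x))
        else:
            rows.append(_trial_row(t, np.nan))
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False)


def _trial_row(t: PhytotoxTrial, length: float) -> dict:
    return {
        "species": t.species,
        "hydrocarbon": t.treatment.hydrocarbon,
        "dose_mg_per_kg": t.treatment.dose_mg_per_kg,
        "replicate": t.replicate,
        "seeds_sown": t.seeds_sown,
        "seeds_germinated": t.seeds_germinated,
        "root_length_mm": length,
    }
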