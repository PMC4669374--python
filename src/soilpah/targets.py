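"""Headline quantities recomputed from the packaged reference tables.

Each entry recomputes one published summary statistic from the packaged
treatment-mean tables using the package's own operations — resistance
indices from the enzyme tables, fold-changes and column averages from the
count tables, inhibition summaries from the Phytotoxkit table, and the
culture-media fold increase — rounded half-up at the precision the
corresponding table prints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from ._util import round_half_up
from . import datasets
from .dose_response import fold_change, resistance_index, treatment_mean
from .phytotox import hydrocarbon_mean_inhibition, species_mean_inhibition


@dataclass(frozen=True)
class TargetResult:
    target_id: str
    description: str
    value: float
    printed: float
    n: int
    tolerance: float

    @property
    def ok(self) -> bool:
        return abs(self.value - self.printed) <= self.tolerance


def _activity_mean(analyte: str, hydrocarbon: str, dose: int | None) -> float:
    records = datasets.load_activity_table(analyte)
    return treatment_mean(records, analyte, hydrocarbon, dose)


def _rs(analyte: str, hydrocarbon: str, dose: int) -> float:
    c0 = _activity_mean(analyte, hydrocarbon, 0)
    p = _activity_mean(analyte, hydrocarbon, dose)
    return round_half_up(resistance_index(c0, p), 3)


def _count_fold(hydrocarbon: str, dose: int | None) -> float:
    control = _activity_mean("organotrophic_count", hydrocarbon, 0)
    treated = _activity_mean("organotrophic_count", hydrocarbon, dose)
    return round_half_up(fold_change(treated, control), 1)


def _species_ri(species: str) -> float:
    table = datasets.load_phytotox_inhibition()
    return round_half_up(species_mean_inhibition(table, species, metric="ri"), 1)


def _hydrocarbon_mean(hydrocarbon: str, metric: str) -> float:
    table = datasets.load_phytotox_inhibition()
    return round_half_up(hydrocarbon_mean_inhibition(table, hydrocarbon, metric=metric), 1)


def _media_fold(microorganism: str, treatment: str) -> float:
    table = datasets.load_media_counts()
    sel = table[table["microorganism"] == microorganism].set_index("treatment")["value"]
    return round_half_up(fold_change(float(sel[treatment]), float(sel["control"])), 2)


@dataclass(frozen=True)
class _Target:
    target_id: str
    description: str
    printed: float
    n: int
    tolerance: float
    compute: Callable[[], float]


TARGETS: tuple[_Target, ...] = (
    _Target("t1", "RS, dehydrogenases, pyrene, 4000 mg/kg (from printed means)",
            0.709, 2, 0.0005, lambda: _rs("dehydrogenases", "pyrene", 4000)),
    _Target("t2", "RS, urease, pyrene, 2000 mg/kg (from printed means)",
            0.419, 2, 0.0005, lambda: _rs("urease", "pyrene", 2000)),
    _Target("t3", "RS, urease, pyrene, 4000 mg/kg (from printed means)",
            0.260, 2, 0.0005, lambda: _rs("urease", "pyrene", 4000)),
    _Target("t4", "fold increase of pyrene column-mean bacterial count vs control",
            2.2, 4, 0.05, lambda: _count_fold("pyrene", None)),
    _Target("t5", "fold increase of phenanthrene column-mean bacterial count vs control",
            1.4, 4, 0.05, lambda: _count_fold("phenanthrene", None)),
    _Target("t6", "fold increase of bacterial count at pyrene 4000 mg/kg vs control",
            2.9, 2, 0.05, lambda: _count_fold("pyrene", 4000)),
    _Target("t7", "mean root-growth inhibition of Sinapis alba over the four PAHs (%)",
            28.0, 4, 0.05, lambda: _species_ri("Sinapis_alba")),
    _Target("t8", "mean germination inhibition by pyrene over the three species (%)",
            11.1, 3, 0.05, lambda: _hydrocarbon_mean("pyrene", "sg")),
    _Target("t9", "mean root-growth inhibition by phenanthrene over the three species (%)",
            20.6, 3, 0.05, lambda: _hydrocarbon_mean("phenanthrene", "ri")),
    _Target("t10", "column average of naphthalene bacterial counts (1e9 cfu/kg DM)",
            30.02, 4, 0.005, lambda: _activity_mean("organotrophic_count", "naphthalene", None)),
    _Target("t11", "column average of anthracene urease activity (mmol N-NH4/kg DM/h)",
            1.86, 4, 0.005, lambda: _activity_mean("urease", "anthracene", None)),
    _Target("t12", "fold increase of total bacteria under anthracene vs control (media counts)",
            1.34, 2, 0.005, lambda: _media_fold("bacteria", "anthracene")),
)


def compute_targets() -> list[TargetResult]:
    """Recompute every headline quantity from the packaged tables."""
    out = []
    for t in TARGETS:
        value = float(t.compute())
        if t.target_id in ("t10", "t11"):
            value = round_half_up(value, 2)
        out.append(
            TargetResult(
                target_id=t.target_id,
                description=t.description,
                value=value,
                printed=t.printed,
                n=t.n,
                tolerance=t.tolerance,
            )
        )
    return out
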