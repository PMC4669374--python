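"""Synthetic replicate-level datasets with the study's statistical structure.

The generator emulates the laboratory design — 4 PAHs x 4 doses
(0/1000/2000/4000 mg kg-1 DM) x 3 replicates — well enough that every
pipeline stage can be verified by parameter recovery:

* colony-appearance series are mixtures of a fast (r-strategist) class
  concentrated on days 1-3 and a slow (K-strategist) class spread over
  days 4-10, with per-plate totals Poisson around an expected count that
  grows with dose (bacterial counts increase under PAH contamination);
* enzyme activities decline linearly with dose (floored at zero) with
  multiplicative replicate noise of a fixed coefficient of variation;
* Phytotoxkit trials draw per-seed germination Bernoulli outcomes and
  zero-truncated normal root lengths.

All randomness flows from one integer seed through spawned
``numpy.random.SeedSequence`` substreams (one per plate/cell), so partial
re-runs and re-orderings are stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
import pandas as pd

from .exceptions import InvalidParamsError
from .plate_counts import (
    DEFAULT_DAYS,
    DOSES,
    HYDROCARBONS,
    ColonyAppearanceSeries,
    TreatmentKey,
)
from .phytotox import SPECIES, TRIAL_DOSE, PhytotoxTrial


def _default_fast() -> tuple[float, ...]:
    # r-strategists: everything within the first three days
    return (0.5, 0.3, 0.2) + (0.0,) * (DEFAULT_DAYS - 3)


def _default_slow() -> tuple[float, ...]:
    # K-strategists: uniform emergence over days 4-10
    return (0.0, 0.0, 0.0) + (1.0 / 7.0,) * (DEFAULT_DAYS - 3)


def _default_multipliers() -> dict[int, float]:
    # pooled dose means of the observed count tables relative to control
    return {0: 1.0, 1000: 1.56, 2000: 2.08, 4000: 2.63}


@dataclass(frozen=True)
class CommunitySimParams:
    """Mixture model for colony-appearance timing and abundance."""

    days: int = DEFAULT_DAYS
    fast_appearance: tuple[float, ...] = field(default_factory=_default_fast)
    slow_appearance: tuple[float, ...] = field(default_factory=_default_slow)
    fast_fraction: float = 0.2
    expected_total_colonies: float = 120.0
    dose_abundance_multiplier: dict[int, float] = field(default_factory=_default_multipliers)
    hydrocarbons: tuple[str, ...] = HYDROCARBONS
    doses: tuple[int, ...] = DOSES
    replicates: int = 3

    def __post_init__(self) -> None:
        for name, dist in (("fast_appearance", self.fast_appearance),
                           ("slow_appearance", self.slow_appearance)):
            arr = np.asarray(dist, dtype=float)
            if arr.size != self.days or np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-9:
                raise InvalidParamsError(
                    f"{name} must be a length-{self.days} distribution summing to 1"
                )
        if not 0.0 <= self.fast_fraction <= 1.0:
            raise InvalidParamsError("fast_fraction must be in [0, 1]")
        if not self.expected_total_colonies > 0:
            raise InvalidParamsError("expected_total_colonies must be > 0")
        if any(m <= 0 for m in self.dose_abundance_multiplier.values()):
            raise InvalidParamsError("dose multipliers must be > 0")
        if self.replicates < 1:
            raise InvalidParamsError("replicates must be >= 1")

    @property
    def mixture(self) -> np.ndarray:
        fast = np.asarray(self.fast_appearance, dtype=float)
        slow = np.asarray(self.slow_appearance, dtype=float)
        return self.fast_fraction * fast + (1.0 - self.fast_fraction) * slow


def simulate_colony_series(params: CommunitySimParams, seed: int) -> list[ColonyAppearanceSeries]:
    """One appearance series per hydrocarbon x dose x replicate plate.

    Totals are Poisson around ``expected * multiplier[dose]`` (floored at 1
    colony so the indices stay defined) and allocated across days
    multinomially from the strategist mixture.
    """
    root = np.random.SeedSequence(seed)
    plates = [
        (hc, dose, rep)
        for hc in params.hydrocarbons
        for dose in params.doses
        for rep in range(1, params.replicates + 1)
    ]
    children = root.spawn(len(plates))
    out = []
    for (hc, dose, rep), child in zip(plates, children):
        rng = np.random.default_rng(child)
        mult = params.dose_abundance_multiplier.get(dose, 1.0)
        total = max(1, int(rng.poisson(params.expected_total_colonies * mult)))
        counts = rng.multinomial(total, params.mixture)
        out.append(
            ColonyAppearanceSeries(
                sample_id=f"{hc}_{dose}_r{rep}",
                treatment=TreatmentKey(hc, dose),
                replicate=rep,
                daily_new_colonies=tuple(int(c) for c in counts),
            )
        )
    return out


def _default_controls() -> dict[str, float]:
    return {"organotrophic_count": 18.25, "dehydrogenases": 8.63, "urease": 2.76}


def _default_slopes() -> dict[str, dict[str, float]]:
    # per-dose-unit change; derived from the 0 -> 4000 mg/kg endpoints of the
    # observed tables (negative slope = increase with dose, used for counts)
    return {
        "organotrophic_count": {
            "naphthalene": -6.5275e-3,
            "phenanthrene": -3.2175e-3,
            "anthracene": -1.13625e-2,
            "pyrene": -8.635e-3,
        },
        "dehydrogenases": {
            "naphthalene": 6.025e-4,
            "phenanthrene": 8.675e-4,
            "anthracene": 1.9e-4,
            "pyrene": 3.675e-4,
        },
        "urease": {
            "naphthalene": 4.125e-4,
            "phenanthrene": 4.25e-4,
            "anthracene": 3.95e-4,
            "pyrene": 4.05e-4,
        },
    }


@dataclass(frozen=True)
class EnzymeSimParams:
    """Linear dose-decline model for activities / counts with CV noise."""

    control_means: dict[str, float] = field(default_factory=_default_controls)
    slopes: dict[str, dict[str, float]] = field(default_factory=_default_slopes)
    cv: float = 0.05
    doses: tuple[int, ...] = DOSES
    replicates: int = 3

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.control_means.values()):
            raise InvalidParamsError("control means must be > 0")
        if self.cv < 0:
            raise InvalidParamsError("cv must be >= 0")
        if self.replicates < 1:
            raise InvalidParamsError("replicates must be >= 1")
        for analyte in self.control_means:
            if analyte not in self.slopes:
                raise InvalidParamsError(f"no slopes configured for analyte {analyte!r}")


def simulate_enzyme(params: EnzymeSimParams, seed: int) -> pd.DataFrame:
    """Tidy activity records: value = max(control - slope*dose, 0) * noise.

    Noise is multiplicative normal with the configured CV, clipped at zero
    (activities cannot be negative).  CV = 0 puts values exactly on the
    dose line.
    """
    root = np.random.SeedSequence(seed)
    cells = [
        (analyte, hc)
        for analyte in params.control_means
        for hc in params.slopes[analyte]
    ]
    children = root.spawn(len(cells))
    rows = []
    for (analyte, hc), child in zip(cells, children):
        rng = np.random.default_rng(child)
        slope = params.slopes[analyte][hc]
        c0 = params.control_means[analyte]
        for dose in params.doses:
            expected = max(c0 - slope * dose, 0.0)
            for rep in range(1, params.replicates + 1):
                noise = rng.normal(1.0, params.cv) if params.cv > 0 else 1.0
                rows.append(
                    {
                        "analyte": analyte,
                        "hydrocarbon": hc,
                        "dose_mg_per_kg": dose,
                        "replicate": rep,
                        "value": max(expected * noise, 0.0),
                    }
                )
    return pd.DataFrame(rows)


def _default_germination() -> dict[str, dict[str, float]]:
    # back-derived from the observed germination-inhibition percentages
    return {
        "Lepidium_sativum": {"control": 1.0, "naphthalene": 0.80, "phenanthrene": 0.90,
                             "anthracene": 1.0, "pyrene": 0.834},
        "Sorghum_saccharatum": {"control": 1.0, "naphthalene": 1.0, "phenanthrene": 1.0,
                                "anthracene": 0.934, "pyrene": 1.0},
        "Sinapis_alba": {"control": 1.0, "naphthalene": 0.934, "phenanthrene": 1.0,
                         "anthracene": 0.967, "pyrene": 0.834},
    }


def _default_root_mean() -> dict[str, dict[str, float]]:
    # control root lengths typical of 3-day Phytotoxkit assays; treated
    # means scaled by (1 - RI/100) from the observed inhibition table
    ctrl = {"Lepidium_sativum": 50.0, "Sorghum_saccharatum": 40.0, "Sinapis_alba": 45.0}
    ri = {
        "Lepidium_sativum": {"naphthalene": 16.2, "phenanthrene": 22.5,
                             "anthracene": 16.4, "pyrene": 15.9},
        "Sorghum_saccharatum": {"naphthalene": 9.3, "phenanthrene": -1.25,
                                "anthracene": -22.7, "pyrene": -23.2},
        "Sinapis_alba": {"naphthalene": 21.8, "phenanthrene": 40.4,
                         "anthracene": 37.9, "pyrene": 11.9},
    }
    out: dict[str, dict[str, float]] = {}
    for sp in SPECIES:
        out[sp] = {"control": ctrl[sp]}
        for hc, r in ri[sp].items():
            out[sp][hc] = ctrl[sp] * (1.0 - r / 100.0)
    return out


def _default_root_sd() -> dict[str, float]:
    return {sp: 5.0 for sp in SPECIES}


@dataclass(frozen=True)
class PhytotoxSimParams:
    """Per-seed germination and root-growth model at the single assay dose."""

    germination_prob: dict[str, dict[str, float]] = field(default_factory=_default_germination)
    root_mean_mm: dict[str, dict[str, float]] = field(default_factory=_default_root_mean)
    root_sd_mm: dict[str, float] = field(default_factory=_default_root_sd)
    seeds_per_plate: int = 10
    plates: int = 3
    dose_mg_per_kg: int = TRIAL_DOSE

    def __post_init__(self) -> None:
        for sp, probs in self.germination_prob.items():
            if any(not 0.0 <= p <= 1.0 for p in probs.values()):
                raise InvalidParamsError(f"{sp}: germination probabilities must be in [0, 1]")
        if any(sd < 0 for sd in self.root_sd_mm.values()):
            raise InvalidParamsError("root-length sd must be >= 0")
        if self.seeds_per_plate < 1 or self.plates < 1:
            raise InvalidParamsError("need >= 1 seed per plate and >= 1 plate")


def simulate_phytotox(params: PhytotoxSimParams, seed: int) -> list[PhytotoxTrial]:
    """Control and treated plates per species x hydrocarbon.

    Germination is an independent Bernoulli draw per seed; root lengths of
    germinated seeds are normal, truncated at zero.
    """
    root = np.random.SeedSequence(seed)
    cells = [
        (sp, cond)
        for sp in params.germination_prob
        for cond in params.germination_prob[sp]
    ]
    children = root.spawn(len(cells))
    trials = []
    for (sp, cond), child in zip(cells, children):
        rng = np.random.default_rng(child)
        p = params.germination_prob[sp][cond]
        mu = params.root_mean_mm[sp][cond]
        sd = params.root_sd_mm[sp]
        dose = 0 if cond == "control" else params.dose_mg_per_kg
        for plate in range(1, params.plates + 1):
            germinated = int(rng.binomial(params.seeds_per_plate, p))
            lengths = np.maximum(rng.normal(mu, sd, germinated), 0.0) if germinated else []
            trials.append(
                PhytotoxTrial(
                    species=sp,
                    treatment=TreatmentKey(cond, dose),
                    replicate=plate,
                    seeds_sown=params.seeds_per_plate,
                    seeds_germinated=germinated,
                    root_lengths_mm=tuple(float(x) for x in lengths),
                )
            )
    return trials


def write_manifest(path: str | Path, seed: int, **params_objects) -> None:
    """Record the seed and every parameter object of a simulation run."""
    payload = {"seed": int(seed)}
    for name, obj in params_objects.items():
        payload[name] = asdict(obj)
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
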