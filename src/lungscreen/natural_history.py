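"""Person-level lung-cancer natural history.

A tumor is assigned one of three histological pathways (squamous,
adeno/large cell, small cell).  Disease onset — the appearance of a
preclinical, eventually screen-detectable lesion — occurs with a
per-pathway lifetime probability, at an age drawn from a Weibull
distribution.  The lesion then progresses through discrete stages:

    PRE_I   undetectable preclinical stage I
    PRE_II  screen-detectable preclinical stage II (the "II-" group)
    CLIN_III, CLIN_IV  invasive stages (the "III+" group), detectable
            by screening until the tumor surfaces clinically

Each stage has an exponentially distributed dwell time.  A tumor
entering CLIN_III either surfaces clinically at the end of its stage-III
dwell, or progresses to CLIN_IV and surfaces at the end of its stage-IV
dwell.  Clinical surfacing is only possible in CLIN_III/CLIN_IV;
preclinical disease can only be found by screening.

An *indolent* tumor never leaves PRE_II: it remains screen-detectable
for the rest of the person's life but never causes symptoms.  This is
the over-diagnosis mechanism — such a lesion can only ever be found by
a screen, and only matters because other-cause death may precede it.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd


class CellType(str, enum.Enum):
    """Histological pathway of a tumor."""

    SQUAMOUS = "squamous"
    ADENO_LARGE = "adeno_large"
    SMALL = "small"


CELL_TYPES = tuple(CellType)


class Stage(enum.IntEnum):
    """Ordered disease stages.

    ``PRE_I`` is never screen-detectable.  ``PRE_II`` is detectable only
    by screening.  ``CLIN_III``/``CLIN_IV`` are screen-detectable until
    clinical surfacing, after which the diagnosis is clinical.
    """

    PRE_I = 1
    PRE_II = 2
    CLIN_III = 3
    CLIN_IV = 4

    @property
    def screen_detectable(self) -> bool:
        return self is not Stage.PRE_I


def _validate_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class OnsetParams:
    """Weibull onset model, one parameter triple per cell type.

    ``weibull_mean`` is the mean of the onset-age distribution in years;
    the scale is recovered as mean / Gamma(1 + 1/shape).
    ``lifetime_onset_prob`` is the probability that a lesion of this
    type ever arises in a person's lifetime (before any competing
    mortality is applied).
    """

    weibull_shape: Mapping[CellType, float]
    weibull_mean: Mapping[CellType, float]
    lifetime_onset_prob: Mapping[CellType, float]

    def __post_init__(self) -> None:
        for ct in CELL_TYPES:
            if self.weibull_shape[ct] <= 0 or self.weibull_mean[ct] <= 0:
                raise ValueError(f"Weibull shape/mean must be > 0 for {ct.value}")
            _validate_prob(f"lifetime_onset_prob[{ct.value}]", self.lifetime_onset_prob[ct])

    def weibull_scale(self, cell_type: CellType) -> float:
        shape = self.weibull_shape[cell_type]
        return self.weibull_mean[cell_type] / math.gamma(1.0 + 1.0 / shape)


@dataclass(frozen=True)
class ProgressionParams:
    """Stage-progression model.

    ``mean_dwell[cell][stage]`` is the exponential mean dwell time
    (years) in each of the four stages.  ``p_clinical_dx_at_III`` is the
    probability that a tumor entering CLIN_III surfaces clinically in
    stage III rather than progressing to CLIN_IV.  ``indolent_fraction``
    is the probability that a tumor, on entering PRE_II, never
    progresses further (the over-diagnosis parameter); it is shared
    across cell types because it is calibrated as a single quantity.
    """

    mean_dwell: Mapping[CellType, Mapping[Stage, float]]
    p_clinical_dx_at_III: Mapping[CellType, float]
    indolent_fraction: float = 0.0

    def __post_init__(self) -> None:
        for ct in CELL_TYPES:
            for st in Stage:
                if self.mean_dwell[ct][st] <= 0:
                    raise ValueError(f"mean_dwell[{ct.value}][{st.name}] must be > 0")
            _validate_prob(f"p_clinical_dx_at_III[{ct.value}]", self.p_clinical_dx_at_III[ct])
        _validate_prob("indolent_fraction", self.indolent_fraction)

    def with_indolent_fraction(self, f: float) -> "ProgressionParams":
        return replace(self, indolent_fraction=f)


@dataclass(frozen=True)
class NaturalHistoryParams:
    """Complete natural-history parameter bundle for one population."""

    onset: OnsetParams
    progression: ProgressionParams
    cell_type_probs: Mapping[CellType, float]

    def __post_init__(self) -> None:
        total = sum(self.cell_type_probs[ct] for ct in CELL_TYPES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cell_type_probs must sum to 1, got {total}")


@dataclass
class DiseasePath:
    """One simulated tumor's trajectory in continuous age (years)."""

    cell_type: CellType
    onset_age: float
    stage_entry_ages: dict[Stage, float]
    clinical_dx_age: Optional[float]
    clinical_dx_stage: Optional[Stage]
    indolent: bool

    def __post_init__(self) -> None:
        ages = [self.stage_entry_ages[s] for s in sorted(self.stage_entry_ages)]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("stage entry ages must be strictly increasing")
        if self.indolent:
            if self.clinical_dx_age is not None or Stage.CLIN_III in self.stage_entry_ages:
                raise ValueError("indolent path cannot surface or enter CLIN_III")
        if self.clinical_dx_stage is not None and self.clinical_dx_stage not in (
            Stage.CLIN_III,
            Stage.CLIN_IV,
        ):
            raise ValueError("clinical surfacing only occurs in CLIN_III/CLIN_IV")

    def stage_at(self, age: float) -> Optional[Stage]:
        """Stage occupied at ``age``, or None before onset / after surfacing."""
        if age < self.onset_age:
            return None
        if self.clinical_dx_age is not None and age >= self.clinical_dx_age:
            return None
        current = None
        for stage in Stage:
            entry = self.stage_entry_ages.get(stage)
            if entry is not None and age >= entry:
                current = stage
        return current

    def screen_detectable_at(self, age: float) -> bool:
        stage = self.stage_at(age)
        return stage is not None and stage.screen_detectable


@dataclass(frozen=True)
class LifeTable:
    """Annual other-cause death probabilities on an integer age grid.

    Survivors past the last tabulated age die deterministically at
    ``cap_age`` (the end of the last covered year), which acts as an
    administrative censoring age.
    """

    ages: np.ndarray
    annual_death_prob: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        probs = np.asarray(self.annual_death_prob, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "annual_death_prob", probs)
        if ages.ndim != 1 or ages.size == 0 or ages.size != probs.size:
            raise ValueError("ages and annual_death_prob must be equal-length 1-D arrays")
        if np.any(np.diff(ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        if np.any((probs < 0) | (probs > 1)):
            raise ValueError("annual death probabilities must be in [0, 1]")

    @property
    def cap_age(self) -> float:
        return float(self.ages[-1]) + 1.0

    def prob_at(self, age: float) -> float:
        if age < self.ages[0] or age >= self.cap_age:
            raise ValueError(f"age {age} outside life-table range "
                             f"[{self.ages[0]}, {self.cap_age})")
        idx = int(np.searchsorted(self.ages, age, side="right")) - 1
        return float(self.annual_death_prob[idx])

    @classmethod
    def read_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        return cls(ages=df["age"].to_numpy(), annual_death_prob=df["annual_death_prob"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.ages, "annual_death_prob": self.annual_death_prob}).to_csv(
            path, index=False
        )


def sample_onset(
    params: OnsetParams,
    cell_type: CellType,
    risk_factor: float,
    rng: np.random.Generator,
) -> Optional[float]:
    """Draw an onset age, or None if no lesion ever arises.

    ``risk_factor`` multiplies the lifetime onset probability; it is the
    between-arm heterogeneity parameter (1 = equal risk in both arms).
    """
    if risk_factor <= 0:
        raise ValueError("risk_factor must be > 0")
    p = risk_factor * params.lifetime_onset_prob[cell_type]
    if p > 1.0:
        raise ValueError(
            f"risk_factor x lifetime_onset_prob = {p} exceeds 1 for {cell_type.value}"
        )
    if rng.random() >= p:
        return None
    shape = params.weibull_shape[cell_type]
    return float(params.weibull_scale(cell_type) * rng.weibull(shape))


def sample_disease_path(
    onset_age: float,
    cell_type: CellType,
    params: ProgressionParams,
    rng: np.random.Generator,
) -> DiseasePath:
    """Simulate stage progression from a given onset age.

    Dwell times are exponential and drawn at stage entry.  Indolence is
    decided on entry to PRE_II; an indolent tumor stays there forever.
    """
    if onset_age < 0:
        raise ValueError("onset_age must be >= 0")
    dwell = params.mean_dwell[cell_type]
    entries: dict[Stage, float] = {Stage.PRE_I: onset_age}
    t = onset_age + rng.exponential(dwell[Stage.PRE_I])
    entries[Stage.PRE_II] = t

    if rng.random() < params.indolent_fraction:
        return DiseasePath(
            cell_type=cell_type,
            onset_age=onset_age,
            stage_entry_ages=entries,
            clinical_dx_age=None,
            clinical_dx_stage=None,
            indolent=True,
        )

    t += rng.exponential(dwell[Stage.PRE_II])
    entries[Stage.CLIN_III] = t
    t += rng.exponential(dwell[Stage.CLIN_III])
    if rng.random() < params.p_clinical_dx_at_III[cell_type]:
        dx_age, dx_stage = t, Stage.CLIN_III
    else:
        entries[Stage.CLIN_IV] = t
        t += rng.exponential(dwell[Stage.CLIN_IV])
        dx_age, dx_stage = t, Stage.CLIN_IV
    return DiseasePath(
        cell_type=cell_type,
        onset_age=onset_age,
        stage_entry_ages=entries,
        clinical_dx_age=dx_age,
        clinical_dx_stage=dx_stage,
        indolent=False,
    )


def sample_other_cause_death(
    life_table: LifeTable,
    current_age: float,
    rng: np.random.Generator,
) -> float:
    """Draw an other-cause death age by sequential annual Bernoulli trials.

    Each trial covers one year starting at ``current_age``; the annual
    probability is looked up at the year's starting age.  Death within a
    year is placed uniformly inside it.  A person surviving every
    tabulated year dies at the table's cap age.
    """
    if current_age < life_table.ages[0] or current_age >= life_table.cap_age:
        raise ValueError(f"current_age {current_age} outside life-table range")
    age = current_age
    while age < life_table.cap_age:
        if rng.random() < life_table.prob_at(age):
            return min(age + rng.random(), life_table.cap_age)
        age += 1.0
    return life_table.cap_age
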