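"""Screening protocol applied to a disease path.

The intervention arm of the emulated trial is screened every four
months for six years (19 exams counting the prevalence screen at entry).
At an attended exam the tumor is detectable if it currently occupies
PRE_II (stage group II-) or CLIN_III/CLIN_IV before clinical surfacing
(stage group III+).  Each group has its own test sensitivity.

A *systematic negative error* models within-tumor correlation of
false negatives: once a tumor has been missed at a screen, the miss
probability at every later screen in the same stage group is raised by
a fixed increment, ``miss' = min(1, (1 - sens) + syserr)``.  The
increment is persistent and, by default, does not compound with
successive misses (``compound_syserr`` enables per-miss compounding).

By default an attended exam taken while the lesion already exists but
is still below the detectable threshold (stage PRE_I) also counts as a
prior false negative for the tumor: the screen failed to find a cancer
that was present.  This keeps the systematic-error mechanism active
even at perfect sensitivity — the configuration in which it is
calibrated — because a tumor first screened too early carries its
elevated miss risk into the detectable window.  Set
``pre_detectable_misses=False`` to count only misses at detectable
exams.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .natural_history import DiseasePath, Stage


class DetectionMode(str, enum.Enum):
    SCREEN_DETECTED = "screen_detected"
    CLINICALLY_DIAGNOSED = "clinically_diagnosed"
    NEVER_DIAGNOSED = "never_diagnosed"


class StageGroup(str, enum.Enum):
    II_MINUS = "II_minus"
    III_PLUS = "III_plus"


@dataclass(frozen=True)
class ScreeningPolicy:
    """Exam schedule in trial time (years since entry).

    Defaults follow a 4-monthly, 6-year protocol with the prevalence
    exam at time 0 included, i.e. floor(duration/interval) + 1 exams.
    """

    interval: float = 1.0 / 3.0
    duration: float = 6.0
    attendance_prob: float = 1.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError("interval must be > 0")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if not 0.0 <= self.attendance_prob <= 1.0:
            raise ValueError("attendance_prob must be in [0, 1]")


@dataclass(frozen=True)
class TestCharacteristics:
    """Stage-group sensitivities and systematic-error increments."""

    __test__ = False  # domain class, not a pytest collectible

    sens_II: float = 1.0
    sens_III: float = 1.0
    syserr_II: float = 0.0
    syserr_III: float = 0.0
    compound_syserr: bool = False
    pre_detectable_misses: bool = True

    def __post_init__(self) -> None:
        for name in ("sens_II", "sens_III", "syserr_II", "syserr_III"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def miss_prob(self, group: StageGroup, prior_misses: int) -> float:
        """Per-exam miss probability given the tumor's miss history in ``group``."""
        if group is StageGroup.II_MINUS:
            sens, err = self.sens_II, self.syserr_II
        else:
            sens, err = self.sens_III, self.syserr_III
        if prior_misses == 0:
            return 1.0 - sens
        bump = err * prior_misses if self.compound_syserr else err
        return min(1.0, (1.0 - sens) + bump)


@dataclass(frozen=True)
class DetectionOutcome:
    mode: DetectionMode
    dx_time: Optional[float]  # trial time (years since entry), None if never
    dx_stage_group: Optional[StageGroup]

    def __post_init__(self) -> None:
        if self.mode is DetectionMode.NEVER_DIAGNOSED:
            if self.dx_time is not None or self.dx_stage_group is not None:
                raise ValueError("never_diagnosed outcome carries no dx fields")
        elif self.dx_time is None:
            raise ValueError("diagnosed outcome requires dx_time")
        if (
            self.mode is DetectionMode.CLINICALLY_DIAGNOSED
            and self.dx_stage_group is not StageGroup.III_PLUS
        ):
            raise ValueError("clinical diagnosis only occurs in stage group III+")


def build_schedule(policy: ScreeningPolicy) -> np.ndarray:
    """Exam times {0, interval, 2*interval, ...} up to and including duration."""
    n_exams = math.floor(policy.duration / policy.interval + 1e-9) + 1
    return policy.start_time + policy.interval * np.arange(n_exams)


def stage_group_at(path: DiseasePath, age: float) -> Optional[StageGroup]:
    """Screen-detectable stage group at ``age``, or None."""
    stage = path.stage_at(age)
    if stage is None or stage is Stage.PRE_I:
        return None
    if stage is Stage.PRE_II:
        return StageGroup.II_MINUS
    return StageGroup.III_PLUS


def apply_screening(
    path: DiseasePath,
    death_age: float,
    trial_entry_age: float,
    schedule: Sequence[float],
    test: TestCharacteristics,
    attendance_prob: float,
    rng: np.random.Generator,
) -> DetectionOutcome:
    """Walk the exam schedule and decide how (if at all) the tumor is found.

    Exams are evaluated in time order.  The first positive exam that
    precedes both clinical surfacing and death yields a screen
    detection; otherwise the tumor surfaces clinically (if surfacing
    precedes death) or is never diagnosed.  The caller is responsible
    for follow-up censoring.
    """
    if not 0.0 <= attendance_prob <= 1.0:
        raise ValueError("attendance_prob must be in [0, 1]")
    misses = {StageGroup.II_MINUS: 0, StageGroup.III_PLUS: 0}
    pre_misses = 0  # attended exams while the lesion existed but was undetectable
    for t in schedule:
        age = trial_entry_age + t
        if age >= death_age:
            break
        if path.clinical_dx_age is not None and age >= path.clinical_dx_age:
            break
        if attendance_prob < 1.0 and rng.random() >= attendance_prob:
            continue
        group = stage_group_at(path, age)
        if group is None:
            if test.pre_detectable_misses and path.stage_at(age) is Stage.PRE_I:
                pre_misses += 1
            continue
        if rng.random() >= test.miss_prob(group, misses[group] + pre_misses):
            return DetectionOutcome(
                mode=DetectionMode.SCREEN_DETECTED, dx_time=float(t), dx_stage_group=group
            )
        misses[group] += 1
    if path.clinical_dx_age is not None and path.clinical_dx_age < death_age:
        return DetectionOutcome(
            mode=DetectionMode.CLINICALLY_DIAGNOSED,
            dx_time=path.clinical_dx_age - trial_entry_age,
            dx_stage_group=StageGroup.III_PLUS,
        )
    return DetectionOutcome(mode=DetectionMode.NEVER_DIAGNOSED, dx_time=None, dx_stage_group=None)
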