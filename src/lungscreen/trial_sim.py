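"""Two-arm trial assembly: person-level simulation and count aggregation.

The emulated design follows the classic chest x-ray trial: ~9200 male
smokers aged 45+ randomized to an intervention arm screened every four
months for six years, or to a usual-care control arm (no effective
screening by default).  The product of a run is a :class:`CountTable`
of diagnoses by arm x detection mode x stage group — the quantity the
calibration machinery scores against observed data.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from ._engine import (
    ArmDraws,
    HypothesisParams,
    _OutcomeCache,
    _counts_from_outcome,
    arm_outcome,
    generate_arm_draws,
)
from .counts import ARMS, CountTable
from .natural_history import (
    CellType,
    LifeTable,
    NaturalHistoryParams,
    sample_disease_path,
    sample_onset,
    sample_other_cause_death,
)
from .screening import (
    DetectionMode,
    DetectionOutcome,
    ScreeningPolicy,
    TestCharacteristics,
    apply_screening,
    build_schedule,
)


@dataclass(frozen=True)
class TrialConfig:
    """Design of one two-arm screening trial."""

    n_intervention: int = 4618
    n_control: int = 4593
    entry_age_low: float = 45.0
    entry_age_high: float = 65.0
    followup_years: float = 12.0
    risk_factor_intervention: float = 1.0
    policy_intervention: ScreeningPolicy = ScreeningPolicy(attendance_prob=0.75)
    policy_control: ScreeningPolicy = ScreeningPolicy(
        interval=1.0, duration=6.0, attendance_prob=0.0
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_intervention <= 0 or self.n_control <= 0:
            raise ValueError("arm sizes must be > 0")
        if self.followup_years < 0:
            raise ValueError("followup_years must be >= 0")
        if self.risk_factor_intervention <= 0:
            raise ValueError("risk_factor_intervention must be > 0")
        for pol in (self.policy_intervention, self.policy_control):
            if pol.attendance_prob > 0 and pol.duration > self.followup_years:
                raise ValueError("screening duration cannot exceed follow-up")

    def policy(self, arm: str) -> ScreeningPolicy:
        return self.policy_intervention if arm == "intervention" else self.policy_control

    def arm_size(self, arm: str) -> int:
        return self.n_intervention if arm == "intervention" else self.n_control


@dataclass
class PersonRecord:
    """One simulated person: final outcome plus path metadata."""

    outcome: DetectionOutcome
    cell_type: Optional[CellType]
    entry_age: float
    death_age: float
    path: object = None


def person_rng(seed: int, arm: str, person_idx: int) -> np.random.Generator:
    """A named, reproducible stream for one person (common random numbers)."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, ARMS.index(arm), person_idx])
    )


def simulate_person(
    config: TrialConfig,
    arm: str,
    nh: NaturalHistoryParams,
    test: TestCharacteristics,
    life_table: LifeTable,
    rng: np.random.Generator,
) -> PersonRecord:
    """Compose onset -> progression -> other-cause death -> screening.

    Diagnoses after death or beyond the follow-up horizon are censored
    to never-diagnosed, as are tumors that had already surfaced
    clinically before trial entry (such a person would not have been
    enrolled).
    """
    cells = list(CellType)
    probs = [nh.cell_type_probs[ct] for ct in cells]
    cell_type = cells[rng.choice(len(cells), p=probs)]
    entry_age = rng.uniform(config.entry_age_low, config.entry_age_high)
    risk = config.risk_factor_intervention if arm == "intervention" else 1.0

    onset_age = sample_onset(nh.onset, cell_type, risk, rng)
    path = None
    if onset_age is not None:
        path = sample_disease_path(onset_age, cell_type, nh.progression, rng)
    death_age = sample_other_cause_death(life_table, entry_age, rng)

    never = DetectionOutcome(DetectionMode.NEVER_DIAGNOSED, None, None)
    if path is None:
        return PersonRecord(never, cell_type, entry_age, death_age)
    if not path.indolent and path.clinical_dx_age is not None and path.clinical_dx_age <= entry_age:
        return PersonRecord(never, cell_type, entry_age, death_age, path)

    policy = config.policy(arm)
    schedule = build_schedule(policy) if policy.attendance_prob > 0 else []
    outcome = apply_screening(
        path, death_age, entry_age, schedule, test, policy.attendance_prob, rng
    )
    if outcome.dx_time is not None and (
        config.followup_years <= 0 or outcome.dx_time > config.followup_years
    ):
        outcome = never
    return PersonRecord(outcome, cell_type, entry_age, death_age, path)


def records_to_dataframe(records, arm: str) -> pd.DataFrame:
    """Person-level outcome rows (`person_id, arm, mode, dx_time,
    dx_stage_group, cell_type`), ready for CSV export."""
    rows = []
    for i, rec in enumerate(records):
        rows.append(
            {
                "person_id": i,
                "arm": arm,
                "mode": rec.outcome.mode.value,
                "dx_time": rec.outcome.dx_time,
                "dx_stage_group": (
                    rec.outcome.dx_stage_group.value
                    if rec.outcome.dx_stage_group is not None
                    else None
                ),
                "cell_type": rec.cell_type.value if rec.cell_type else None,
            }
        )
    return pd.DataFrame(rows)


class TrialSimulator:
    """Expected count tables over a frozen common-random-number draw set.

    Draws for both arms are generated once at construction (``oversample``
    times the nominal arm sizes); :meth:`expected` then maps any
    hypothesis-parameter vector to an expected count table rescaled to
    the nominal arm sizes.  Repeated calls with the same parameters are
    bit-identical, and calls with different parameters share every
    random number — the common-random-number contract the calibration
    relies on.
    """

    def __init__(
        self,
        config: TrialConfig,
        nh: NaturalHistoryParams,
        test: TestCharacteristics,
        life_table: LifeTable,
        oversample: float = 20.0,
        by_cell_type: bool = False,
        seed: Optional[int] = None,
    ):
        if oversample <= 0:
            raise ValueError("oversample must be > 0")
        self.config = config
        self.nh = nh
        self.test = test
        self.life_table = life_table
        self.by_cell_type = by_cell_type
        self.seed = config.seed if seed is None else seed
        self.draws: dict[str, ArmDraws] = {}
        self._cache: dict[str, _OutcomeCache] = {}
        for k, arm in enumerate(ARMS):
            n_sim = max(1, int(round(config.arm_size(arm) * oversample)))
            self.draws[arm] = generate_arm_draws(
                n_sim,
                nh,
                life_table,
                config.policy(arm),
                config.entry_age_low,
                config.entry_age_high,
                np.random.SeedSequence([self.seed, k]),
            )
            self.draws[arm].compound_syserr = test.compound_syserr
            self.draws[arm].pre_detectable_misses = test.pre_detectable_misses

    def default_hypothesis(self) -> HypothesisParams:
        return HypothesisParams(
            sens_II=self.test.sens_II,
            sens_III=self.test.sens_III,
            syserr_II=self.test.syserr_II,
            syserr_III=self.test.syserr_III,
            indolent_fraction=self.nh.progression.indolent_fraction,
            risk_factor=self.config.risk_factor_intervention,
        )

    def expected(
        self, hyp: Optional[HypothesisParams] = None, use_cache: bool = False
    ) -> CountTable:
        """Expected diagnosis counts, rescaled to nominal arm sizes.

        ``use_cache`` enables the fast path for parameter sweeps that
        hold the four test parameters fixed (risk factor and indolent
        fraction only); the screening pass is then resolved once.
        """
        hyp = self.default_hypothesis() if hyp is None else hyp
        cells: dict[tuple, float] = {}
        for arm in ARMS:
            d = self.draws[arm]
            risk = hyp.risk_factor if arm == "intervention" else 1.0
            cache = None
            if use_cache:
                key = (hyp.sens_II, hyp.sens_III, hyp.syserr_II, hyp.syserr_III)
                cache = self._cache.get(arm)
                if cache is None or cache.key != key:
                    cache = _OutcomeCache(d, hyp, self.config.followup_years)
                    self._cache[arm] = cache
            out = arm_outcome(d, self.nh, hyp, risk, self.config.followup_years, cache)
            scale = self.config.arm_size(arm) / d.n
            for key2, v in _counts_from_outcome(out, d, self.by_cell_type).items():
                cells[(arm, *key2)] = v * scale
        return CountTable.from_dict(cells, by_cell_type=self.by_cell_type)

    def realized(self, hyp: Optional[HypothesisParams] = None) -> CountTable:
        """Raw integer counts at the simulated (not rescaled) arm sizes.

        Meaningful at oversample 1, where it is one stochastic trial
        replicate; used by the synthetic-data generator.
        """
        hyp = self.default_hypothesis() if hyp is None else hyp
        cells: dict[tuple, float] = {}
        for arm in ARMS:
            d = self.draws[arm]
            risk = hyp.risk_factor if arm == "intervention" else 1.0
            out = arm_outcome(d, self.nh, hyp, risk, self.config.followup_years)
            for key2, v in _counts_from_outcome(out, d, self.by_cell_type).items():
                cells[(arm, *key2)] = v
        return CountTable.from_dict(cells, by_cell_type=self.by_cell_type)


def simulate_trial(
    config: TrialConfig,
    nh: NaturalHistoryParams,
    test: TestCharacteristics,
    life_table: LifeTable,
    oversample: float = 20.0,
    by_cell_type: bool = False,
    seed: Optional[int] = None,
) -> CountTable:
    """Expected diagnosis counts for one trial configuration.

    Simulates ``oversample`` times the nominal cohort per arm for
    variance reduction and rescales frequencies to the nominal arm
    sizes.
    """
    sim = TrialSimulator(
        config, nh, test, life_table, oversample=oversample, by_cell_type=by_cell_type, seed=seed
    )
    return sim.expected()
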