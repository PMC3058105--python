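"""Vectorized trial engine with common-random-number support.

The engine draws every random variate a person will ever need *once*,
as flat arrays that do not depend on the six calibrated hypothesis
parameters (stage-group sensitivities, systematic-error increments,
indolent fraction, between-arm risk factor).  Evaluating a candidate
parameter vector is then a deterministic numpy transform of the stored
draws: onset happens iff a stored uniform falls below the (risk-scaled)
lifetime onset probability, a tumor is indolent iff another stored
uniform falls below the indolent fraction, and a detectable exam is
positive iff its stored uniform falls below the effective sensitivity.

This gives exact common random numbers across the whole parameter
space: the deviance objective seen by the optimizer is a deterministic,
piecewise-smooth function of the parameters, and raising a sensitivity
can only ever add detections.  It is also what makes calibration
affordable — the expensive draw generation is paid once per seed.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .natural_history import CELL_TYPES, LifeTable, NaturalHistoryParams, Stage
from .screening import ScreeningPolicy, build_schedule


@dataclass(frozen=True)
class HypothesisParams:
    """The six calibrated quantities, at their null values by default.

    ``risk_factor`` multiplies the intervention arm's lifetime onset
    probability only; the control arm is always at factor 1.
    """

    sens_II: float = 1.0
    sens_III: float = 1.0
    syserr_II: float = 0.0
    syserr_III: float = 0.0
    indolent_fraction: float = 0.0
    risk_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sens_II", "sens_III", "syserr_II", "syserr_III", "indolent_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.risk_factor <= 0:
            raise ValueError("risk_factor must be > 0")

PARAM_NAMES = (
    "sens_II",
    "sens_III",
    "syserr_II",
    "syserr_III",
    "indolent_fraction",
    "risk_factor",
)


@dataclass
class ArmDraws:
    """All parameter-independent randomness for one simulated arm."""

    n: int
    cell: np.ndarray           # int8 index into CELL_TYPES
    u_onset: np.ndarray        # uniforms gating onset
    onset_age: np.ndarray
    entry_age: np.ndarray
    death_age: np.ndarray
    t_pre2: np.ndarray         # age entering PRE_II
    t_clin3: np.ndarray        # age entering CLIN_III (if not indolent)
    clin_dx_age: np.ndarray    # clinical surfacing age (if not indolent)
    dx_at_III: np.ndarray      # surfaced in stage III (else IV)
    u_indolent: np.ndarray
    exam_times: np.ndarray     # trial times, possibly empty
    attended: Optional[np.ndarray]  # (n_exams, n) bool, None = all attend
    u_detect: Optional[np.ndarray]  # (n_exams, n) float32
    compound_syserr: bool = False
    pre_detectable_misses: bool = True


def sample_death_ages(
    life_table: LifeTable, entry_ages: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized annual-Bernoulli other-cause death sampling."""
    entry_ages = np.asarray(entry_ages, dtype=float)
    if entry_ages.size and (
        entry_ages.min() < life_table.ages[0] or entry_ages.max() >= life_table.cap_age
    ):
        raise ValueError("entry ages outside life-table range")
    cap = life_table.cap_age
    age = entry_ages.copy()
    death = np.full(entry_ages.shape, cap)
    active = np.ones(entry_ages.shape, dtype=bool)
    while True:
        active &= age < cap
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        cur = age[idx]
        bins = np.searchsorted(life_table.ages, cur, side="right") - 1
        q = life_table.annual_death_prob[bins]
        died = rng.random(idx.size) < q
        placement = rng.random(idx.size)
        dead_idx = idx[died]
        death[dead_idx] = np.minimum(cur[died] + placement[died], cap)
        active[dead_idx] = False
        age[idx[~died]] += 1.0
    return death


def generate_arm_draws(
    n: int,
    nh: NaturalHistoryParams,
    life_table: LifeTable,
    policy: ScreeningPolicy,
    entry_age_low: float,
    entry_age_high: float,
    seed_seq: np.random.SeedSequence,
) -> ArmDraws:
    rng = np.random.default_rng(seed_seq)
    probs = np.array([nh.cell_type_probs[ct] for ct in CELL_TYPES])
    cell = rng.choice(len(CELL_TYPES), size=n, p=probs).astype(np.int8)
    u_onset = rng.random(n)

    onset_age = np.empty(n)
    dwell = np.empty((4, n))
    for i, ct in enumerate(CELL_TYPES):
        mask = cell == i
        m = int(mask.sum())
        shape = nh.onset.weibull_shape[ct]
        onset_age[mask] = nh.onset.weibull_scale(ct) * rng.weibull(shape, m)
        for j, st in enumerate(Stage):
            dwell[j, mask] = rng.exponential(nh.progression.mean_dwell[ct][st], m)

    u_dx3 = rng.random(n)
    p3 = np.array([nh.progression.p_clinical_dx_at_III[ct] for ct in CELL_TYPES])
    dx_at_III = u_dx3 < p3[cell]
    t_pre2 = onset_age + dwell[0]
    t_clin3 = t_pre2 + dwell[1]
    end3 = t_clin3 + dwell[2]
    clin_dx_age = np.where(dx_at_III, end3, end3 + dwell[3])
    u_indolent = rng.random(n)

    if entry_age_high < entry_age_low:
        raise ValueError("entry_age_high must be >= entry_age_low")
    entry_age = rng.uniform(entry_age_low, entry_age_high, n)
    death_age = sample_death_ages(life_table, entry_age, rng)

    screened = policy.attendance_prob > 0.0
    exam_times = build_schedule(policy) if screened else np.empty(0)
    attended = None
    u_detect = None
    if screened and exam_times.size:
        if policy.attendance_prob < 1.0:
            attended = rng.random((exam_times.size, n)) < policy.attendance_prob
        u_detect = rng.random((exam_times.size, n), dtype=np.float32)

    return ArmDraws(
        n=n,
        cell=cell,
        u_onset=u_onset,
        onset_age=onset_age,
        entry_age=entry_age,
        death_age=death_age,
        t_pre2=t_pre2,
        t_clin3=t_clin3,
        clin_dx_age=clin_dx_age,
        dx_at_III=dx_at_III,
        u_indolent=u_indolent,
        exam_times=exam_times,
        attended=attended,
        u_detect=u_detect,
    )


def _screening_pass(
    d: ArmDraws,
    eligible: np.ndarray,
    indolent: np.ndarray,
    sens_II: float,
    sens_III: float,
    syserr_II: float,
    syserr_III: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (detected in II-, detected in III+) boolean masks."""
    n = d.n
    det_II = np.zeros(n, dtype=bool)
    det_III = np.zeros(n, dtype=bool)
    if d.u_detect is None:
        return det_II, det_III
    detected = np.zeros(n, dtype=bool)
    miss_II = np.zeros(n, dtype=np.int16)
    miss_III = np.zeros(n, dtype=np.int16)
    miss_pre = np.zeros(n, dtype=np.int16)
    for e, tau in enumerate(d.exam_times):
        age = d.entry_age + tau
        active = eligible & ~detected & (age < d.death_age)
        if d.attended is not None:
            active &= d.attended[e]
        in_II = active & (age >= d.t_pre2) & (indolent | (age < d.t_clin3))
        in_III = active & ~indolent & (age >= d.t_clin3) & (age < d.clin_dx_age)
        u = d.u_detect[e]
        for in_grp, det_grp, misses, sens, err in (
            (in_II, det_II, miss_II, sens_II, syserr_II),
            (in_III, det_III, miss_III, sens_III, syserr_III),
        ):
            total = misses + miss_pre
            eff = total if d.compound_syserr else (total > 0)
            p_hit = 1.0 - np.minimum(1.0, (1.0 - sens) + err * eff)
            hit = in_grp & (u < p_hit)
            det_grp |= hit
            detected |= hit
            misses[in_grp & ~hit] += 1
        if d.pre_detectable_misses:
            in_pre = active & (age >= d.onset_age) & (age < d.t_pre2)
            miss_pre[in_pre] += 1
    return det_II, det_III


@dataclass
class ArmOutcome:
    """Per-person outcome masks for one arm at one parameter vector."""

    screen_II: np.ndarray
    screen_III: np.ndarray
    clinical: np.ndarray  # all stage group III+

    @property
    def never(self) -> int:
        n = self.screen_II.size
        return int(n - self.screen_II.sum() - self.screen_III.sum() - self.clinical.sum())


def _branch_outcomes(d: ArmDraws, hyp: HypothesisParams, followup_years: float):
    """Screen/clinical outcome masks under the two indolence branches.

    Both branches are evaluated for every person (everyone eligible);
    the caller selects per person with the indolence indicator.  Only
    valid when the screening parameters are shared by both branches,
    which they always are.
    """
    all_elig = np.ones(d.n, dtype=bool)
    ind_all = np.ones(d.n, dtype=bool)
    prog_all = np.zeros(d.n, dtype=bool)
    det_II_p, det_III_p = _screening_pass(
        d, all_elig, prog_all, hyp.sens_II, hyp.sens_III, hyp.syserr_II, hyp.syserr_III
    )
    det_II_i, _ = _screening_pass(
        d, all_elig, ind_all, hyp.sens_II, hyp.sens_III, hyp.syserr_II, hyp.syserr_III
    )
    trial_dx_time = d.clin_dx_age - d.entry_age
    clin_p = (
        ~det_II_p
        & ~det_III_p
        & (d.clin_dx_age < d.death_age)
        & (trial_dx_time > 0)
        & (trial_dx_time <= followup_years)
    )
    return (det_II_p, det_III_p, clin_p), det_II_i


class _OutcomeCache:
    """Pre-resolved branch outcomes for fits that keep the test fixed.

    When only ``risk_factor`` and/or ``indolent_fraction`` vary, the
    screening pass does not depend on the candidate parameters, so both
    indolence branches can be resolved once; each objective evaluation
    is then a handful of boolean reductions.
    """

    def __init__(self, d: ArmDraws, hyp: HypothesisParams, followup_years: float):
        (self.det_II_p, self.det_III_p, self.clin_p), self.det_II_i = _branch_outcomes(
            d, hyp, followup_years
        )
        self.d = d
        self.not_prevalent = d.clin_dx_age > d.entry_age
        self.key = (hyp.sens_II, hyp.sens_III, hyp.syserr_II, hyp.syserr_III)

    def outcome(self, has_onset: np.ndarray, indolent: np.ndarray) -> ArmOutcome:
        elig_prog = has_onset & ~indolent & self.not_prevalent
        elig_ind = has_onset & indolent
        return ArmOutcome(
            screen_II=(elig_prog & self.det_II_p) | (elig_ind & self.det_II_i),
            screen_III=elig_prog & self.det_III_p,
            clinical=elig_prog & self.clin_p,
        )


def arm_outcome(
    d: ArmDraws,
    nh: NaturalHistoryParams,
    hyp: HypothesisParams,
    risk_factor: float,
    followup_years: float,
    cache: Optional[_OutcomeCache] = None,
) -> ArmOutcome:
    if followup_years <= 0:  # empty observation window records nothing
        z = np.zeros(d.n, dtype=bool)
        return ArmOutcome(z, z.copy(), z.copy())
    p_onset = np.array([nh.onset.lifetime_onset_prob[ct] for ct in CELL_TYPES])
    p_eff = risk_factor * p_onset
    if np.any(p_eff > 1.0 + 1e-12):
        raise ValueError("risk_factor x lifetime_onset_prob exceeds 1")
    has_onset = d.u_onset < p_eff[d.cell]
    indolent = d.u_indolent < hyp.indolent_fraction

    if cache is not None:
        return cache.outcome(has_onset, indolent)

    trial_dx_time = d.clin_dx_age - d.entry_age
    eligible = has_onset & (indolent | (trial_dx_time > 0))
    det_II, det_III = _screening_pass(
        d, eligible, indolent, hyp.sens_II, hyp.sens_III, hyp.syserr_II, hyp.syserr_III
    )
    clinical = (
        eligible
        & ~det_II
        & ~det_III
        & ~indolent
        & (d.clin_dx_age < d.death_age)
        & (trial_dx_time <= followup_years)
    )
    return ArmOutcome(screen_II=det_II, screen_III=det_III, clinical=clinical)


def _counts_from_outcome(
    out: ArmOutcome, d: ArmDraws, by_cell_type: bool
) -> dict[tuple, float]:
    cells: dict[tuple, float] = {}

    def add(mode: str, group: str, mask: np.ndarray) -> None:
        if by_cell_type:
            counts = np.bincount(d.cell[mask], minlength=len(CELL_TYPES))
            for i, ct in enumerate(CELL_TYPES):
                cells[(mode, group, ct.value)] = float(counts[i])
        else:
            cells[(mode, group)] = float(mask.sum())

    add("screen_detected", "II_minus", out.screen_II)
    add("screen_detected", "III_plus", out.screen_III)
    add("clinically_diagnosed", "III_plus", out.clinical)
    return cells
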