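import numpy as np
import pytest

from lungscreen import (
    CellType,
    DiseasePath,
    Stage,
    TestCharacteristics,
    default_truth,
    mlp_fixture_table,
)


@pytest.fixture(scope="session")
def small_truth():
    """Default truth scaled down to 2000-person arms for fast tests."""
    return default_truth(seed=123, n_intervention=2000, n_control=2000)


@pytest.fixture(scope="session")
def fixture_table():
    return mlp_fixture_table()


def make_path(
    onset=50.0,
    pre2=52.0,
    clin3=56.0,
    dx=58.0,
    dx_at_III=True,
    cell_type=CellType.ADENO_LARGE,
    indolent=False,
):
    """Hand-built disease path with chosen stage-entry ages."""
    entries = {Stage.PRE_I: onset, Stage.PRE_II: pre2}
    if indolent:
        return DiseasePath(
            cell_type=cell_type,
            onset_age=onset,
            stage_entry_ages=entries,
            clinical_dx_age=None,
            clinical_dx_stage=None,
            indolent=True,
        )
    entries[Stage.CLIN_III] = clin3
    if not dx_at_III:
        entries[Stage.CLIN_IV] = (clin3 + dx) / 2.0
    return DiseasePath(
        cell_type=cell_type,
        onset_age=onset,
        stage_entry_ages=entries,
        clinical_dx_age=dx,
        clinical_dx_stage=Stage.CLIN_III if dx_at_III else Stage.CLIN_IV,
        indolent=False,
    )


def detection_prob_oracle(sens, syserr, n_window_exams, n_pre_exams=0, compound=False):
    """Brute-force screen-detection probability over first-hit positions.

    Enumerates every possible outcome (hit at exam j after j misses, or
    all exams missed); the miss probability at the i-th detectable exam
    reflects the accumulated false-negative history, including any
    earlier attended exams during the undetectable phase.
    """

    def miss(prior):
        if prior == 0:
            return 1.0 - sens
        bump = syserr * prior if compound else syserr
        return min(1.0, (1.0 - sens) + bump)

    p_detect = 0.0
    p_seq = 1.0  # probability of having missed every exam so far
    for j in range(n_window_exams):
        m = miss(n_pre_exams + j)
        p_detect += p_seq * (1.0 - m)
        p_seq *= m
    assert abs(p_detect + p_seq - 1.0) < 1e-12
    return p_detect
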