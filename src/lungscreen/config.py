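"""YAML/JSON serialization of configuration objects.

Everything the simulator needs — natural history, test
characteristics, trial design, life table — round-trips through plain
dictionaries so configs can live in version-controlled YAML.  Validation
happens in the dataclass constructors; a malformed config fails loudly
at load time.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .natural_history import (
    CELL_TYPES,
    CellType,
    LifeTable,
    NaturalHistoryParams,
    OnsetParams,
    ProgressionParams,
    Stage,
)
from .screening import ScreeningPolicy, TestCharacteristics
from .synthetic_data import TruthSpec
from .trial_sim import TrialConfig


def _per_cell_to_dict(m) -> dict[str, Any]:
    return {ct.value: m[ct] for ct in CELL_TYPES}


def _per_cell_from_dict(d) -> dict[CellType, Any]:
    return {ct: d[ct.value] for ct in CELL_TYPES}


def nh_to_dict(nh: NaturalHistoryParams) -> dict:
    return {
        "onset": {
            "weibull_shape": _per_cell_to_dict(nh.onset.weibull_shape),
            "weibull_mean": _per_cell_to_dict(nh.onset.weibull_mean),
            "lifetime_onset_prob": _per_cell_to_dict(nh.onset.lifetime_onset_prob),
        },
        "progression": {
            "mean_dwell": {
                ct.value: {st.name: nh.progression.mean_dwell[ct][st] for st in Stage}
                for ct in CELL_TYPES
            },
            "p_clinical_dx_at_III": _per_cell_to_dict(nh.progression.p_clinical_dx_at_III),
            "indolent_fraction": nh.progression.indolent_fraction,
        },
        "cell_type_probs": _per_cell_to_dict(nh.cell_type_probs),
    }


def nh_from_dict(d: dict) -> NaturalHistoryParams:
    onset = OnsetParams(
        weibull_shape=_per_cell_from_dict(d["onset"]["weibull_shape"]),
        weibull_mean=_per_cell_from_dict(d["onset"]["weibull_mean"]),
        lifetime_onset_prob=_per_cell_from_dict(d["onset"]["lifetime_onset_prob"]),
    )
    prog = d["progression"]
    progression = ProgressionParams(
        mean_dwell={
            ct: {st: prog["mean_dwell"][ct.value][st.name] for st in Stage} for ct in CELL_TYPES
        },
        p_clinical_dx_at_III=_per_cell_from_dict(prog["p_clinical_dx_at_III"]),
        indolent_fraction=prog.get("indolent_fraction", 0.0),
    )
    return NaturalHistoryParams(
        onset=onset, progression=progression, cell_type_probs=_per_cell_from_dict(d["cell_type_probs"])
    )


def policy_to_dict(p: ScreeningPolicy) -> dict:
    return {
        "interval": p.interval,
        "duration": p.duration,
        "attendance_prob": p.attendance_prob,
        "start_time": p.start_time,
    }


def trial_to_dict(t: TrialConfig) -> dict:
    return {
        "n_intervention": t.n_intervention,
        "n_control": t.n_control,
        "entry_age_low": t.entry_age_low,
        "entry_age_high": t.entry_age_high,
        "followup_years": t.followup_years,
        "risk_factor_intervention": t.risk_factor_intervention,
        "policy_intervention": policy_to_dict(t.policy_intervention),
        "policy_control": policy_to_dict(t.policy_control),
        "seed": t.seed,
    }


def trial_from_dict(d: dict) -> TrialConfig:
    d = dict(d)
    for key in ("policy_intervention", "policy_control"):
        if key in d:
            d[key] = ScreeningPolicy(**d[key])
    return TrialConfig(**d)


def test_to_dict(t: TestCharacteristics) -> dict:
    return {
        "sens_II": t.sens_II,
        "sens_III": t.sens_III,
        "syserr_II": t.syserr_II,
        "syserr_III": t.syserr_III,
        "compound_syserr": t.compound_syserr,
    }


def truth_to_dict(truth: TruthSpec) -> dict:
    return {
        "nh": nh_to_dict(truth.nh),
        "test": test_to_dict(truth.test),
        "trial": trial_to_dict(truth.trial),
        "life_table": {
            "ages": [float(a) for a in truth.life_table.ages],
            "annual_death_prob": [float(q) for q in truth.life_table.annual_death_prob],
        },
        "seed": truth.seed,
    }


def truth_from_dict(d: dict) -> TruthSpec:
    return TruthSpec(
        nh=nh_from_dict(d["nh"]),
        test=TestCharacteristics(**d["test"]),
        trial=trial_from_dict(d["trial"]),
        life_table=LifeTable(
            ages=np.asarray(d["life_table"]["ages"]),
            annual_death_prob=np.asarray(d["life_table"]["annual_death_prob"]),
        ),
        seed=int(d.get("seed", 0)),
    )


def save_truth(truth: TruthSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(truth_to_dict(truth), sort_keys=False))


def load_truth(path) -> TruthSpec:
    return truth_from_dict(yaml.safe_load(Path(path).read_text()))


def config_hash(d: dict) -> str:
    """Stable short hash of a config dict, for run manifests."""
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]
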