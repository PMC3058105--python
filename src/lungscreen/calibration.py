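"""Deviance-based calibration of the simulator to observed counts.

Observed and expected tables are scored as independent Poisson cells.
Under that family the saturated model's expectation is the observed
table itself, and the deviance is

    D = 2 * (loglik_saturated - loglik_model)
      = 2 * sum_cells [ O * ln(O/E) - (O - E) ],

with the O = 0 term equal to E.  Nested model extensions are compared
by the chi-square upper-tail probability of their deviance reduction.

Free parameters are fitted by bounded derivative-free search over the
stochastic simulator.  Because the simulator uses common random numbers
(one frozen draw set per fit), the objective is a deterministic
function of the parameters and nested models can be compared fairly.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

from ._engine import PARAM_NAMES, HypothesisParams
from .counts import CountTable
from .trial_sim import TrialSimulator


# --------------------------------------------------------------------- scores
def _aligned(observed: CountTable, expected: CountTable) -> tuple[np.ndarray, np.ndarray]:
    if not observed.same_layout(expected):
        raise ValueError("observed and expected tables must share an identical cell layout")
    return observed.values(), expected.values()


def poisson_loglik(observed: CountTable, expected: CountTable) -> float:
    """Sum over cells of O*ln(E) - E - ln(O!) under independent Poisson cells.

    A cell with expected 0 but observed > 0 yields -inf (reported with a
    warning, not raised): the model assigns the data zero likelihood.
    """
    obs, exp = _aligned(observed, expected)
    if np.any((exp <= 0) & (obs > 0)):
        warnings.warn("expected count is 0 in a cell with observed > 0; log-likelihood is -inf")
        return float("-inf")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = special.xlogy(obs, exp) - exp - special.gammaln(obs + 1.0)
    return float(np.sum(terms))


def _rescale_to_arm_totals(observed: CountTable, expected: CountTable) -> CountTable:
    """Expected table rescaled so each arm's total matches the observed arm
    total — the conditioning step of the multinomial-per-arm family."""
    scaled = expected.counts.copy()
    arms = scaled.index.get_level_values("arm")
    for arm in arms.unique():
        mask = arms == arm
        e_tot = scaled[mask].sum()
        o_tot = observed.counts[mask].sum()
        if e_tot > 0:
            scaled[mask] *= o_tot / e_tot
    return CountTable(scaled)


def deviance(observed: CountTable, expected: CountTable, family: str = "poisson") -> float:
    """Deviance 2*sum[O*ln(O/E) - (O - E)]; 0 iff E matches O.

    ``family='poisson'`` (default) treats cells as independent Poisson
    counts.  ``family='multinomial'`` conditions on each arm's observed
    total before scoring, so only the allocation across cells within an
    arm is penalized (the O - E terms then cancel arm-by-arm).
    """
    if family == "multinomial":
        expected = _rescale_to_arm_totals(observed, expected)
    elif family != "poisson":
        raise ValueError(f"unknown likelihood family {family!r}")
    obs, exp = _aligned(observed, expected)
    if np.any((exp <= 0) & (obs > 0)):
        warnings.warn("expected count is 0 in a cell with observed > 0; deviance is infinite")
        return float("inf")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(obs > 0, obs / np.where(exp > 0, exp, 1.0), 1.0)
        terms = special.xlogy(obs, ratio) - (obs - exp)
    return float(2.0 * np.sum(terms))


def chi2_pvalue(dev_reduction: float, df: int) -> float:
    """Upper-tail chi-square probability of a deviance reduction."""
    if dev_reduction < 0:
        raise ValueError("deviance reduction must be >= 0")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.sf(dev_reduction, df))


def binomial_excess_test(observed_total: int, expected_total: float, n_at_risk: int) -> float:
    """One-sided exact binomial P(X >= observed) with X ~ Bin(n, expected/n)."""
    if not 0 <= observed_total <= n_at_risk:
        raise ValueError("observed_total must be in [0, n_at_risk]")
    if expected_total <= 0:
        raise ValueError("expected_total must be > 0")
    if expected_total >= n_at_risk:
        raise ValueError("expected_total must be < n_at_risk")
    p = expected_total / n_at_risk
    return float(stats.binom.sf(observed_total - 1, n_at_risk, p))


# ------------------------------------------------------------------ model set
@dataclass(frozen=True)
class ModelSpec:
    """Which hypothesis parameters a model frees, with bounds and starts."""

    name: str
    free_params: tuple[str, ...]
    bounds: Mapping[str, tuple[float, float]]
    start: Mapping[str, float]

    def __post_init__(self) -> None:
        for p in self.free_params:
            if p not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {p!r}")
            lo, hi = self.bounds[p]
            if not lo < hi:
                raise ValueError(f"bad bounds for {p}")
            if not lo <= self.start[p] <= hi:
                raise ValueError(f"start for {p} outside bounds")


_SENS_B = (0.5, 1.0)
_ERR_B = (0.0, 0.6)

MODEL_SPECS: dict[str, ModelSpec] = {
    "Simple": ModelSpec("Simple", (), {}, {}),
    "Sensitivity": ModelSpec(
        "Sensitivity",
        ("sens_II", "sens_III"),
        {"sens_II": _SENS_B, "sens_III": _SENS_B},
        {"sens_II": 0.9, "sens_III": 0.9},
    ),
    "SystematicError": ModelSpec(
        "SystematicError",
        ("syserr_II", "syserr_III"),
        {"syserr_II": _ERR_B, "syserr_III": _ERR_B},
        {"syserr_II": 0.1, "syserr_III": 0.1},
    ),
    "SensitivityError": ModelSpec(
        "SensitivityError",
        ("sens_II", "sens_III", "syserr_II", "syserr_III"),
        {"sens_II": _SENS_B, "sens_III": _SENS_B, "syserr_II": _ERR_B, "syserr_III": _ERR_B},
        {"sens_II": 0.9, "sens_III": 0.9, "syserr_II": 0.1, "syserr_III": 0.1},
    ),
    "Overdiagnosis": ModelSpec(
        "Overdiagnosis", ("indolent_fraction",), {"indolent_fraction": (0.0, 0.6)},
        {"indolent_fraction": 0.1},
    ),
    "RiskDifference": ModelSpec(
        "RiskDifference", ("risk_factor",), {"risk_factor": (0.5, 2.0)}, {"risk_factor": 1.1}
    ),
}

MODEL_ORDER = tuple(MODEL_SPECS)


@dataclass
class FitResult:
    model: str
    fitted_values: dict[str, float]
    deviance: float
    loglik: float
    n_evals: int
    seed: int
    converged: bool = True


# --------------------------------------------------------------------- fitter
_FAST_PARAMS = {"risk_factor", "indolent_fraction"}


def _grid_refine_1d(
    objective, lo: float, hi: float, n_points: int = 21, n_stages: int = 3
) -> tuple[float, float]:
    """Deterministic multistage grid search for a 1-D objective.

    Robust to the small plateaus a finite-sample simulator objective
    has, where gradient or parabolic methods can stall.
    """
    best_x, best_f = lo, float("inf")
    for _ in range(n_stages):
        xs = np.linspace(lo, hi, n_points)
        fs = [objective(float(x)) for x in xs]
        i = int(np.argmin(fs))
        if fs[i] < best_f:
            best_f, best_x = fs[i], float(xs[i])
        step = (hi - lo) / (n_points - 1)
        lo, hi = max(lo, best_x - 1.5 * step), min(hi, best_x + 1.5 * step)
    return best_x, best_f


def fit_model(
    spec: ModelSpec,
    observed: CountTable,
    simulator: TrialSimulator,
    maxfev: int = 300,
    fatol: float = 1e-3,
    n_restarts: int = 3,
    family: str = "poisson",
) -> FitResult:
    """Minimize the deviance of the simulator against an observed table.

    All evaluations share the simulator's frozen draw set (common
    random numbers), so the objective is deterministic given the seed.
    Zero-parameter specs are evaluated once; single-parameter specs use
    a deterministic staged grid search; multi-parameter specs use
    bounded Nelder-Mead with jittered restarts.
    """
    if not observed.is_integer():
        raise ValueError("observed table must contain integer counts")
    base = HypothesisParams()
    free = spec.free_params
    fast = bool(free) and set(free) <= _FAST_PARAMS
    n_evals = 0

    def objective(x: Sequence[float]) -> float:
        nonlocal n_evals
        n_evals += 1
        vals = {p: float(np.clip(v, *spec.bounds[p])) for p, v in zip(free, np.atleast_1d(x))}
        hyp = replace(base, **vals)
        return deviance(observed, simulator.expected(hyp, use_cache=fast), family=family)

    converged = True
    if not free:
        best_x: list[float] = []
        best_f = objective([])
    elif len(free) == 1:
        lo, hi = spec.bounds[free[0]]
        x, best_f = _grid_refine_1d(lambda v: objective([v]), lo, hi)
        best_x = [x]
    else:
        rng = np.random.default_rng(np.random.SeedSequence([simulator.seed, 9001]))
        lows = np.array([spec.bounds[p][0] for p in free])
        highs = np.array([spec.bounds[p][1] for p in free])
        x0 = np.array([spec.start[p] for p in free])
        starts = [x0] + [
            np.clip(x0 + rng.uniform(-0.2, 0.2, len(free)) * (highs - lows), lows, highs)
            for _ in range(n_restarts - 1)
        ]
        best_f, best_x = float("inf"), list(x0)
        per_restart = max(20, maxfev // max(1, n_restarts))
        any_converged = False
        for s in starts:
            res = optimize.minimize(
                objective,
                s,
                method="Nelder-Mead",
                bounds=list(zip(lows, highs)),
                options={"fatol": fatol, "xatol": 1e-3, "maxfev": per_restart},
            )
            any_converged = any_converged or bool(res.success)
            if res.fun < best_f:
                best_f, best_x = float(res.fun), list(np.clip(res.x, lows, highs))
        converged = any_converged

    fitted = {p: float(np.clip(v, *spec.bounds[p])) for p, v in zip(free, best_x)}
    hyp = replace(base, **fitted)
    expected = simulator.expected(hyp, use_cache=fast)
    return FitResult(
        model=spec.name,
        fitted_values=fitted,
        deviance=float(best_f),
        loglik=poisson_loglik(observed, expected),
        n_evals=n_evals,
        seed=simulator.seed,
        converged=converged,
    )
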