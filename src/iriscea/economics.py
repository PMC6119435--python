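"""Cost and QALY accrual, incremental cost-effectiveness and net benefit.

Costs are in 2015/16 GBP per woman registered at a general practice;
outcomes are discounted QALYs per woman.  Three cost streams are accrued
over the cohort trace:

* state costs — women in an abused state incur the per-cycle abuse cost
  (identified states scaled by their cost weights); under the NHS
  perspective only the ``nhs_cost_share`` fraction of this stream counts;
* referral costs — a one-time advocate-contact cost charged per entrant to
  the seeing-advocate state, discounted at the end of the entry cycle;
* programme costs — the per-woman per-cycle intervention cost, charged for
  living women in the intervention arm only.

Occupancy-based streams support two accrual conventions.  The default,
``cycle_start``, counts state membership at the beginning of each of the
``n_cycles`` cycles and discounts at the cycle-start time point; it
reproduces the published pooled totals.  ``trapezoid`` applies the textbook
half-cycle correction (weights ½, 1, …, 1, ½ over the n_cycles + 1 time
points).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import (
    CohortTrace,
    HealthState,
    TransitionMatrix,
    build_transition_matrix,
    initial_distribution,
    run_cohort,
)
from .parameters import ParameterSet

__all__ = [
    "EconResult",
    "discount_factor",
    "accrue_qalys",
    "accrue_costs",
    "derive_nhs_cost_share",
    "compare",
    "run_arm",
    "run_base_case",
]

PERSPECTIVES = ("societal", "nhs")


def discount_factor(
    time_point: int | np.ndarray, rate: float, cycle_length: float
) -> float | np.ndarray:
    """(1 + rate)^(−t · cycle_length): the discount factor at time point t."""
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    return (1.0 + rate) ** (-np.asarray(time_point) * cycle_length)


def _accrual_weights(params: ParameterSet) -> tuple[np.ndarray, np.ndarray]:
    """(time points, weights·discount) for occupancy-based streams."""
    n = params.n_cycles
    if params.accrual == "cycle_start":
        t = np.arange(n)
        w = np.ones(n)
    elif params.accrual == "trapezoid":
        t = np.arange(n + 1)
        w = np.ones(n + 1)
        w[0] = w[-1] = 0.5
    else:
        raise ValueError(f"unknown accrual mode {params.accrual!r}")
    disc = discount_factor(t, params.discount_rate_annual, params.cycle_length_years)
    return t, w * disc


def accrue_qalys(trace: CohortTrace, params: ParameterSet) -> float:
    """Discounted QALYs per woman: utility-weighted occupancy time."""
    util = np.zeros(5)
    for s, spec in params.utilities.items():
        util[HealthState[s]] = spec.base
    t, w = _accrual_weights(params)
    return float(np.sum(w * (trace.occupancy[t] @ util)) * params.cycle_length_years)


def accrue_costs(
    trace: CohortTrace, params: ParameterSet, arm: str, perspective: str = "societal"
) -> float:
    """Discounted cost per woman for one arm under one perspective."""
    if perspective not in PERSPECTIVES:
        raise ValueError(f"unknown perspective {perspective!r}; expected {PERSPECTIVES}")
    if arm not in ("control", "intervention"):
        raise ValueError(f"unknown arm {arm!r}")

    c_abuse = params.cost_abuse_per_cycle.base
    state_cost = np.zeros(5)
    state_cost[HealthState.U] = c_abuse
    state_cost[HealthState.A] = params.cost_weight_seeing.base * c_abuse
    state_cost[HealthState.I] = params.cost_weight_not_seeing.base * c_abuse
    if perspective == "nhs":
        state_cost = state_cost * params.nhs_cost_share

    t, w = _accrual_weights(params)
    total = float(np.sum(w * (trace.occupancy[t] @ state_cost)))

    # one-time referral cost per entrant to the seeing-advocate state,
    # discounted at the end-of-cycle time point where the entrant arrives
    cycles = np.arange(1, trace.n_cycles + 1)
    disc_end = discount_factor(
        cycles, params.discount_rate_annual, params.cycle_length_years
    )
    entrants_A = trace.entrants[:, HealthState.A]
    total += float(params.cost_referral_once.base * np.sum(entrants_A * disc_end))
    if params.charge_initial_advocates:
        total += params.cost_referral_once.base * trace.occupancy[0, HealthState.A]

    if arm == "intervention":
        living = 1.0 - trace.occupancy[t, HealthState.D]
        total += float(
            params.cost_intervention_per_woman_cycle.base * np.sum(w * living)
        )
    return total


def derive_nhs_cost_share(params: ParameterSet, target_control_nhs_cost: float) -> float:
    """Back-solve the NHS share of the abuse cost from a control-arm NHS total.

    The NHS-perspective control cost is affine in the share:
    ``cost(share) = share * state_cost_stream + referral_stream``, so the
    solution is closed form.  Raises if the target lies below the
    share-independent referral floor or above the societal total.
    """
    if target_control_nhs_cost <= 0:
        raise ValueError("target must be positive")
    trial = params.copy()
    matrix = build_transition_matrix(trial, "control")
    trace = run_cohort(matrix, initial_distribution(trial), trial.n_cycles)
    trial.nhs_cost_share = 0.0
    floor = accrue_costs(trace, trial, "control", "nhs")  # referral stream only
    trial.nhs_cost_share = 1.0
    ceiling = accrue_costs(trace, trial, "control", "nhs")
    if not (floor <= target_control_nhs_cost <= ceiling):
        raise ValueError(
            f"target {target_control_nhs_cost} outside feasible range "
            f"[{floor:.2f}, {ceiling:.2f}]"
        )
    return (target_control_nhs_cost - floor) / (ceiling - floor)


@dataclass
class EconResult:
    """Per-arm discounted totals plus incremental cost-effectiveness."""

    control_cost: float
    control_qaly: float
    intervention_cost: float
    intervention_qaly: float
    incremental_cost: float
    incremental_qaly: float
    icer: float | None  # None when a dominance label applies or ΔQALY = 0
    dominance: str | None  # intervention-dominates | control-dominates | None
    nmb: float
    wtp: float
    perspective: str = "societal"


def compare(
    control: tuple[float, float],
    intervention: tuple[float, float],
    wtp: float,
    perspective: str = "societal",
) -> EconResult:
    """Incremental comparison of (cost, QALY) pairs at a willingness to pay.

    The ICER is reported as a number only when incremental cost and QALYs
    are strictly of the same sign; the sign patterns (≤0, ≥0) / (≥0, ≤0)
    with at least one strict inequality carry a dominance label instead.
    """
    d_cost = intervention[0] - control[0]
    d_qaly = intervention[1] - control[1]
    nmb = wtp * d_qaly - d_cost
    dominance = None
    icer: float | None = None
    if d_cost <= 0 and d_qaly >= 0 and (d_cost < 0 or d_qaly > 0):
        dominance = "intervention-dominates"
    elif d_cost >= 0 and d_qaly <= 0 and (d_cost > 0 or d_qaly < 0):
        dominance = "control-dominates"
    elif d_qaly != 0:
        icer = d_cost / d_qaly
    return EconResult(
        control_cost=control[0],
        control_qaly=control[1],
        intervention_cost=intervention[0],
        intervention_qaly=intervention[1],
        incremental_cost=d_cost,
        incremental_qaly=d_qaly,
        icer=icer,
        dominance=dominance,
        nmb=nmb,
        wtp=wtp,
        perspective=perspective,
    )


def run_arm(
    params: ParameterSet,
    arm: str,
    perspective: str = "societal",
    matrix: TransitionMatrix | None = None,
) -> tuple[float, float]:
    """(cost, QALYs) per woman for one arm of the deterministic model."""
    if matrix is None:
        matrix = build_transition_matrix(params, arm)
    trace = run_cohort(matrix, initial_distribution(params), params.n_cycles)
    return (
        accrue_costs(trace, params, arm, perspective),
        accrue_qalys(trace, params),
    )


def run_base_case(params: ParameterSet, perspective: str = "societal") -> EconResult:
    """Both arms of the deterministic model plus the incremental comparison."""
    control = run_arm(params, "control", perspective)
    intervention = run_arm(params, "intervention", perspective)
    return compare(control, intervention, params.wtp, perspective)
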