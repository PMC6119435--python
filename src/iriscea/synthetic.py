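"""Random structurally-valid parameter sets and closed-form miniature chains.

Generated sets keep the model's transition graph (its structural zeros), so
property tests exercise the same sparsity pattern as the real analysis; a
dense variant exists for engine stress tests.  The miniature chains carry
their analytically known answers, so every pipeline stage can be checked
without any external input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import (
    ALLOWED_EXITS,
    LIVING_STATES,
    DistributionSpec,
    ParameterSet,
    default_iris_parameters,
)

__all__ = ["SyntheticSpec", "random_parameter_set", "random_dense_matrix", "toy_models", "ToyModel"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs for the random parameter-set generator."""

    seed: int
    cost_scale: float = 2000.0
    utility_range: tuple[float, float] = (0.3, 0.9)
    exit_cap: float = 0.3  # per-row cap on total exit probability

    def violations(self) -> list[str]:
        out = []
        if not (0.0 <= self.exit_cap < 1.0):
            out.append("exit_cap must lie in [0, 1)")
        lo, hi = self.utility_range
        if not (0.0 <= lo <= hi <= 1.0):
            out.append("utility_range must be an interval within [0, 1]")
        if self.cost_scale < 0:
            out.append("cost_scale must be non-negative")
        return out


def _spec_around(rng: np.random.Generator, base: float, family: str, cap: float | None = None) -> DistributionSpec:
    """A coherent (low <= base <= high) uncertainty spec around a value."""
    lo = base * rng.uniform(0.5, 1.0)
    hi = base + (base - lo) * rng.uniform(0.5, 2.0)
    if cap is not None:
        hi = min(hi, cap)
    if family in ("beta", "dirichlet_row_member"):
        hi = min(hi, 1.0)
    return DistributionSpec(family, base, min(lo, base), max(hi, base))


def random_parameter_set(spec: SyntheticSpec) -> ParameterSet:
    """A random parameter set with the model's shape; always valid."""
    problems = spec.violations()
    if problems:
        raise ValueError("; ".join(problems))
    rng = np.random.default_rng(spec.seed)
    params = default_iris_parameters()

    prev = float(rng.uniform(0.05, 0.5))
    params.prevalence = _spec_around(rng, prev, "beta", cap=1.0)

    a = float(rng.uniform(0.0, 0.05))
    i = float(rng.uniform(0.0, 0.2))
    params.start_split_abused = {
        "A": _spec_around(rng, a, "uniform"),
        "I": _spec_around(rng, i, "uniform"),
        "U": DistributionSpec.fixed(1.0 - a - i),
    }

    for arm in ("control", "intervention"):
        for state in LIVING_STATES:
            targets = ALLOWED_EXITS[state]
            if spec.exit_cap == 0.0:
                raw = np.zeros(len(targets))
            else:
                raw = rng.dirichlet(np.ones(len(targets))) * rng.uniform(
                    0.0, spec.exit_cap
                )
            params.exits[arm][state] = {
                t: _spec_around(rng, float(v), "dirichlet_row_member")
                for t, v in zip(targets, raw)
            }

    lo, hi = spec.utility_range
    params.utilities = {
        s: _spec_around(rng, float(rng.uniform(lo, hi)), "beta") for s in LIVING_STATES
    }
    params.cost_abuse_per_cycle = _spec_around(
        rng, float(rng.uniform(0.0, spec.cost_scale)), "gamma"
    )
    params.cost_referral_once = _spec_around(
        rng, float(rng.uniform(0.0, spec.cost_scale)), "gamma"
    )
    params.cost_intervention_per_woman_cycle = _spec_around(
        rng, float(rng.uniform(0.0, spec.cost_scale / 100.0)), "gamma"
    )
    params.cost_weight_seeing = _spec_around(rng, float(rng.uniform(0.5, 1.5)), "gamma")
    params.cost_weight_not_seeing = _spec_around(
        rng, float(rng.uniform(0.5, 1.5)), "gamma"
    )
    params.rng_seed = int(rng.integers(0, 2**31 - 1))
    return params


def random_dense_matrix(rng: np.random.Generator, n_states: int = 5) -> np.ndarray:
    """A fully dense row-stochastic matrix with an absorbing last state,
    for engine stress tests only (ignores the model's structural zeros)."""
    P = rng.dirichlet(np.ones(n_states), size=n_states)
    P[-1] = 0.0
    P[-1, -1] = 1.0
    return P


@dataclass
class ToyModel:
    """A miniature chain with its analytically known answer attached."""

    name: str
    matrix: np.ndarray | None = None
    start: np.ndarray | None = None
    params: ParameterSet | None = None
    expected: dict = field(default_factory=dict)


def toy_models() -> dict[str, ToyModel]:
    """Closed-form fixtures used across the test-suite.

    * ``two_state_death`` — alive→dead 0.1 per cycle; dead fraction after
      t cycles is 1 − 0.9^t (0.19 at t = 2).
    * ``symmetric_switch`` — two living states swapping with probability p
      and equal death rates; the conditional-on-alive long run is (½, ½).
    * ``recovery_balance`` — N↔U with incidence 0.1, recovery 0.3, no
      deaths; long-run occupancy (0.75, 0.25), so calibrating to a 0.75
      not-abused target recovers incidence = recovery × (1 − 0.75)/0.75.
    * ``equal_arms`` — both arms identical with zero programme and referral
      costs; every incremental result is exactly zero.
    * ``zero_cost`` — all costs zero; arm costs are exactly zero.
    """
    out = {}

    out["two_state_death"] = ToyModel(
        name="two_state_death",
        matrix=np.array([[0.9, 0.1], [0.0, 1.0]]),
        start=np.array([1.0, 0.0]),
        expected={"dead_after": lambda t: 1.0 - 0.9**t},
    )

    p, d = 0.2, 0.05
    out["symmetric_switch"] = ToyModel(
        name="symmetric_switch",
        matrix=np.array(
            [[1 - p - d, p, d], [p, 1 - p - d, d], [0.0, 0.0, 1.0]]
        ),
        start=np.array([1.0, 0.0, 0.0]),
        expected={"quasi_stationary": np.array([0.5, 0.5])},
    )

    balance = default_iris_parameters()
    for arm in ("control", "intervention"):
        balance.exits[arm] = {
            "N": {"U": DistributionSpec.fixed(0.1), "D": DistributionSpec.fixed(0.0)},
            "U": {
                "N": DistributionSpec.fixed(0.3),
                "A": DistributionSpec.fixed(0.0),
                "I": DistributionSpec.fixed(0.0),
                "D": DistributionSpec.fixed(0.0),
            },
            "A": {"N": DistributionSpec.fixed(0.5), "D": DistributionSpec.fixed(0.0)},
            "I": {"N": DistributionSpec.fixed(0.5), "D": DistributionSpec.fixed(0.0)},
        }
    out["recovery_balance"] = ToyModel(
        name="recovery_balance",
        params=balance,
        expected={
            "not_abused_fraction": 0.75,
            "closed_form_incidence": lambda target, recovery: recovery
            * (1.0 - target)
            / target,
        },
    )

    equal = default_iris_parameters()
    equal.exits["intervention"] = {
        s: dict(equal.exits["control"][s]) for s in LIVING_STATES
    }
    equal.cost_intervention_per_woman_cycle = DistributionSpec.fixed(0.0)
    equal.cost_referral_once = DistributionSpec.fixed(0.0)
    out["equal_arms"] = ToyModel(
        name="equal_arms",
        params=equal,
        expected={"incremental_cost": 0.0, "incremental_qaly": 0.0, "nmb": 0.0},
    )

    zero = default_iris_parameters()
    for f in (
        "cost_abuse_per_cycle",
        "cost_referral_once",
        "cost_intervention_per_woman_cycle",
    ):
        setattr(zero, f, DistributionSpec.fixed(0.0))
    out["zero_cost"] = ToyModel(
        name="zero_cost", params=zero, expected={"arm_cost": 0.0}
    )
    return out
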