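"""Markov cohort engine: transition matrices, cohort traces, long-run states.

The model tracks a closed cohort of women over five states in the fixed
order ``[N, U, A, I, D]``:

* ``N`` — not abused
* ``U`` — abused but not identified
* ``A`` — abused and identified, seeing the advocate educator
* ``I`` — abused and identified, not seeing the advocate educator
* ``D`` — dead (absorbing)

Transitions run on 6-month cycles.  Each living row of the transition
matrix is assembled from exit probabilities only; the stay probability is
their complement, so rows sum to 1 by construction.  Structural zeros
follow the model graph: the not-abused can only become abused-unidentified
or die, and identified women can only stay, recover, or die.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ALLOWED_EXITS, LIVING_STATES, ParameterSet

__all__ = [
    "HealthState",
    "STATE_ORDER",
    "TransitionMatrix",
    "CohortTrace",
    "QuasiStationaryResult",
    "build_transition_matrix",
    "initial_distribution",
    "run_cohort",
    "quasi_stationary_distribution",
    "ConstructionError",
]


class HealthState(enum.IntEnum):
    N = 0  # not abused
    U = 1  # abused, not identified
    A = 2  # abused, identified, seeing advocate educator
    I = 3  # abused, identified, not seeing advocate educator
    D = 4  # dead (absorbing)


STATE_ORDER = tuple(s.name for s in HealthState)


class ConstructionError(ValueError):
    """A transition row cannot be closed (exits sum to 1 or more)."""


@dataclass(frozen=True)
class TransitionMatrix:
    """A 5x5 per-cycle row-stochastic matrix for one arm."""

    probs: np.ndarray
    arm: str

    def __post_init__(self):
        P = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", P)
        if P.shape != (5, 5):
            raise ValueError(f"expected a 5x5 matrix, got {P.shape}")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("rows must sum to 1 within 1e-12")
        if (P < -1e-15).any() or (P > 1 + 1e-15).any():
            raise ValueError("entries must lie in [0, 1]")
        if not (P[HealthState.D, HealthState.D] == 1.0):
            raise ValueError("death must be absorbing")


def build_transition_matrix(params: ParameterSet, arm: str) -> TransitionMatrix:
    """Assemble an arm's matrix from its exit probabilities.

    Raises :class:`ConstructionError`, naming the row, if any living state's
    exits sum to 1 or more.
    """
    if arm not in ("control", "intervention"):
        raise ValueError(f"unknown arm {arm!r}")
    P = np.zeros((5, 5))
    for state in LIVING_STATES:
        i = HealthState[state]
        row = params.exit_probs(arm, state)
        total = sum(row.values())
        if total >= 1.0:
            raise ConstructionError(
                f"{arm} arm, state {state}: exits sum to {total:.6g} >= 1"
            )
        for target, p in row.items():
            if target not in ALLOWED_EXITS[state]:
                raise ConstructionError(
                    f"{arm} arm, state {state}: transition to {target} is not allowed"
                )
            P[i, HealthState[target]] = p
        P[i, i] = 1.0 - total
    P[HealthState.D, HealthState.D] = 1.0
    return TransitionMatrix(P, arm)


def initial_distribution(params: ParameterSet) -> np.ndarray:
    """Starting occupancy: 1 − prevalence in N; the abused mass split over
    U, A, I by the starting-split fractions; nobody starts dead."""
    prev = params.prevalence.base
    split = {s: params.start_split_abused[s].base for s in ("U", "A", "I")}
    v = np.zeros(5)
    v[HealthState.N] = 1.0 - prev
    for s, frac in split.items():
        v[HealthState[s]] = prev * frac
    return v


@dataclass
class CohortTrace:
    """State occupancy over time plus per-cycle new entrants per state.

    ``occupancy[t]`` is the distribution at time point ``t`` (0 … n_cycles);
    ``entrants[c - 1, s]`` is the fraction newly transitioning into state
    ``s`` from any *other* state during cycle ``c`` (attributed to the end
    of the cycle).  Initial occupants at t = 0 are not entrants.
    """

    occupancy: np.ndarray  # (n_cycles + 1, n_states)
    entrants: np.ndarray  # (n_cycles, n_states)

    @property
    def n_cycles(self) -> int:
        return self.entrants.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: time_point, state, occupancy, entrants."""
        n_t, n_s = self.occupancy.shape
        names = STATE_ORDER if n_s == 5 else [f"S{i}" for i in range(n_s)]
        rows = []
        for t in range(n_t):
            for s in range(n_s):
                rows.append(
                    {
                        "time_point": t,
                        "state": names[s],
                        "occupancy": self.occupancy[t, s],
                        "entrants": self.entrants[t - 1, s] if t >= 1 else 0.0,
                    }
                )
        return pd.DataFrame(rows)


def run_cohort(
    matrix: TransitionMatrix | np.ndarray, start: np.ndarray, n_cycles: int
) -> CohortTrace:
    """Deterministic cohort trace: occupancy(t) = start · P^t.

    Accepts any square row-stochastic matrix (miniature test chains
    included), not just the 5-state model matrix.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be at least 1")
    P = matrix.probs if isinstance(matrix, TransitionMatrix) else np.asarray(matrix, float)
    start = np.asarray(start, dtype=float)
    occ = np.empty((n_cycles + 1, P.shape[0]))
    ent = np.empty((n_cycles, P.shape[0]))
    off_diag = P - np.diag(np.diag(P))
    occ[0] = start
    for c in range(1, n_cycles + 1):
        ent[c - 1] = occ[c - 1] @ off_diag
        occ[c] = occ[c - 1] @ P
    return CohortTrace(occupancy=occ, entrants=ent)


@dataclass
class QuasiStationaryResult:
    """Long-run distribution conditional on being alive."""

    distribution: np.ndarray  # over living states, sums to 1
    iterations: int
    converged: bool


def quasi_stationary_distribution(
    matrix: TransitionMatrix | np.ndarray,
    max_cycles: int = 3000,
    tol: float = 1e-12,
    living: slice | None = None,
) -> QuasiStationaryResult:
    """Iterate the chain, renormalising mass among living states each cycle.

    With an absorbing death state the unconditioned chain drains to
    all-dead, so the long-run state of interest is the distribution
    conditional on being alive.  Iteration stops when the maximum absolute
    change falls below ``tol`` or after ``max_cycles`` (the convergence flag
    records which).  ``living`` defaults to all states but the last.
    """
    if max_cycles < 1:
        raise ValueError("max_cycles must be at least 1")
    P = matrix.probs if isinstance(matrix, TransitionMatrix) else np.asarray(matrix, float)
    if living is None:
        living = slice(0, P.shape[0] - 1)
    Q = P[living, living]  # sub-stochastic living-to-living block
    v = np.full(Q.shape[0], 1.0 / Q.shape[0])
    converged = False
    it = 0
    for it in range(1, max_cycles + 1):
        nxt = v @ Q
        s = nxt.sum()
        if s <= 0.0:
            raise ValueError("no mass remains among living states")
        nxt /= s
        if np.max(np.abs(nxt - v)) < tol:
            v = nxt
            converged = True
            break
        v = nxt
    return QuasiStationaryResult(distribution=v, iterations=it, converged=converged)
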