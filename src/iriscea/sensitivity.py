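"""One-way and probabilistic sensitivity analysis.

Distribution fitting is by method of moments from the tabulated base value
(taken as the mean) and 95% limits (span / 3.92 taken as the standard
deviation).  Transition-row members are sampled individually and each row
is re-closed through the stay complement; a ``true_dirichlet`` mode instead
draws whole rows from a Dirichlet whose concentration is least-squares
fitted to the per-member limits.

By default, transition probabilities whose uncertainty specification is
identical in both arms (natural recovery, mortality — the arms differ only
in identification rates) are treated as arm-invariant quantities and
receive a single draw per simulation; ``psa_independent_arms=True`` draws
every tabulated row independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .economics import run_arm, run_base_case
from .engine import ConstructionError
from .parameters import (
    LIVING_STATES,
    DistributionSpec,
    ParameterSet,
    path_name,
    set_value,
)

__all__ = [
    "TornadoEntry",
    "PsaResult",
    "FittedDistribution",
    "fit_distribution",
    "sample_parameter_set",
    "owsa",
    "run_psa",
    "ceac",
    "percentile_interval",
    "shrink_uncertainty",
]

DEFAULT_WTP_GRID = tuple(range(0, 50_001, 1000))


# --------------------------------------------------------------------------
# Distribution fitting
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FittedDistribution:
    """Sampler parameters for one input distribution."""

    family: str
    args: tuple[float, ...]

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "fixed":
            return self.args[0]
        if self.family == "beta":
            return float(rng.beta(*self.args))
        if self.family == "gamma":
            shape, scale = self.args
            return float(rng.gamma(shape, scale))
        if self.family == "uniform":
            return float(rng.uniform(*self.args))
        raise ValueError(f"cannot sample family {self.family!r}")

    @property
    def mean(self) -> float:
        if self.family == "fixed":
            return self.args[0]
        if self.family == "beta":
            a, b = self.args
            return a / (a + b)
        if self.family == "gamma":
            shape, scale = self.args
            return shape * scale
        if self.family == "uniform":
            lo, hi = self.args
            return 0.5 * (lo + hi)
        raise ValueError(self.family)


def _moments(spec: DistributionSpec) -> tuple[float, float]:
    return spec.base, (spec.high - spec.low) / 3.92


def fit_distribution(spec: DistributionSpec, name: str = "parameter") -> FittedDistribution:
    """Method-of-moments fit of a sampling distribution to a spec.

    Beta (and Dirichlet row members in independent-beta mode) match mean
    and sd on [0, 1]; gamma matches mean and sd on [0, ∞); uniform uses the
    limits directly; fixed or zero-width specs are point masses.
    """
    if spec.degenerate:
        return FittedDistribution("fixed", (spec.base,))
    family = "beta" if spec.family == "dirichlet_row_member" else spec.family
    if family == "uniform":
        return FittedDistribution("uniform", (spec.low, spec.high))
    mean, sd = _moments(spec)
    var = sd * sd
    if family == "beta":
        if var >= mean * (1.0 - mean):
            raise ValueError(
                f"{name}: limits imply sd {sd:.4g} infeasible for a beta with mean {mean:.4g}"
            )
        nu = mean * (1.0 - mean) / var - 1.0
        return FittedDistribution("beta", (mean * nu, (1.0 - mean) * nu))
    if family == "gamma":
        if mean <= 0:
            raise ValueError(f"{name}: gamma mean must be positive")
        return FittedDistribution("gamma", (mean * mean / var, var / mean))
    raise ValueError(f"{name}: cannot fit family {spec.family!r}")


def _dirichlet_concentration(specs: list[DistributionSpec]) -> float:
    """Least-squares fit of a single row concentration to per-member limits.

    For a Dirichlet with concentration a0 the member variance is
    m(1-m)/(a0+1); solve min_x sum_j (v_j * x - s_j^2)^2 over x = 1/(a0+1)
    with v_j = m_j (1 - m_j).
    """
    v = np.array([s.base * (1.0 - s.base) for s in specs])
    s2 = np.array([_moments(s)[1] ** 2 for s in specs])
    x = float(np.dot(v, s2) / np.dot(v, v))
    return max(1.0 / x - 1.0, 1.0)


# --------------------------------------------------------------------------
# Joint sampling
# --------------------------------------------------------------------------


def _shared_key(params: ParameterSet, path: tuple[str, ...]) -> tuple[str, ...]:
    """Collapse an exit path to an arm-invariant key when both arms carry an
    identical spec for the same transition and sharing is enabled."""
    if params.psa_independent_arms or path[0] != "exits":
        return path
    _, arm, state, target = path
    other = "intervention" if arm == "control" else "control"
    if params.exits[other][state].get(target) == params.exits[arm][state][target]:
        return ("exits", "shared", state, target)
    return path


def sample_parameter_set(
    params: ParameterSet, rng: np.random.Generator
) -> tuple[ParameterSet, list[str]]:
    """One joint draw of all uncertain inputs.

    Returns the drawn :class:`ParameterSet` (which passes validation) plus
    an audit list of the repairs applied: any transition row whose drawn
    exits sum to 1 or more is rescaled to 0.999 of their sum, and the
    starting split's U member is re-closed as the complement of A and I.
    """
    draw = params.copy()
    audit: list[str] = []
    cache: dict[tuple[str, ...], float] = {}

    dirichlet_rows: dict[tuple[str, str], float] = {}
    if params.dirichlet_mode == "true_dirichlet":
        for arm in ("control", "intervention"):
            for state in LIVING_STATES:
                specs = list(params.exits[arm][state].values())
                if all(s.degenerate for s in specs):
                    continue
                dirichlet_rows[(arm, state)] = _dirichlet_concentration(specs)

    if dirichlet_rows:
        row_cache: dict[tuple[str, ...], dict[str, float]] = {}
        for (arm, state), a0 in dirichlet_rows.items():
            targets = list(params.exits[arm][state])
            bases = [params.exits[arm][state][t].base for t in targets]
            stay = 1.0 - sum(bases)
            key_parts = tuple(
                _shared_key(params, ("exits", arm, state, t)) for t in targets
            )
            key = ("row",) + key_parts[0][:2] + (state,)
            if all(k[1] == "shared" for k in key_parts):
                key = ("row", "shared", state)
            if key not in row_cache:
                alpha = np.array(bases + [stay]) * a0
                sampled = rng.dirichlet(alpha)
                row_cache[key] = dict(zip(targets, sampled[:-1]))
            for t, v in row_cache[key].items():
                set_value(draw, ("exits", arm, state, t), float(v))

    for path, spec in params.iter_uncertain():
        if path[0] == "exits" and dirichlet_rows:
            continue
        key = _shared_key(params, path)
        if key not in cache:
            cache[key] = fit_distribution(spec, path_name(path)).sample(rng)
        set_value(draw, path, cache[key])

    # re-close the starting split: U is the complement of the drawn A and I
    a = draw.start_split_abused["A"].base
    i = draw.start_split_abused["I"].base
    if a + i >= 1.0:
        f = 0.999 / (a + i)
        a, i = a * f, i * f
        audit.append(f"start_split_abused rescaled by {f:.6g}")
        set_value(draw, ("start_split_abused", "A"), a)
        set_value(draw, ("start_split_abused", "I"), i)
    draw.start_split_abused["U"] = DistributionSpec.fixed(1.0 - a - i)

    # repair any row whose drawn exits leave no positive stay complement
    for arm in ("control", "intervention"):
        for state in LIVING_STATES:
            row = draw.exit_probs(arm, state)
            total = sum(row.values())
            if total >= 1.0:
                f = 0.999 / total
                for t, v in row.items():
                    set_value(draw, ("exits", arm, state, t), v * f)
                audit.append(f"exits.{arm}.{state} rescaled by {f:.6g}")
    return draw, audit


# --------------------------------------------------------------------------
# One-way sensitivity analysis (tornado)
# --------------------------------------------------------------------------


@dataclass
class TornadoEntry:
    parameter: str
    low: float
    high: float
    nmb_at_low: float
    nmb_at_high: float
    feasible: bool = True

    @property
    def span(self) -> float:
        return abs(self.nmb_at_high - self.nmb_at_low)


def _nmb_with(
    params: ParameterSet, paths: list[tuple[str, ...]], value: float, wtp: float
) -> tuple[float, bool]:
    trial = params.copy()
    for path in paths:
        set_value(trial, path, value)
    problems = trial.validate()
    if problems:
        return math.nan, False
    try:
        res = run_base_case(trial, "societal")
    except ConstructionError:
        return math.nan, False
    return wtp * res.incremental_qaly - res.incremental_cost, True


def _owsa_items(
    params: ParameterSet,
) -> list[tuple[str, list[tuple[str, ...]], DistributionSpec]]:
    """Variation items mirroring the printed layout of the input table:
    rows printed once (N, A, I exits, when identical in both arms) are
    varied in both arms simultaneously; the U row, printed per arm, is
    varied per arm; everything else is a single slot."""
    items = []
    seen: set[tuple[str, ...]] = set()
    for path, spec in params.iter_uncertain():
        if path in seen:
            continue
        if path[0] == "exits":
            _, arm, state, target = path
            other = "intervention" if arm == "control" else "control"
            if state != "U" and params.exits[other][state].get(target) == spec:
                other_path = ("exits", other, state, target)
                seen.add(other_path)
                items.append((f"exits.{state}.{target}", [path, other_path], spec))
                continue
        items.append((path_name(path), [path], spec))
    return items


def owsa(
    params: ParameterSet,
    wtp: float | None = None,
    overrides: dict[str, tuple[float, float]] | None = None,
) -> list[TornadoEntry]:
    """Tornado analysis: the societal net monetary benefit with each
    uncertain parameter at its lower and upper limit, all else at base.

    ``overrides`` maps parameter names (dotted paths) to an explicit
    (low, high) range replacing the tabulated limits.  A limit that makes a
    transition row infeasible is flagged, not clamped.  Entries are sorted
    by span, largest first.
    """
    wtp = params.wtp if wtp is None else wtp
    overrides = overrides or {}
    entries = []
    for name, paths, spec in _owsa_items(params):
        lo, hi = overrides.get(name, (spec.low, spec.high))
        if name not in overrides and spec.degenerate:
            continue
        nmb_lo, ok_lo = _nmb_with(params, paths, lo, wtp)
        nmb_hi, ok_hi = _nmb_with(params, paths, hi, wtp)
        entries.append(
            TornadoEntry(
                parameter=name,
                low=lo,
                high=hi,
                nmb_at_low=nmb_lo,
                nmb_at_high=nmb_hi,
                feasible=ok_lo and ok_hi,
            )
        )
    entries.sort(key=lambda e: (math.isnan(e.span), -e.span if not math.isnan(e.span) else 0.0))
    return entries


# --------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# --------------------------------------------------------------------------


@dataclass
class PsaResult:
    """Per-simulation incremental results with derived summaries."""

    incremental_cost: np.ndarray
    incremental_qaly: np.ndarray
    seed: int
    wtp: float
    wtp_grid: tuple[float, ...]
    n_repaired: int = 0

    @property
    def n_sim(self) -> int:
        return self.incremental_cost.size

    def nmb(self, wtp: float | None = None) -> np.ndarray:
        wtp = self.wtp if wtp is None else wtp
        return wtp * self.incremental_qaly - self.incremental_cost

    @property
    def fraction_dominant(self) -> float:
        """Intervention cheaper and more effective."""
        return float(
            np.mean((self.incremental_cost < 0) & (self.incremental_qaly > 0))
        )

    @property
    def fraction_dominated(self) -> float:
        """Intervention costlier and less effective."""
        return float(
            np.mean((self.incremental_cost > 0) & (self.incremental_qaly < 0))
        )

    def fraction_cost_effective(self, wtp: float | None = None) -> float:
        return float(np.mean(self.nmb(wtp) > 0))

    def percentile_intervals(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        return {
            "incremental_cost": percentile_interval(self.incremental_cost, level),
            "incremental_qaly": percentile_interval(self.incremental_qaly, level),
            "nmb": percentile_interval(self.nmb(), level),
        }

    @property
    def ceac_curve(self) -> list[tuple[float, float]]:
        return ceac(self, self.wtp_grid)


def run_psa(
    params: ParameterSet,
    n_sim: int | None = None,
    seed: int | None = None,
    wtp_grid: tuple[float, ...] = DEFAULT_WTP_GRID,
) -> PsaResult:
    """Monte Carlo propagation of joint parameter uncertainty.

    Each simulation draws one parameter set, runs both arms under the
    societal perspective and records the incremental cost and QALYs.  Fully
    reproducible from (params, n_sim, seed).
    """
    n_sim = params.n_psa if n_sim is None else n_sim
    if n_sim < 1:
        raise ValueError("n_sim must be at least 1")
    seed = params.rng_seed if seed is None else seed
    rng = np.random.default_rng(seed)
    d_cost = np.empty(n_sim)
    d_qaly = np.empty(n_sim)
    n_repaired = 0
    for k in range(n_sim):
        draw, audit = sample_parameter_set(params, rng)
        n_repaired += bool(audit)
        c_cost, c_qaly = run_arm(draw, "control", "societal")
        i_cost, i_qaly = run_arm(draw, "intervention", "societal")
        d_cost[k] = i_cost - c_cost
        d_qaly[k] = i_qaly - c_qaly
    return PsaResult(
        incremental_cost=d_cost,
        incremental_qaly=d_qaly,
        seed=seed,
        wtp=params.wtp,
        wtp_grid=tuple(wtp_grid),
        n_repaired=n_repaired,
    )


def ceac(psa: PsaResult, wtp_grid) -> list[tuple[float, float]]:
    """Cost-effectiveness acceptability curve: for each willingness to pay,
    the fraction of simulations with positive net monetary benefit."""
    grid = list(wtp_grid)
    if not grid or any(w < 0 for w in grid):
        raise ValueError("wtp grid must be non-empty and non-negative")
    return [(float(w), psa.fraction_cost_effective(w)) for w in grid]


def percentile_interval(samples, level: float = 0.95) -> tuple[float, float]:
    """Empirical central interval by the linear-interpolation convention
    (numpy default): for samples 1..1000 at 95% this is (25.975, 975.025)."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 samples")
    alpha = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(samples, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


def shrink_uncertainty(params: ParameterSet, factor: float) -> ParameterSet:
    """Scale every parameter's limits towards its base by ``factor``
    (0 collapses all distributions to point masses); used to check that the
    probabilistic analysis degenerates to the base case."""
    out = params.copy()
    for path, spec in params.iter_uncertain():
        new = DistributionSpec(
            spec.family,
            spec.base,
            spec.base - factor * (spec.base - spec.low),
            spec.base + factor * (spec.high - spec.base),
        )
        if len(path) == 1:
            setattr(out, path[0], new)
        else:
            obj = getattr(out, path[0])
            for key in path[1:-1]:
                obj = obj[key]
            obj[path[-1]] = new
    return out
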