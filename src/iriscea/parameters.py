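"""Parameter schema for the IRIS cost-utility model.

Every model input — transition probabilities, utilities, costs, run
settings — is carried by a :class:`ParameterSet`.  Each uncertain input is a
:class:`DistributionSpec` holding its base-case value together with the
family and 95% limits used by the sensitivity analyses.  "Stay" probabilities
are never stored: the engine always closes each transition row with the
complement of its exits.

The pooled national base case ships as :func:`default_iris_parameters`.
The published parameter table prints, for the abused-but-not-identified row,
stay probabilities (0.9444 control, 0.9419 intervention) that disagree with
the complement of its printed exit probabilities (0.94126, 0.92796).  The
``stay_mode`` argument selects how that row is read; see the methods note
for the numerical evidence behind the default.
"""

from __future__ import annotations

import copy
import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import yaml

__all__ = [
    "DistributionSpec",
    "ParameterSet",
    "SchemaError",
    "ValidationError",
    "default_iris_parameters",
    "load_parameters",
    "save_parameters",
    "validate",
    "export_parameter_csv",
    "intervention_unit_cost",
    "STAY_MODES",
    "LIVING_STATES",
    "ALLOWED_EXITS",
]

#: Living health states in canonical order; "D" (dead) is appended by the engine.
LIVING_STATES = ("N", "U", "A", "I")

#: Structural transition graph: per living state, the allowed exit targets.
#: Identified women (A, I) can only recover or die; the not-abused can only
#: become abused-unidentified or die.
ALLOWED_EXITS = {
    "N": ("U", "D"),
    "U": ("N", "A", "I", "D"),
    "A": ("N", "D"),
    "I": ("N", "D"),
}

STAY_MODES = ("printed_stay", "complement", "printed_renormalized")
ACCRUAL_MODES = ("cycle_start", "trapezoid")
DIRICHLET_MODES = ("independent_beta", "true_dirichlet")

DISTRIBUTION_FAMILIES = ("beta", "gamma", "dirichlet_row_member", "uniform", "fixed")


class SchemaError(KeyError):
    """A required field is missing from a parameter file."""


class ValidationError(ValueError):
    """A parameter file violates an invariant of the schema."""


@dataclass(frozen=True)
class DistributionSpec:
    """An uncertain scalar input: base-case value, family and 95% limits."""

    family: str
    base: float
    low: float
    high: float

    @classmethod
    def fixed(cls, value: float) -> "DistributionSpec":
        return cls("fixed", value, value, value)

    @property
    def degenerate(self) -> bool:
        return self.family == "fixed" or self.low == self.high

    def scaled(self, factor: float) -> "DistributionSpec":
        """Rescale base and both limits by ``factor`` (same family)."""
        return DistributionSpec(
            self.family, self.base * factor, self.low * factor, self.high * factor
        )

    def violations(self, name: str) -> list[str]:
        out = []
        if self.family not in DISTRIBUTION_FAMILIES:
            out.append(f"{name}: unknown distribution family {self.family!r}")
            return out
        if not (self.low <= self.base <= self.high):
            out.append(
                f"{name}: limits must satisfy low <= base <= high "
                f"(got {self.low} <= {self.base} <= {self.high})"
            )
        if self.family == "fixed" and not (self.low == self.base == self.high):
            out.append(f"{name}: fixed family requires low = base = high")
        if self.family in ("beta", "dirichlet_row_member") and not (
            0.0 <= self.low and self.high <= 1.0
        ):
            out.append(f"{name}: beta limits must lie in [0, 1]")
        if self.family == "gamma" and self.low < 0.0:
            out.append(f"{name}: gamma lower limit must be non-negative")
        return out


# --------------------------------------------------------------------------
# Printed pooled-national parameter table (2015/16 GBP), kept verbatim so the
# fixture can be regression-tested digit for digit and exported for audit.
# Transition rows: (base, low, high, family); stays are listed separately.
# --------------------------------------------------------------------------

TABLE_PREVALENCE = ("beta", 0.17, 0.147, 0.194)

TABLE_START_SPLIT = {
    "A": ("uniform", 0.003, 0.0, 0.0066),
    "I": ("uniform", 0.033, 0.0, 0.0660),
    "U": 0.964,  # complement
}

# Arm-invariant rows are printed once; the U row is printed per arm.
TABLE_EXITS = {
    "control": {
        "N": {"U": (0.0037, 0.0004, 0.0106), "D": (0.00551, 0.0010, 0.0136)},
        "U": {
            "N": (0.0500, 0.0450, 0.0553),
            "A": (0.0005, 0.0001, 0.0011),
            "I": (0.0027, 0.0016, 0.0040),
            "D": (0.00554, 0.0039, 0.0074),
        },
        "A": {"N": (0.1408, 0.0707, 0.2301), "D": (0.00554, 0.0000, 0.0309)},
        "I": {"N": (0.0781, 0.0136, 0.1912), "D": (0.00554, 0.0000, 0.0438)},
    },
    "intervention": {
        "N": {"U": (0.0037, 0.0004, 0.0106), "D": (0.00551, 0.0010, 0.0136)},
        "U": {
            "N": (0.0500, 0.0450, 0.0553),
            "A": (0.0056, 0.0040, 0.0076),
            "I": (0.0109, 0.0086, 0.0135),
            "D": (0.00554, 0.0039, 0.0074),
        },
        "A": {"N": (0.1408, 0.0707, 0.2301), "D": (0.00554, 0.0000, 0.0309)},
        "I": {"N": (0.0781, 0.0136, 0.1912), "D": (0.00554, 0.0000, 0.0438)},
    },
}

#: Printed per-cycle stay probabilities for the U row, inconsistent with the
#: complement of the printed exits above (0.94126 / 0.92796).
TABLE_STAY_U = {"control": 0.9444, "intervention": 0.9419}

TABLE_UTILITIES = {
    "N": ("beta", 0.85, 0.840, 0.860),
    "U": ("beta", 0.63, 0.503, 0.749),
    "A": ("beta", 0.65, 0.518, 0.771),
    "I": ("beta", 0.63, 0.503, 0.749),
}

TABLE_COSTS = {
    "intervention_per_woman_cycle": ("gamma", 0.46, 0.01, 1.69),
    "referral_once": ("gamma", 312.0, 8.0, 1127.0),
    "abuse_per_cycle": ("gamma", 2043.0, 52.0, 7536.0),
    "weight_seeing": ("gamma", 1.0, 0.75, 1.25),
    "weight_not_seeing": ("gamma", 1.0, 0.90, 1.10),
}

#: Programme budget per 6 months across the six sites, and the number of
#: registered women aged 16+ it covers.  Their ratio is the per-cycle
#: intervention cost.
INTERVENTION_BUDGET_6M = 272_613.0
REGISTERED_WOMEN = 595_902

#: NHS share of the per-cycle abuse cost.  Not printed anywhere; back-derived
#: in closed form from the published control-arm NHS-perspective total (£1232)
#: via economics.derive_nhs_cost_share and frozen here.  Override in config
#: for alternative NHS costings.
DEFAULT_NHS_COST_SHARE = 0.27807


def intervention_unit_cost(
    budget: float = INTERVENTION_BUDGET_6M, n_women: int = REGISTERED_WOMEN
) -> float:
    """Per-woman per-6-months programme cost, rounded to the penny."""
    return round(budget / n_women, 2)


@dataclass
class ParameterSet:
    """All inputs of the cost-utility model, with uncertainty specifications.

    Transition probabilities are stored as exit probabilities only; the
    per-cycle "stay" probability of every living state is always the
    complement of its exits.
    """

    prevalence: DistributionSpec
    start_split_abused: dict[str, DistributionSpec]  # keys U, A, I
    exits: dict[str, dict[str, dict[str, DistributionSpec]]]  # arm -> state -> target
    utilities: dict[str, DistributionSpec]  # keys N, U, A, I
    cost_abuse_per_cycle: DistributionSpec
    cost_weight_seeing: DistributionSpec
    cost_weight_not_seeing: DistributionSpec
    cost_intervention_per_woman_cycle: DistributionSpec
    cost_referral_once: DistributionSpec
    nhs_cost_share: float = DEFAULT_NHS_COST_SHARE
    discount_rate_annual: float = 0.035
    cycle_length_years: float = 0.5
    n_cycles: int = 20
    wtp: float = 20_000.0
    cohort_size: int = 10_000
    n_psa: int = 1000
    rng_seed: int = 20180829
    # run-configuration toggles
    stay_mode: str = "printed_stay"
    accrual: str = "cycle_start"
    charge_initial_advocates: bool = False
    dirichlet_mode: str = "independent_beta"
    psa_independent_arms: bool = False

    # -- convenience accessors -------------------------------------------

    def exit_probs(self, arm: str, state: str) -> dict[str, float]:
        return {t: s.base for t, s in self.exits[arm][state].items()}

    def stay_prob(self, arm: str, state: str) -> float:
        return 1.0 - sum(self.exit_probs(arm, state).values())

    def utility_values(self) -> dict[str, float]:
        return {s: spec.base for s, spec in self.utilities.items()}

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def validate(self) -> list[str]:
        return validate(self)

    # -- uncertain-parameter traversal -----------------------------------

    def iter_uncertain(self) -> Iterator[tuple[tuple[str, ...], DistributionSpec]]:
        """Yield (path, spec) for every input carrying a distribution.

        Paths address the storage slots used by :func:`get_spec` /
        :func:`set_value`; the U member of the starting split is derived and
        never yielded.
        """
        yield ("prevalence",), self.prevalence
        for s in ("A", "I"):
            yield ("start_split_abused", s), self.start_split_abused[s]
        for arm in ("control", "intervention"):
            for state in LIVING_STATES:
                for target in ALLOWED_EXITS[state]:
                    yield ("exits", arm, state, target), self.exits[arm][state][target]
        for s in LIVING_STATES:
            yield ("utilities", s), self.utilities[s]
        yield ("cost_abuse_per_cycle",), self.cost_abuse_per_cycle
        yield ("cost_weight_seeing",), self.cost_weight_seeing
        yield ("cost_weight_not_seeing",), self.cost_weight_not_seeing
        yield (
            "cost_intervention_per_woman_cycle",
        ), self.cost_intervention_per_woman_cycle
        yield ("cost_referral_once",), self.cost_referral_once


def get_spec(params: ParameterSet, path: tuple[str, ...]) -> DistributionSpec:
    obj = getattr(params, path[0])
    for key in path[1:]:
        obj = obj[key]
    return obj


def set_value(params: ParameterSet, path: tuple[str, ...], value: float) -> None:
    """Replace the base value at ``path`` in place (limits follow the value)."""
    spec = get_spec(params, path)
    new = DistributionSpec(spec.family, value, min(spec.low, value), max(spec.high, value))
    if len(path) == 1:
        setattr(params, path[0], new)
    else:
        obj = getattr(params, path[0])
        for key in path[1:-1]:
            obj = obj[key]
        obj[path[-1]] = new


def path_name(path: tuple[str, ...]) -> str:
    return ".".join(path)


# --------------------------------------------------------------------------
# Fixture construction
# --------------------------------------------------------------------------


def _u_row_for_mode(arm: str, mode: str) -> dict[str, DistributionSpec]:
    """Effective U-row exit specs for a stay-mode reading of the table.

    ``complement``             — printed exits verbatim; stay is their
                                 complement (0.94126 / 0.92796).
    ``printed_stay``           — printed stay, U→N and U→D authoritative; the
                                 identification exits are rescaled so the row
                                 closes exactly on the printed stay.  Limits
                                 are rescaled with the base, preserving the
                                 printed coefficient of variation.
    ``printed_renormalized``   — printed stay and printed exits, whole row
                                 divided by its sum.
    """
    printed = TABLE_EXITS[arm]["U"]
    if mode == "complement":
        return {
            t: DistributionSpec("dirichlet_row_member", *printed[t]) for t in printed
        }
    stay = TABLE_STAY_U[arm]
    if mode == "printed_stay":
        id_residual = 1.0 - stay - printed["N"][0] - printed["D"][0]
        if id_residual < 0:
            raise ValidationError(
                f"{arm} U row: printed stay leaves a negative identification residual"
            )
        factor = id_residual / (printed["A"][0] + printed["I"][0])
        row = {}
        for t in printed:
            spec = DistributionSpec("dirichlet_row_member", *printed[t])
            row[t] = spec.scaled(factor) if t in ("A", "I") else spec
        return row
    if mode == "printed_renormalized":
        total = stay + sum(v[0] for v in printed.values())
        return {
            t: DistributionSpec("dirichlet_row_member", *printed[t]).scaled(1.0 / total)
            for t in printed
        }
    raise ValueError(f"unknown stay_mode {mode!r}; expected one of {STAY_MODES}")


def default_iris_parameters(stay_mode: str = "printed_stay") -> ParameterSet:
    """The pooled national base case, straight from the published table."""
    exits: dict[str, dict[str, dict[str, DistributionSpec]]] = {}
    for arm in ("control", "intervention"):
        exits[arm] = {}
        for state in LIVING_STATES:
            if state == "U":
                exits[arm][state] = _u_row_for_mode(arm, stay_mode)
            else:
                exits[arm][state] = {
                    t: DistributionSpec("dirichlet_row_member", *vals)
                    for t, vals in TABLE_EXITS[arm][state].items()
                }
    start = {
        "A": DistributionSpec(*TABLE_START_SPLIT["A"]),
        "I": DistributionSpec(*TABLE_START_SPLIT["I"]),
        "U": DistributionSpec.fixed(TABLE_START_SPLIT["U"]),
    }
    costs = {k: DistributionSpec(*v) for k, v in TABLE_COSTS.items()}
    return ParameterSet(
        prevalence=DistributionSpec(*TABLE_PREVALENCE),
        start_split_abused=start,
        exits=exits,
        utilities={s: DistributionSpec(*v) for s, v in TABLE_UTILITIES.items()},
        cost_abuse_per_cycle=costs["abuse_per_cycle"],
        cost_weight_seeing=costs["weight_seeing"],
        cost_weight_not_seeing=costs["weight_not_seeing"],
        cost_intervention_per_woman_cycle=costs["intervention_per_woman_cycle"],
        cost_referral_once=costs["referral_once"],
        stay_mode=stay_mode,
    )


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------


def validate(params: ParameterSet) -> list[str]:
    """Return a list of invariant violations (empty iff the set is valid)."""
    out: list[str] = []
    for path, spec in params.iter_uncertain():
        out.extend(spec.violations(path_name(path)))

    def _prob(name: str, v: float) -> None:
        if not (0.0 <= v <= 1.0):
            out.append(f"{name}: probability {v} outside [0, 1]")

    _prob("prevalence", params.prevalence.base)
    split = {s: params.start_split_abused[s].base for s in ("U", "A", "I")}
    for s, v in split.items():
        _prob(f"start_split_abused.{s}", v)
    if abs(sum(split.values()) - 1.0) > 1e-9:
        out.append(
            f"start_split_abused: U + A + I = {sum(split.values())!r} must sum to 1"
        )
    for arm in ("control", "intervention"):
        for state in LIVING_STATES:
            row = params.exit_probs(arm, state)
            for t, v in row.items():
                _prob(f"exits.{arm}.{state}.{t}", v)
            if sum(row.values()) >= 1.0:
                out.append(
                    f"exits.{arm}.{state}: exit probabilities sum to "
                    f"{sum(row.values()):.6g} >= 1; the stay complement must be positive"
                )
            extra = set(row) - set(ALLOWED_EXITS[state])
            if extra:
                out.append(f"exits.{arm}.{state}: disallowed transitions {sorted(extra)}")
    for s, spec in params.utilities.items():
        if not (0.0 <= spec.base <= 1.0):
            out.append(f"utilities.{s}: utility {spec.base} outside [0, 1]")
    for name in (
        "cost_abuse_per_cycle",
        "cost_weight_seeing",
        "cost_weight_not_seeing",
        "cost_intervention_per_woman_cycle",
        "cost_referral_once",
    ):
        if getattr(params, name).base < 0:
            out.append(f"{name}: cost must be non-negative")
    if not (0.0 <= params.nhs_cost_share <= 1.0):
        out.append("nhs_cost_share: must lie in [0, 1]")
    if params.discount_rate_annual < 0:
        out.append("discount_rate_annual: must be non-negative")
    if params.cycle_length_years <= 0:
        out.append("cycle_length_years: must be positive")
    if params.n_cycles < 1:
        out.append("n_cycles: must be at least 1")
    if params.stay_mode not in STAY_MODES:
        out.append(f"stay_mode: {params.stay_mode!r} not one of {STAY_MODES}")
    if params.accrual not in ACCRUAL_MODES:
        out.append(f"accrual: {params.accrual!r} not one of {ACCRUAL_MODES}")
    if params.dirichlet_mode not in DIRICHLET_MODES:
        out.append(f"dirichlet_mode: {params.dirichlet_mode!r} not one of {DIRICHLET_MODES}")
    return out


# --------------------------------------------------------------------------
# Serialisation: flat, human-readable YAML
# --------------------------------------------------------------------------

_SPEC_FIELDS = ("family", "base", "low", "high")
_SCALAR_FIELDS = (
    "nhs_cost_share",
    "discount_rate_annual",
    "cycle_length_years",
    "n_cycles",
    "wtp",
    "cohort_size",
    "n_psa",
    "rng_seed",
    "stay_mode",
    "accrual",
    "charge_initial_advocates",
    "dirichlet_mode",
    "psa_independent_arms",
)
_REQUIRED = (
    "prevalence",
    "start_split_abused",
    "exits",
    "utilities",
    "cost_abuse_per_cycle",
    "cost_weight_seeing",
    "cost_weight_not_seeing",
    "cost_intervention_per_woman_cycle",
    "cost_referral_once",
)


def _spec_to_dict(spec: DistributionSpec) -> dict:
    return {f: getattr(spec, f) for f in _SPEC_FIELDS}


def _spec_from_dict(d: dict, name: str) -> DistributionSpec:
    try:
        return DistributionSpec(
            str(d["family"]), float(d["base"]), float(d["low"]), float(d["high"])
        )
    except KeyError as exc:
        raise SchemaError(f"{name}: missing field {exc.args[0]!r}") from None


def parameters_to_dict(params: ParameterSet) -> dict:
    d: dict = {
        "prevalence": _spec_to_dict(params.prevalence),
        "start_split_abused": {
            s: _spec_to_dict(params.start_split_abused[s]) for s in ("U", "A", "I")
        },
        "exits": {
            arm: {
                state: {t: _spec_to_dict(s) for t, s in row.items()}
                for state, row in params.exits[arm].items()
            }
            for arm in ("control", "intervention")
        },
        "utilities": {s: _spec_to_dict(v) for s, v in params.utilities.items()},
        "cost_abuse_per_cycle": _spec_to_dict(params.cost_abuse_per_cycle),
        "cost_weight_seeing": _spec_to_dict(params.cost_weight_seeing),
        "cost_weight_not_seeing": _spec_to_dict(params.cost_weight_not_seeing),
        "cost_intervention_per_woman_cycle": _spec_to_dict(
            params.cost_intervention_per_woman_cycle
        ),
        "cost_referral_once": _spec_to_dict(params.cost_referral_once),
    }
    for f in _SCALAR_FIELDS:
        d[f] = getattr(params, f)
    return d


def parameters_from_dict(d: dict) -> ParameterSet:
    for f in _REQUIRED:
        if f not in d:
            raise SchemaError(f"missing required field {f!r}")
    defaults = default_iris_parameters()
    exits = {}
    for arm in ("control", "intervention"):
        if arm not in d["exits"]:
            raise SchemaError(f"exits: missing arm {arm!r}")
        exits[arm] = {}
        for state in LIVING_STATES:
            if state not in d["exits"][arm]:
                raise SchemaError(f"exits.{arm}: missing state {state!r}")
            exits[arm][state] = {
                t: _spec_from_dict(v, f"exits.{arm}.{state}.{t}")
                for t, v in d["exits"][arm][state].items()
            }
    start = {
        s: _spec_from_dict(d["start_split_abused"][s], f"start_split_abused.{s}")
        for s in d["start_split_abused"]
    }
    if set(start) != {"U", "A", "I"}:
        raise SchemaError("start_split_abused: must provide exactly U, A and I")
    kwargs = dict(
        prevalence=_spec_from_dict(d["prevalence"], "prevalence"),
        start_split_abused=start,
        exits=exits,
        utilities={
            s: _spec_from_dict(d["utilities"][s], f"utilities.{s}")
            for s in d["utilities"]
        },
        cost_abuse_per_cycle=_spec_from_dict(
            d["cost_abuse_per_cycle"], "cost_abuse_per_cycle"
        ),
        cost_weight_seeing=_spec_from_dict(d["cost_weight_seeing"], "cost_weight_seeing"),
        cost_weight_not_seeing=_spec_from_dict(
            d["cost_weight_not_seeing"], "cost_weight_not_seeing"
        ),
        cost_intervention_per_woman_cycle=_spec_from_dict(
            d["cost_intervention_per_woman_cycle"], "cost_intervention_per_woman_cycle"
        ),
        cost_referral_once=_spec_from_dict(d["cost_referral_once"], "cost_referral_once"),
    )
    for f in _SCALAR_FIELDS:
        kwargs[f] = d.get(f, getattr(defaults, f))
    return ParameterSet(**kwargs)


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(parameters_to_dict(params), sort_keys=False), encoding="utf-8"
    )


def load_parameters(path: str | Path) -> ParameterSet:
    """Read a parameter file; raise on schema errors or invariant violations."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: not a mapping")
    params = parameters_from_dict(raw)
    problems = validate(params)
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))
    return params


def export_parameter_csv(params: ParameterSet, path: str | Path) -> None:
    """Audit export: one row per uncertain parameter (name, base, limits, family)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "base", "low", "high", "family", "source"])
        for p, spec in params.iter_uncertain():
            source = "pooled national table" if len(p) < 2 or p[0] != "exits" else (
                f"pooled national table ({p[1]} arm, stay_mode={params.stay_mode})"
                if p[2] == "U"
                else "pooled national table"
            )
            w.writerow(
                [path_name(p), spec.base, spec.low, spec.high, spec.family, source]
            )
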