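"""Fitting specifications, data tables, and problem binding.

A fitting experiment is described by three machine-readable artefacts:

* a JSON *fitting specification* with entries ``algorithm`` (identifier),
  ``arguments`` (name → number), ``output`` (data column → model output),
  ``input`` (protocol input → data column) and ``prior`` (per-parameter
  Uniform bounds or a fixed Point value), plus an optional ``units``
  sidecar declaring data-column units;
* a CSV *data table* whose first row names each variable — for current
  fitting, two equal-length columns of (time, current) pairs;
* a JSON *protocol* (see :mod:`hergfit.protocol`).

``bind_problem`` resolves the name maps against the built-in channel model
and produces a runnable :class:`FittingProblem`.  Binding is name-based
only: permuting data columns, or renaming a column and updating the maps,
never changes the bound problem.  Units must match the model's (ms, nA),
with one narrow exception: a time column declared in seconds is converted
to ms.
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np

from .errors import BindingError, DataError, SpecError
from .model import (
    PARAMETER_NAMES,
    ModelConstants,
    RateParameters,
    simulate,
)
from .protocol import VoltageProtocol

logger = logging.getLogger(__name__)

__all__ = [
    "UniformPrior",
    "PointPrior",
    "PriorSpec",
    "FittingSpec",
    "DataTable",
    "FittingProblem",
    "parse_fitting_spec",
    "serialize_fitting_spec",
    "count_free_parameters",
    "read_data_table",
    "write_data_table",
    "bind_problem",
    "default_fitting_spec",
    "NOISE_PARAMETER",
]

SUPPORTED_ALGORITHMS = ("AdaptiveMCMC",)
#: Name of the observation-noise standard deviation in the prior.
NOISE_PARAMETER = "obj:std"

_SPEC_KEYS_REQUIRED = ("algorithm", "arguments", "output", "input", "prior")
_SPEC_KEYS_OPTIONAL = ("units", "objective")

#: Model output / input names exposed by the built-in channel model.
#: ``exp_times`` is the simulation input that sets the output sample times.
MODEL_OUTPUTS = ("IKr",)
MODEL_INPUTS = ("exp_times",)
MODEL_UNITS = {"exp_times": "ms", "IKr": "nA"}
#: Default units assumed for data columns when the spec declares none.
DEFAULT_DATA_UNITS = {"time": "s", "current": "nA"}


@dataclass(frozen=True)
class UniformPrior:
    lower: float
    upper: float

    def __post_init__(self):
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise SpecError(f"uniform prior bounds must be finite: [{self.lower}, {self.upper}]")
        if not self.lower < self.upper:
            raise SpecError(
                f"uniform prior requires lower < upper, got [{self.lower}, {self.upper}]"
            )

    @property
    def range(self) -> float:
        return self.upper - self.lower

    def to_json_value(self):
        return [self.lower, self.upper]


@dataclass(frozen=True)
class PointPrior:
    value: float

    def __post_init__(self):
        if not np.isfinite(self.value):
            raise SpecError(f"point prior value must be finite: {self.value}")

    def to_json_value(self):
        return self.value


PriorEntry = Union[UniformPrior, PointPrior]


class PriorSpec:
    """Ordered per-parameter prior: Uniform(lower, upper) or Point(value)."""

    def __init__(self, entries: Mapping[str, PriorEntry]):
        self.entries: dict[str, PriorEntry] = dict(entries)
        if not self.entries:
            raise SpecError("prior must contain at least one entry")
        # An all-Point prior is representable (count_free_parameters -> 0);
        # inference requires >= 1 Uniform entry, enforced at binding time.

    @property
    def free_names(self) -> tuple[str, ...]:
        """Names with Uniform entries, in declaration order."""
        return tuple(n for n, e in self.entries.items() if isinstance(e, UniformPrior))

    @property
    def fixed_values(self) -> dict[str, float]:
        return {n: e.value for n, e in self.entries.items() if isinstance(e, PointPrior)}

    def __getitem__(self, name: str) -> PriorEntry:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __eq__(self, other) -> bool:
        return isinstance(other, PriorSpec) and self.entries == other.entries

    @classmethod
    def from_json_obj(cls, obj) -> "PriorSpec":
        if not isinstance(obj, dict) or not obj:
            raise SpecError("'prior' must be a non-empty JSON object")
        entries: dict[str, PriorEntry] = {}
        for name, value in obj.items():
            if isinstance(value, (int, float)) and not isinstance(value, bool):
                entries[name] = PointPrior(float(value))
            elif (
                isinstance(value, list)
                and len(value) == 2
                and all(isinstance(v, (int, float)) and not isinstance(v, bool) for v in value)
            ):
                entries[name] = UniformPrior(float(value[0]), float(value[1]))
            else:
                raise SpecError(
                    f"prior entry {name!r} must be a 2-member [lower, upper] list "
                    f"or a single fixed value, got {value!r}"
                )
        return cls(entries)

    def to_json_obj(self) -> dict:
        return {n: e.to_json_value() for n, e in self.entries.items()}


@dataclass
class FittingSpec:
    """Parsed and validated fitting specification."""

    algorithm: str
    arguments: dict[str, float]
    output_map: dict[str, str]  # data column -> model output
    input_map: dict[str, str]  # protocol input -> data column
    prior: PriorSpec
    units: dict[str, str] = field(default_factory=dict)  # data column -> unit

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FittingSpec)
            and self.algorithm == other.algorithm
            and self.arguments == other.arguments
            and self.output_map == other.output_map
            and self.input_map == other.input_map
            and self.prior == other.prior
            and self.units == other.units
        )


def _validate_arguments(algorithm: str, args: dict[str, float]) -> None:
    if algorithm == "AdaptiveMCMC":
        required = ("cmaOpt", "cmaMaxFevals", "burn", "numIters")
        for key in required:
            if key not in args:
                raise SpecError(f"AdaptiveMCMC requires argument {key!r}")
        if not args["numIters"] > args["burn"] >= 0:
            raise SpecError(
                f"AdaptiveMCMC requires numIters > burn >= 0, "
                f"got numIters={args['numIters']}, burn={args['burn']}"
            )
        if args["cmaOpt"] < 1:
            raise SpecError(f"cmaOpt must be >= 1, got {args['cmaOpt']}")
        if args["cmaMaxFevals"] < 100:
            raise SpecError(f"cmaMaxFevals must be >= 100, got {args['cmaMaxFevals']}")


def parse_fitting_spec(text: str) -> FittingSpec:
    """Parse a JSON fitting-specification document.

    Rejects malformed JSON, missing required entries, unknown top-level
    keys, unknown algorithm identifiers and malformed prior entries.
    """
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SpecError(f"fitting specification is not well-formed JSON: {exc}") from exc
    if not isinstance(obj, dict):
        raise SpecError("fitting specification must be a JSON object")

    unknown = set(obj) - set(_SPEC_KEYS_REQUIRED) - set(_SPEC_KEYS_OPTIONAL)
    if unknown:
        raise SpecError(f"unknown top-level entries: {sorted(unknown)}")
    missing = [k for k in _SPEC_KEYS_REQUIRED if k not in obj]
    if missing:
        raise SpecError(f"missing required entries: {missing}")

    algorithm = obj["algorithm"]
    if not isinstance(algorithm, str) or not algorithm:
        raise SpecError("'algorithm' must be a non-empty string")
    if algorithm not in SUPPORTED_ALGORITHMS:
        raise SpecError(
            f"unknown algorithm {algorithm!r}; supported: {list(SUPPORTED_ALGORITHMS)}"
        )

    # Reserved extension point: only the Gaussian objective exists today.
    if "objective" in obj and obj["objective"] != "gaussian":
        raise SpecError(
            f"unsupported objective {obj['objective']!r}; only 'gaussian' is available"
        )

    arguments = obj["arguments"]
    if not isinstance(arguments, dict) or not arguments:
        raise SpecError("'arguments' must be a non-empty JSON object")
    args: dict[str, float] = {}
    for key, value in arguments.items():
        if not isinstance(value, (int, float)) or isinstance(value, bool) or not np.isfinite(value):
            raise SpecError(f"argument {key!r} must be a finite number, got {value!r}")
        args[key] = float(value)
    _validate_arguments(algorithm, args)

    def _name_map(key: str) -> dict[str, str]:
        m = obj[key]
        if not isinstance(m, dict) or not m:
            raise SpecError(f"'{key}' must be a non-empty JSON object")
        for k, v in m.items():
            if not isinstance(v, str) or not v:
                raise SpecError(f"'{key}' entry {k!r} must map to a non-empty name")
        return dict(m)

    output_map = _name_map("output")
    input_map = _name_map("input")
    prior = PriorSpec.from_json_obj(obj["prior"])

    units = {}
    if "units" in obj:
        u = obj["units"]
        if not isinstance(u, dict) or not all(
            isinstance(k, str) and isinstance(v, str) for k, v in u.items()
        ):
            raise SpecError("'units' must map column names to unit strings")
        units = dict(u)

    return FittingSpec(algorithm, args, output_map, input_map, prior, units)


def serialize_fitting_spec(spec: FittingSpec) -> str:
    """JSON text whose re-parse equals ``spec`` field-by-field."""
    obj = {
        "algorithm": spec.algorithm,
        "arguments": spec.arguments,
        "output": spec.output_map,
        "input": spec.input_map,
        "prior": spec.prior.to_json_obj(),
    }
    if spec.units:
        obj["units"] = spec.units
    return json.dumps(obj, indent=2) + "\n"


def count_free_parameters(spec: FittingSpec) -> int:
    """Number of Uniform (non-Point) prior entries."""
    return len(spec.prior.free_names)


@dataclass
class DataTable:
    """Named numeric columns of equal length, with per-column unit labels."""

    columns: dict[str, np.ndarray]
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        lengths = {len(v) for v in self.columns.values()}
        if len(lengths) > 1:
            raise DataError(f"columns have unequal lengths: {lengths}")
        for name, values in self.columns.items():
            values = np.asarray(values, dtype=float)
            if not np.all(np.isfinite(values)):
                raise DataError(f"column {name!r} contains non-finite values")
            self.columns[name] = values

    @property
    def n_rows(self) -> int:
        return len(next(iter(self.columns.values())))

    def __getitem__(self, name: str) -> np.ndarray:
        return self.columns[name]


def read_data_table(source: str, units: Optional[Mapping[str, str]] = None) -> DataTable:
    """Read a CSV data table (header row of unique names, numeric body).

    ``source`` is CSV text or a path to a CSV file.  Rejects ragged rows,
    duplicate or missing headers and non-numeric cells.
    """
    if "\n" not in source and "," not in source:
        with open(source, "r", newline="") as fh:
            text = fh.read()
    else:
        text = source
    rows = list(csv.reader(io.StringIO(text)))
    rows = [r for r in rows if r]  # drop blank lines
    if not rows:
        raise DataError("empty data file")
    header = [h.strip() for h in rows[0]]
    if len(set(header)) != len(header):
        raise DataError(f"duplicate column names in header: {header}")
    for name in header:
        if not name:
            raise DataError("empty column name in header")
        try:
            float(name)
        except ValueError:
            pass
        else:
            raise DataError(
                f"header row looks numeric ({name!r}); the first row must name each variable"
            )
    ncol = len(header)
    body = rows[1:]
    if not body:
        raise DataError("data file has a header but no rows")
    for i, row in enumerate(body):
        if len(row) != ncol:
            raise DataError(
                f"ragged row {i + 2}: expected {ncol} fields, got {len(row)}"
            )
    try:
        values = np.array(body, dtype=float)
    except ValueError as exc:
        raise DataError(f"non-numeric cell in data file: {exc}") from exc
    columns = {name: values[:, j] for j, name in enumerate(header)}
    return DataTable(columns, dict(units or {}))


def write_data_table(table: DataTable, path: str) -> None:
    """Write a data table as plain CSV (17 significant digits, so float64
    values round-trip exactly)."""
    names = list(table.columns)
    data = np.column_stack([table.columns[n] for n in names])
    with open(path, "w", newline="") as fh:
        fh.write(",".join(names) + "\n")
        for row in data:
            fh.write(",".join(format(v, ".17g") for v in row) + "\n")


class FittingProblem:
    """A fully bound fitting problem: model + constants + protocol + data
    + prior + noise model, ready for posterior evaluation.

    ``free_names`` fixes the parameter-vector ordering (prior declaration
    order).  ``simulate_currents(theta)`` maps a free-parameter vector to
    model outputs at the bound sample times.
    """

    def __init__(
        self,
        constants: ModelConstants,
        protocol: VoltageProtocol,
        times: np.ndarray,
        observed: np.ndarray,
        prior: PriorSpec,
        arguments: dict[str, float],
        rate_constraint=None,
        backend: str = "fast",
    ):
        from .inference import RateConstraint  # local import to avoid cycle

        self.constants = constants
        self.protocol = protocol
        self.times = np.asarray(times, dtype=float)
        self.observed = np.asarray(observed, dtype=float)
        if self.times.shape != self.observed.shape:
            raise BindingError("observed array length must equal sample-time length")
        self.prior = prior
        self.arguments = dict(arguments)
        self.rate_constraint = rate_constraint if rate_constraint is not None else RateConstraint()
        self.backend = backend

        self.free_names: tuple[str, ...] = prior.free_names
        if not self.free_names:
            raise BindingError("inference needs at least one Uniform prior entry")
        self.fixed: dict[str, float] = prior.fixed_values
        for name in PARAMETER_NAMES + (NOISE_PARAMETER,):
            if name not in prior:
                raise BindingError(f"prior is missing an entry for parameter {name!r}")
        unknown = set(prior.entries) - set(PARAMETER_NAMES) - {NOISE_PARAMETER}
        if unknown:
            raise BindingError(f"prior names unknown to the model: {sorted(unknown)}")

        #: σ of the Gaussian noise if fixed by a Point prior, else None (free).
        self.sigma_fixed: Optional[float] = self.fixed.get(NOISE_PARAMETER)
        # Index of each model parameter in the free vector (or None if fixed).
        self._free_index = {n: i for i, n in enumerate(self.free_names)}
        self.n_simulations = 0  # diagnostic counter

        # Precomputed per-problem simulation context for the fast backend:
        # compiled protocol plan, command voltages and driving force at the
        # bound sample times (they never change between evaluations).
        from ._fastsim import protocol_plan

        self._plan = protocol_plan(protocol)
        self._voltages = protocol.voltages(self.times)
        self._driving_force = self._voltages - constants.EK
        self._v0 = protocol.voltage_at(0.0)
        self._vrange = protocol.voltage_range()

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def free_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lower = np.array([self.prior[n].lower for n in self.free_names])
        upper = np.array([self.prior[n].upper for n in self.free_names])
        return lower, upper

    def full_parameter_values(self, theta: np.ndarray) -> dict[str, float]:
        """All prior-named values implied by a free vector."""
        theta = np.asarray(theta, dtype=float)
        values = dict(self.fixed)
        for name, i in self._free_index.items():
            values[name] = float(theta[i])
        return values

    def rate_parameters(self, theta: np.ndarray) -> RateParameters:
        values = self.full_parameter_values(theta)
        return RateParameters(**{n: values[n] for n in PARAMETER_NAMES})

    def sigma(self, theta: np.ndarray) -> float:
        if self.sigma_fixed is not None:
            return self.sigma_fixed
        return float(np.asarray(theta)[self._free_index[NOISE_PARAMETER]])

    def simulate_currents(self, theta: np.ndarray) -> np.ndarray:
        """Model IKr at the bound sample times for a free-parameter vector."""
        from .errors import SimulationError
        from .model import evaluate_rates, gate_solution

        params = self.rate_parameters(theta)
        self.n_simulations += 1
        if self.backend != "fast":
            return simulate(params, self.constants, self.protocol, self.times).currents

        from ._fastsim import propagate_gates

        # Validates positivity and exponent overflow across the clamp range.
        evaluate_rates(params, self._vrange[0])
        evaluate_rates(params, self._vrange[1])
        g0 = gate_solution(evaluate_rates(params, self._v0))
        a, r = propagate_gates(
            params.as_array(), *self._plan, self.times, 0.05, g0.a_inf, g0.r_inf
        )
        open_prob = a * r
        if not np.all(np.isfinite(open_prob)):
            raise SimulationError("non-finite state in fast simulation")
        return params.GKr * open_prob * self._driving_force


def bind_problem(
    spec: FittingSpec,
    data: DataTable,
    constants: ModelConstants,
    protocol: VoltageProtocol,
    rate_constraint=None,
    backend: str = "fast",
) -> FittingProblem:
    """Resolve a spec's name maps against a data table and the built-in
    model, returning a runnable :class:`FittingProblem`.

    Simulation sample times are taken from the data column named by the
    spec's input map (the simulator generates outputs at exactly the times
    in the data file).  Units are checked; the single permitted conversion
    is time in seconds → ms.
    """
    available = sorted(data.columns)

    # --- input map: protocol inputs <- data columns -------------------
    if set(spec.input_map) != set(MODEL_INPUTS):
        raise BindingError(
            f"input map must bind exactly the model inputs {list(MODEL_INPUTS)}, "
            f"got {sorted(spec.input_map)}"
        )
    time_column = spec.input_map["exp_times"]
    if time_column not in data.columns:
        raise BindingError(
            f"input map names column {time_column!r} absent from data; available: {available}"
        )

    # --- output map: data columns -> model outputs --------------------
    if list(spec.output_map.values()) != list(MODEL_OUTPUTS) and set(
        spec.output_map.values()
    ) != set(MODEL_OUTPUTS):
        raise BindingError(
            f"output map must target the model outputs {list(MODEL_OUTPUTS)}, "
            f"got {sorted(spec.output_map.values())}"
        )
    (current_column,) = [c for c, out in spec.output_map.items() if out == "IKr"]
    if current_column not in data.columns:
        raise BindingError(
            f"output map names column {current_column!r} absent from data; "
            f"available: {available}"
        )

    # --- units ---------------------------------------------------------
    def column_unit(column: str, default: str) -> str:
        if column in spec.units:
            return spec.units[column]
        if column in data.units:
            return data.units[column]
        return default

    time_unit = column_unit(time_column, DEFAULT_DATA_UNITS["time"])
    current_unit = column_unit(current_column, DEFAULT_DATA_UNITS["current"])

    times = np.asarray(data[time_column], dtype=float)
    if time_unit == "s":
        times = times * 1000.0
        logger.info(
            "time column %r declared in seconds; converted to ms for simulation",
            time_column,
        )
    elif time_unit != MODEL_UNITS["exp_times"]:
        raise BindingError(
            f"time column {time_column!r} has unit {time_unit!r}; "
            f"model expects {MODEL_UNITS['exp_times']!r} (only s↔ms is auto-converted)"
        )
    if current_unit != MODEL_UNITS["IKr"]:
        raise BindingError(
            f"current column {current_column!r} has unit {current_unit!r}; "
            f"model expects {MODEL_UNITS['IKr']!r} and no conversion is applied"
        )

    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise BindingError(f"time column {time_column!r} is not strictly increasing")
    if times[0] < 0 or times[-1] > protocol.total_duration + 1e-9:
        raise BindingError(
            f"sample times span [{times[0]}, {times[-1]}] ms, outside the "
            f"protocol duration [0, {protocol.total_duration}] ms"
        )

    observed = np.asarray(data[current_column], dtype=float)
    return FittingProblem(
        constants=constants,
        protocol=protocol,
        times=times,
        observed=observed,
        prior=spec.prior,
        arguments=spec.arguments,
        rate_constraint=rate_constraint,
        backend=backend,
    )


def default_fitting_spec(reduced: bool = False) -> FittingSpec:
    """The built-in hERG fitting specification: AdaptiveMCMC with a
    5-restart CMA-ES initialisation, box-uniform priors on the nine model
    parameters and a fixed observation-noise σ = 0.00463 nA.

    With ``reduced=True`` the computational budgets are scaled down
    (2 CMA-ES restarts / 4,000 evaluations, 20,000 MCMC iterations with
    10,000 burn-in) for quick studies and continuous testing.
    """
    if reduced:
        arguments = {"cmaOpt": 2.0, "cmaMaxFevals": 4000.0, "burn": 10000.0, "numIters": 20000.0}
    else:
        arguments = {"cmaOpt": 5.0, "cmaMaxFevals": 20000.0, "burn": 50000.0, "numIters": 100000.0}
    prior = PriorSpec(
        {
            "kO1": UniformPrior(1e-7, 0.1),
            "kO2": UniformPrior(1e-7, 0.1),
            "kC1": UniformPrior(1e-7, 0.1),
            "kC2": UniformPrior(1e-7, 0.1),
            "kI1": UniformPrior(1e-7, 0.1),
            "kI2": UniformPrior(1e-7, 0.1),
            "kA1": UniformPrior(1e-7, 0.1),
            "kA2": UniformPrior(1e-7, 0.1),
            "GKr": UniformPrior(0.0612, 0.612),
            NOISE_PARAMETER: PointPrior(0.00463),
        }
    )
    return FittingSpec(
        algorithm="AdaptiveMCMC",
        arguments=arguments,
        output_map={"exp_IKr": "IKr"},
        input_map={"exp_times": "t"},
        prior=prior,
        units={"t": "s", "exp_IKr": "nA"},
    )
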