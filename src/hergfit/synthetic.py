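"""Synthetic voltage-clamp datasets with known ground truth.

The generator emulates the statistical structure the Gaussian whole-trace
likelihood assumes: a noise-free model trace sampled on a regular grid
(default every 0.1 ms), plus i.i.d. Gaussian observation noise with fixed
standard deviation (default 0.00463 nA, matching the built-in fitting
specification).  It models the *post-processed* recording only — no leak,
drift or capacitance artefacts.

The default truth parameters are synthetic: realistic hERG-like kinetics
chosen strictly inside the built-in prior box and satisfying the default
physiological rate constraint, with signal-to-noise well above 20 under
the fixture protocol.  They are documentation constants of this package,
not estimates from any recorded cell.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, replace

import numpy as np

from .errors import HergfitError
from .fitting_io import (
    DataTable,
    FittingSpec,
    bind_problem,
    default_fitting_spec,
    serialize_fitting_spec,
    write_data_table,
)
from .model import ModelConstants, RateParameters, simulate_fast
from .protocol import VoltageProtocol, default_fixture_protocol, dump_protocol

__all__ = ["TruthRecord", "default_truth", "generate_dataset", "write_fixture"]

#: Synthetic ground-truth kinetics (ms⁻¹ / mV⁻¹) and conductance (μS).
DEFAULT_TRUE_PARAMETERS = RateParameters(
    kO1=2.26e-4,
    kO2=0.0699,
    kC1=3.45e-5,
    kC2=0.05462,
    kI1=0.0873,
    kI2=8.91e-3,
    kA1=5.15e-3,
    kA2=0.03158,
    GKr=0.1524,
)


@dataclass(frozen=True)
class TruthRecord:
    """Everything needed to generate — and later audit — a synthetic
    dataset: true parameters, constants, protocol, noise σ (nA), sampling
    interval (ms) and the noise seed."""

    params: RateParameters
    constants: ModelConstants
    protocol: VoltageProtocol
    sigma: float = 0.00463
    dt: float = 0.1
    seed: int = 20180511

    def __post_init__(self):
        if not self.sigma >= 0:
            raise HergfitError("sigma must be non-negative")
        if not self.dt > 0:
            raise HergfitError("sampling interval must be positive")

    def validate(self, spec: FittingSpec | None = None, rate_constraint=None) -> None:
        """Refuse truths outside the prior box or the rate-constraint
        region, so recovery checks stay meaningful."""
        from .inference import RateConstraint

        spec = spec if spec is not None else default_fitting_spec()
        for name in self.params.__dataclass_fields__:
            value = getattr(self.params, name)
            entry = spec.prior[name]
            if hasattr(entry, "lower") and not (entry.lower < value < entry.upper):
                raise HergfitError(
                    f"truth parameter {name}={value} outside the prior box "
                    f"[{entry.lower}, {entry.upper}]"
                )
        constraint = rate_constraint if rate_constraint is not None else RateConstraint()
        if not constraint.satisfied(self.params):
            raise HergfitError("truth parameters violate the physiological rate constraint")

    def sample_times(self) -> np.ndarray:
        """Regular grid (ms) covering the protocol at interval ``dt``."""
        n = int(round(self.protocol.total_duration / self.dt))
        return np.linspace(0.0, n * self.dt, n + 1)


def default_truth() -> TruthRecord:
    """The documented default study conditions: realistic synthetic hERG
    kinetics under the information-rich fixture protocol, σ = 0.00463 nA,
    0.1 ms sampling, fixed seed."""
    return TruthRecord(
        params=DEFAULT_TRUE_PARAMETERS,
        constants=ModelConstants(),
        protocol=default_fixture_protocol(),
    )


def generate_dataset(truth: TruthRecord) -> tuple[DataTable, TruthRecord]:
    """Simulate the protocol on the truth's regular grid and add i.i.d.
    N(0, σ²) observation noise.

    Returns a ``(t, exp_IKr)`` data table — time in **seconds**, matching
    the CSV convention of the built-in fitting specification — plus the
    truth record for later recovery checks.
    """
    truth.validate()
    times_ms = truth.sample_times()
    trace = simulate_fast(truth.params, truth.constants, truth.protocol, times_ms)
    rng = np.random.default_rng(truth.seed)
    noise = rng.normal(0.0, truth.sigma, size=times_ms.size) if truth.sigma > 0 else 0.0
    table = DataTable(
        columns={"t": times_ms / 1000.0, "exp_IKr": trace.currents + noise},
        units={"t": "s", "exp_IKr": "nA"},
    )
    return table, truth


def write_fixture(
    table: DataTable,
    spec: FittingSpec,
    protocol: VoltageProtocol,
    out_dir: str,
    truth: TruthRecord | None = None,
) -> dict[str, str]:
    """Write a self-contained fixture: data.csv, spec.json, protocol.json
    and (when a truth record is given) truth.json.  Re-reading the files
    reproduces the objects exactly; the same seed yields byte-identical
    files."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "data": os.path.join(out_dir, "data.csv"),
        "spec": os.path.join(out_dir, "spec.json"),
        "protocol": os.path.join(out_dir, "protocol.json"),
    }
    write_data_table(table, paths["data"])
    with open(paths["spec"], "w") as fh:
        fh.write(serialize_fitting_spec(spec))
    with open(paths["protocol"], "w") as fh:
        fh.write(dump_protocol(protocol))
    if truth is not None:
        paths["truth"] = os.path.join(out_dir, "truth.json")
        record = {
            "params": {
                name: getattr(truth.params, name)
                for name in truth.params.__dataclass_fields__
            },
            "EK": truth.constants.EK,
            "sigma": truth.sigma,
            "dt_ms": truth.dt,
            "seed": truth.seed,
        }
        with open(paths["truth"], "w") as fh:
            json.dump(record, fh, indent=2)
            fh.write("\n")
    return paths


def make_problem(
    truth: TruthRecord | None = None,
    spec: FittingSpec | None = None,
    dt: float | None = None,
    backend: str = "fast",
):
    """Convenience: generate a dataset from ``truth`` (default study
    conditions) and bind it straight into a fitting problem."""
    truth = truth if truth is not None else default_truth()
    if dt is not None:
        truth = replace(truth, dt=dt)
    spec = spec if spec is not None else default_fitting_spec()
    table, truth = generate_dataset(truth)
    problem = bind_problem(spec, table, truth.constants, truth.protocol, backend=backend)
    return problem, truth
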