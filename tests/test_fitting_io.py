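import json

import numpy as np
import pytest

from hergfit.errors import BindingError, DataError, SpecError
from hergfit.fitting_io import (
    DataTable,
    PointPrior,
    UniformPrior,
    bind_problem,
    count_free_parameters,
    default_fitting_spec,
    parse_fitting_spec,
    read_data_table,
    serialize_fitting_spec,
)
from hergfit.model import ModelConstants
from hergfit.protocol import holding_protocol

# The shipped hERG fitting document: AdaptiveMCMC with CMA-ES start-point
# selection, box-uniform priors on the nine model parameters, fixed noise σ.
HERG_SPEC_TEXT = json.dumps(
    {
        "algorithm": "AdaptiveMCMC",
        "arguments": {"cmaOpt": 5, "cmaMaxFevals": 20000, "burn": 50000, "numIters": 100000},
        "output": {"exp_IKr": "IKr"},
        "input": {"exp_times": "t"},
        "prior": {
            "kO1": [1e-7, 0.1], "kO2": [1e-7, 0.1],
            "kC1": [1e-7, 0.1], "kC2": [1e-7, 0.1],
            "kI1": [1e-7, 0.1], "kI2": [1e-7, 0.1],
            "kA1": [1e-7, 0.1], "kA2": [1e-7, 0.1],
            "GKr": [0.0612, 0.612],
            "obj:std": 0.00463,
        },
    }
)


class TestParseFittingSpec:
    def test_herg_document_parses_to_expected_structure(self):
        spec = parse_fitting_spec(HERG_SPEC_TEXT)
        assert spec.algorithm == "AdaptiveMCMC"
        assert spec.arguments == {
            "cmaOpt": 5.0, "cmaMaxFevals": 20000.0, "burn": 50000.0, "numIters": 100000.0
        }
        assert spec.output_map == {"exp_IKr": "IKr"}
        assert spec.input_map == {"exp_times": "t"}
        assert count_free_parameters(spec) == 9
        assert spec.prior["obj:std"] == PointPrior(0.00463)
        assert spec.prior["GKr"] == UniformPrior(0.0612, 0.612)

    def test_malformed_json_rejected(self):
        with pytest.raises(SpecError, match="JSON"):
            parse_fitting_spec("{not json")

    def test_missing_required_entry_named_in_error(self):
        obj = json.loads(HERG_SPEC_TEXT)
        del obj["prior"]
        with pytest.raises(SpecError, match="prior"):
            parse_fitting_spec(json.dumps(obj))

    def test_reversed_prior_bounds_rejected(self):
        obj = json.loads(HERG_SPEC_TEXT)
        obj["prior"]["kO1"] = [0.1, 1e-7]
        with pytest.raises(SpecError, match="lower < upper"):
            parse_fitting_spec(json.dumps(obj))

    def test_malformed_prior_entry_rejected(self):
        obj = json.loads(HERG_SPEC_TEXT)
        obj["prior"]["kO1"] = [1e-7, 0.1, 5.0]
        with pytest.raises(SpecError, match="kO1"):
            parse_fitting_spec(json.dumps(obj))

    def test_unknown_top_level_key_rejected(self):
        obj = json.loads(HERG_SPEC_TEXT)
        obj["extra"] = 1
        with pytest.raises(SpecError, match="extra"):
            parse_fitting_spec(json.dumps(obj))

    def test_unknown_algorithm_lists_supported_ones(self):
        obj = json.loads(HERG_SPEC_TEXT)
        obj["algorithm"] = "NestedSampling"
        with pytest.raises(SpecError, match="AdaptiveMCMC"):
            parse_fitting_spec(json.dumps(obj))

    def test_non_gaussian_objective_rejected(self):
        obj = json.loads(HERG_SPEC_TEXT)
        obj["objective"] = "student-t"
        with pytest.raises(SpecError, match="gaussian"):
            parse_fitting_spec(json.dumps(obj))

    def test_invalid_mcmc_arguments_rejected(self):
        obj = json.loads(HERG_SPEC_TEXT)
        obj["arguments"]["burn"] = 200000
        with pytest.raises(SpecError, match="numIters > burn"):
            parse_fitting_spec(json.dumps(obj))

    def test_round_trip_serialisation(self):
        spec = parse_fitting_spec(HERG_SPEC_TEXT)
        assert parse_fitting_spec(serialize_fitting_spec(spec)) == spec
        builder = default_fitting_spec()
        assert parse_fitting_spec(serialize_fitting_spec(builder)) == builder


class TestCountFreeParameters:
    def test_all_point_prior_counts_zero(self):
        obj = json.loads(HERG_SPEC_TEXT)
        obj["prior"] = {k: 0.01 for k in obj["prior"]}
        assert count_free_parameters(parse_fitting_spec(json.dumps(obj))) == 0

    def test_freeing_the_noise_parameter_counts_ten(self):
        obj = json.loads(HERG_SPEC_TEXT)
        obj["prior"]["obj:std"] = [1e-4, 1e-2]
        assert count_free_parameters(parse_fitting_spec(json.dumps(obj))) == 10


class TestReadDataTable:
    def test_small_table(self):
        table = read_data_table("t,exp_IKr\n0,0.0\n0.0001,0.02\n")
        assert set(table.columns) == {"t", "exp_IKr"}
        assert table.n_rows == 2
        np.testing.assert_array_equal(table["t"], [0.0, 0.0001])

    def test_ragged_rows_rejected(self):
        with pytest.raises(DataError, match="ragged"):
            read_data_table("t,exp_IKr\n0,0.0\n0.0001\n")

    def test_missing_header_rejected(self):
        with pytest.raises(DataError, match="name"):
            read_data_table("0,0.0\n0.0001,0.02\n")

    def test_duplicate_names_rejected(self):
        with pytest.raises(DataError, match="duplicate"):
            read_data_table("t,t\n0,0.0\n")

    def test_non_numeric_cell_rejected(self):
        with pytest.raises(DataError, match="non-numeric"):
            read_data_table("t,exp_IKr\n0,abc\n")

    def test_non_finite_value_rejected(self):
        with pytest.raises(DataError, match="non-finite"):
            read_data_table("t,exp_IKr\n0,inf\n")


def _spec_and_table(n=5, dt_s=0.001):
    spec = parse_fitting_spec(HERG_SPEC_TEXT)
    times = np.arange(n) * dt_s
    table = DataTable(
        columns={"t": times, "exp_IKr": np.linspace(0.0, 0.1, n)},
        units={"t": "s", "exp_IKr": "nA"},
    )
    return spec, table


class TestBindProblem:
    def test_sample_times_taken_from_data_column_with_unit_conversion(self):
        spec, table = _spec_and_table()
        problem = bind_problem(spec, table, ModelConstants(), holding_protocol(100.0))
        np.testing.assert_allclose(problem.times, table["t"] * 1000.0)
        np.testing.assert_array_equal(problem.observed, table["exp_IKr"])
        assert problem.sigma_fixed == 0.00463
        assert problem.n_free == 9

    def test_column_order_is_irrelevant(self):
        spec, table = _spec_and_table()
        reordered = DataTable(
            columns={"exp_IKr": table["exp_IKr"], "t": table["t"]}, units=dict(table.units)
        )
        a = bind_problem(spec, table, ModelConstants(), holding_protocol(100.0))
        b = bind_problem(spec, reordered, ModelConstants(), holding_protocol(100.0))
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.observed, b.observed)

    def test_renaming_columns_with_updated_maps_is_equivalent(self):
        spec, table = _spec_and_table()
        renamed = DataTable(
            columns={"time_s": table["t"], "current": table["exp_IKr"]},
            units={"time_s": "s", "current": "nA"},
        )
        spec2 = parse_fitting_spec(HERG_SPEC_TEXT)
        spec2.input_map = {"exp_times": "time_s"}
        spec2.output_map = {"current": "IKr"}
        spec2.units = {"time_s": "s", "current": "nA"}
        a = bind_problem(spec, table, ModelConstants(), holding_protocol(100.0))
        b = bind_problem(spec2, renamed, ModelConstants(), holding_protocol(100.0))
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.observed, b.observed)

    def test_unmapped_column_error_lists_available_names(self):
        spec, table = _spec_and_table()
        spec.output_map = {"missing_column": "IKr"}
        with pytest.raises(BindingError, match="exp_IKr"):
            bind_problem(spec, table, ModelConstants(), holding_protocol(100.0))

    def test_non_monotone_time_column_rejected(self):
        spec, _ = _spec_and_table()
        table = DataTable(
            columns={"t": np.array([0.0, 0.002, 0.001]), "exp_IKr": np.zeros(3)},
            units={"t": "s", "exp_IKr": "nA"},
        )
        with pytest.raises(BindingError, match="increasing"):
            bind_problem(spec, table, ModelConstants(), holding_protocol(100.0))

    def test_foreign_current_unit_rejected(self):
        spec, table = _spec_and_table()
        spec.units = {"t": "s", "exp_IKr": "pA"}
        with pytest.raises(BindingError, match="pA"):
            bind_problem(spec, table, ModelConstants(), holding_protocol(100.0))

    def test_times_beyond_protocol_duration_rejected(self):
        spec, table = _spec_and_table(n=5, dt_s=0.5)  # up to 2 s
        with pytest.raises(BindingError, match="duration"):
            bind_problem(spec, table, ModelConstants(), holding_protocol(100.0))

    def test_all_point_prior_rejected_at_binding(self):
        obj = json.loads(HERG_SPEC_TEXT)
        obj["prior"] = {k: 0.01 for k in obj["prior"]}
        spec = parse_fitting_spec(json.dumps(obj))
        _, table = _spec_and_table()
        with pytest.raises(BindingError, match="Uniform"):
            bind_problem(spec, table, ModelConstants(), holding_protocol(100.0))
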