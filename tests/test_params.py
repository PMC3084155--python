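"""Parameter housekeeping: published values, file round-trip, consistency."""

import math

import numpy as np
import pytest
import yaml

from htn_cea import (
    DistributionSpec,
    SchemaError,
    StrategyCostComponents,
    ValidationError,
    base_case,
    load_parameters,
    save_parameters,
    validate_distributions,
)
from htn_cea.distributions import lognormal, uniform


class TestBaseCase:
    @pytest.mark.parametrize("name, expected", [
        ("usual.drug_cost_year", 206.43),
        ("usual.test_cost_year", 29.10),
        ("usual.programme_fee_year", 0.0),
        ("usual.hazard_ratio", 0.6150),
        ("programme.drug_cost_year", 216.55),
        ("programme.programme_fee_year", 14.66),
        ("programme.hazard_ratio", 0.5124),
        ("common.visit_cost", 9.63),
        ("common.overhead_per_visit", 1.98),
        ("common.ambulance_cost_year", 17.44),
        ("common.drug_coverage", 0.70),
        ("common.event_hospital_cost", 10041.65),
        ("common.first_year_test_cost", 117.78),
        ("common.risk_int_65_74", 0.0255),
        ("common.risk_int_75plus", 0.0400),
        ("common.risk_high_65_74", 0.0325),
        ("common.risk_high_75plus", 0.2000),
        ("common.p_sudden_death", 0.10),
        ("common.p_unrecognized", 0.367),
        ("common.cfr_assisted_65_74", 0.15),
        ("common.cfr_assisted_75plus", 0.30),
        ("common.cfr_unassisted_65_74", 0.30),
        ("common.cfr_unassisted_75plus", 0.60),
        ("common.p_start_intermediate", 0.70),
        ("common.start_age", 65.0),
    ])
    def test_published_base_values(self, params, name, expected):
        assert params.get_spec(name).base == pytest.approx(expected)

    def test_visit_laws_cover_both_published_counts(self, params):
        """The two visit-count lognormals (bases 7.68 and 4.72) are both
        present; the default assigns the higher utilisation to the programme,
        the reading consistent with the costing ledger."""
        assert params.programme.n_visits_year.base == pytest.approx(7.68)
        assert params.usual.n_visits_year.base == pytest.approx(4.72)
        printed = base_case(visits="printed")
        assert printed.usual.n_visits_year.base == pytest.approx(7.68)
        assert printed.programme.n_visits_year.base == pytest.approx(4.72)

    def test_every_published_row_maps_to_a_field(self, params):
        """Completeness: each variable-table row has exactly one home."""
        expected = {
            # per-strategy rows (x2)
            *(f"{s}.{f}" for s in ("usual", "programme")
              for f in ("drug_cost_year", "test_cost_year", "n_visits_year",
                        "hazard_ratio")),
            "programme.programme_fee_year",
            # common cost rows
            "common.overhead_per_visit", "common.visit_cost",
            "common.ambulance_cost_year", "common.drug_coverage",
            "common.event_hospital_cost", "common.first_year_test_cost",
            # outcome rows
            "common.risk_int_65_74", "common.risk_int_75plus",
            "common.risk_high_65_74", "common.risk_high_75plus",
            "common.p_sudden_death", "common.p_unrecognized",
            "common.cfr_assisted_65_74", "common.cfr_assisted_75plus",
            "common.cfr_unassisted_65_74", "common.cfr_unassisted_75plus",
            "common.p_start_intermediate", "common.start_age",
        }
        assert expected <= set(params.sampled_names()) | {"usual.programme_fee_year"}
        assert params.programme.hazard_ratio_scenario is not None


class TestDistributionSpec:
    def test_uniform_base_must_lie_inside_bounds(self):
        with pytest.raises(ValidationError):
            DistributionSpec("uniform", base=25.0, p1=10.0, p2=20.0)

    def test_lognormal_requires_positive_sigma(self):
        with pytest.raises(ValidationError):
            lognormal(1.0, 0.0, base=2.7)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError):
            DistributionSpec("triangular", base=1.0)

    def test_truncated_normal_respects_open_interval(self):
        spec = DistributionSpec("normal", base=0.5, p1=0.5, p2=5.0,
                                lower=0.0, upper=1.5)
        x = spec.sample(np.random.default_rng(0), 5000)
        assert (x > 0).all() and (x <= 1.5).all()

    def test_integer_flag_floors_draws(self):
        spec = uniform(65.0, 80.0, base=65.0, integer=True)
        x = spec.sample(np.random.default_rng(1), 1000)
        assert np.array_equal(x, np.floor(x))
        assert x.min() >= 65 and x.max() <= 79


class TestRoundTrip:
    def test_save_load_identity(self, params, tmp_path):
        path = tmp_path / "params.yaml"
        save_parameters(params, path)
        assert load_parameters(path) == params

    def test_missing_key_names_the_key(self, params, tmp_path):
        path = tmp_path / "params.yaml"
        save_parameters(params, path)
        doc = yaml.safe_load(path.read_text())
        del doc["usual"]["hazard_ratio"]
        path.write_text(yaml.safe_dump(doc))
        with pytest.raises(SchemaError, match="hazard_ratio"):
            load_parameters(path)

    def test_out_of_range_value_rejected(self, params, tmp_path):
        path = tmp_path / "params.yaml"
        save_parameters(params, path)
        doc = yaml.safe_load(path.read_text())
        doc["common"]["drug_coverage"]["base"] = 1.3  # outside [0.40, 1.00]
        path.write_text(yaml.safe_dump(doc))
        with pytest.raises(ValidationError):
            load_parameters(path)

    def test_invalid_coverage_component_rejected(self):
        with pytest.raises(ValidationError):
            StrategyCostComponents(
                drug_cost_year=1, test_cost_year=1, programme_fee_year=0,
                n_visits_year=1, visit_cost=1, overhead_per_visit=1,
                ambulance_cost_year=1, drug_coverage=1.3,
                first_year_test_cost=0, event_hospital_cost=0)


class TestConsistencyReport:
    def test_symmetric_uniform_has_zero_deviation(self, params):
        rep = validate_distributions(params).set_index("parameter")
        row = rep.loc["programme.programme_fee_year"]
        assert row["implied_centre"] == pytest.approx(14.66)
        assert row["deviation"] == pytest.approx(0.0)

    def test_lognormal_implied_mean_close_to_base(self, params):
        rep = validate_distributions(params).set_index("parameter")
        row = rep.loc["usual.drug_cost_year"]
        assert row["implied_centre"] == pytest.approx(math.exp(4.36 + 1.39 ** 2 / 2), rel=1e-9)
        assert row["deviation"] < 0.01

    def test_fixed_parameters_never_flagged(self, params):
        rep = validate_distributions(params).set_index("parameter")
        row = rep.loc["usual.programme_fee_year"]
        assert row["deviation"] == 0.0 and not row["flagged"]

    def test_off_centre_scenario_bands_are_flagged(self, params):
        """Starting age and stratum mix carry point estimates inside wide
        scenario bands; the report surfaces them instead of erroring."""
        rep = validate_distributions(params).set_index("parameter")
        assert rep.loc["common.start_age", "flagged"]
        assert rep.loc["common.p_start_intermediate", "flagged"]
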