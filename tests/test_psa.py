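"""Parameter sampling, PSA driver, summaries and sweeps."""

import numpy as np
import pandas as pd
import pytest

import diagcea as d
from diagcea.errors import ConfigError
from diagcea.scenarios import SCENARIOS


class TestParameterSpec:
    def test_fixed_always_returns_its_constant(self):
        spec = d.ParameterSpec.fixed("c_expert", 174.28)
        rng = np.random.default_rng(0)
        assert {spec.sample(rng) for _ in range(5)} == {174.28}

    @pytest.mark.parametrize(
        "family,params",
        [
            ("lognormal", (1.0, -0.1)),
            ("gamma", (-1.0, 2.0)),
            ("beta", (0.0, 3.0)),
            ("uniform", (2.0, 1.0)),
            ("cauchy", (0.0, 1.0)),
        ],
    )
    def test_invalid_specs_rejected(self, family, params):
        with pytest.raises(ConfigError):
            d.ParameterSpec("x", family, params)

    def test_analytic_means(self):
        assert d.ParameterSpec("g", "gamma", (4, 1211.8675)).mean() == pytest.approx(
            4847.47
        )
        assert d.ParameterSpec("b", "beta", (154, 1382)).mean() == pytest.approx(
            154 / 1536
        )
        assert d.ParameterSpec("u", "uniform", (0.1, 0.9)).mean() == pytest.approx(0.5)


class TestSampling:
    def test_reproducible_and_order_independent(self, table3_specs):
        a = d.sample_parameters(table3_specs, np.random.default_rng(5))
        b = d.sample_parameters(list(reversed(table3_specs)), np.random.default_rng(5))
        assert a == b

    def test_duplicate_names_rejected(self):
        specs = [d.ParameterSpec.fixed("x", 1.0), d.ParameterSpec.fixed("x", 2.0)]
        with pytest.raises(ConfigError, match="duplicate"):
            d.sample_parameters(specs, np.random.default_rng(0))


class TestSummarize:
    def test_hand_arithmetic(self):
        s = d.summarize([1.0, 2.0, 3.0])
        assert (s.mean, s.median, s.sd) == (2.0, 2.0, 1.0)
        assert s.ci95_low == pytest.approx(2 - 1.96 / np.sqrt(3))
        assert s.ci95_high == pytest.approx(2 + 1.96 / np.sqrt(3))

    def test_constant_vector_collapses(self):
        s = d.summarize([7.0] * 10)
        assert s.sd == 0.0 and s.ci95_low == s.ci95_high == 7.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            d.summarize([])

    def test_summary_invariants(self):
        rng = np.random.default_rng(3)
        s = d.summarize(rng.lognormal(8, 1, size=500))
        assert s.min <= s.median <= s.max
        assert s.ci95_low <= s.mean <= s.ci95_high
        assert s.sd >= 0


class TestRunPsa:
    def test_single_replicate_degenerate_summary(self, table3_specs, config):
        res = d.run_psa(SCENARIOS["dd_mca_s4"], table3_specs, 1, 11, config)
        s = res.summary
        assert s.mean == s.median == s.min == s.max
        assert s.sd == 0.0

    def test_all_fixed_specs_give_zero_variance(self, config):
        specs = [d.ParameterSpec.fixed(k, v) for k, v in d.params_point("table1").items()]
        res = d.run_psa(SCENARIOS["dd_mca_s4"], specs, 100, 11, config)
        assert res.summary.min == res.summary.max
        assert res.summary.sd == pytest.approx(0.0, abs=1e-8)
        assert res.summary.mean == pytest.approx(
            5021.75 / res.table["expected_qaly"].iloc[0]
        )

    def test_bit_identical_replicate_tables_for_same_seed(self, table3_specs, config):
        a = d.run_psa(SCENARIOS["dd_mca_s2"], table3_specs, 40, 17, config)
        b = d.run_psa(SCENARIOS["dd_mca_s2"], table3_specs, 40, 17, config)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.summary == b.summary

    def test_deterministic_run_lies_inside_psa_envelope(self, table3_specs, config):
        point = {s.name: s.mean() for s in table3_specs}
        tree, registry, overrides = d.scenario_model("dd_mca_s3", point)
        det = d.evaluate(tree, registry, config, overrides=overrides)
        res = d.run_psa(SCENARIOS["dd_mca_s3"], table3_specs, 400, 23, config)
        assert res.summary.min <= det.cost_per_qaly <= res.summary.max

    def test_ratio_of_expectations_mode_recorded_and_smaller(
        self, table3_specs
    ):
        cfg = d.default_config(ratio_mode="of_expectations")
        roe = d.run_psa(SCENARIOS["dd_mca_s4"], table3_specs, 300, 13, cfg)
        per = d.run_psa(
            SCENARIOS["dd_mca_s4"], table3_specs, 300, 13, d.default_config()
        )
        assert roe.summary.ratio_mode == "of_expectations"
        # mean of ratios exceeds ratio of means for positively skewed costs
        assert roe.summary.mean < per.summary.mean


class TestCompareAndSweep:
    def test_common_draws_share_sampled_parameters(self, table3_specs, config):
        res = d.compare(
            [SCENARIOS["dd_mca_s2"], SCENARIOS["dd_mca_s3"]],
            table3_specs, 30, 19, config,
        )
        a, b = res["dd_mca_s2"].table, res["dd_mca_s3"].table
        pd.testing.assert_series_equal(a["c_es"], b["c_es"])

    def test_single_cell_sweep_equals_run_psa(self, table3_specs, config):
        res = d.run_psa(SCENARIOS["dd_mca_s4"], table3_specs, 50, 29, config)
        table = d.sweep(
            [SCENARIOS["dd_mca_s4"]], table3_specs, "c_es",
            n_sims=50, seed=29, config=config, bins=[0.0, 1e9],
        )
        assert len(table) == 1
        assert table["mean"].iloc[0] == pytest.approx(res.summary.mean)
        assert table["n_replicates"].iloc[0] == 50

    def test_fixing_precision_grid_monotone(self, table3_specs, config):
        table = d.sweep(
            [SCENARIOS["dd_mca_ai"]], table3_specs, "ai_precision",
            n_sims=250, seed=31, config=config, values=[0.1, 0.5, 0.9],
        )
        means = table.sort_values("cell_mid")["mean"].to_numpy()
        assert means[0] > means[1] > means[2]

    def test_unknown_parameter_rejected(self, table3_specs, config):
        with pytest.raises(ConfigError, match="unknown parameter"):
            d.sweep(
                [SCENARIOS["dd_mca_s4"]], table3_specs, "nope",
                n_sims=5, seed=1, config=config, values=[1.0],
            )


class TestConvergence:
    def test_se_of_mean_scales_with_replicates(self, table3_specs, config):
        """SD of independent-seed means shrinks like 1/sqrt(n_sims)."""
        means = {
            n: [
                d.run_psa(SCENARIOS["dd_mca_s3"], table3_specs, n, 400 + k, config).summary.mean
                for k in range(12)
            ]
            for n in (100, 400)
        }
        ratio = np.std(means[100], ddof=1) / np.std(means[400], ddof=1)
        assert 1.2 < ratio < 3.4  # 2x expected, wide band for 12 seeds


class TestParameterFiles:
    def test_yaml_round_trip(self, table3_specs):
        from diagcea.psa import dump_parameter_specs

        text = dump_parameter_specs(table3_specs)
        again = d.load_parameter_specs(text)
        assert sorted(again, key=lambda s: s.name) == sorted(
            table3_specs, key=lambda s: s.name
        )

    def test_bare_number_is_fixed_shorthand(self):
        specs = d.load_parameter_specs("c_expert: 174.28\n")
        assert specs == [d.ParameterSpec.fixed("c_expert", 174.28)]

    def test_shipped_parameter_fixtures_parse(self):
        for name in ("params_table1.yaml", "params_table3.yaml", "params_table5.yaml"):
            specs = d.load_parameter_specs(d.fixture_text(name))
            assert len(specs) >= 15
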