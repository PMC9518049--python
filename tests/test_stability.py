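"""Likelihood-ratio instability and transferability machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rplogit.data import split_dataset
from rplogit.design import build_design
from rplogit.estimation import fit_mnl
from rplogit.simulate import GeneratorConfig, generate_study_like
from rplogit.stability import (
    chi_square_confidence,
    critical_chi_square,
    global_instability_test,
    global_test_summary,
    instability_matrix,
    parse_rendered_cell,
    render_instability_matrix,
    transferability_test,
)
from rplogit.validation import fixed_effects_spec, fixed_effects_truth


class TestGlobalTest:
    def test_helmet_group_statistic_from_printed_log_likelihoods(self):
        res = global_instability_test(
            -4025.185, [-1199.931, -1258.448, -1477.467],
            params_pooled=21, params_periods=[17, 12, 14], confidence=0.99,
        )
        assert res.chi2 == pytest.approx(178.68, abs=0.005)
        assert res.dof == 22
        assert res.decision == "reject-equality"

    def test_nonhelmet_group_statistic_from_printed_log_likelihoods(self):
        res = global_instability_test(
            -13641.844, [-3477.439, -4151.247, -5942.630],
            params_pooled=22, params_periods=[19, 15, 14], confidence=0.99,
        )
        assert res.chi2 == pytest.approx(141.06, abs=0.005)
        assert res.dof == 26
        assert res.decision == "reject-equality"

    def test_pooled_equal_to_period_sum_fails_to_reject(self):
        res = global_instability_test(-300.0, [-100.0, -100.0, -100.0],
                                      params_pooled=5, params_periods=[5, 5, 5])
        assert res.chi2 == 0.0
        assert res.decision == "fail-to-reject"

    @given(st.permutations([-1199.931, -1258.448, -1477.467]))
    @settings(deadline=None, max_examples=10)
    def test_invariant_to_period_ordering(self, lls):
        res = global_instability_test(-4025.185, list(lls), 21, [17, 12, 14])
        assert res.chi2 == pytest.approx(178.678, abs=1e-9)

    def test_negative_statistic_warned_not_clamped_silently(self):
        res = global_instability_test(-250.0, [-100.0, -160.0],
                                      params_pooled=4, params_periods=[4, 4])
        assert res.chi2 == pytest.approx(-20.0)
        assert res.warning is not None


class TestCriticalValues:
    @pytest.mark.parametrize("dof, expected", [(22, 40.29), (26, 45.64)])
    def test_upper_tail_one_percent_quantiles(self, dof, expected):
        assert critical_chi_square(0.99, dof) == pytest.approx(expected, abs=0.005)

    def test_cdf_at_zero_is_zero(self):
        for dof in (1, 5, 22):
            assert chi_square_confidence(0.0, dof) == 0.0

    @given(st.floats(0.5, 0.999), st.integers(1, 40))
    @settings(deadline=None, max_examples=50)
    def test_quantile_and_cdf_are_mutual_inverses(self, conf, dof):
        assert chi_square_confidence(critical_chi_square(conf, dof), dof) == pytest.approx(
            conf, abs=1e-9
        )


@pytest.fixture(scope="module")
def three_period_fits():
    spec, truth = fixed_effects_spec(), fixed_effects_truth()
    cfg = GeneratorConfig(
        truth=truth, spec=spec, seed=101,
        period_profiles={"2017": (800, None), "2018": (800, None), "2019": (800, None)},
    )
    study = generate_study_like(cfg)
    parts = split_dataset(study, by="period")
    fits = {p: fit_mnl(build_design(parts[p], spec), std_errors=False) for p in parts}
    return spec, parts, fits


class TestTransferability:
    def test_self_transfer_statistic_is_zero(self, three_period_fits):
        _, parts, fits = three_period_fits
        res = transferability_test(fits["2017"], parts["2017"], fits["2017"])
        assert res.chi2 == pytest.approx(0.0, abs=1e-8)
        assert res.decision == "fail-to-reject"

    def test_restricted_statistic_nonnegative_in_both_directions(self, three_period_fits):
        _, parts, fits = three_period_fits
        matrix = instability_matrix(fits, parts)
        assert len(matrix) == 6
        assert all(r.chi2 >= 0 for r in matrix.values())

    def test_dof_is_transferred_model_parameter_count(self, three_period_fits):
        _, parts, fits = three_period_fits
        res = transferability_test(fits["2018"], parts["2017"], fits["2017"],
                                   direction=("2017", "2018"))
        assert res.dof == fits["2018"].n_params
        assert res.direction == ("2017", "2018")

    def test_respecify_refit_mode_warns(self, three_period_fits):
        _, parts, fits = three_period_fits
        res = transferability_test(fits["2018"], parts["2017"], fits["2017"],
                                   mode="respecify-refit")
        assert res.warning is not None


class TestMatrixRendering:
    def test_cell_format_round_trip(self):
        value, dof, conf = parse_rendered_cell("1583.938 (12) [>99%]")
        assert value == pytest.approx(1583.938)
        assert dof == 12
        assert conf == pytest.approx(0.99)

    def test_rendered_matrix_diagonal_empty(self, three_period_fits):
        _, parts, fits = three_period_fits
        table = render_instability_matrix(instability_matrix(fits, parts))
        for p in table.index:
            assert table.loc[p, p] == "-"
        off = table.loc["2017", "2018"]
        value, dof, conf = parse_rendered_cell(off)
        assert dof == fits["2018"].n_params

    def test_global_summary_table_shape(self):
        summary = global_test_summary(
            {
                "helmet": {
                    "ll_pooled": -4025.185,
                    "ll_periods": {"2017": -1199.931, "2018": -1258.448, "2019": -1477.467},
                    "params_pooled": 21,
                    "params_periods": {"2017": 17, "2018": 12, "2019": 14},
                },
                "non-helmet": {
                    "ll_pooled": -13641.844,
                    "ll_periods": {"2017": -3477.439, "2018": -4151.247, "2019": -5942.630},
                    "params_pooled": 22,
                    "params_periods": {"2017": 19, "2018": 15, "2019": 14},
                },
            }
        )
        assert list(summary.columns) == ["helmet", "non-helmet"]
        assert summary.loc["chi2", "helmet"] == pytest.approx(178.68, abs=0.005)
        assert summary.loc["chi2", "non-helmet"] == pytest.approx(141.06, abs=0.005)
        assert summary.loc["conclusion", "helmet"] == "temporally unstable"
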