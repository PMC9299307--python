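import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from interactkit import (
    ConfigurationError,
    FactorialDataset,
    SpecificationError,
    build_design,
    ci_overlap_fraction,
    emm_contrasts,
    estimate_emms,
    fit_ols,
    overlap_decisions,
    summarize_cells,
)
from interactkit.synth import EXAMPLE1_MEANS, EXAMPLE1_SIGMA, generate_example2

from conftest import dataset_from_cells, exact_cell_data


@pytest.fixture(scope="module")
def table2_fit():
    """Balanced 2x2 whose cell means and sds are exact: the worked example."""
    cells = exact_cell_data(EXAMPLE1_MEANS, n=50, sd=EXAMPLE1_SIGMA)
    d = dataset_from_cells(cells, factor_names=("group", "stimulus"), response="arousal")
    return d, fit_ols(build_design(d), d)


class TestEstimateEmms:
    def test_balanced_emm_equals_observed_mean_exactly(self, table2_fit):
        d, fit = table2_fit
        emms = estimate_emms(fit)
        for cell, value in zip(emms.cells, emms.emm):
            assert value == pytest.approx(EXAMPLE1_MEANS[cell], abs=1e-10)

    def test_balanced_emm_ses_all_equal_sqrt_mse_over_n(self, table2_fit):
        d, fit = table2_fit
        emms = estimate_emms(fit)
        expected = math.sqrt(fit.mse / 50)
        np.testing.assert_allclose(emms.se, expected, rtol=1e-10)
        # with the residual sd implied by the published observed SEs this
        # rounds to the published estimated-marginal-mean SE
        assert round(expected, 3) == 0.008

    def test_emm_ses_differ_from_observed_ses(self, table2_fit):
        # observed SEs vary with the cell sds; model SEs pool the error term
        d, fit = table2_fit
        rng = np.random.default_rng(0)
        cells = {
            cell: mu + sd * (lambda z: (z - z.mean()) / z.std(ddof=1))(rng.standard_normal(50))
            for (cell, mu), sd in zip(EXAMPLE1_MEANS.items(), [0.07, 0.05, 0.06, 0.035])
        }
        d2 = dataset_from_cells(cells, factor_names=("group", "stimulus"), response="arousal")
        fit2 = fit_ols(build_design(d2), d2)
        emms = estimate_emms(fit2)
        obs_se = {c.cell: c.observed_se for c in summarize_cells(d2)}
        assert np.ptp(emms.se) < 1e-12  # model SEs identical across cells
        assert np.ptp(list(obs_se.values())) > 1e-3  # observed SEs are not
        for cell, se in zip(emms.cells, emms.se):
            assert abs(se - obs_se[cell]) > 1e-4

    def test_ci_width_is_two_t_crit_se(self, example1_fit):
        emms = estimate_emms(example1_fit, level=0.9)
        tcrit = stats.t.ppf(0.95, example1_fit.df_error)
        np.testing.assert_allclose(
            emms.ci_high - emms.ci_low, 2 * tcrit * emms.se, rtol=1e-12
        )
        assert np.all(emms.ci_low < emms.emm) and np.all(emms.emm < emms.ci_high)

    def test_unknown_factor_rejected(self, example1_fit):
        with pytest.raises(ConfigurationError):
            estimate_emms(example1_fit, by=["condition"])

    def test_covariate_emm_is_prediction_at_grand_mean(self):
        # oracle: average the model's predictions by hand over the other
        # factor's levels with the covariate at its mean
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(
            {
                "A": np.repeat(["a", "b"], 20),
                "B": np.tile(np.repeat(["x", "y"], 10), 2),
                "age": rng.uniform(20, 60, 40),
            }
        )
        frame["y"] = (
            1.0
            + 0.5 * (frame["A"] == "a")
            + 0.05 * frame["age"]
            + rng.standard_normal(40) * 0.3
        )
        d = FactorialDataset.from_frame(frame, ["A", "B"], "y", ["age"])
        design = build_design(d)
        fit = fit_ols(design, d)
        emms = estimate_emms(fit, by=["A"])
        for cell, value in zip(emms.cells, emms.emm):
            preds = [
                fit.predict_row(design.row({"A": cell[0], "B": b})) for b in ["x", "y"]
            ]
            assert value == pytest.approx(np.mean(preds), rel=1e-10)

    def test_unbalanced_third_factor_separates_emm_from_observed(self):
        d = generate_example2(seed=1)
        fit = fit_ols(build_design(d), d)
        emms = estimate_emms(fit, by=["group", "stimulus"])
        obs = {c.cell: c.observed_mean for c in summarize_cells(d)}
        # collapse observed means over the working-memory factor
        idx = d.cell_index(["group", "stimulus"])
        y = d.response_values
        gaps = []
        for cell, value in zip(emms.cells, emms.emm):
            observed = y[(idx == cell).to_numpy()].mean()
            gaps.append(abs(observed - value))
        assert max(gaps) > 0.1


class TestCiOverlapFraction:
    def test_identical_intervals(self):
        assert ci_overlap_fraction((0, 1), (0, 1)) == 1.0

    def test_disjoint_and_touching(self):
        assert ci_overlap_fraction((0, 1), (2, 3)) == 0.0
        assert ci_overlap_fraction((0, 1), (1, 2)) == 0.0

    def test_partial_overlap(self):
        assert ci_overlap_fraction((0, 1), (0.8, 1.8)) == pytest.approx(0.2)

    def test_zero_length_intervals(self):
        assert ci_overlap_fraction((1, 1), (1, 1)) == 1.0
        assert ci_overlap_fraction((1, 1), (2, 2)) == 0.0

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError):
            ci_overlap_fraction((1, 0), (0, 1))

    @settings(max_examples=200, derandomize=True)
    @given(
        lo_a=st.floats(-50, 50), len_a=st.floats(0.01, 10),
        lo_b=st.floats(-50, 50), len_b=st.floats(0.01, 10),
        shift=st.floats(-20, 20), scale=st.floats(0.1, 10),
    )
    def test_symmetric_and_shift_scale_invariant(self, lo_a, len_a, lo_b, len_b, shift, scale):
        a = (lo_a, lo_a + len_a)
        b = (lo_b, lo_b + len_b)
        f = ci_overlap_fraction(a, b)
        assert 0.0 <= f <= 1.0
        assert f == ci_overlap_fraction(b, a)
        a2 = (scale * a[0] + shift, scale * a[1] + shift)
        b2 = (scale * b[0] + shift, scale * b[1] + shift)
        assert ci_overlap_fraction(a2, b2) == pytest.approx(f, abs=1e-7)


class TestOverlapDecisions:
    def test_quarter_overlap_boundary_matches_p_near_0_04(self):
        # two equal-SE independent means exactly at the 25% overlap boundary:
        # |diff| = 1.5 * t_crit * se, so t_diff = 1.5 * t_crit / sqrt(2)
        df = 10_000
        se = 1.0
        tcrit = stats.t.ppf(0.975, df)
        d = 1.5 * tcrit * se
        assert ci_overlap_fraction((0, 2 * tcrit * se), (d, d + 2 * tcrit * se)) == pytest.approx(0.25)
        p = 2 * stats.t.sf(d / (se * math.sqrt(2)), df)
        assert p == pytest.approx(0.0376, abs=0.002)

    def test_identical_cells_not_flagged(self):
        d = dataset_from_cells(
            {(a, b): [1.0, 2.0, 3.0] for a in "ab" for b in "xy"}
        )
        fit = fit_ols(build_design(d), d)
        decisions = overlap_decisions(estimate_emms(fit))
        assert len(decisions) == 6
        assert not any(dec.flagged for dec in decisions)
        assert all(dec.overlap_fraction == 1.0 for dec in decisions)

    def test_example1_truth_flags_all_pairs(self, table2_fit):
        # at the worked example's ground truth every cell pair separates:
        # the control group sits above the lesion group for both stimuli
        d, fit = table2_fit
        decisions = overlap_decisions(estimate_emms(fit))
        assert all(dec.flagged for dec in decisions)

    def test_flag_matches_threshold_definition(self, example1_fit):
        for dec in overlap_decisions(estimate_emms(example1_fit), threshold=0.4):
            assert dec.flagged == (dec.overlap_fraction < 0.4)


class TestEmmContrasts:
    def test_identical_cells_give_zero_estimate_p_one(self):
        d = dataset_from_cells({(a, b): [1.0, 2.0] for a in "ab" for b in "xy"})
        fit = fit_ols(build_design(d), d)
        out = emm_contrasts(fit, [(("a", "x"), (("b", "x")))])
        assert out["estimate"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_balanced_pair_t_equals_pooled_model_t_oracle(self, example1_fit):
        emms = estimate_emms(example1_fit)
        pair = (emms.cells[0], emms.cells[1])
        out = emm_contrasts(example1_fit, [pair])
        # oracle: difference of cell means over sqrt(2*mse/n), df = N - p
        i, j = emms.cells.index(pair[0]), emms.cells.index(pair[1])
        t_oracle = (emms.emm[i] - emms.emm[j]) / math.sqrt(2 * example1_fit.mse / 50)
        assert out["t"].iloc[0] == pytest.approx(t_oracle, rel=1e-10)
        assert out["df"].iloc[0] == example1_fit.df_error

    def test_one_vs_rest_contrast_accepted(self, example1_fit):
        out = emm_contrasts(example1_fit, [[1.0, -1 / 3, -1 / 3, -1 / 3]])
        assert len(out) == 1
        assert np.isfinite(out["estimate"].iloc[0])

    def test_nonzero_sum_contrast_rejected(self, example1_fit):
        with pytest.raises(SpecificationError, match="sum to zero"):
            emm_contrasts(example1_fit, [[1.0, 1.0, -1.0, 0.0]])

    def test_correction_applied_over_family(self, example1_fit):
        emms = estimate_emms(example1_fit)
        pairs = [(a, b) for k, a in enumerate(emms.cells) for b in emms.cells[k + 1:]]
        out = emm_contrasts(example1_fit, pairs, correction="bonferroni")
        np.testing.assert_allclose(
            out["p_adj"], np.minimum(1.0, out["p_raw"] * len(pairs)), rtol=1e-12
        )
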