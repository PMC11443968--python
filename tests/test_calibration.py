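"""Grid-search calibration and mixed-effects pooling."""

import warnings

import numpy as np
import pandas as pd
import pytest

from ceimerge import (Condition, GridSpec, build_grid, fit_incentive,
                      grid_response_lookup, match_trial_thresholds,
                      single_driver_response, synth_participants)
from ceimerge.defaults import LAMBDA_U


class TestBuildGrid:
    def test_cell_count_and_corners(self):
        grid = build_grid()
        assert len(grid) == 625
        assert (0.01, 0.3) in grid
        assert (0.4, 0.9) in grid

    def test_axis_spacing(self):
        spec = GridSpec()
        du = np.diff(spec.upper_values)
        dl = np.diff(spec.lower_values)
        assert du == pytest.approx((0.9 - 0.3) / 24)
        assert dl == pytest.approx((0.4 - 0.01) / 24)


class TestSingleDriverResponse:
    def test_deterministic(self):
        cond = Condition.from_label("0_0")
        a = single_driver_response(cond, 0.058, 0.488)
        b = single_driver_response(cond, 0.058, 0.488)
        assert a == b

    def test_high_threshold_driver_barely_responds(self):
        # a near-maximal upper threshold never trips within the first second;
        # the only deviation left is the small drag-induced drift
        dev = single_driver_response(Condition.from_label("2_0"), 0.01, 0.9)
        assert abs(dev) < 0.15

    def test_low_threshold_driver_brakes_hard(self):
        dev = single_driver_response(Condition.from_label("0_0"), 0.058, 0.35)
        assert dev < -0.5

    def test_deviation_magnitude_monotone_in_theta_u(self):
        spec = GridSpec()
        cond = Condition.from_label("0_0")
        col = [abs(single_driver_response(cond, 0.058, tu))
               for tu in spec.upper_values]
        assert all(b <= a + 1e-9 for a, b in zip(col, col[1:]))

    def test_right_side_uses_mirrored_scene(self):
        cond = Condition.from_label("4_0")
        left = single_driver_response(cond, 0.058, 0.488, side="left")
        right = single_driver_response(Condition.from_label("-4_0"),
                                       0.058, 0.488, side="right")
        assert left == pytest.approx(right)


class TestGridLookupAndMatching:
    @pytest.fixture(scope="class")
    def lookup(self):
        # a reduced 7x7 grid keeps this a unit test; the full 625-cell grid is
        # exercised in the acceptance suite
        grid = build_grid(GridSpec(n=7))
        return grid_response_lookup(Condition.from_label("0_0"), grid)

    def test_invalid_cells_are_nan(self, lookup):
        bad = lookup[lookup.theta_l >= lookup.theta_u]
        assert bad.deviation.isna().all()
        assert lookup.deviation.notna().sum() > 30

    def test_exact_match_returns_that_cell(self, lookup):
        row = lookup.dropna().iloc[10]
        # perturb within float tolerance: still an exact winner
        tl, tu = match_trial_thresholds(row.deviation, lookup)
        matched = lookup[(lookup.theta_l == tl) & (lookup.theta_u == tu)]
        assert matched.deviation.iloc[0] == pytest.approx(row.deviation,
                                                          abs=1e-12)

    def test_tie_breaks_to_most_passive_cell(self, lookup):
        # many cells never trigger and share the drift deviation; the match
        # must return the largest theta_u (then theta_l) among them
        drift = lookup.dropna().deviation.max()
        tl, tu = match_trial_thresholds(drift, lookup)
        ties = lookup.dropna()
        ties = ties[np.abs(ties.deviation - drift) <= 1e-12]
        assert tu == ties.theta_u.max()
        assert tl == ties[ties.theta_u == tu].theta_l.max()

    def test_grid_cell_round_trip(self, lookup):
        # a deviation generated from a known cell is matched to a cell with
        # an identical response (identifiable up to response plateaus)
        for _, row in lookup.dropna().iloc[::9].iterrows():
            tl, tu = match_trial_thresholds(row.deviation, lookup)
            matched_dev = lookup[(lookup.theta_l == tl)
                                 & (lookup.theta_u == tu)].deviation.iloc[0]
            assert matched_dev == pytest.approx(row.deviation, abs=1e-12)


class TestSynthParticipants:
    def test_shape_and_determinism(self):
        conds = [Condition.from_label("0_0"), Condition.from_label("4_0")]
        df = synth_participants([(0.06, 0.45), (0.2, 0.6)], conds, reps=2,
                                seed=3)
        assert len(df) == 2 * 2 * 2
        assert set(df.columns) == {"participant", "side", "condition", "rep",
                                   "deviation_at_1s"}
        # noise off: repetitions of a condition are identical
        per = df.groupby(["participant", "condition"]).deviation_at_1s.nunique()
        assert (per == 1).all()

    def test_noise_makes_repetitions_differ(self):
        conds = [Condition.from_label("0_0")]
        df = synth_participants([(0.06, 0.5)], conds, reps=4, seed=3,
                                noise=True)
        assert df.deviation_at_1s.nunique() > 1


class TestFitIncentive:
    def _synthetic_estimates(self, thetas, lam, noise_sd, seed=0,
                             n_reps=6):
        rng = np.random.default_rng(seed)
        rows = []
        for pid, th in enumerate(thetas):
            for dp in (-4.0, -2.0, 0.0, 2.0, 4.0):
                for dv in (-0.8, 0.0, 0.8):
                    for _ in range(n_reps):
                        mean = (th + lam[0] * dp + lam[1] * dv
                                + lam[2] * dp * dv)
                        val = mean + noise_sd * rng.standard_normal()
                        rows.append((pid, dp, dv, val - 0.3, val))
        return pd.DataFrame(rows, columns=["participant", "dp", "dv",
                                           "theta_l", "theta_u"])

    def test_constant_estimates_give_zero_slopes(self):
        df = self._synthetic_estimates([0.45, 0.55, 0.62], (0, 0, 0), 0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_incentive(df)
        assert max(abs(l) for l in fit.lambda_u) < 1e-8
        assert fit.participant_thetas.theta_u.values == pytest.approx(
            [0.45, 0.55, 0.62], abs=5e-3)

    def test_slope_recovery_within_two_se(self):
        df = self._synthetic_estimates([0.45, 0.5, 0.55, 0.6, 0.65],
                                       LAMBDA_U, 0.02, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_incentive(df)
        for got, se, true in zip(fit.lambda_u, fit.se_u, LAMBDA_U):
            assert abs(got - true) <= 2 * se

    def test_balanced_design_equals_ols(self):
        import statsmodels.formula.api as smf
        df = self._synthetic_estimates([0.5, 0.6], (0.003, 0.018, -0.006),
                                       0.01, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_incentive(df)
            ols = smf.ols("theta_u ~ dp * dv", df).fit()
        assert fit.lambda_u[0] == pytest.approx(ols.params["dp"], abs=1e-6)
        assert fit.lambda_u[1] == pytest.approx(ols.params["dv"], abs=1e-6)
        assert fit.lambda_u[2] == pytest.approx(ols.params["dp:dv"], abs=1e-6)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            fit_incentive(pd.DataFrame({"participant": [0, 1]}))
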