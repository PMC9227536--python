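"""Noncompartmental analysis and fold-error metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbpkcat.nca import (aafe, caafe, fold_errors, nca, outlier_percentages,
                         resample_profile, validate_prediction)
from pbpkcat.pbpk import DoseEvent, simulate


class TestNca:
    def test_monoexponential_closed_form(self):
        k, c0, t0 = 0.5, 10.0, 0.01
        t = np.linspace(t0, 30.0, 2000)
        c = c0 * np.exp(-k * t)
        res = nca(t, c, dose_mg=5.0, iv=True)
        # analytic area over the sampled window [t0, inf)
        auc = c0 / k * np.exp(-k * t0)
        assert res.auc_inf == pytest.approx(auc, rel=1e-6)
        assert res.t_half == pytest.approx(np.log(2) / k, rel=1e-6)
        assert res.clp == pytest.approx(5.0 / auc, rel=1e-6)
        # one-compartment: moment Vss = CL / k (small t0 truncation bias)
        assert res.vss == pytest.approx(res.clp / k, rel=6e-3)
        assert res.cmax == pytest.approx(c[0])
        assert res.tmax == pytest.approx(t[0])

    def test_sparse_design_still_accurate(self):
        t = np.array([0.167, 0.33, 0.5, 1.0, 2.0, 4.0, 8.0])
        c = 10.0 * np.exp(-0.5 * t)
        res = nca(t, c, dose_mg=5.0)
        # log-down trapezoid is exact on a monoexponential decline
        assert res.auc_inf == pytest.approx(
            20.0 - 10.0 / 0.5 * (1 - np.exp(-0.5 * 0.167)), rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            nca([1.0], [2.0])

    def test_flat_terminal_phase_warns_and_leaves_auc_inf_unset(self):
        with pytest.warns(UserWarning, match="terminal"):
            res = nca([1, 2, 3, 4], [1.0, 1.0, 1.0, 1.0])
        assert res.auc_inf is None
        assert res.auc_last == pytest.approx(3.0)

    def test_recovers_model_clearance_and_vss(self, dog_model, iv_grid):
        dose = DoseEvent(route="iv_bolus", amount=10.0, per_kg=True)
        prof = simulate(dog_model, [dose], t_eval=iv_grid(48.0, 1200))
        res = nca(prof.times[1:], prof.plasma[1:], dose_mg=100.0, iv=True)
        assert res.clp == pytest.approx(dog_model.clp, rel=0.02)
        # hepatic elimination is peripheral, so moment Vss sits slightly
        # below the composite volume
        assert res.vss == pytest.approx(dog_model.vss_l(), rel=0.05)


class TestFoldErrors:
    def test_identity_and_scaling(self):
        np.testing.assert_allclose(fold_errors([1, 2, 3], [1, 2, 3]), 1.0)
        np.testing.assert_allclose(fold_errors([2, 4], [1, 2]), 2.0)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="resample"):
            fold_errors([1, 2, 3], [1, 2])

    def test_resample_helper_is_loglinear(self):
        t = np.array([0.0, 1.0, 2.0])
        c = np.array([8.0, 4.0, 2.0])
        out = resample_profile(t, c, np.array([0.5, 1.5]))
        np.testing.assert_allclose(out, [8 / np.sqrt(2), 4 / np.sqrt(2)])


class TestAafe:
    @pytest.mark.parametrize("ratios,expected", [
        ([1.0, 1.0, 1.0], 1.0),
        ([2.0, 0.5], 2.0),
        ([10.0], 10.0),
    ])
    def test_reference_values(self, ratios, expected):
        assert aafe(ratios) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.floats(min_value=0.01, max_value=100.0),
                    min_size=1, max_size=20))
    def test_reciprocal_symmetry_and_floor(self, ratios):
        a = aafe(ratios)
        assert a >= 1.0 - 1e-12
        assert aafe([1.0 / r for r in ratios]) == pytest.approx(a, rel=1e-9)

    def test_unity_only_for_perfect_prediction(self):
        assert aafe([1.0] * 5) == 1.0
        assert aafe([1.0, 1.01]) > 1.0

    def test_caafe_pools_points(self):
        arms = [[2.0, 2.0], [1.0, 1.0, 1.0, 1.0]]
        # pooled: mean of |log| over six points
        assert caafe(arms) == pytest.approx(10 ** (2 * np.log10(2) / 6))
        # arm-averaging alternative
        assert caafe(arms, pool_points=False) == pytest.approx(np.sqrt(2))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aafe([])
        with pytest.raises(ValueError):
            caafe([])


class TestOutliers:
    def test_counting(self):
        assert outlier_percentages([1.0] * 4) == (0.0, 0.0)
        ratios = [1.0] * 7 + [2.5]
        assert outlier_percentages(ratios) == (12.5, 0.0)
        assert outlier_percentages([4.0] * 3) == (100.0, 100.0)

    def test_boundaries_are_inclusive(self):
        assert outlier_percentages([2.0, 0.5, 3.0, 1 / 3]) == (50.0, 0.0)

    def test_validation_report_flags(self):
        good = validate_prediction([[1.1, 0.9, 1.2]], [[1.0, 1.0, 1.0]])
        assert good.acceptable
        bad = validate_prediction([[4.0, 4.0]], [[1.0, 1.0]])
        assert not bad.acceptable_twofold
        assert not bad.acceptable_threefold
        assert not bad.acceptable_aafe
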