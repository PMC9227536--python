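"""In-vitro assay math: depletion fits, permeability, binding, partitioning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbpkcat.invitro import (BindingAssay, DepletionCourse, InvalidAssayError,
                             TransportAssay, calc_bp, calc_clblood,
                             calc_clint_hep, calc_clint_mic, calc_efflux_ratio,
                             calc_fraction_unbound, calc_papp,
                             fit_first_order_k)


def _course(times, concs, matrix="microsome"):
    return DepletionCourse(matrix=matrix, times=tuple(times),
                           concentrations=tuple(concs))


class TestDepletionFit:
    def test_flat_course_gives_zero_rate(self):
        k, r2 = fit_first_order_k(_course([0, 15, 30, 45], [2.0] * 4))
        assert k == pytest.approx(0.0, abs=1e-12)

    def test_exact_exponential_recovered(self):
        t = np.array([0.0, 15.0, 30.0, 45.0])
        k, r2 = fit_first_order_k(_course(t, np.exp(-0.036 * t)))
        assert k == pytest.approx(0.036, rel=1e-12)
        assert r2 == pytest.approx(1.0)

    @pytest.mark.parametrize("times,concs", [
        ((0, 60), (1.0, 0.5)),                    # too few points
        ((0, 30, 60), (1.0, 0.5, -0.1)),          # non-positive concentration
        ((0, 30, 30), (1.0, 0.5, 0.3)),           # non-increasing times
        ((10, 30, 60), (1.0, 0.5, 0.3)),          # first point not zero
    ])
    def test_invalid_courses_rejected(self, times, concs):
        with pytest.raises(InvalidAssayError):
            _course(times, concs)

    def test_noisy_course_warns_on_poor_linearity(self):
        with pytest.warns(UserWarning, match="log-linear"):
            fit_first_order_k(_course([0, 10, 20, 30], [1.0, 0.2, 0.9, 0.15]))

    @settings(derandomize=True, max_examples=30)
    @given(k=st.floats(min_value=0.0, max_value=1.0))
    def test_exponential_recovery_property(self, k):
        t = np.array([0.0, 5.0, 12.0, 25.0, 40.0])
        fitted, _ = fit_first_order_k(_course(t, 3.0 * np.exp(-k * t)))
        assert fitted == pytest.approx(k, rel=1e-9, abs=1e-12)


class TestPermeability:
    def _assay(self, amounts, c0=10.0, area=1.12, times=(0, 1800, 3600)):
        return TransportAssay(direction="a2b", c0=c0, area_cm2=area,
                              times_s=tuple(times),
                              receiver_amounts=tuple(amounts))

    def test_no_transport_gives_zero(self):
        assert calc_papp(self._assay([0.0, 0.0, 0.0])) == 0.0

    def test_hand_computed_example(self):
        # 0.1 nmol gained per 1800 s at C0 = 10 nmol/mL, A = 1.12 cm^2
        papp = calc_papp(self._assay([0.0, 0.1, 0.2]))
        assert papp == pytest.approx((0.1 / 1800) / (10 * 1.12), rel=1e-12)

    def test_linearity_in_slope_and_inverse_in_c0_area(self):
        base = calc_papp(self._assay([0.0, 0.1, 0.2]))
        assert calc_papp(self._assay([0.0, 0.2, 0.4])) == pytest.approx(2 * base)
        assert calc_papp(self._assay([0.0, 0.1, 0.2], c0=20)) == pytest.approx(base / 2)
        assert calc_papp(self._assay([0.0, 0.1, 0.2], area=2.24)) == pytest.approx(base / 2)

    def test_decreasing_amounts_warn_and_return_zero(self):
        with pytest.warns(UserWarning, match="non-positive"):
            assert calc_papp(self._assay([0.2, 0.1, 0.0])) == 0.0

    def test_efflux_ratio(self):
        assert calc_efflux_ratio(31.2e-6, 31.2e-6) == pytest.approx(1.0)
        assert calc_efflux_ratio(10.0, 5.0) == pytest.approx(2.0)
        # measured Caco-2 pair: no meaningful active efflux
        assert calc_efflux_ratio(49.5e-6, 31.2e-6) == pytest.approx(1.587, abs=5e-4)
        with pytest.raises(InvalidAssayError):
            calc_efflux_ratio(1.0, 0.0)


class TestBinding:
    def test_fraction_unbound(self):
        assert calc_fraction_unbound(
            BindingAssay(buffer_chamber=1.0, sample_chamber=1.0)) == 1.0
        assert calc_fraction_unbound(
            BindingAssay(buffer_chamber=0.0, sample_chamber=1.0)) == 0.0
        fu = calc_fraction_unbound(
            BindingAssay(buffer_chamber=0.0582 * 5.0, sample_chamber=5.0))
        assert fu == pytest.approx(0.0582)

    def test_equilibrium_failure_warns(self):
        with pytest.warns(UserWarning, match="equilibrium"):
            fu = calc_fraction_unbound(
                BindingAssay(buffer_chamber=1.2, sample_chamber=1.0))
        assert fu == 1.0

    def test_blood_to_plasma_ratio(self):
        assert calc_bp(BindingAssay(c_plasma_ref=2.0, c_plasma=2.0)) == 1.0
        assert calc_bp(BindingAssay(c_plasma_ref=1.24, c_plasma=1.0)) == pytest.approx(1.24)
        with pytest.raises(InvalidAssayError):
            calc_bp(BindingAssay(c_plasma_ref=1.0, c_plasma=0.0))


class TestIntrinsicClearance:
    def test_zero_rate_gives_zero_clearance(self):
        assert calc_clint_mic(0.0, 1000.0, 0.5) == 0.0
        assert calc_clint_hep(0.0, 1000.0, 0.5) == 0.0

    def test_hand_arithmetic(self):
        # 0.5 mg/mL protein -> volume/protein = 2000 uL/mg
        assert calc_clint_mic(0.036, 1000.0, 0.5) == pytest.approx(72.0)
        assert calc_clint_mic(0.01, 1000.0, 0.5) == pytest.approx(20.0)
        # 1 mL at 0.5e6 cells/mL
        assert calc_clint_hep(0.01, 1000.0, 0.5) == pytest.approx(20.0)

    def test_clblood_linearity_and_composition(self):
        assert calc_clblood(0.0, 0.0131, 1.56) == 0.0
        base = calc_clblood(0.5, 0.0131, 1.56)
        assert calc_clblood(1.0, 0.0131, 1.56) == pytest.approx(2 * base)
        # rat blood clearance: 13.1 mL blood per 200 g, B:P 1.56
        k = 0.0430 * 0.2 / (0.0131 * 1.56)
        assert calc_clblood(k, 0.0131, 1.56) / 0.2 == pytest.approx(0.0430)
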