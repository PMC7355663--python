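"""Unbound-fraction prediction and binding-class tests."""

import numpy as np
import pytest

from melbind.models import SipsParameters
from melbind.prediction import (
    BindingClass,
    cassette_correction,
    classify_fu,
    classify_kd,
    dilution_scale,
    fraction_unbound_sips,
)


class TestMassBalanceUnboundFraction:
    def test_strong_binder_in_vitro(self, chloroquine_sips):
        fu = fraction_unbound_sips(chloroquine_sips, melanin_conc=1.0, total_conc=1.0)
        assert fu == pytest.approx(0.41, abs=0.01)

    def test_strong_binder_at_tissue_melanin(self, chloroquine_sips):
        fu = fraction_unbound_sips(chloroquine_sips, melanin_conc=34.8, total_conc=1.0)
        assert fu == pytest.approx(0.0012, abs=0.0001)

    def test_no_melanin_means_fully_unbound(self, chloroquine_sips):
        assert fraction_unbound_sips(chloroquine_sips, 0.0, 1.0) == 100.0

    def test_monotone_decreasing_in_melanin(self, papaverine_sips):
        fus = [
            fraction_unbound_sips(papaverine_sips, m, 1.0)
            for m in (0.0, 0.5, 1.0, 5.0, 34.8)
        ]
        assert all(a > b for a, b in zip(fus, fus[1:]))

    def test_mass_balance_closes(self, papaverine_sips):
        from melbind.models import sips_bound

        total, melanin = 1.0, 34.8
        fu = fraction_unbound_sips(papaverine_sips, melanin, total)
        free = fu / 100.0 * total
        assert free + melanin * sips_bound(free, papaverine_sips) == pytest.approx(total, rel=1e-9)

    def test_agrees_with_dilution_scaling_in_linear_regime(self):
        # n = 1 and L << Kd: binding is linear, so the two routes coincide
        params = SipsParameters(kd=500.0, bmax=20.0, n=1.0)
        total = 1e-3
        fu1 = fraction_unbound_sips(params, 1.0, total)
        fu2 = fraction_unbound_sips(params, 34.8, total)
        assert dilution_scale(fu1, 34.8) == pytest.approx(fu2, rel=1e-4)

    def test_invalid_inputs_rejected(self, chloroquine_sips):
        with pytest.raises(ValueError):
            fraction_unbound_sips(chloroquine_sips, -1.0, 1.0)
        with pytest.raises(ValueError):
            fraction_unbound_sips(chloroquine_sips, 1.0, 0.0)


class TestDilutionScaling:
    def test_reference_case(self):
        assert dilution_scale(9.2, 34.8) == pytest.approx(0.29, abs=0.01)

    def test_non_binder_unaffected(self):
        assert dilution_scale(100.0, 34.8) == pytest.approx(100.0)

    def test_unit_dilution_is_identity(self):
        assert dilution_scale(37.5, 1.0) == pytest.approx(37.5)

    def test_round_trip_inverse(self):
        fu = 9.2
        assert dilution_scale(dilution_scale(fu, 34.8), 1 / 34.8) == pytest.approx(fu)

    def test_fully_bound_rejected(self):
        with pytest.raises(ValueError):
            dilution_scale(0.0, 34.8)


class TestCassetteCorrection:
    def test_divides_by_factor(self):
        assert cassette_correction(21.0) == pytest.approx(10.0)

    def test_unit_factor_is_identity(self):
        assert cassette_correction(19.3, factor=1.0) == pytest.approx(19.3)

    def test_chains_to_reported_single_compound_value(self):
        # 19.3% cassette unbound fraction corrects to ~9.2% single-compound
        assert cassette_correction(19.3) == pytest.approx(9.19, abs=0.01)

    def test_factor_below_one_rejected(self):
        with pytest.raises(ValueError):
            cassette_correction(10.0, factor=0.5)


class TestClassification:
    @pytest.mark.parametrize(
        "kd, expected",
        [
            (0.8, BindingClass.EXTREME),
            (28.0, BindingClass.HIGH),
            (214.0, BindingClass.INTERMEDIATE),
            (912.0, BindingClass.LOW),
            # boundary values join the weaker-binding class
            (6.5, BindingClass.HIGH),
            (65.0, BindingClass.INTERMEDIATE),
            (650.0, BindingClass.LOW),
        ],
    )
    def test_kd_tiers(self, kd, expected):
        assert classify_kd(kd) is expected

    @pytest.mark.parametrize(
        "fu, expected",
        [
            (0.0012, BindingClass.EXTREME),
            (0.33, BindingClass.HIGH),
            (5.7, BindingClass.INTERMEDIATE),
            (54.0, BindingClass.LOW),
            (0.1, BindingClass.HIGH),
            (1.0, BindingClass.INTERMEDIATE),
            (10.0, BindingClass.LOW),
        ],
    )
    def test_fu_tiers(self, fu, expected):
        assert classify_fu(fu) is expected

    def test_tier_systems_are_consistent_through_the_regression_slope(self):
        # Kd = 65 * fu maps fu boundaries onto Kd boundaries; classes agree
        # for values away from the boundaries
        for fu in np.logspace(-2, 1.8, 25):
            kd = 65.0 * fu
            if any(abs(fu - b) / b < 0.05 for b in (0.1, 1.0, 10.0)):
                continue
            assert classify_kd(kd) is classify_fu(fu)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_kd(0.0)
        with pytest.raises(ValueError):
            classify_fu(101.0)
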