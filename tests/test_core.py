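"""Closed-form single/split-dose survival and its microdosimetric inputs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import imksurv as ik
from imksurv.core import KEV_TO_JOULE


class TestGammaCoefficient:
    def test_reference_xray_value(self, ctx):
        # 4.68 keV/um in 0.5-um water domains -> 0.954 Gy (0.2%)
        assert ik.gamma_coefficient(ctx) == pytest.approx(0.954, rel=2e-3)
        assert ik.gamma_coefficient(ctx) == pytest.approx(0.9547, abs=1e-4)

    def test_unit_conversion_oracle(self):
        # independent hand conversion at y_D = 2 keV/um
        expected = 2.0 * KEV_TO_JOULE / (math.pi * 0.25 * 1e-12) * 1e3
        got = ik.gamma_coefficient(ik.MicrodosimetricContext(y_D=2.0))
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.4080, abs=1e-4)

    def test_inverse_square_scaling_in_domain_radius(self, ctx):
        doubled = ik.MicrodosimetricContext(y_D=ctx.y_D, rho=ctx.rho, r_d=2 * ctx.r_d)
        assert ik.gamma_coefficient(doubled) * 4 == pytest.approx(
            ik.gamma_coefficient(ctx), rel=1e-14
        )

    @pytest.mark.parametrize("bad", [{"y_D": 0.0}, {"rho": -1.0}, {"r_d": 0.0}])
    def test_nonpositive_fields_rejected(self, bad):
        with pytest.raises(ik.InvalidContextError):
            ik.MicrodosimetricContext(**bad)


class TestLeaCatcheside:
    def test_acute_limit_is_one(self):
        assert ik.lea_catcheside_factor(1.279, 0.0) == 1.0
        assert ik.lea_catcheside_factor(50.0, 0.0) == 1.0

    def test_series_branch_continuity(self):
        # series branch below x = 1e-6 joins the closed form smoothly: the
        # jump across the switch is far smaller than the function's own change
        below = ik.lea_catcheside_factor(1.0, 1e-6 - 1e-12)
        above = ik.lea_catcheside_factor(1.0, 1e-6 + 1e-12)
        assert abs(above - below) < 1e-9

    def test_one_hour_delivery(self):
        assert ik.lea_catcheside_factor(1.279, 1.0) == pytest.approx(0.6813, abs=1e-4)

    def test_long_delivery_asymptote(self):
        # F -> 2/x * (1 - 1/x) with x = (a+c) T
        x = 200.0
        F = ik.lea_catcheside_factor(2.0, 100.0)
        assert F == pytest.approx(2.0 / x * (1.0 - 1.0 / x), abs=1e-6)
        assert F == pytest.approx(0.00990, abs=1e-4)

    def test_strictly_decreasing_and_bounded(self):
        times = np.linspace(0.0, 50.0, 401)
        vals = [ik.lea_catcheside_factor(1.5, t) for t in times]
        assert all(0 < v <= 1 for v in vals)
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_f_times_t_long_time_limit(self):
        # F*T -> 2/(a+c) as T grows
        rate = 1.7
        for T in (1e3, 1e4, 1e5):
            assert ik.lea_catcheside_factor(rate, T) * T == pytest.approx(
                2.0 / rate, rel=2.0 / (rate * T)
            )

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            ik.lea_catcheside_factor(1.0, -0.1)


class TestSingleDose:
    def test_sas_progeny_2gy_acute(self, sas_progeny, gamma):
        burden = ik.neg_log_survival_single(sas_progeny, 0.954, 2.0)
        assert burden == pytest.approx(0.67595, abs=1e-5)
        assert math.exp(-burden) == pytest.approx(0.5087, abs=1e-4)

    def test_zero_dose_survives_fully(self, sas_progeny, gamma):
        assert ik.neg_log_survival_single(sas_progeny, gamma, 0.0) == 0.0

    def test_protraction_spares(self, sas_progeny, gamma):
        acute = ik.neg_log_survival_single(sas_progeny, gamma, 10.0, T=0.0)
        slow = ik.neg_log_survival_single(sas_progeny, gamma, 10.0, T=10.0 / 0.6)
        assert slow < acute

    def test_monotone_in_dose(self, sas_progeny, gamma):
        doses = np.linspace(0, 15, 61)
        burdens = [ik.neg_log_survival_single(sas_progeny, gamma, d) for d in doses]
        assert all(b2 >= b1 for b1, b2 in zip(burdens, burdens[1:]))

    def test_negative_dose_rejected(self, sas_progeny, gamma):
        with pytest.raises(ValueError):
            ik.neg_log_survival_single(sas_progeny, gamma, -1.0)


class TestSplitDose:
    def test_zero_interval_collapses_to_acute(self, sas_progeny):
        split = ik.neg_log_survival_split(sas_progeny, 0.954, 2.0, 2.0, 0.0)
        acute = ik.neg_log_survival_single(sas_progeny, 0.954, 4.0)
        assert split == pytest.approx(acute, rel=1e-14)
        assert split == pytest.approx(1.70390, abs=1e-5)

    def test_infinite_interval_independent_fractions(self, sas_progeny):
        split = ik.neg_log_survival_split(sas_progeny, 0.954, 2.0, 2.0, 1e6)
        single = ik.neg_log_survival_single(sas_progeny, 0.954, 2.0)
        assert split == pytest.approx(2 * single, abs=1e-9)
        assert split == pytest.approx(1.35190, abs=1e-5)

    def test_three_hour_interval(self, sas_progeny):
        burden = ik.neg_log_survival_split(sas_progeny, 0.954, 2.0, 2.0, 3.0)
        assert burden == pytest.approx(1.35949, abs=1e-5)
        assert math.exp(-burden) == pytest.approx(0.2568, abs=2e-4)

    def test_monotone_recovery_with_interval(self, sas_progeny, gamma):
        taus = np.linspace(0, 24, 49)
        burdens = [
            ik.neg_log_survival_split(sas_progeny, gamma, 2, 2, t) for t in taus
        ]
        assert all(b2 < b1 for b1, b2 in zip(burdens, burdens[1:]))

    def test_negative_interval_rejected(self, sas_progeny, gamma):
        with pytest.raises(ValueError):
            ik.neg_log_survival_split(sas_progeny, gamma, 2, 2, -1.0)


class TestResistantProgenyDerivation:
    def test_hsc2_family_scaling(self):
        parent = ik.PopulationParams(0.166, 0.168, 1.499)
        derived = ik.derive_resistant_progeny(parent, 1.896)
        assert round(derived.alpha0, 3) == 0.088
        assert round(derived.beta0, 3) == 0.089
        assert round(derived.repair_rate, 3) == 2.842

    def test_sas_family_scaling_within_rounding(self, sas_progeny):
        derived = ik.derive_resistant_progeny(sas_progeny, 1.059)
        assert derived.alpha0 == pytest.approx(0.197, abs=1e-3)

    def test_unity_factor_is_identity(self, sas_progeny):
        assert ik.derive_resistant_progeny(sas_progeny, 1.0) is sas_progeny

    def test_alpha_beta_ratio_preserved(self, sas_progeny):
        derived = ik.derive_resistant_progeny(sas_progeny, 1.7)
        assert derived.alpha0 / derived.beta0 == pytest.approx(
            sas_progeny.alpha0 / sas_progeny.beta0, rel=1e-12
        )

    def test_nonpositive_factor_rejected(self, sas_progeny):
        with pytest.raises(ValueError):
            ik.derive_resistant_progeny(sas_progeny, 0.0)


class TestMixtureSurvival:
    @pytest.mark.parametrize(
        "Sp, Ss, fs, expected",
        [
            (0.1, 0.3, 0.5, 0.2),
            (0.01, 0.5, 0.012, 0.01588),
            (0.42, 0.9, 0.0, 0.42),
            (0.42, 0.9, 1.0, 0.9),
        ],
    )
    def test_weighted_sum(self, Sp, Ss, fs, expected):
        assert ik.mixture_survival(Sp, Ss, fs) == pytest.approx(expected, rel=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        Sp=st.floats(0.0, 1.0),
        Ss=st.floats(0.0, 1.0),
        fs=st.floats(0.0, 1.0),
    )
    def test_affine_and_bounded(self, Sp, Ss, fs):
        S = ik.mixture_survival(Sp, Ss, fs)
        assert min(Sp, Ss) - 1e-15 <= S <= max(Sp, Ss) + 1e-15
        # affine in f_s: midpoint of the f_s endpoints
        mid = 0.5 * (ik.mixture_survival(Sp, Ss, 0.0) + ik.mixture_survival(Sp, Ss, 1.0))
        assert ik.mixture_survival(Sp, Ss, 0.5) == pytest.approx(mid, abs=1e-12)

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError):
            ik.mixture_survival(0.5, 0.5, 1.2)


class TestTwoPopulationModel:
    def test_stem_repair_tie_enforced(self, sas_family):
        model = sas_family.parent_model()
        assert model.stem.repair_rate == pytest.approx(
            model.w_sldr * model.progeny.repair_rate, rel=1e-12
        )
        bad_stem = ik.PopulationParams(0.074, 0.027, 9.9)
        with pytest.raises(ValueError, match="stem repair rate"):
            ik.TwoPopulationModel(model.progeny, bad_stem, f_s=0.01, w_sldr=1.059)

    def test_resistant_sibling_uses_enhanced_progeny(self, sas_family):
        resistant = sas_family.resistant_model()
        eff = resistant.effective_progeny
        assert eff.alpha0 == pytest.approx(0.208 / 1.059, rel=1e-12)
        assert eff.repair_rate == pytest.approx(1.059 * 1.279, rel=1e-12)
        # non-resistant branch leaves progeny untouched
        assert sas_family.parent_model().effective_progeny.alpha0 == 0.208
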