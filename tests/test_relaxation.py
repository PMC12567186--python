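"""Temperature laws: Arrhenius, VFT, glass transition, fragility, map logic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dielrelax.relaxation import (
    F_TG,
    LN10,
    R_GAS,
    NoCrossingError,
    VFTFit,
    build_relaxation_map,
    dielectric_tg_crossing,
    fit_arrhenius,
    fit_vft,
    fragility_from_vft,
    tg_from_vft,
    tg_kelvin_from_vft,
)

# Published VFT triples with their tabulated Tg (degC) and fragility m
PUBLISHED_VFT = [
    (10.03, 2529.0, 144.5, -43.0, 34.5),
    (12.90, 3168.0, 70.75, -114.7, 28.4),
    (6.03, 933.7, 306.4, 79.2, 67.7),
    (6.20, 467.1, 305.5, 54.9, 130.9),
    (4.76, 228.8, 396.9, 136.9, 235.7),
]


class TestArrhenius:
    def test_two_point_closed_form(self):
        fit = fit_arrhenius([(200.0, 1e2), (250.0, 1e4)])
        expected_ea = 2.0 * LN10 * R_GAS / (1.0 / 200.0 - 1.0 / 250.0) / 1e3
        assert fit.Ea == pytest.approx(expected_ea, rel=1e-12)
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-12)
        assert expected_ea == pytest.approx(38.289, abs=0.01)

    def test_exact_recovery_of_published_secondary_process(self):
        # generator truth: log f_inf = 13.5, Ea = 48.54 kJ/mol
        T = np.arange(150.0, 221.0, 10.0)
        logf = 13.5 - 48.54e3 / (LN10 * R_GAS * T)
        fit = fit_arrhenius(np.column_stack([T, 10.0**logf]))
        assert fit.log10_f_inf == pytest.approx(13.5, abs=1e-9)
        assert fit.Ea == pytest.approx(48.54, rel=1e-9)

    def test_flat_group_has_zero_activation_energy(self):
        fit = fit_arrhenius([(200.0, 50.0), (250.0, 50.0), (300.0, 50.0)])
        assert fit.Ea == pytest.approx(0.0, abs=1e-9)

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            fit_arrhenius([(200.0, 1e2)])


class TestVFT:
    def test_exact_recovery_of_published_alpha_triple(self):
        T = np.arange(253.15, 413.16, 10.0)
        logf = 10.03 - 2529.0 / (LN10 * (T - 144.5))
        fit = fit_vft(np.column_stack([T, 10.0**logf]))
        assert fit.ok
        assert fit.log10_f_inf == pytest.approx(10.03, abs=1e-6)
        assert fit.B == pytest.approx(2529.0, rel=1e-6)
        assert fit.T0 == pytest.approx(144.5, abs=1e-4)

    def test_fixed_f_inf_mode_recovers_b_and_t0(self):
        T = np.arange(260.0, 401.0, 20.0)
        logf = 10.03 - 2529.0 / (LN10 * (T - 144.5))
        fit = fit_vft(np.column_stack([T, 10.0**logf]), fixed_log10_f_inf=10.03)
        assert fit.fixed_f_inf and fit.ok
        assert fit.B == pytest.approx(2529.0, rel=1e-6)
        assert fit.T0 == pytest.approx(144.5, abs=1e-4)

    def test_noisy_recovery_is_unbiased(self):
        rng = np.random.default_rng(0)
        T = np.arange(253.15, 413.16, 10.0)
        truth = 10.03 - 2529.0 / (LN10 * (T - 144.5))
        tg_err = []
        for _ in range(50):
            logf = truth + rng.normal(0.0, 0.01, T.size)
            fit = fit_vft(np.column_stack([T, 10.0**logf]))
            tg_err.append(tg_kelvin_from_vft(fit) - 230.118)
        bias = float(np.median(tg_err))
        # median bias indistinguishable from zero at Monte-Carlo resolution
        assert abs(bias) < 3.0 * float(np.std(tg_err)) / math.sqrt(len(tg_err))

    def test_asymptote_inside_data_is_flagged(self):
        # near-vertical drop at the coldest point forces the Vogel asymptote
        # onto the data boundary
        pts = [(165.0, 1e-30), (175.0, 1e2), (185.0, 10.0**2.05), (195.0, 10.0**2.1)]
        fit = fit_vft(pts)
        assert not fit.ok

    def test_speeding_up_on_cooling_is_not_vft(self):
        pts = [(200.0, 1e4), (250.0, 1e3), (300.0, 1e2)]
        assert not fit_vft(pts).ok


class TestTgAndFragility:
    @pytest.mark.parametrize("lf, B, T0, tg_c, m", PUBLISHED_VFT)
    def test_published_tg_values(self, lf, B, T0, tg_c, m):
        assert tg_from_vft(VFTFit(lf, B, T0)) == pytest.approx(tg_c, abs=0.2)

    @pytest.mark.parametrize("lf, B, T0, tg_c, m", PUBLISHED_VFT)
    def test_published_fragility_values(self, lf, B, T0, tg_c, m):
        assert fragility_from_vft(VFTFit(lf, B, T0)) == pytest.approx(m, rel=0.01)

    def test_constructed_identity_tg_300K(self):
        lf = 8.0
        C = 2.0 + math.log10(2.0 * math.pi) + lf
        fit = VFTFit(lf, LN10 * C * 300.0, 0.0)
        assert tg_kelvin_from_vft(fit) == pytest.approx(300.0, rel=1e-12)

    def test_arrhenius_limit_fragility_is_C(self):
        fit = VFTFit(10.0, 1500.0, 0.0)
        C = 2.0 + math.log10(2.0 * math.pi * 1e10)
        assert fragility_from_vft(fit) == pytest.approx(C, rel=1e-12)

    def test_tg_equals_numeric_root_of_vft_law(self):
        from scipy.optimize import brentq

        fit = VFTFit(10.03, 2529.0, 144.5)
        root = brentq(
            lambda T: fit.log10_frequency_at(T) - math.log10(F_TG),
            fit.T0 + 1e-3, 1000.0, xtol=1e-12,
        )
        assert tg_kelvin_from_vft(fit) == pytest.approx(root, abs=1e-9)

    def test_fragility_forms_agree(self):
        fit = VFTFit(10.03, 2529.0, 144.5)
        tg = tg_kelvin_from_vft(fit)
        alt = fit.B * tg / (LN10 * (tg - fit.T0) ** 2)
        assert fragility_from_vft(fit) == pytest.approx(alt, rel=1e-9)

    def test_undefined_when_f_inf_too_small(self):
        with pytest.raises(ValueError):
            tg_from_vft(VFTFit(-3.0, 1000.0, 100.0))


@settings(deadline=None, max_examples=80, derandomize=True)
@given(lf=st.floats(min_value=4.0, max_value=16.0),
       B=st.floats(min_value=200.0, max_value=8000.0),
       T0=st.floats(min_value=10.0, max_value=400.0))
def test_monotonicity_of_tg_and_fragility(lf, B, T0):
    """m strictly increases with T0; Tg strictly increases with T0 and B."""
    base = VFTFit(lf, B, T0)
    assert fragility_from_vft(VFTFit(lf, B, T0 + 5.0)) > fragility_from_vft(base)
    assert tg_kelvin_from_vft(VFTFit(lf, B, T0 + 5.0)) > tg_kelvin_from_vft(base)
    assert tg_kelvin_from_vft(VFTFit(lf, B + 100.0, T0)) > tg_kelvin_from_vft(base)


class TestTgCrossing:
    def test_vft_group_agrees_with_closed_form_tg(self):
        T = np.arange(253.15, 413.16, 10.0)
        logf = 10.03 - 2529.0 / (LN10 * (T - 144.5))
        tc = dielectric_tg_crossing(np.column_stack([T, 10.0**logf]))
        assert tc == pytest.approx(tg_from_vft(VFTFit(10.03, 2529.0, 144.5)), abs=0.5)

    def test_bracketing_group_uses_log_linear_interpolation(self):
        # Arrhenius points straddling the -2.8 level; expected value from the
        # two-point interpolation in 1/T computed independently here
        lf_inf, ea = 12.0, 60.0
        T = np.array([190.0, 200.0, 210.0, 220.0])
        logf = lf_inf - ea * 1e3 / (LN10 * R_GAS * T)
        pts = np.column_stack([T, 10.0**logf])
        i = int(np.searchsorted(logf, -2.8)) - 1
        x1, x2 = 1.0 / T[i], 1.0 / T[i + 1]
        x = x1 + (-2.8 - logf[i]) * (x2 - x1) / (logf[i + 1] - logf[i])
        assert dielectric_tg_crossing(pts) == pytest.approx(1.0 / x - 273.15, abs=1e-9)

    def test_group_far_above_level_is_flagged(self):
        T = np.arange(250.0, 351.0, 10.0)
        logf = 12.0 - 8.0e3 / (LN10 * R_GAS * T)  # stays above log f0 = 0
        assert np.all(logf > 0)
        with pytest.raises(NoCrossingError):
            dielectric_tg_crossing(np.column_stack([T, 10.0**logf]))


class TestRelaxationMapAssembly:
    def _result(self, T, entries, flags=None, fixed=()):
        from dielrelax.fitting import IsothermFitResult
        from dielrelax.models import CompositeDielectricModel, HNProcess

        procs = [HNProcess(1.0, f0, 0.8, 1.0, lab) for lab, f0 in entries]
        prov = {lab: {"f0": "fixed:arrhenius" if lab in fixed else "fit"}
                for lab, _ in entries}
        return IsothermFitResult(
            temperature=T,
            model=CompositeDielectricModel(3.0, procs),
            residual_norm=0.0, representation="tan_delta",
            provenance=prov, flags=flags or {},
        )

    def test_collects_entries_per_label(self):
        results = [
            self._result(T, [("beta", 10.0 * T), ("slow", T / 100.0)])
            for T in (200.0, 220.0, 240.0)
        ]
        rmap = build_relaxation_map(results)
        assert len(rmap.entries) == 6
        assert rmap.labels == ["beta", "slow"]
        assert len(rmap.group("beta")) == 3

    def test_unresolved_entries_are_skipped(self):
        results = [self._result(200.0, [("beta", 1e3), ("slow", 1.0)],
                                flags={"slow": "unresolved"})]
        rmap = build_relaxation_map(results)
        assert [e.label for e in rmap.entries] == ["beta"]

    def test_imposed_frequencies_excluded_from_law_refits(self):
        results = [
            self._result(200.0, [("beta", 1e3)]),
            self._result(240.0, [("beta", 1e5)], fixed=("beta",)),
        ]
        rmap = build_relaxation_map(results)
        assert len(rmap.group("beta", free_only=True)) == 1
        assert len(rmap.group("beta", free_only=False)) == 2
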