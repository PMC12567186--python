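"""Per-isotherm and staged dataset fitting."""

import math
from dataclasses import replace

import numpy as np
import pytest

from dielrelax import synthetic
from dielrelax.fitting import (
    FitConfig,
    FitPlan,
    FitWindow,
    ProcessSpec,
    estimate_eps_inf,
    fit_dataset,
    fit_isotherm,
    fix_process_frequency,
)
from dielrelax.relaxation import ArrheniusFit, LN10, R_GAS


class TestEstimateEpsInf:
    def test_selection_rule_coldest_then_highest_frequency(self, two_process_protocol):
        ds, truth = synthetic.generate_dataset(two_process_protocol, seed=0)
        coldest = min(ds.spectra, key=lambda s: s.temperature)
        assert estimate_eps_inf(ds) == coldest.eps_real[-1]

    def test_single_spectrum_dataset(self, debye_spectrum):
        from dielrelax.io import SpectraDataset

        ds = SpectraDataset(spectra=[debye_spectrum])
        assert estimate_eps_inf(ds) == debye_spectrum.eps_real[-1]

    def test_recovers_generator_eps_inf_within_two_percent(self):
        proto = synthetic.preset("A90_no_annealing")
        ds, _ = synthetic.generate_dataset(proto, seed=0)
        assert estimate_eps_inf(ds) == pytest.approx(proto.eps_inf, rel=0.02)

    def test_empty_dataset_rejected(self):
        from dielrelax.io import SpectraDataset

        with pytest.raises(ValueError):
            estimate_eps_inf(SpectraDataset(spectra=[]))


class TestFitIsotherm:
    def test_noiseless_debye_recovered_to_1e_3(self, debye_spectrum):
        cfg = FitConfig(processes=[ProcessSpec("debye")], include_conductivity=False,
                        eps_inf=3.0, representation="tan_delta", seed=0)
        res = fit_isotherm(debye_spectrum, cfg)
        p = res.model.processes[0]
        assert p.delta_eps == pytest.approx(2.0, rel=1e-3)
        assert p.f0 == pytest.approx(100.0, rel=1e-3)
        assert p.a == pytest.approx(1.0, rel=1e-3)
        assert res.success

    def test_two_process_plus_conductivity_recovered_to_1_percent(self, two_process_protocol):
        ds, truth = synthetic.generate_dataset(two_process_protocol, seed=0)
        cfg = FitConfig(processes=[ProcessSpec("beta"), ProcessSpec("alpha_c")],
                        include_conductivity=True, eps_inf=3.5, seed=0)
        s = ds.spectra[-1]
        res = fit_isotherm(s, cfg)
        t = truth["per_temperature"][-1]
        for p in res.model.processes:
            tp = t["processes"][p.label]
            assert p.f0 == pytest.approx(tp["f0"], rel=0.01)
            assert p.delta_eps == pytest.approx(tp["delta_eps"], rel=0.01)
            assert p.a == pytest.approx(tp["a"], rel=0.01)

    def test_constraints_are_honored(self, debye_spectrum):
        cfg = FitConfig(
            processes=[ProcessSpec("debye", a=0.77, b=0.9,
                                   f0_policy="fixed", f0_value=250.0)],
            include_conductivity=False, eps_inf=3.0, seed=0,
        )
        res = fit_isotherm(debye_spectrum, cfg)
        p = res.model.processes[0]
        assert p.a == 0.77 and p.b == 0.9
        assert p.f0 == pytest.approx(250.0, rel=1e-12)  # held via log10 round trip
        assert res.provenance["debye"]["f0"] == "fixed:user"
        assert res.provenance["debye"]["a"] == "fixed:user"

    def test_deterministic_for_a_given_seed(self, two_process_protocol):
        ds, _ = synthetic.generate_dataset(
            replace(two_process_protocol, noise_sd=0.01), seed=3
        )
        cfg = FitConfig(processes=[ProcessSpec("beta"), ProcessSpec("alpha_c")],
                        include_conductivity=True, eps_inf=3.5, seed=11)
        r1 = fit_isotherm(ds.spectra[0], cfg)
        r2 = fit_isotherm(ds.spectra[0], cfg)
        for p1, p2 in zip(r1.model.processes, r2.model.processes):
            assert (p1.delta_eps, p1.f0, p1.a, p1.b) == (p2.delta_eps, p2.f0, p2.a, p2.b)
        assert r1.residual_norm == r2.residual_norm

    def test_tan_delta_fit_immune_to_thickness_drift(self, two_process_protocol):
        """Rescaling eps' and eps'' jointly leaves tan-delta fits unchanged,
        while eps''-representation strengths are biased by exactly the factor."""
        ds0, _ = synthetic.generate_dataset(two_process_protocol, seed=0)
        dsg, _ = synthetic.generate_dataset(
            replace(two_process_protocol, thickness_drift=(1.0, 51.0 / 32.0)), seed=0
        )
        s0, sg = ds0.spectra[-1], dsg.spectra[-1]
        g = sg.eps_real[0] / s0.eps_real[0]
        assert g == pytest.approx(51.0 / 32.0, rel=1e-12)

        specs = [ProcessSpec("beta"), ProcessSpec("alpha_c")]
        tan_cfg = FitConfig(processes=specs, include_conductivity=True,
                            eps_inf=3.5, representation="tan_delta", seed=0)
        r0, rg = fit_isotherm(s0, tan_cfg), fit_isotherm(sg, tan_cfg)
        for p0, pg in zip(r0.model.processes, rg.model.processes):
            assert pg.delta_eps == pytest.approx(p0.delta_eps, rel=5e-3)
            assert pg.f0 == pytest.approx(p0.f0, rel=5e-3)

        loss_cfg = replace(tan_cfg, representation="eps_imag")
        r0, rg = fit_isotherm(s0, loss_cfg), fit_isotherm(sg, loss_cfg)
        for p0, pg in zip(r0.model.processes, rg.model.processes):
            assert pg.delta_eps / p0.delta_eps == pytest.approx(g, rel=1e-3)
            assert pg.f0 == pytest.approx(p0.f0, rel=1e-3)


class TestFixProcessFrequency:
    def test_zero_activation_energy_is_flat(self):
        fit = ArrheniusFit(log10_f_inf=12.0, Ea=0.0)
        assert fix_process_frequency(fit, 150.0) == pytest.approx(1e12)
        assert fix_process_frequency(fit, 400.0) == pytest.approx(1e12)

    def test_published_secondary_process_parameters(self):
        # log f_inf = 9.04, Ea = 11.01 kJ/mol at -100 degC
        fit = ArrheniusFit(log10_f_inf=9.04, Ea=11.01)
        expected = 10.0 ** (9.04 - 11.01e3 / (LN10 * R_GAS * 173.15))
        assert fix_process_frequency(fit, 173.15) == pytest.approx(expected, rel=1e-12)

    def test_two_point_fit_interpolates_exactly_at_anchors(self):
        from dielrelax.relaxation import fit_arrhenius

        fit = fit_arrhenius([(200.0, 1e2), (250.0, 1e4)])
        assert fix_process_frequency(fit, 200.0) == pytest.approx(1e2, rel=1e-9)
        assert fix_process_frequency(fit, 250.0) == pytest.approx(1e4, rel=1e-9)


class TestFitDataset:
    def test_single_window_matches_per_isotherm_fits(self):
        proto = synthetic.preset("debye_single")
        ds, _ = synthetic.generate_dataset(proto, seed=0)
        cfg = FitConfig(processes=[ProcessSpec("debye")], include_conductivity=False,
                        seed=0)
        plan = FitPlan(windows=[FitWindow(-np.inf, np.inf, cfg)])
        results = fit_dataset(ds, plan)
        eps_inf = estimate_eps_inf(ds)
        for res, spectrum in zip(results, sorted(ds.spectra, key=lambda s: s.temperature)):
            solo = fit_isotherm(spectrum, replace(cfg, eps_inf=eps_inf))
            assert res.model.processes[0].f0 == pytest.approx(
                solo.model.processes[0].f0, rel=1e-4
            )

    def test_fast_process_pinned_with_arrhenius_provenance(self):
        proto = synthetic.SyntheticProtocol(
            processes=[
                synthetic.ProcessLaw("fast", "arrhenius", 11.0, Ea=35.0,
                                     delta_eps=2.0, a=0.8, b=1.0),
                synthetic.ProcessLaw("slow", "arrhenius", 9.0, Ea=55.0,
                                     delta_eps=3.0, a=0.7, b=1.0),
            ],
            conductivity=None, eps_inf=3.0,
            t_start_C=-60.0, t_stop_C=40.0, t_step_C=10.0, noise_sd=0.0,
        )
        ds, truth = synthetic.generate_dataset(proto, seed=0)
        w1 = FitWindow(-np.inf, 273.15, FitConfig(
            processes=[ProcessSpec("fast")], include_conductivity=False, seed=0))
        w2 = FitWindow(273.15, np.inf, FitConfig(
            processes=[ProcessSpec("fast", f0_policy="arrhenius"), ProcessSpec("slow")],
            include_conductivity=False, seed=0))
        results = fit_dataset(ds, FitPlan(windows=[w1, w2]))
        hot = [r for r in results if r.temperature > 273.15]
        assert hot, "high-temperature window produced no fits"
        tmap = {t["temperature_K"]: t for t in truth["per_temperature"]}
        for res in hot:
            assert res.provenance["fast"]["f0"] == "fixed:arrhenius"
            fast = res.model.processes[0]
            # Arrhenius extrapolation of an Arrhenius truth is exact
            assert math.log10(fast.f0) == pytest.approx(
                math.log10(tmap[res.temperature]["processes"]["fast"]["f0"]), abs=0.01
            )

    def test_uncovered_temperatures_are_skipped_with_warning(self):
        proto = synthetic.preset("debye_single")
        ds, _ = synthetic.generate_dataset(proto, seed=0)
        cfg = FitConfig(processes=[ProcessSpec("debye")], include_conductivity=False, seed=0)
        plan = FitPlan(windows=[FitWindow(-np.inf, 273.15, cfg)])
        with pytest.warns(UserWarning, match="skipped"):
            results = fit_dataset(ds, plan)
        assert all(r.temperature < 273.15 for r in results)
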