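import numpy as np
import pytest

from chelatherm.itc import (
    InjectionSchedule,
    Thermogram,
    cell_totals_after_injection,
    fit_itc,
    monte_carlo_errors,
    predict_injection_heats,
    subtract_background,
)
from chelatherm.speciation import ComplexSpecies, ProtolysisScheme
from chelatherm.synth import gen_itc_dataset
from oracles import finite_difference_heats, stepwise_mixing_totals

LADDER = (2.40, 3.13, 6.80, 7.73)


class TestInjectionSchedule:
    def test_defaults_match_design(self):
        s = InjectionSchedule()
        assert s.cell_volume == pytest.approx(200e-6)
        assert s.syringe_conc == pytest.approx(500e-6)
        assert s.cell_metal_conc == pytest.approx(50e-6)
        assert s.n_injections == 19
        assert all(0.5e-6 <= v <= 2e-6 for v in s.injection_volumes)

    def test_syringe_capacity_enforced(self):
        with pytest.raises(ValueError, match="capacity"):
            InjectionSchedule(injection_volumes=(3e-6,) * 19)


class TestCellTotals:
    def test_pre_injection(self):
        s = InjectionSchedule()
        m, l = cell_totals_after_injection(s, 0, n_factor=0.9)
        assert m == pytest.approx(0.9 * 50e-6)
        assert l == 0.0

    def test_first_order_limit(self):
        s = InjectionSchedule(injection_volumes=(1e-9,))
        _, l = cell_totals_after_injection(s, 1)
        assert l == pytest.approx(500e-6 * 1e-9 / 200e-6, rel=1e-4)

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            cell_totals_after_injection(InjectionSchedule(), 20)

    def test_against_stepwise_mixing_oracle(self):
        s = InjectionSchedule(injection_volumes=(2e-6,) * 19)
        oracle = stepwise_mixing_totals(200e-6, 500e-6, 50e-6, s.injection_volumes)
        for i in (5, 12, 19):
            m, l = cell_totals_after_injection(s, i)
            assert m == pytest.approx(oracle[i, 0], rel=0.005)
            assert l == pytest.approx(oracle[i, 1], rel=0.005)


class TestPredictHeats:
    def test_zero_enthalpy_gives_offset(self, scheme, ml_species):
        q = predict_injection_heats(
            InjectionSchedule(), scheme, [ml_species], [0.0], pH=3.5, q_dil=1.5
        )
        assert q == pytest.approx(np.full(19, 1.5))

    def test_stoichiometric_limit(self, scheme):
        # all ligand instantly bound before equivalence: q per mole constant
        strong = ComplexSpecies(1, 1, 25.0, "ML")
        sched = InjectionSchedule(injection_volumes=(0.5e-6,) * 5)
        dH = 2e4
        q = predict_injection_heats(
            sched, scheme, [strong], [dH], pH=5.0, include_displaced_heat=False
        )
        moles = 500e-6 * 0.5e-6
        per_mole = q / (1e6 * moles * dH)
        assert per_mole == pytest.approx(np.ones(5), rel=0.02)

    def test_against_finite_difference_oracle(self, scheme):
        species = [ComplexSpecies(1, 1, 13.0, "ML"), ComplexSpecies(2, 1, 16.5, "M2L")]
        dH = [2.0e4, 8.0e3]
        sched = InjectionSchedule()
        q = predict_injection_heats(sched, scheme, species, dH, pH=3.6)
        oracle = finite_difference_heats(
            sched, LADDER, [(1, 1, 13.0), (2, 1, 16.5)], dH, 3.6
        )
        scale = np.max(np.abs(oracle))
        assert np.max(np.abs(q - oracle)) / scale <= 1e-3

    def test_energy_telescoping(self, scheme, ml_species):
        sched = InjectionSchedule()
        dH = [1.7e4]
        q = predict_injection_heats(
            sched, scheme, [ml_species], dH, pH=3.5,
            q_dil=0.0, include_displaced_heat=False,
        )
        from chelatherm.itc import _complex_profiles

        final = _complex_profiles(sched, scheme, [ml_species], 3.5, 1.0)[-1]
        assert q.sum() == pytest.approx(
            1e6 * sched.cell_volume * dH[0] * final[0], rel=1e-12
        )

    def test_sign_flip_exact(self, scheme, ml_species):
        kw = dict(pH=3.5, n_factor=0.93)
        q_pos = predict_injection_heats(
            InjectionSchedule(), scheme, [ml_species], [2e4], **kw
        )
        q_neg = predict_injection_heats(
            InjectionSchedule(), scheme, [ml_species], [-2e4], **kw
        )
        assert q_neg == pytest.approx(-q_pos, rel=1e-12)

    def test_endothermic_and_exothermic_shapes(self, scheme):
        lanthanide = predict_injection_heats(
            InjectionSchedule(), scheme, [ComplexSpecies(1, 1, 13.0)], [2e4], pH=3.5
        )
        assert np.all(lanthanide > 0)
        main_group = predict_injection_heats(
            InjectionSchedule(), scheme, [ComplexSpecies(1, 1, 18.5)], [-3e4], pH=2.0
        )
        assert np.all(main_group < 0)


class TestSubtractBackground:
    def test_blank_equal_sample_zeros(self):
        t = Thermogram(np.arange(5.0), pH=3.5)
        out = subtract_background(t, Thermogram(np.arange(5.0), pH=3.5, is_blank=True))
        assert out.heats == pytest.approx(np.zeros(5))
        assert not out.is_blank

    def test_zero_blank_identity(self):
        t = Thermogram(np.arange(5.0), pH=3.5)
        out = subtract_background(t, Thermogram(np.zeros(5), pH=3.5, is_blank=True))
        assert out.heats == pytest.approx(t.heats)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            subtract_background(
                Thermogram(np.zeros(5), 3.5), Thermogram(np.zeros(4), 3.5)
            )

    def test_constant_offset_removed(self, scheme, ml_species):
        ds = gen_itc_dataset(
            scheme, [ml_species], [2e4], pH=3.5, q_dil=2.0, noise_sigma=0.0, seed=0
        )
        corrected = subtract_background(ds.sample, ds.blank)
        clean = predict_injection_heats(
            ds.schedule, scheme, [ml_species], [2e4], pH=3.5, q_dil=0.0
        )
        assert corrected.heats == pytest.approx(clean, abs=1e-9)


class TestFitITC:
    def test_eu_like_noise_free_recovery(self, scheme):
        truth = ComplexSpecies(1, 1, 13.0, "ML")
        ds = gen_itc_dataset(scheme, [truth], [2.1e4], pH=3.5, noise_sigma=0.0, seed=0)
        fit = fit_itc(
            [subtract_background(ds.sample, ds.blank)],
            ds.schedule, scheme, [ComplexSpecies(1, 1, 12.0, "ML")],
        )
        assert fit.log_betas["ML"] == pytest.approx(13.0, abs=0.01)
        assert fit.delta_H["ML"] == pytest.approx(2.1e4, rel=0.01)
        assert fit.n_factors[0] == pytest.approx(1.0, abs=0.01)

    def test_pb_like_noise_free_recovery(self, aprotic):
        # Pb-like: exothermic, high affinity, low pH; proton competition via
        # the four-step ladder
        scheme = ProtolysisScheme(LADDER)
        truth = ComplexSpecies(1, 1, 18.5, "ML")
        ds = gen_itc_dataset(scheme, [truth], [-3.0e4], pH=2.0, noise_sigma=0.0, seed=0)
        fit = fit_itc(
            [subtract_background(ds.sample, ds.blank)],
            ds.schedule, scheme, [ComplexSpecies(1, 1, 17.0, "ML")],
        )
        assert fit.log_betas["ML"] == pytest.approx(18.5, abs=0.05)
        assert fit.delta_H["ML"] == pytest.approx(-3.0e4, rel=0.02)

    def test_nested_model_comparison(self, scheme):
        truth = ComplexSpecies(1, 1, 13.0, "ML")
        ds = gen_itc_dataset(scheme, [truth], [2e4], pH=3.5, noise_sigma=0.05, seed=5)
        corrected = subtract_background(ds.sample, ds.blank)
        fit1 = fit_itc([corrected], ds.schedule, scheme,
                       [ComplexSpecies(1, 1, 12.5, "ML")])
        fit2 = fit_itc(
            [corrected], ds.schedule, scheme,
            [ComplexSpecies(1, 1, 12.5, "ML"), ComplexSpecies(2, 1, 16.0, "M2L")],
        )
        # the simpler (true) model is preferred: the extra species buys no
        # meaningful rms improvement
        assert fit1.rms <= fit2.rms * 1.05
        # and the ML-only fit still recovers the truth
        assert fit1.log_betas["ML"] == pytest.approx(13.0, abs=0.05)

    def test_global_two_dataset_fit(self, scheme):
        truth = ComplexSpecies(1, 1, 13.0, "ML")
        ds1 = gen_itc_dataset(scheme, [truth], [2e4], pH=3.5, noise_sigma=0.0, seed=1)
        ds2 = gen_itc_dataset(scheme, [truth], [2e4], pH=3.6, n_factor=0.9,
                              noise_sigma=0.0, seed=2)
        fit = fit_itc(
            [subtract_background(ds1.sample, ds1.blank),
             subtract_background(ds2.sample, ds2.blank)],
            [ds1.schedule, ds2.schedule], scheme,
            [ComplexSpecies(1, 1, 12.0, "ML")],
        )
        assert fit.log_betas["ML"] == pytest.approx(13.0, abs=0.01)
        assert fit.n_factors[0] == pytest.approx(1.0, abs=0.01)
        assert fit.n_factors[1] == pytest.approx(0.9, abs=0.01)

    def test_empty_input_rejected(self, scheme, ml_species):
        with pytest.raises(ValueError):
            fit_itc([], InjectionSchedule(), scheme, [ml_species])


class TestMonteCarlo:
    def _noise_free_fit(self, scheme, ml_species):
        ds = gen_itc_dataset(scheme, [ml_species], [2e4], pH=3.5,
                             noise_sigma=0.0, seed=0)
        corrected = subtract_background(ds.sample, ds.blank)
        fit = fit_itc([corrected], ds.schedule, scheme,
                      [ComplexSpecies(1, 1, 12.5, "ML")])
        return ds, corrected, fit

    def test_zero_noise_interval_widths(self, scheme, ml_species):
        ds, corrected, fit = self._noise_free_fit(scheme, ml_species)
        iv = monte_carlo_errors(fit, [corrected], ds.schedule, scheme,
                                n_reps=60, seed=1)
        assert iv["log_beta:ML"].width <= 1e-6

    def test_seed_determinism(self, scheme, ml_species):
        ds, corrected, fit = self._noise_free_fit(scheme, ml_species)
        iv1 = monte_carlo_errors(fit, [corrected], ds.schedule, scheme,
                                 n_reps=55, seed=42)
        iv2 = monte_carlo_errors(fit, [corrected], ds.schedule, scheme,
                                 n_reps=55, seed=42)
        assert iv1["log_beta:ML"] == iv2["log_beta:ML"]

    def test_small_reps_warns(self, scheme, ml_species):
        ds, corrected, fit = self._noise_free_fit(scheme, ml_species)
        with pytest.warns(UserWarning, match="n_reps"):
            monte_carlo_errors(fit, [corrected], ds.schedule, scheme,
                               n_reps=10, seed=1)

    def test_low_affinity_widens_intervals(self, scheme):
        # identifiability guard: c-value < 1 must widen the intervals,
        # not silently report tight wrong values
        sigma = 0.3
        results = {}
        for label, lb in (("high", 13.0), ("low", 10.5)):
            truth = ComplexSpecies(1, 1, lb, "ML")
            ds = gen_itc_dataset(scheme, [truth], [2e4], pH=3.5,
                                 noise_sigma=sigma, seed=9)
            corrected = subtract_background(ds.sample, ds.blank)
            fit = fit_itc([corrected], ds.schedule, scheme,
                          [ComplexSpecies(1, 1, lb, "ML")])
            iv = monte_carlo_errors(fit, [corrected], ds.schedule, scheme,
                                    n_reps=60, seed=3)
            results[label] = iv["log_beta:ML"].width
        assert results["low"] > 3 * results["high"]
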