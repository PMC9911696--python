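"""ITC: peak integration, SVD component filter, Wiseman fits, F-test."""
import numpy as np
import pytest

from rnatopo import itc, synthetic_data as sd
from rnatopo.itc import InjectionSchedule, Isotherm, Thermogram


@pytest.fixture(scope="module")
def schedule():
    return InjectionSchedule(cell_conc=70e-6, syringe_conc=700e-6)


class TestIntegratePeaks:
    def test_rectangular_pulse_exact_area(self, schedule):
        m, n = 100, schedule.n_injections
        M = np.zeros((m, n))
        M[40:60, :] = 2.0                      # area = 20 s * 2 = 40 per injection
        thermo = Thermogram(M, 1.0, schedule)
        iso = itc.integrate_peaks(thermo)
        moles = schedule.syringe_conc * schedule.injection_volume
        assert np.allclose(iso.heat, 40.0 / moles, rtol=1e-3)

    def test_constant_baseline_removed(self, schedule):
        m, n = 100, schedule.n_injections
        M = np.zeros((m, n))
        M[40:60, :] = 2.0
        iso0 = itc.integrate_peaks(Thermogram(M, 1.0, schedule))
        iso1 = itc.integrate_peaks(Thermogram(M + 0.7, 1.0, schedule))
        assert np.allclose(iso0.heat, iso1.heat, rtol=1e-6)

    def test_generator_round_trip_within_1pct(self, schedule):
        thermo, truth = sd.make_itc_two_component(weights=(1.0, 0.0), snr=None,
                                                  schedule=schedule, seed=0)
        iso = itc.integrate_peaks(thermo)
        expect = np.array(truth["heats"]["exothermic"])
        assert np.abs((iso.heat - expect) / expect).max() < 0.01


class TestSvdSelect:
    def test_rank_one_noiseless(self, schedule):
        t = np.linspace(0, 1, 80)
        u = np.exp(-0.5 * ((t - 0.4) / 0.1) ** 2)
        v = np.linspace(1, 0.1, schedule.n_injections)
        thermo = Thermogram(np.outer(u, v), 1.0, schedule)
        sel = itc.svd_select(thermo)
        assert list(sel.kept) == [0]
        assert sel.autocorr[0] > 0.9

    def test_pure_noise_rejected(self, schedule):
        kept_counts = []
        for s in range(100):
            M = np.random.default_rng(s).normal(size=(100, 20))
            thermo = Thermogram(M, 1.0, InjectionSchedule(70e-6, 700e-6, n_injections=20))
            kept_counts.append(len(itc.svd_select(thermo).kept))
        assert sum(1 for k in kept_counts if k == 0) >= 95

    def test_two_component_synthetic_keeps_two(self, schedule):
        thermo, _ = sd.make_itc_two_component(snr=20, schedule=schedule, seed=3)
        sel = itc.svd_select(thermo)
        assert len(sel.kept) == 2

    def test_fraction_invariants(self, schedule):
        thermo, _ = sd.make_itc_two_component(snr=20, schedule=schedule, seed=4)
        sel = itc.svd_select(thermo)
        assert sel.fractions.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(sel.singular_values) <= 1e-12)
        assert np.all(np.diff(sel.fractions) <= 1e-12)

    def test_all_zero_errors(self, schedule):
        with pytest.raises(ValueError):
            itc.svd_select(Thermogram(np.zeros((10, 5)),
                                      1.0, InjectionSchedule(1e-6, 1e-5, n_injections=5)))


class TestReconstruct:
    def test_rank_one_reconstruction_exact(self, schedule):
        t = np.linspace(0, 1, 80)
        M = np.outer(np.exp(-t), np.linspace(1, 0.1, schedule.n_injections))
        thermo = Thermogram(M, 1.0, schedule)
        sel = itc.svd_select(thermo)
        recon = itc.reconstruct_matrix(sel)
        assert np.abs(recon - M).max() < 1e-10 * np.abs(M).max()

    def test_full_svd_machine_precision(self, schedule):
        thermo, _ = sd.make_itc_two_component(snr=20, schedule=schedule, seed=5)
        sel = itc.svd_select(thermo, threshold=-2.0)    # keep everything
        recon = itc.reconstruct_matrix(sel)
        assert np.abs(recon - thermo.M).max() < 1e-10 * np.abs(thermo.M).max()

    def test_component_isotherm_tracks_ground_truth(self, schedule):
        thermo, truth = sd.make_itc_two_component(snr=20, schedule=schedule, seed=6)
        sel = itc.svd_select(thermo)
        isos = itc.reconstruct_isotherms(thermo, sel)
        target = np.array(truth["heats"]["exothermic"])
        best = max(abs(np.corrcoef(iso.heat, target)[0, 1]) for iso in isos)
        assert best > 0.95


class TestOneSiteFit:
    def test_noiseless_recovery_01pct(self, schedule):
        heats = itc.one_site_heats(schedule, N=1.0, kd=1e-6, dH=-10.0)
        iso = Isotherm(schedule.molar_ratios(), heats)
        fit = itc.fit_one_site(iso, schedule)
        assert fit.params["N"] == pytest.approx(1.0, rel=1e-3)
        assert fit.params["Kd"] == pytest.approx(1e-6, rel=1e-3)
        assert fit.params["dH"] == pytest.approx(-10.0, rel=1e-3)

    def test_flat_heats_flagged(self, schedule):
        iso = Isotherm(schedule.molar_ratios(), np.zeros(schedule.n_injections))
        fit = itc.fit_one_site(iso, schedule)
        assert fit.params["dH"] == 0.0
        assert "flat" in fit.flags

    def test_units_invariance_of_kd(self):
        s1 = InjectionSchedule(70e-6, 700e-6, 1.4e-3, 10e-6, 25)
        s2 = InjectionSchedule(140e-6, 1400e-6, 2.8e-3, 20e-6, 25)
        h1 = itc.one_site_heats(s1, 1.0, 1e-6, -10.0)
        fit = itc.fit_one_site(Isotherm(s2.molar_ratios(),
                                        itc.one_site_heats(s2, 1.0, 1e-6, -10.0)), s2)
        assert fit.params["Kd"] == pytest.approx(1e-6, rel=1e-3)

    def test_ode_path_agrees_with_closed_form(self, schedule):
        a = itc.one_site_heats(schedule, 0.8, 2e-6, -8.0)
        b = itc.one_site_heats_ode(schedule, 0.8, 2e-6, -8.0)
        assert np.abs(a - b).max() < 0.02 * np.abs(a).max()

    def test_low_c_value_warns(self):
        weak = InjectionSchedule(1e-7, 1e-6)
        heats = itc.one_site_heats(weak, 1.0, 1e-3, -10.0)
        with pytest.warns(UserWarning):
            itc.fit_one_site(Isotherm(weak.molar_ratios(), heats), weak)

    def test_thermo_bookkeeping(self, schedule):
        heats = itc.one_site_heats(schedule, 1.0, 1e-6, -10.0)
        fit = itc.fit_one_site(Isotherm(schedule.molar_ratios(), heats), schedule)
        R, T = 1.987204e-3, 298.15
        dG = R * T * np.log(fit.params["Kd"])
        assert fit.dG == pytest.approx(dG, abs=1e-9)
        assert fit.dG == pytest.approx(fit.params["dH"] - T * fit.dS, abs=1e-9)


class TestTwoSiteFit:
    def test_well_separated_recovery(self, schedule):
        truth = dict(N1=0.6, kd1=1e-7, dH1=4.0, N2=0.7, kd2=1e-5, dH2=-9.0)
        heats = itc.two_site_heats(schedule, truth["N1"], truth["kd1"], truth["dH1"],
                                   truth["N2"], truth["kd2"], truth["dH2"])
        iso = Isotherm(schedule.molar_ratios(), heats)
        fit = itc.fit_two_site(iso, schedule,
                               x0={"N1": 0.5, "Kd1": 3e-7, "dH1": 3.0,
                                   "N2": 0.5, "Kd2": 3e-5, "dH2": -7.0})
        assert fit.params["N1"] == pytest.approx(0.6, rel=0.01)
        assert fit.params["Kd1"] == pytest.approx(1e-7, rel=0.01)
        assert fit.params["dH1"] == pytest.approx(4.0, rel=0.01)
        assert fit.params["N2"] == pytest.approx(0.7, rel=0.01)
        assert fit.params["Kd2"] == pytest.approx(1e-5, rel=0.01)
        assert fit.params["dH2"] == pytest.approx(-9.0, rel=0.01)

    def test_apparent_stoichiometry_sum(self, schedule):
        heats = itc.two_site_heats(schedule, 0.6, 1e-7, 4.0, 0.7, 1e-5, -9.0)
        fit = itc.fit_two_site(Isotherm(schedule.molar_ratios(), heats), schedule,
                               x0={"N1": 0.5, "Kd1": 3e-7, "dH1": 3.0,
                                   "N2": 0.5, "Kd2": 3e-5, "dH2": -7.0})
        assert fit.n_apparent == pytest.approx(fit.params["N1"] + fit.params["N2"])

    def test_nested_collapse_to_one_site(self, schedule):
        # population of site 2 set to ~zero: two-site data equal one-site data
        h2 = itc.two_site_heats(schedule, 1.0, 1e-6, -10.0, 1e-9, 1e-5, -1.0)
        h1 = itc.one_site_heats(schedule, 1.0, 1e-6, -10.0)
        assert np.abs(h2 - h1).max() < 1e-6 * np.abs(h1).max()


class TestModelSelection:
    def test_identical_rss_chooses_one_site(self, schedule):
        f1 = itc.BindingFit("one_site", {}, 1.0, 25, 3, 0, 0, 1.0)
        f2 = itc.BindingFit("two_site_independent", {}, 1.0, 25, 6, 0, 0, 1.0)
        chosen, F, p = itc.select_model_ftest(f1, f2)
        assert chosen == "one_site"
        assert F == 0.0

    def test_level_on_one_site_data(self, schedule):
        # F-test at alpha=0.05 keeps the true (one-site) model >= 90% of runs
        heats = itc.one_site_heats(schedule, 1.0, 1e-6, -10.0)
        sigma = 0.02 * np.abs(heats).max()
        correct = 0
        for s in range(50):
            noisy = heats + np.random.default_rng(s).normal(0, sigma, heats.shape)
            iso = Isotherm(schedule.molar_ratios(), noisy)
            f1 = itc.fit_one_site(iso, schedule)
            try:
                f2 = itc.fit_two_site(iso, schedule)
                chosen, _, _ = itc.select_model_ftest(f1, f2)
            except Exception:
                chosen = "one_site"
            correct += chosen == "one_site"
        assert correct >= 45

    def test_power_on_two_site_data(self, schedule):
        heats = itc.two_site_heats(schedule, 0.6, 1e-7, 6.0, 0.7, 1e-5, -9.0)
        sigma = np.abs(heats).max() / 50
        correct = 0
        for s in range(40):
            noisy = heats + np.random.default_rng(100 + s).normal(0, sigma, heats.shape)
            iso = Isotherm(schedule.molar_ratios(), noisy)
            f1 = itc.fit_one_site(iso, schedule)
            f2 = itc.fit_two_site(iso, schedule,
                                  x0={"N1": 0.5, "Kd1": 3e-7, "dH1": 3.0,
                                      "N2": 0.5, "Kd2": 3e-5, "dH2": -7.0})
            chosen, _, _ = itc.select_model_ftest(f1, f2)
            correct += chosen == "two_site_independent"
        assert correct >= 38

    def test_kd_estimator_bias_at_snr20(self, schedule):
        heats = itc.one_site_heats(schedule, 1.0, 1e-6, -10.0)
        sigma = np.abs(heats).max() / 20
        kds = []
        for s in range(100):
            noisy = heats + np.random.default_rng(s).normal(0, sigma, heats.shape)
            fit = itc.fit_one_site(Isotherm(schedule.molar_ratios(), noisy), schedule)
            kds.append(fit.params["Kd"])
        assert abs(np.mean(kds) - 1e-6) / 1e-6 < 0.05
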