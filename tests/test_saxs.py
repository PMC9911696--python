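"""Debye profiles, ensemble synthesis, chi-square, Guinier, P(r), Vc."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnatopo import saxs
from rnatopo.config import SAXSConfig
from rnatopo.rna_cg import CGStructure


def beads_at(coords):
    coords = np.asarray(coords, float)
    n = len(coords)
    return CGStructure(coords=coords, nt_index=np.arange(n), role=np.zeros(n, int),
                       chain_id=np.zeros(n, int), helix_id=np.full(n, -1),
                       bonds=np.empty((0, 2), int))


class TestDebye:
    def test_point_scatterer(self):
        p = saxs.debye_profile(beads_at([[0, 0, 0]]), q_grid=np.linspace(0.01, 0.5, 20))
        assert np.allclose(p.I, 1.0)

    def test_two_bead_closed_form(self):
        d = 10.0
        q = np.array([0.05, 0.1, 0.3, 0.5])
        p = saxs.debye_profile(beads_at([[0, 0, 0], [0, 0, d]]), q_grid=q,
                               bin_width=0.001)
        expected = 2 * (1 + np.sin(q * d) / (q * d))
        assert np.allclose(p.I, expected, rtol=1e-4)
        assert saxs.debye_profile(beads_at([[0, 0, 0], [0, 0, d]]),
                                  q_grid=np.array([1e-8])).I[0] == pytest.approx(4.0, rel=1e-6)

    def test_sphere_guinier_rg(self, sphere_phantom):
        prof = saxs.debye_profile(sphere_phantom, q_grid=np.linspace(0.002, 0.5, 250))
        rg, i0, _ = saxs.guinier_fit(prof)
        assert rg == pytest.approx(np.sqrt(3 / 5) * sphere_phantom.radius, rel=0.03)

    def test_intensity_positive_and_bounded(self, truth_y):
        p = saxs.debye_profile(truth_y)
        assert np.all(p.I > 0)
        assert p.I[0] == max(p.I[:10])

    def test_empty_structure(self):
        with pytest.raises(ValueError):
            saxs.debye_profile(beads_at(np.empty((0, 3))))


class TestSynthesize:
    def test_single_curve_identity(self):
        q = np.linspace(0.01, 0.5, 50)
        a = saxs.SAXSProfile(q, np.exp(-q))
        out = saxs.synthesize_ensemble([a], [1.0])
        assert np.allclose(out.I, a.I)

    def test_equal_curves_half_half(self):
        q = np.linspace(0.01, 0.5, 50)
        a = saxs.SAXSProfile(q, np.exp(-q))
        out = saxs.synthesize_ensemble([a, saxs.SAXSProfile(q, a.I.copy())], [0.5, 0.5])
        assert np.allclose(out.I, a.I)

    def test_weighted_arithmetic(self):
        q = np.array([0.1])
        a = saxs.SAXSProfile(q, np.array([2.0]))
        b = saxs.SAXSProfile(q, np.array([10.0]))
        out = saxs.synthesize_ensemble([a, b], [0.3, 0.7])
        assert out.I[0] == pytest.approx(7.6)

    def test_grid_mismatch_not_silent(self):
        a = saxs.SAXSProfile(np.linspace(0.01, 0.5, 50), np.ones(50))
        b = saxs.SAXSProfile(np.linspace(0.02, 0.5, 50), np.ones(50))
        with pytest.raises(ValueError):
            saxs.synthesize_ensemble([a, b], [0.5, 0.5])

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 100))
    def test_linearity_property(self, seed):
        rng = np.random.default_rng(seed)
        q = np.linspace(0.01, 0.5, 30)
        curves = [saxs.SAXSProfile(q, rng.uniform(0.1, 5, 30)) for _ in range(3)]
        nu = rng.dirichlet(np.ones(3))
        mu = rng.dirichlet(np.ones(3))
        left = saxs.synthesize_ensemble(curves, nu).I + saxs.synthesize_ensemble(curves, mu).I
        right = np.stack([c.I for c in curves], axis=1) @ (nu + mu)
        assert np.allclose(left, right)


class TestChiSquare:
    def test_perfect_fit(self):
        q = np.linspace(0.01, 0.5, 100)
        I = 100 * np.exp(-10 * q)
        e = saxs.SAXSProfile(q, I, 0.01 * I)
        chi2, a, b = saxs.chi_square(e, saxs.SAXSProfile(q, I.copy()))
        assert chi2 == pytest.approx(0.0, abs=1e-20)
        assert a == pytest.approx(1.0)
        assert b == pytest.approx(0.0, abs=1e-9)

    def test_scale_offset_closure_joint(self):
        cfg = SAXSConfig(offset_mode="joint")
        q = np.linspace(0.01, 0.5, 100)
        I = 100 * np.exp(-10 * q) + 3.0
        e = saxs.SAXSProfile(q, I, np.full(100, 0.5))
        syn = saxs.SAXSProfile(q, (I - 7.0) / 2.5)
        chi2, a, b = saxs.chi_square(e, syn, cfg)
        assert chi2 == pytest.approx(0.0, abs=1e-18)
        assert a == pytest.approx(2.5)
        assert b == pytest.approx(7.0)

    def test_noise_calibration(self):
        # matched noise model gives reduced chi-square ~ 1
        q = np.linspace(0.005, 0.5, 200)
        I = 1e4 * np.exp(-(q * 25) ** 2 / 3) + 50
        sig = 0.01 * I + 1.0
        chis = []
        for s in range(50):
            noisy = I + np.random.default_rng(s).normal(0, sig)
            chis.append(saxs.chi_square(saxs.SAXSProfile(q, noisy, sig),
                                        saxs.SAXSProfile(q, I))[0])
        assert np.mean(chis) == pytest.approx(1.0, abs=3 / np.sqrt(200))

    def test_sigma_required(self):
        q = np.linspace(0.01, 0.5, 10)
        with pytest.raises(ValueError):
            saxs.chi_square(saxs.SAXSProfile(q, np.ones(10)),
                            saxs.SAXSProfile(q, np.ones(10)))


class TestOptimizeFractions:
    @pytest.fixture(scope="class")
    def conformer_curves(self):
        from rnatopo import synthetic_data as sd
        cgs = [sd.make_phantom(sd.PhantomSpec(preset=p)) for p in sd.JUNCTION_PRESETS]
        return [saxs.debye_profile(c) for c in cgs]

    def test_noiseless_recovery(self, conformer_curves):
        truth = np.array([0.2, 0.3, 0.5])
        mix = saxs.synthesize_ensemble(conformer_curves, truth)
        expt = saxs.SAXSProfile(mix.q, mix.I, 0.01 * mix.I + 1e-9)
        fit = saxs.optimize_fractions(expt, conformer_curves)
        assert np.abs(fit.fractions - truth).max() < 0.01
        assert fit.chi2 < 0.05

    def test_vertex_solution(self, conformer_curves):
        one = conformer_curves[1]
        expt = saxs.SAXSProfile(one.q, one.I.copy(), 0.01 * one.I + 1e-9)
        fit = saxs.optimize_fractions(expt, conformer_curves)
        assert fit.fractions[1] >= 0.99

    def test_simplex_invariants(self, conformer_curves):
        truth = np.array([0.6, 0.1, 0.3])
        mix = saxs.synthesize_ensemble(conformer_curves, truth)
        rng = np.random.default_rng(0)
        sig = 0.02 * mix.I + 1e-9
        expt = saxs.SAXSProfile(mix.q, mix.I + rng.normal(0, sig), sig)
        fit = saxs.optimize_fractions(expt, conformer_curves, np.array([0.5, 0.25, 0.25]))
        assert np.all(fit.fractions >= -1e-12)
        assert fit.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_collinear_degeneracy_flagged(self):
        q = np.linspace(0.01, 0.5, 80)
        base = 100 * np.exp(-5 * q)
        curves = [saxs.SAXSProfile(q, base),
                  saxs.SAXSProfile(q, base * (1 + 1e-12))]
        expt = saxs.SAXSProfile(q, base.copy(), 0.01 * base)
        with pytest.warns(UserWarning):
            fit = saxs.optimize_fractions(expt, curves)
        assert fit.degenerate


class TestGuinier:
    def test_exact_model_recovery(self):
        q = np.linspace(0.001, 0.2, 150)
        rg_true, i0_true = 20.0, 100.0
        p = saxs.SAXSProfile(q, i0_true * np.exp(-(q * rg_true) ** 2 / 3))
        rg, i0, used = saxs.guinier_fit(p)
        assert rg == pytest.approx(rg_true, abs=1e-6)
        assert i0 == pytest.approx(i0_true, rel=1e-6)

    def test_q_range_rule(self):
        q = np.linspace(0.001, 0.2, 150)
        p = saxs.SAXSProfile(q, 100 * np.exp(-(q * 20.0) ** 2 / 3))
        rg, _, (qmin, qmax) = saxs.guinier_fit(p)
        assert qmax * rg < 1.3

    def test_nondecaying_profile_errors(self):
        q = np.linspace(0.01, 0.1, 30)
        with pytest.raises(ValueError):
            saxs.guinier_fit(saxs.SAXSProfile(q, np.full(30, 5.0) + q))


class TestPrDistribution:
    @pytest.fixture(scope="class")
    def sphere_profile(self, sphere_phantom):
        return saxs.debye_profile(sphere_phantom, q_grid=np.linspace(0.005, 0.3, 120))

    def test_dmax_of_sphere(self, sphere_phantom, sphere_profile):
        r, P, dmax = saxs.pr_distribution(sphere_profile)
        assert dmax == pytest.approx(2 * sphere_phantom.radius, rel=0.10)

    def test_near_positivity(self, sphere_profile):
        _, P, _ = saxs.pr_distribution(sphere_profile)
        assert P.min() >= -0.01 * P.max()

    def test_real_reciprocal_rg_consistency(self, sphere_profile):
        r, P, _ = saxs.pr_distribution(sphere_profile)
        rg_real = saxs.rg_from_pr(r, P)
        rg_recip, _, _ = saxs.guinier_fit(sphere_profile)
        assert rg_real == pytest.approx(rg_recip, rel=0.05)


class TestVc:
    def test_pure_guinier_closed_form(self):
        rg = 20.0
        q = np.linspace(1e-4, 1.2, 4000)    # integrand decayed at q_max
        p = saxs.SAXSProfile(q, 100 * np.exp(-(q * rg) ** 2 / 3))
        vc, _ = saxs.vc_molecular_weight(p, rg=rg, i0=100.0)
        assert vc == pytest.approx(2 * rg ** 2 / 3, rel=1e-3)

    def test_intensity_scale_invariance(self):
        rg = 20.0
        q = np.linspace(1e-4, 1.2, 4000)
        p1 = saxs.SAXSProfile(q, 100 * np.exp(-(q * rg) ** 2 / 3))
        p2 = saxs.SAXSProfile(q, 200 * np.exp(-(q * rg) ** 2 / 3))
        v1, _ = saxs.vc_molecular_weight(p1, rg=rg, i0=100.0)
        v2, _ = saxs.vc_molecular_weight(p2, rg=rg, i0=200.0)
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_duplex_mass_within_accuracy_class(self):
        from rnatopo import rna_cg as rc
        duplex = rc.build_aform_helix(20)          # 40 nt, ~13.2 kDa
        prof = saxs.debye_profile(duplex, q_grid=np.linspace(0.005, 0.5, 200))
        rg, i0, _ = saxs.guinier_fit(prof)
        _, mw = saxs.vc_molecular_weight(prof, rg=rg, i0=i0)
        true_mw = 40 * 330.0
        assert true_mw / 2 <= mw <= true_mw * 2

    def test_truncated_integral_warns(self):
        rg = 20.0
        q = np.linspace(1e-3, 0.05, 60)            # far from decayed
        p = saxs.SAXSProfile(q, 100 * np.exp(-(q * rg) ** 2 / 3))
        with pytest.warns(UserWarning):
            saxs.vc_molecular_weight(p, rg=rg, i0=100.0)


def test_dat_round_trip(tmp_path):
    q = np.linspace(0.01, 0.5, 40)
    p = saxs.SAXSProfile(q, np.exp(-q), 0.01 * np.exp(-q) + 1e-4)
    f = tmp_path / "prof.dat"
    saxs.write_dat(p, f)
    back = saxs.read_dat(f)
    assert np.allclose(back.q, p.q)
    assert np.allclose(back.I, p.I)
    assert np.allclose(back.sigma, p.sigma)
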