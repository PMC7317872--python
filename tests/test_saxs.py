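"""SAXS shape analysis against closed-form sphere/Gaussian oracles."""

import numpy as np
import pytest
from scipy import stats

from transdimer.exceptions import AggregationError, InvalidParameterError
from transdimer.saxs import (
    SAXSProfile,
    guinier_fit,
    ift_pr,
    model_consistency_z,
    normalized_kratky,
    scan_dmax,
    vc_molecular_weight,
)
from transdimer.synthdata import (
    SphereModel,
    dumbbell_intensity,
    gaussian_profile,
    make_saxs_profile,
    sphere_intensity,
    sphere_pr,
)

Q = np.linspace(0.05, 6.0, 500)
SPHERE_RG = 3.0 * np.sqrt(3.0 / 5.0)


@pytest.fixture
def sphere_profile():
    return make_saxs_profile(SphereModel(R=3.0, I0=100.0, q_grid=tuple(Q)))


@pytest.fixture
def gaussian_prof():
    q = np.linspace(0.02, 2.0, 300)
    return SAXSProfile(q=q, I=gaussian_profile(q, 3.2, 50.0),
                       sigma=np.full(q.size, 1e-6))


class TestGuinier:
    def test_gaussian_profile_recovered_exactly(self, gaussian_prof):
        g = guinier_fit(gaussian_prof)
        assert g.Rg == pytest.approx(3.2, rel=1e-6)
        assert g.I0 == pytest.approx(50.0, rel=1e-6)

    def test_sphere_rg_at_narrow_window(self, sphere_profile):
        g = guinier_fit(sphere_profile, qRg_max=0.6)
        assert g.Rg == pytest.approx(SPHERE_RG, rel=0.005)

    def test_intensity_scaling_leaves_rg_invariant(self, sphere_profile):
        scaled = SAXSProfile(q=sphere_profile.q, I=10 * sphere_profile.I,
                             sigma=10 * sphere_profile.sigma)
        g1 = guinier_fit(sphere_profile)
        g2 = guinier_fit(scaled)
        assert g2.Rg == pytest.approx(g1.Rg, rel=1e-9)
        assert g2.I0 == pytest.approx(10 * g1.I0, rel=1e-9)

    def test_nonnegative_slope_raises_aggregation_error(self):
        q = np.linspace(0.02, 1.0, 200)
        # apparent intensity rising with q at low q: no valid Guinier region
        I = gaussian_profile(q, 3.0, 10.0) * (1.0 + 5.0 * q**2)
        with pytest.raises(AggregationError):
            guinier_fit(SAXSProfile(q=q, I=I))

    def test_window_respects_qrg_limit(self, sphere_profile):
        g = guinier_fit(sphere_profile, qRg_max=1.3)
        assert g.qmax_rg <= 1.3 + 0.05


class TestKratky:
    def test_gaussian_peak_at_sqrt_three(self, gaussian_prof):
        g = guinier_fit(gaussian_prof)
        k = normalized_kratky(gaussian_prof, g)
        assert k.peak_x == pytest.approx(np.sqrt(3.0), abs=0.01)
        assert k.peak_y == pytest.approx(3.0 / np.e, abs=0.01)

    def test_rod_like_profile_shifts_peak_beyond_globular_value(self):
        q = np.linspace(0.02, 4.0, 600)
        # long thin cylinder: I ~ exp(-q^2 Rc^2/2)/q at intermediate q
        L, Rc = 30.0, 0.8
        I = (np.pi / (q * L)) * np.exp(-(q * Rc) ** 2 / 2.0)
        prof = SAXSProfile(q=q, I=I)
        g = guinier_fit(prof, qRg_max=1.0)
        k = normalized_kratky(prof, g)
        assert k.peak_x > 1.74


class TestPairDistance:
    def test_sphere_pr_matches_analytic_shape(self, sphere_profile):
        pr = ift_pr(sphere_profile, Dmax=7.5)
        analytic = sphere_pr(pr.r, 3.0) * np.trapezoid(pr.p, pr.r)
        sup = np.max(np.abs(pr.p - analytic)) / np.max(analytic)
        assert sup < 0.02

    def test_effective_dmax_is_particle_diameter(self, sphere_profile):
        pr = ift_pr(sphere_profile, Dmax=7.5)
        step = pr.r[1] - pr.r[0]
        assert abs(pr.effective_dmax() - 6.0) <= 1.5 * step

    def test_real_space_rg_consistent_with_guinier(self, sphere_profile):
        g = guinier_fit(sphere_profile, qRg_max=0.6)
        pr = ift_pr(sphere_profile, Dmax=7.5)
        assert pr.Rg_real == pytest.approx(g.Rg, rel=0.02)

    def test_pr_integrates_to_forward_intensity(self, sphere_profile):
        g = guinier_fit(sphere_profile, qRg_max=0.6)
        pr = ift_pr(sphere_profile, Dmax=7.5)
        assert pr.I0_real == pytest.approx(g.I0, rel=0.03)

    def test_forward_residuals_white_at_chosen_alpha(self):
        noisy = make_saxs_profile(
            SphereModel(R=3.0, I0=100.0, q_grid=tuple(Q), noise_frac=0.02),
            seed=8)
        pr = ift_pr(noisy, Dmax=7.5)
        from transdimer.saxs import _ift_kernel
        K = _ift_kernel(noisy.q, pr.r)
        resid = (K @ pr.p - noisy.I) / noisy.sigma
        signs = resid > 0
        runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
        n1, n2 = int(signs.sum()), int((~signs).sum())
        mean = 1 + 2 * n1 * n2 / (n1 + n2)
        var = (2 * n1 * n2 * (2 * n1 * n2 - n1 - n2)
               / ((n1 + n2) ** 2 * (n1 + n2 - 1)))
        z = (runs - mean) / np.sqrt(var)
        assert abs(z) < 3.0  # no gross structure in the residuals

    def test_endpoints_vanish_and_pr_nonnegative(self, sphere_profile):
        pr = ift_pr(sphere_profile, Dmax=7.5)
        assert pr.p[0] == 0.0 and pr.p[-1] == 0.0
        assert np.all(pr.p >= 0.0)

    def test_invalid_dmax_rejected(self, sphere_profile):
        with pytest.raises(InvalidParameterError):
            ift_pr(sphere_profile, Dmax=-1.0)


class TestDmaxScan:
    def test_sphere_diameter_found(self, sphere_profile):
        scan = scan_dmax(sphere_profile, np.arange(5.0, 10.1, 0.5))
        assert scan.Dmax == pytest.approx(6.0, abs=0.75)

    def test_dumbbell_tip_to_tip_dimension(self):
        q = np.linspace(0.02, 4.0, 600)
        prof = SAXSProfile(q=q, I=dumbbell_intensity(q, 2.0, 8.0, 100.0),
                           sigma=np.full(q.size, 1e-5))
        scan = scan_dmax(prof, np.arange(9.0, 16.1, 0.5))
        assert scan.Dmax == pytest.approx(12.0, abs=0.75)

    def test_range_not_covering_truth_warns(self, sphere_profile):
        with pytest.warns(UserWarning, match="ambiguous"):
            scan_dmax(sphere_profile, np.arange(2.0, 4.6, 0.5))


class TestVolumeOfCorrelation:
    def test_invariant_under_intensity_scaling(self, sphere_profile):
        g = guinier_fit(sphere_profile, qRg_max=0.6)
        vc1 = vc_molecular_weight(sphere_profile, g)
        scaled = SAXSProfile(q=sphere_profile.q, I=7 * sphere_profile.I,
                             sigma=7 * sphere_profile.sigma)
        g2 = guinier_fit(scaled, qRg_max=0.6)
        vc2 = vc_molecular_weight(scaled, g2)
        assert vc2.Vc == pytest.approx(vc1.Vc, rel=1e-6)
        assert vc2.mw_kda == pytest.approx(vc1.mw_kda, rel=1e-6)

    def test_calibration_self_consistency(self):
        """A Gaussian profile built to a target QR returns the calibration
        MW within 10%."""
        q = np.linspace(0.01, 5.0, 1000)
        Rg = 3.0
        prof = SAXSProfile(q=q, I=gaussian_profile(q, Rg, 42.0))
        g = guinier_fit(prof)
        vc = vc_molecular_weight(prof, g)
        # for a Gaussian profile, int q I dq = 3 I0/(2 Rg^2) analytically
        vc_expected_nm2 = 2.0 * Rg**2 / 3.0
        qr_A3 = (vc_expected_nm2 * 100.0) ** 2 / (Rg * 10.0)
        assert vc.mw_kda == pytest.approx(qr_A3 / 0.1231 / 1000.0, rel=0.1)

    def test_truncation_sensitivity_reported(self, sphere_profile):
        g = guinier_fit(sphere_profile, qRg_max=0.6)
        vc = vc_molecular_weight(sphere_profile, g)
        assert vc.mw_sensitivity >= 0.0
        assert np.isfinite(vc.mw_sensitivity)


class TestModelConsistency:
    def test_perfect_model_has_zero_z_and_unit_p(self):
        res = model_consistency_z({"Rg": 3.2, "d": 5.6},
                                  {"Rg": (3.2, 0.2), "d": (5.6, 0.3)})
        assert all(z == 0.0 for z in res.z.values())
        assert all(p == 1.0 for p in res.p.values())
        assert res.consistent

    def test_z_of_one_point_two_eight_gives_p_point_two(self):
        res = model_consistency_z({"Rg": 3.2 + 1.2816 * 0.2},
                                  {"Rg": (3.2, 0.2)})
        assert res.min_p == pytest.approx(0.20, abs=0.002)
        assert res.consistent

    def test_z_of_one_point_nine_six_sits_at_threshold(self):
        res = model_consistency_z({"Rg": 3.2 + 1.96 * 0.2},
                                  {"Rg": (3.2, 0.2)})
        assert res.min_p == pytest.approx(0.05, abs=0.001)

    def test_invalid_sd_rejected(self):
        with pytest.raises(InvalidParameterError):
            model_consistency_z({"Rg": 3.0}, {"Rg": (3.0, 0.0)})
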