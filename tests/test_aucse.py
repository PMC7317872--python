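"""Sedimentation-equilibrium model and global K_D fitting."""

import numpy as np
import pytest

from transdimer.aucse import (
    MonomerDimerSE,
    SpeciesParams,
    global_fit_se,
    reduced_buoyant_term,
    rpm_to_omega,
    se_profile,
)
from transdimer.exceptions import InvalidParameterError
from transdimer.synthdata import SEGroundTruth, make_se_scans

R_GAS = 8.31446261815324e7  # erg / (mol K)


@pytest.fixture
def species():
    return SpeciesParams(M=26000.0, vbar=0.73, rho=1.0, eps_l=14400.0)


class TestBuoyantTerm:
    def test_zero_at_rest(self, species):
        assert reduced_buoyant_term(species, 0.0) == 0.0

    def test_linear_in_mass(self, species):
        om = rpm_to_omega(28000.0)
        dimer = SpeciesParams(M=52000.0, vbar=0.73, rho=1.0)
        assert reduced_buoyant_term(dimer, om) == pytest.approx(
            2.0 * reduced_buoyant_term(species, om), rel=1e-12)

    def test_unit_analysis_oracle(self, species):
        """26 kDa, vbar 0.73, rho 1.0, 32000 rpm, 293 K, hand-checked."""
        om = 32000.0 * 2 * np.pi / 60.0
        expected = 26000.0 * (1 - 0.73) * om**2 / (R_GAS * 293.0)
        assert reduced_buoyant_term(species, om, 293.0) == pytest.approx(
            expected, rel=1e-12)

    def test_floating_species_rejected(self):
        with pytest.raises(InvalidParameterError):
            SpeciesParams(M=26000.0, vbar=1.1, rho=1.0)


class TestProfile:
    r = np.linspace(6.9, 7.2, 60)

    def test_flat_at_rest(self, species):
        A = se_profile(1e-5, 18e-6, species, self.r, 0.0, baseline=0.02)
        expected = species.eps_l * (1e-5 + 2e-10 / 18e-6) + 0.02
        assert np.allclose(A, expected)

    def test_infinite_kd_is_ideal_monomer(self, species):
        om = rpm_to_omega(28000.0)
        A = se_profile(1e-5, 1e12, species, self.r, om)
        sigma = reduced_buoyant_term(species, om)
        ideal = species.eps_l * 1e-5 * np.exp(
            sigma * (self.r**2 - self.r[0]**2) / 2.0)
        assert np.allclose(A, ideal, rtol=1e-10)

    def test_mass_action_identity_at_every_radius(self, species):
        om = rpm_to_omega(32000.0)
        c_ref, KD = 2e-5, 18e-6
        sigma = reduced_buoyant_term(species, om)
        e = np.exp(sigma * (self.r**2 - self.r[0]**2) / 2.0)
        c_m = c_ref * e
        A = se_profile(c_ref, KD, species, self.r, om)
        reconstructed = species.eps_l * (c_m + 2.0 * c_m**2 / KD)
        assert np.allclose(A, reconstructed, rtol=1e-12)

    def test_strictly_increasing_for_positive_buoyancy(self, species):
        A = se_profile(1e-5, 18e-6, species, self.r, rpm_to_omega(24000.0))
        assert np.all(np.diff(A) > 0)


class TestGlobalFit:
    def test_noiseless_data_fit_to_machine_precision(self):
        truth = SEGroundTruth(KD=18e-6, M_monomer=26000.0,
                              speeds=tuple(rpm_to_omega(s)
                                           for s in (24000, 28000, 32000)))
        scans = make_se_scans(truth, noise_sd_AU=0.0, seed=0)
        fit = global_fit_se(scans, truth.species, ci=False)
        assert fit.rms < 1e-8
        assert fit.KD == pytest.approx(18e-6, rel=1e-4)

    @pytest.mark.parametrize("kd_um,mass,c_load", [(18.0, 26000.0, 36e-6),
                                                   (52.0, 15000.0, 45e-6)])
    def test_kd_recovery_at_experimental_noise(self, kd_um, mass, c_load):
        truth = SEGroundTruth(KD=kd_um * 1e-6, M_monomer=mass, c_load=c_load,
                              speeds=tuple(rpm_to_omega(s)
                                           for s in (24000, 28000, 32000)))
        scans = make_se_scans(truth, noise_sd_AU=0.005, seed=3)
        fit = MonomerDimerSE(scans, truth.species).fit(ci=False)
        assert fit.KD == pytest.approx(kd_um * 1e-6, rel=0.2)

    def test_scans_at_two_speeds_share_kd(self):
        """Global consistency: any two-speed subset of one ground truth
        yields the same K_D."""
        truth = SEGroundTruth(KD=18e-6, M_monomer=26000.0,
                              speeds=tuple(rpm_to_omega(s)
                                           for s in (24000, 28000, 32000)))
        scans = make_se_scans(truth, noise_sd_AU=0.0, seed=0)
        fit_a = global_fit_se(scans[:2], truth.species, ci=False)
        fit_b = global_fit_se(scans[1:], truth.species, ci=False)
        assert fit_a.KD == pytest.approx(fit_b.KD, rel=1e-3)

    def test_monomer_only_data_reports_no_association(self):
        truth = SEGroundTruth(KD=1e6, M_monomer=26000.0,
                              speeds=tuple(rpm_to_omega(s)
                                           for s in (24000, 32000)))
        scans = make_se_scans(truth, noise_sd_AU=0.003, seed=4)
        fit = global_fit_se(scans, truth.species)
        assert fit.no_association

    def test_single_scan_rejected(self, species):
        truth = SEGroundTruth(KD=18e-6, M_monomer=26000.0,
                              speeds=(rpm_to_omega(24000),))
        scans = make_se_scans(truth, noise_sd_AU=0.0, seed=0)
        with pytest.raises(InvalidParameterError):
            global_fit_se(scans, species)


class TestGenerator:
    def test_rest_profile_is_total_loading_absorbance(self):
        truth = SEGroundTruth(KD=18e-6, M_monomer=26000.0, speeds=(0.0,),
                              baseline=0.01)
        scan = make_se_scans(truth, noise_sd_AU=0.0, seed=0)[0]
        assert np.allclose(scan.A, truth.eps_l * truth.c_load + 0.01,
                           rtol=1e-10)

    def test_reproducible_for_fixed_seed(self):
        truth = SEGroundTruth(KD=18e-6, M_monomer=26000.0,
                              speeds=(rpm_to_omega(24000),
                                      rpm_to_omega(32000)))
        a = make_se_scans(truth, seed=9)
        b = make_se_scans(truth, seed=9)
        assert all(np.array_equal(x.A, y.A) for x, y in zip(a, b))
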