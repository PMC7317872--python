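"""Time-resolved anisotropy: ratio construction and biexponential fits."""

import numpy as np
import pytest

from transdimer.anisotropy import (
    AnisotropyDecayModel,
    PolarizedDecay,
    anisotropy_curve,
    fit_biexponential,
)
from transdimer.exceptions import DegenerateInputError, InvalidParameterError
from transdimer.synthdata import make_anisotropy_decay

T = np.arange(0.0, 50.0, 0.05)


class TestAnisotropyCurve:
    def test_isotropic_emission_gives_zero(self):
        decay = PolarizedDecay(T, np.full(T.size, 100.0),
                               np.full(T.size, 100.0))
        _, r = anisotropy_curve(decay)
        assert np.allclose(r, 0.0)

    def test_fully_polarized_limit_gives_one(self):
        decay = PolarizedDecay(T, np.full(T.size, 100.0),
                               np.zeros(T.size))
        _, r = anisotropy_curve(decay)
        assert np.allclose(r, 1.0)

    def test_printed_convention_flips_sign_for_polarized_light(self):
        decay = make_anisotropy_decay(0.3, 0.4, 0.5, 0.6, 10.0, T, 0.0)
        _, r_std = anisotropy_curve(decay, convention="standard")
        _, r_alt = anisotropy_curve(decay, convention="perpendicular")
        assert np.all(r_std[:100] > 0)
        assert np.all(r_alt[:100] < 0)

    def test_round_trip_recovers_planted_anisotropy(self):
        decay = make_anisotropy_decay(0.3, 0.4, 0.5, 0.6, 10.0, T, 0.0)
        t, r = anisotropy_curve(decay)
        planted = 0.3 * (0.4 * np.exp(-t / 0.5) + 0.6 * np.exp(-t / 10.0))
        assert np.allclose(r, planted, atol=1e-12)

    def test_time_zero_value_is_r0_times_amplitude_sum(self):
        # amplitudes deliberately not normalized: r(0) = r0 (A1 + A2)
        decay = make_anisotropy_decay(0.35, 0.3, 0.5, 0.5, 10.0, T, 0.0)
        _, r = anisotropy_curve(decay)
        assert r[0] == pytest.approx(0.35 * 0.8, abs=1e-12)

    def test_all_masked_is_degenerate(self):
        decay = PolarizedDecay(T, np.full(T.size, 1e-9),
                               np.full(T.size, 1e-9))
        with pytest.raises(DegenerateInputError):
            anisotropy_curve(decay, intensity_threshold=1.0)


class TestBiexponentialFit:
    def test_planted_parameters_recovered_within_ten_percent(self):
        decay = make_anisotropy_decay(0.3, 0.4, 0.5, 0.6, 10.0, T,
                                      noise_sd=0.002, seed=1)
        fit = AnisotropyDecayModel(decay).fit()
        assert fit.phi1 == pytest.approx(0.5, rel=0.1)
        assert fit.phi2 == pytest.approx(10.0, rel=0.1)
        assert fit.r0 == pytest.approx(0.3, rel=0.1)
        assert fit.A1 + fit.A2 == pytest.approx(1.0, abs=1e-9)

    def test_monoexponential_degenerate_case(self):
        decay = make_anisotropy_decay(0.3, 1.0, 4.0, 0.0, 4.0, T,
                                      noise_sd=0.001, seed=2)
        with pytest.warns(UserWarning, match="monoexponential"):
            fit = AnisotropyDecayModel(decay).fit()
        assert fit.mono_fallback
        assert fit.phi1 == pytest.approx(4.0, rel=0.05)

    def test_fitted_model_monotone_decreasing(self):
        decay = make_anisotropy_decay(0.3, 0.4, 0.5, 0.6, 10.0, T,
                                      noise_sd=0.002, seed=3)
        fit = AnisotropyDecayModel(decay).fit()
        tt = np.linspace(0.0, 40.0, 400)
        assert np.all(np.diff(fit.r_model(tt)) < 0)

    def test_unphysical_r0_flagged_not_clamped(self):
        decay = make_anisotropy_decay(0.55, 0.4, 0.5, 0.6, 10.0, T, 0.0)
        fit = AnisotropyDecayModel(decay).fit()
        assert fit.r0_exceeds_limit
        assert fit.r0 > 0.4

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidParameterError):
            fit_biexponential(np.ones(10), np.arange(10.0))

    def test_dimer_slower_than_monomer_global_rotation(self):
        """Slow correlation times preserve the size ordering between
        monomer-like and dimer-like decays."""
        mono = make_anisotropy_decay(0.3, 0.4, 0.5, 0.6, 8.0, T,
                                     noise_sd=0.002, seed=4)
        dimer = make_anisotropy_decay(0.3, 0.4, 0.5, 0.6, 16.0, T,
                                      noise_sd=0.002, seed=5)
        f1 = AnisotropyDecayModel(mono).fit()
        f2 = AnisotropyDecayModel(dimer).fit()
        assert f2.phi2 > f1.phi2
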