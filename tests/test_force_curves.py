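"""Synthetic force curves and single-molecule event selection."""

import numpy as np
import pytest

from transdimer.exceptions import InvalidParameterError
from transdimer.smfs import (
    ForceCurve,
    PullingConfig,
    fit_fjc,
    fjc_force,
    select_single_events,
)
from transdimer.synthdata import (
    MixtureSpec,
    make_baseline_curve,
    make_dfs_dataset,
    make_force_curve,
    sample_rupture_forces,
    state_loading_rate,
)


class TestCurveGeneration:
    def test_noiseless_force_matches_fjc_inversion(self, tether,
                                                   noiseless_pull):
        curve = make_force_curve(tether, noiseless_pull, 180.0, seed=0)
        target = 0.99 * tether.Lc
        i = int(np.argmin(np.abs(curve.extension - target)))
        assert curve.force[i] == pytest.approx(
            float(fjc_force(curve.extension[i], tether)), rel=1e-8)

    def test_last_above_baseline_sample_is_rupture_force(self, tether,
                                                         noiseless_pull):
        curve = make_force_curve(tether, noiseless_pull, 120.0, seed=0)
        peak = float(np.max(curve.force))
        assert peak == pytest.approx(120.0, abs=1e-9)
        after = curve.force[np.argmax(curve.force) + 1:]
        assert np.all(after < 1e-9)

    def test_extension_monotone_nondecreasing(self, tether, pull):
        curve = make_force_curve(tether, pull, 150.0, seed=1)
        assert np.all(np.diff(curve.extension) >= -1e-9)

    def test_rupture_beyond_ramp_rejected(self, tether, pull):
        with pytest.raises(InvalidParameterError):
            make_force_curve(tether, pull, 150.0, total_distance=40.0)
        with pytest.raises(InvalidParameterError):
            make_force_curve(tether, pull, -5.0)

    def test_reproducible_for_fixed_seed(self, tether, pull):
        a = make_force_curve(tether, pull, 100.0, seed=5)
        b = make_force_curve(tether, pull, 100.0, seed=5)
        assert np.array_equal(a.force, b.force)


class TestFJCFit:
    def test_noiseless_curve_recovers_contour_length(self, tether,
                                                     noiseless_pull):
        curve = make_force_curve(tether, noiseless_pull, 180.0, seed=0)
        fit = fit_fjc(curve)
        assert fit.params.Lc == pytest.approx(tether.Lc, rel=0.005)
        assert fit.params.kuhn == pytest.approx(tether.kuhn, rel=0.02)

    def test_noisy_round_trip_within_one_percent(self, tether, pull):
        curve = make_force_curve(tether, pull, 180.0, seed=3)
        fit = fit_fjc(curve)
        assert fit.params.Lc == pytest.approx(tether.Lc, rel=0.01)

    def test_flat_noise_curve_is_no_event(self, pull):
        curve = make_baseline_curve(pull, seed=2)
        assert fit_fjc(curve) is None


class TestEventSelection:
    def test_event_yield_matches_planted_fraction(self, tether, low_state,
                                                  high_state):
        mix = MixtureSpec(((low_state, 0.5), (high_state, 0.5)))
        pulls = [PullingConfig(kc=20.0, v=v)
                 for v in (500.0, 2000.0, 10000.0, 15000.0)]
        curves = make_dfs_dataset(mix, tether, pulls, n_per_speed=300,
                                  event_fraction=0.08, seed=11)
        events = select_single_events(curves)
        yield_frac = len(events) / len(curves)
        assert 0.05 <= yield_frac <= 0.105

    def test_two_drop_curve_rejected(self, tether, pull):
        curve = make_force_curve(tether, pull, 180.0, seed=4)
        # splice in a second sharp drop mid-stretch
        f = curve.force.copy()
        peak = int(np.argmax(f))
        mid = peak // 2
        f[mid:mid + 4] -= 90.0
        doctored = ForceCurve(curve.extension, f, curve.v, curve.kc,
                              "two-drop", curve.sampling_rate)
        assert select_single_events([doctored]) == []

    def test_rupture_forces_track_planted_values(self, tether, pull,
                                                 high_state):
        rate, _ = state_loading_rate(high_state, tether, pull)
        planted = sample_rupture_forces(high_state, rate, 60, seed=3)
        curves = [make_force_curve(tether, pull, float(F), seed=i,
                                   curve_id=str(i))
                  for i, F in enumerate(planted)]
        events = select_single_events(curves)
        assert len(events) >= 57  # nearly all detected
        by_id = {c.id: F for c, F in zip(curves, planted)}
        errs = [abs(e.F_rupture - by_id[e.curve_id]) for e in events]
        frac_ok = np.mean(np.array(errs) < 3 * pull.noise_sd)
        assert frac_ok >= 0.95

    def test_false_positive_rate_on_pure_noise(self, pull):
        noise = [make_baseline_curve(pull, seed=i) for i in range(400)]
        events = select_single_events(noise)
        assert len(events) / len(noise) < 0.005

    def test_empty_pulls_rejected(self, tether, low_state):
        mix = MixtureSpec(((low_state, 1.0),))
        with pytest.raises(InvalidParameterError):
            make_dfs_dataset(mix, tether, [], 10)
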