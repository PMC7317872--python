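"""smFRET efficiencies, population mode, and distance conversion."""

import numpy as np
import pytest

from transdimer.exceptions import InvalidParameterError, OutOfDomainError
from transdimer.fret import (
    FRETExperiment,
    FRETPairConfig,
    FRETTrace,
    detect_bleach,
    distance_from_efficiency,
    efficiency_from_distance,
    most_probable_efficiency,
    trace_efficiency,
)
from transdimer.synthdata import FRETGroundTruth, make_fret_traces


def _step_trace(e=0.5, n_pre=100, n_post=50, I=500.0, bg=0.0, scale=1.0):
    n = n_pre + n_post
    t = np.arange(n, dtype=float)
    acceptor = np.where(t < n_pre, e * I, 0.0) + bg
    donor = np.where(t < n_pre, (1 - e) * I, I) + bg
    return FRETTrace(t, donor * scale, acceptor * scale, bg, bg)


class TestTraceEfficiency:
    def test_equal_channels_give_half(self):
        assert trace_efficiency(_step_trace(0.5)) == pytest.approx(0.5)

    def test_invariant_under_channel_scaling(self):
        e1 = trace_efficiency(_step_trace(0.7))
        # scaling both channels by 10 leaves the ratio unchanged (bg = 0)
        e2 = trace_efficiency(_step_trace(0.7, scale=10.0))
        assert e2 == pytest.approx(e1, abs=1e-12)

    def test_acceptor_at_background_excluded(self):
        t = np.arange(200.0)
        rng = np.random.default_rng(0)
        bg = 30.0
        trace = FRETTrace(t, 500.0 + rng.normal(0, 5, 200),
                          bg + rng.normal(0, 5, 200), bg_donor=bg,
                          bg_acceptor=bg)
        assert trace_efficiency(trace) is None

    def test_zero_efficiency_traces_excluded(self):
        truth = FRETGroundTruth(E_true=0.0)
        traces = make_fret_traces(truth, 5, seed=1)
        assert all(trace_efficiency(t) is None for t in traces)

    def test_short_prebleach_excluded(self):
        assert trace_efficiency(_step_trace(0.5, n_pre=5)) is None

    def test_bleach_frame_detected_at_step(self):
        assert detect_bleach(_step_trace(0.6, n_pre=120)) in (119, 120, 121)


class TestGeneratorInvariants:
    def test_total_intensity_conserved_before_bleach(self):
        truth = FRETGroundTruth(E_true=0.6)
        traces = make_fret_traces(truth, 10, seed=2)
        for tr in traces:
            b = detect_bleach(tr)
            total = (tr.donor[:b] - tr.bg_donor
                     + tr.acceptor[:b] - tr.bg_acceptor)
            assert np.mean(total) == pytest.approx(truth.I_total, rel=0.02)

    def test_reproducible_for_fixed_seed(self):
        truth = FRETGroundTruth(E_true=0.4)
        a = make_fret_traces(truth, 3, seed=5)
        b = make_fret_traces(truth, 3, seed=5)
        assert all(np.array_equal(x.donor, y.donor) for x, y in zip(a, b))

    def test_invalid_efficiency_rejected(self):
        with pytest.raises(InvalidParameterError):
            FRETGroundTruth(E_true=1.2)


class TestPopulationMode:
    @pytest.mark.parametrize("e_true", [0.2, 0.4, 0.6, 0.8])
    def test_recovery_bias_below_two_percent(self, e_true):
        traces = make_fret_traces(FRETGroundTruth(E_true=e_true), 25, seed=3)
        res = FRETExperiment(traces).fit()
        assert res.EFRETmp == pytest.approx(e_true, abs=0.02)

    def test_identical_values_return_that_value(self):
        res = most_probable_efficiency(np.full(20, 0.37))
        assert res.EFRETmp == 0.37

    def test_small_population_rejected(self):
        with pytest.raises(InvalidParameterError):
            most_probable_efficiency([0.5] * 5)

    def test_bimodal_population_flagged(self):
        rng = np.random.default_rng(4)
        es = np.concatenate([rng.normal(0.3, 0.01, 60),
                             rng.normal(0.7, 0.01, 40)])
        with pytest.warns(UserWarning, match="unimodal"):
            res = most_probable_efficiency(es)
        assert not res.unimodal
        assert res.EFRETmp == pytest.approx(0.3, abs=0.05)  # dominant mode


class TestDistanceConversion:
    def test_half_efficiency_gives_forster_radius(self):
        cfg = FRETPairConfig(R0=6.0)
        assert distance_from_efficiency(0.5, cfg) == pytest.approx(6.0)

    def test_reference_value(self):
        cfg = FRETPairConfig(R0=6.0)
        assert distance_from_efficiency(0.60, cfg) == pytest.approx(
            6.0 * (2.0 / 3.0) ** (1.0 / 6.0), rel=1e-12)

    def test_round_trip_identity(self):
        cfg = FRETPairConfig(R0=5.4)
        for R in (3.0, 5.4, 8.0):
            E = efficiency_from_distance(R, cfg)
            assert distance_from_efficiency(E, cfg) == pytest.approx(
                R, abs=1e-12)

    def test_strictly_decreasing_in_efficiency(self):
        cfg = FRETPairConfig(R0=6.0)
        es = np.linspace(0.05, 0.95, 50)
        rs = [distance_from_efficiency(e, cfg) for e in es]
        assert np.all(np.diff(rs) < 0)

    def test_out_of_domain_rejected(self):
        cfg = FRETPairConfig(R0=6.0)
        for bad in (0.0, 1.0, -0.2, 1.3):
            with pytest.raises(OutOfDomainError):
                distance_from_efficiency(bad, cfg)
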