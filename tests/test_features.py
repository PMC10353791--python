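"""Spike detection, feature extraction on ground-truth traces, and fitness."""

import math

import numpy as np
import pytest

from condpop.features import (
    FeatureTargets,
    FeatureVector,
    NONSPIKING_SENTINEL,
    adaptation_index,
    detect_spikes,
    extract_features,
    feature_fitness,
)
from condpop.fixtures import synth_trace
from condpop.model import StimulusProtocol, VoltageTrace


def flat_trace(level=-80.0, dt=0.025, amplitude_pa=90.0):
    n = int(round(300.0 / dt)) + 1
    return VoltageTrace(
        dt=dt,
        vm={"soma": np.full(n, level)},
        ca={"soma": np.zeros(n)},
        protocol=StimulusProtocol(amplitude=amplitude_pa),
        vrest=level,
    )


class TestDetectSpikes:
    def test_constant_trace_has_no_spikes(self):
        assert detect_spikes(flat_trace()) == []

    def test_constructed_spikes_recovered(self):
        times = [12.0, 50.0, 100.0, 180.0]
        tr = synth_trace(times)
        events = detect_spikes(tr)
        assert len(events) == 4
        for ev, t in zip(events, times):
            assert ev.onset_time == pytest.approx(50.0 + t, abs=tr.dt)

    def test_subthreshold_ramp_ignored(self):
        """A ramp with peak slope 10 mV/ms never crosses the 15 mV/ms criterion."""
        dt = 0.025
        n = int(round(300.0 / dt)) + 1
        t = np.arange(n) * dt
        vm = -80.0 + np.clip(t - 50.0, 0.0, 10.0) * 10.0  # 10 mV/ms for 10 ms
        tr = flat_trace()
        tr.vm["soma"] = vm
        assert detect_spikes(tr) == []

    def test_threshold_voltage_is_vm_at_onset(self):
        tr = synth_trace([100.0], rest=-76.0)
        (ev,) = detect_spikes(tr)
        assert ev.threshold_vm == pytest.approx(-76.0, abs=0.5)

    def test_coarse_dt_rejected(self):
        with pytest.raises(ValueError, match="dt"):
            detect_spikes(np.zeros(100), dt=2.0)


class TestAdaptationIndex:
    @pytest.mark.parametrize(
        "isis, expected",
        [([10.0, 10.0, 10.0], 0.0), ([8.0, 12.0, 16.0], 0.5), ([10.0, 20.0], 0.5)],
    )
    def test_formula(self, isis, expected):
        assert adaptation_index(isis) == pytest.approx(expected)

    def test_single_isi_undefined(self):
        assert math.isnan(adaptation_index([12.0]))

    def test_nonpositive_isi_rejected(self):
        with pytest.raises(ValueError):
            adaptation_index([10.0, 0.0])


class TestExtractFeatures:
    def test_counts_latency_isi_from_fixture(self):
        tr50 = synth_trace([30.0], amplitude_pa=50.0)
        tr90 = synth_trace([12.0, 50.0, 100.0, 180.0], amplitude_pa=90.0)
        fv = extract_features(tr50, tr90)
        f90 = fv.by_protocol[90.0]
        assert f90["spike_count"] == 4
        assert f90["latency"] == pytest.approx(12.0, abs=tr90.dt)
        assert f90["isi_first"] == pytest.approx(38.0, abs=2 * tr90.dt)
        assert fv.by_protocol[50.0]["spike_count"] == 1

    def test_amplitude_and_width_exact(self):
        tr90 = synth_trace([100.0], amplitude=80.0, width=0.9, fahp=8.0)
        tr50 = synth_trace([], amplitude_pa=50.0)
        fv = extract_features(tr50, tr90)
        f90 = fv.by_protocol[90.0]
        assert f90["mean_amplitude"] == pytest.approx(80.0, abs=0.2)
        assert f90["ap_width"] == pytest.approx(0.9, abs=0.05)
        assert f90["fahp_amplitude"] == pytest.approx(8.0, abs=0.2)
        assert f90["abs_fahp_amplitude"] == pytest.approx(8.0, abs=0.2)

    def test_many_seeded_fixtures_recovered(self):
        """Timing features within one dt, amplitudes within one sample, over
        randomly drawn fixture geometries."""
        rng = np.random.default_rng(7)
        for _ in range(60):
            k = rng.integers(1, 5)
            times = np.sort(rng.uniform(5.0, 195.0, size=k))
            while k > 1 and np.min(np.diff(times)) < 14.0:
                times = np.sort(rng.uniform(5.0, 195.0, size=k))
            amp = rng.uniform(60.0, 100.0)
            width = rng.uniform(0.7, 1.6)
            fahp = rng.uniform(4.0, 12.0)
            tr = synth_trace(list(times), amplitude=amp, width=width, fahp=fahp)
            events = detect_spikes(tr)
            assert len(events) == k
            for ev, t in zip(events, times):
                assert abs(ev.onset_time - (50.0 + t)) <= tr.dt + 1e-9
                assert abs((ev.peak_vm - ev.threshold_vm) - amp) <= 0.3

    def test_nonspiking_pair_has_undefined_shape_features(self):
        fv = extract_features(flat_trace(amplitude_pa=50.0), flat_trace(amplitude_pa=90.0))
        f = fv.by_protocol[90.0]
        assert f["spike_count"] == 0
        assert all(math.isnan(f[k]) for k in f if k != "spike_count")

    def test_protocol_mismatch_rejected(self):
        bad = flat_trace(amplitude_pa=90.0)
        bad.protocol = StimulusProtocol(amplitude=90.0, pre_ms=10.0)
        with pytest.raises(ValueError, match="protocol"):
            extract_features(flat_trace(amplitude_pa=50.0), bad)


def make_targets(entries):
    return FeatureTargets(entries=entries)


class TestFitness:
    @pytest.fixture
    def targets(self):
        return make_targets({
            (90.0, "spike_count"): (4.0, 0.8),
            (90.0, "latency"): (12.0, 2.4),
            (90.0, "mean_amplitude"): (80.0, 16.0),
        })

    def vector(self, count=4.0, latency=12.0, amplitude=80.0):
        feats = {name: math.nan for name in
                 ("spike_count", "latency", "threshold", "mean_amplitude",
                  "fahp_amplitude", "abs_fahp_amplitude", "ap_width",
                  "isi_first", "adaptation_index")}
        feats.update(spike_count=count, latency=latency, mean_amplitude=amplitude)
        empty = dict.fromkeys(feats, math.nan)
        empty["spike_count"] = 0.0
        return FeatureVector(by_protocol={50.0: empty, 90.0: feats})

    def test_zero_deviation_is_perfect(self, targets):
        res = feature_fitness(self.vector(), targets)
        assert res.pareto_efficiency == 0.0
        assert res.valid

    def test_two_sigma_boundary_is_invalid(self, targets):
        res = feature_fitness(self.vector(latency=12.0 + 2 * 2.4), targets)
        assert res.pareto_efficiency == pytest.approx(2.0)
        assert not res.valid

    def test_strict_threshold(self, targets):
        eps = 1e-9
        almost = feature_fitness(self.vector(latency=12.0 + 2.4 * (2 - eps)), targets)
        assert almost.valid
        exact = feature_fitness(self.vector(latency=12.0 + 2.4 * 2.0), targets)
        assert not exact.valid

    def test_nonspiking_sentinel(self, targets):
        res = feature_fitness(self.vector(count=0.0), targets)
        # count=0 at 90 pA and 0 at 50 pA → fully non-spiking
        assert res.pareto_efficiency == NONSPIKING_SENTINEL
        assert res.sentinel_applied and not res.valid

    def test_scale_equivariance(self, targets):
        """Scaling one feature's deviation and SD together leaves F unchanged."""
        base = feature_fitness(self.vector(latency=15.0), targets).per_feature[(90.0, "latency")]
        scaled_targets = make_targets({
            (90.0, "spike_count"): (4.0, 0.8),
            (90.0, "latency"): (12.0, 2.4 * 3.0),
            (90.0, "mean_amplitude"): (80.0, 16.0),
        })
        scaled = feature_fitness(self.vector(latency=12.0 + 9.0), scaled_targets)
        assert scaled.per_feature[(90.0, "latency")] == pytest.approx(base)

    def test_monotone_in_deviation(self, targets):
        ps = [
            feature_fitness(self.vector(latency=12.0 + d), targets).pareto_efficiency
            for d in (0.0, 1.0, 3.0, 10.0)
        ]
        assert ps == sorted(ps)

    def test_undefined_features_skipped(self, targets):
        v = self.vector()
        v.by_protocol[90.0]["mean_amplitude"] = math.nan
        res = feature_fitness(v, targets)
        assert (90.0, "mean_amplitude") not in res.per_feature
        assert res.valid

    def test_sd_below_floor_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            make_targets({(90.0, "latency"): (12.0, 0.5)})  # floor for ms features is 1
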