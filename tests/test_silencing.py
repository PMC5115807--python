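import numpy as np
import pytest

from nartools import (
    SpikeRaster,
    VoltageTrace,
    detect_spikes,
    light_dark_ratios,
    zone_rates,
)
from nartools.synthetic import SilencingGenParams, gen_silencing_experiment


def flat_trace(level=-65.0, duration=2.0, rate=5000.0):
    n = int(duration * rate) + 1
    time = np.arange(n) / rate
    return VoltageTrace(time=time, potential=np.full(n, level),
                        injection_epoch=(0.0, duration))


class TestDetectSpikes:
    def test_flat_trace_no_spikes(self):
        assert detect_spikes(flat_trace()).size == 0

    def test_refractory_merges_close_crossings(self):
        rate = 10_000.0
        n = 1001
        time = np.arange(n) / rate
        v = np.full(n, -65.0)
        v[100:103] = 10.0  # first crossing
        v[110:113] = 10.0  # second crossing 1 ms later
        trace = VoltageTrace(time=time, potential=v, injection_epoch=(0.0, 0.1))
        assert detect_spikes(trace, refractory=0.002).size == 1
        assert detect_spikes(trace, refractory=0.0005).size == 2

    def test_nonfinite_samples_rejected(self):
        trace = flat_trace()
        bad = VoltageTrace(time=trace.time,
                           potential=np.where(trace.time < 1.0, np.nan, -65.0),
                           injection_epoch=(0.0, 2.0))
        with pytest.raises(ValueError):
            detect_spikes(bad)

    def test_ground_truth_recovery(self):
        params = SilencingGenParams(baseline_rate=10.0, sweep_count=10, seed=21)
        traces, truth = gen_silencing_experiment(params)
        recovered, total, false_pos = 0, 0, 0
        for trace, true_times in zip(traces, truth.spike_times):
            detected = detect_spikes(trace, threshold=-10.0)
            total += true_times.size
            for t in true_times:
                if detected.size and np.min(np.abs(detected - t)) < 0.002:
                    recovered += 1
            for t in detected:
                if true_times.size == 0 or np.min(np.abs(true_times - t)) >= 0.002:
                    false_pos += 1
        assert recovered >= 0.95 * total
        assert false_pos == 0


class TestZoneRates:
    def test_unit_bins(self):
        raster = SpikeRaster([np.array([0.5, 1.5, 2.5])])
        stats = zone_rates(raster, np.array([0.0, 1.0, 2.0, 3.0]))
        np.testing.assert_array_equal(stats.counts, [[1, 1, 1]])
        np.testing.assert_array_equal(stats.rate, [1.0, 1.0, 1.0])

    def test_empty_raster(self):
        stats = zone_rates(SpikeRaster([np.array([])]), np.arange(0.0, 4.0))
        assert stats.counts.sum() == 0
        assert stats.n_outside == 0

    def test_conservation_within_window(self):
        params = SilencingGenParams(sweep_count=5, seed=3)
        _, truth = gen_silencing_experiment(params)
        edges = np.arange(0.0, 14.0)
        stats = zone_rates(truth, edges)
        total_in = sum(
            int(((t >= 0) & (t < 13.0)).sum()) for t in truth.spike_times
        )
        assert stats.counts.sum() == total_in
        assert stats.counts.sum() + stats.n_outside == sum(
            t.size for t in truth.spike_times
        )

    def test_silenced_light_zones_empty(self):
        params = SilencingGenParams(silenced_rate=0.0, sweep_count=10, seed=5)
        _, truth = gen_silencing_experiment(params)
        stats = zone_rates(truth, np.arange(0.0, 14.0))
        # light epoch 1-11 s: zones 1..10 must be empty
        assert stats.counts[:, 1:11].sum() == 0

    def test_nonuniform_edges_rejected(self):
        with pytest.raises(ValueError):
            zone_rates(SpikeRaster([np.array([0.5])]), np.array([0.0, 1.0, 3.0]))


class TestLightDarkRatios:
    def _stats(self, rasters, protocol=""):
        return zone_rates(SpikeRaster(rasters), np.arange(0.0, 13.0))

    def test_identical_rasters_give_unity(self):
        rasters = [np.array([0.5, 3.2, 7.7, 11.5]) for _ in range(4)]
        ratios = light_dark_ratios(self._stats(rasters), self._stats(rasters))
        assert all(r == pytest.approx(1.0) for r in ratios.values())

    def test_complete_silencing_gives_zero_during(self):
        light = [np.array([0.5, 11.5])] * 3  # nothing in 1-11 s
        dark = [np.array([0.5, 4.0, 8.0, 11.5])] * 3
        ratios = light_dark_ratios(self._stats(light), self._stats(dark))
        assert ratios["during"] == 0.0

    def test_zero_dark_denominator_flagged(self):
        light = [np.array([5.0])] * 2
        dark = [np.array([])] * 2
        ratios = light_dark_ratios(self._stats(light), self._stats(dark))
        assert np.isnan(ratios["during"])

    def test_rebound_ratio_matches_poisson_expectation(self):
        # rebound at 2x baseline: after-window ratio ~ 2 at large sweep count
        light_params = SilencingGenParams(
            sweep_count=300, baseline_rate=10.0, silenced_rate=0.5,
            rebound_rate=20.0, seed=17,
        )
        dark_params = SilencingGenParams(
            sweep_count=300, baseline_rate=10.0, light_epoch=None, seed=18,
        )
        _, light_truth = gen_silencing_experiment(light_params)
        _, dark_truth = gen_silencing_experiment(dark_params)
        edges = np.arange(0.0, 13.0)
        ratios = light_dark_ratios(
            zone_rates(light_truth, edges), zone_rates(dark_truth, edges)
        )
        assert ratios["after"] == pytest.approx(2.0, rel=0.15)
        assert ratios["during"] < 0.15
        assert ratios["before"] == pytest.approx(1.0, rel=0.2)

    def test_mismatched_grids_rejected(self):
        light = zone_rates(SpikeRaster([np.array([0.5])]), np.arange(0.0, 13.0))
        dark = zone_rates(SpikeRaster([np.array([0.5])]), np.arange(0.0, 12.0))
        with pytest.raises(ValueError):
            light_dark_ratios(light, dark)


class TestGenerator:
    def test_determinism(self):
        a_traces, a_truth = gen_silencing_experiment(SilencingGenParams(seed=9))
        b_traces, b_truth = gen_silencing_experiment(SilencingGenParams(seed=9))
        for ta, tb in zip(a_traces, b_traces):
            assert np.array_equal(ta.potential, tb.potential)
        for ra, rb in zip(a_truth.spike_times, b_truth.spike_times):
            assert np.array_equal(ra, rb)

    def test_no_light_epoch_keeps_rate_constant(self):
        params = SilencingGenParams(
            sweep_count=200, baseline_rate=8.0, light_epoch=None, seed=4
        )
        _, truth = gen_silencing_experiment(params)
        stats = zone_rates(truth, np.arange(0.0, 13.0))
        # mean rate within injection zones close to the generating rate
        inj_rates = stats.rate[:12]
        assert inj_rates.mean() == pytest.approx(8.0, rel=0.1)
        assert inj_rates.std() < 1.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            SilencingGenParams(baseline_rate=-1.0)

    def test_hyperpolarization_during_light(self):
        params = SilencingGenParams(
            baseline_rate=0.0, silenced_rate=0.0, rebound_rate=0.0,
            noise_sd=0.0, seed=0,
        )
        traces, _ = gen_silencing_experiment(params)
        v, t = traces[0].potential, traces[0].time
        during = v[(t > 2.0) & (t < 10.0)].mean()
        before = v[(t > 0.2) & (t < 0.9)].mean()
        assert before - during == pytest.approx(params.hyperpolarization)
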