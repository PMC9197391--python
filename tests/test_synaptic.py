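import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import match_events
from pairclamp.intrinsic import detect_spikes
from pairclamp.recordings import PairRecording, Recording, Sweep, Trace
from pairclamp.stats import wilcoxon_signed_rank
from pairclamp.synaptic import (
    EvokedResponse,
    classify_connection,
    detect_spontaneous_epsps,
    epsp_change,
    evoked_response,
    paired_pulse_ratio,
)
from pairclamp.synth import (
    BackgroundParams,
    NeuronParams,
    ProtocolSpec,
    SynapseParams,
    simulate_neuron,
    simulate_pair,
)
from pairclamp.synth.background import events_to_wave, kernel_peak_delay, psp_kernel


def _presyn_trains(pair):
    return [
        detect_spikes(sw.voltage, sweep_index=i) for i, sw in enumerate(pair.pre.sweeps)
    ]


def _response(amps, noise_sd=2.0, latency=2.0):
    amps = np.asarray(amps, dtype=float)
    return EvokedResponse(
        amplitudes=amps,
        mean_amplitudes=amps.mean(axis=0),
        latency=latency,
        failures=amps < 2 * noise_sd,
        noise_sd=noise_sd,
        mode="EPSC",
    )


class TestEvokedResponse:
    def test_mean_includes_failures(self, connected_pair):
        # Measured mean tracks the generator's failure-inclusive mean; that
        # mean itself follows the closed form (1 - failure_p) * A_1 up to
        # binomial sampling noise in the realized failure count.
        pair, truth = connected_pair
        resp = evoked_response(pair, _presyn_trains(pair))
        clean_mean = truth.evoked_amplitudes[:, 0].mean()
        assert resp.mean_epsc1 == pytest.approx(clean_mean, rel=0.15)
        a1 = truth.analytic_amplitudes[0]
        binom_sd = a1 * np.sqrt(0.3 * 0.7 / 30)
        assert abs(clean_mean - 0.7 * a1) <= 3 * binom_sd
        assert resp.latency == pytest.approx(2.0, abs=1.0)
        assert resp.amplitudes.shape == (30, 10)

    def test_zero_synapse_below_criterion(self, unconnected_pair):
        pair, _ = unconnected_pair
        resp = evoked_response(pair, _presyn_trains(pair))
        # Null mean carries only the (positively biased) extremum of averaged
        # noise; it must stay below the connection criterion.
        assert resp.mean_epsc1 < 1.5 * resp.noise_sd

    def test_epsp_mode_alignment(self, neuron):
        # EPSP mode on a 10-pulse 20 Hz train: 10 amplitudes per trial.
        syn = SynapseParams(q=2.0, failure_p=0.0)
        proto = ProtocolSpec(kind="presyn_train", n_trials=6)
        pair, truth = simulate_pair(neuron, neuron, synapse=syn, protocol=proto, seed=8)
        # Rebuild the postsynaptic channel as current clamp (depolarizing).
        kernel = psp_kernel(syn.tau_rise, syn.tau_decay, 0.1)
        sweeps = []
        rng = np.random.default_rng(0)
        for t in range(6):
            n = pair.pre.sweeps[0].voltage.n
            wave = np.zeros(n)
            for spk, amp in zip(truth.spike_times[t], truth.evoked_amplitudes[t]):
                i = int(round((spk + syn.latency) / 0.1))
                wave[i : i + kernel.size] += amp * kernel[: n - i]
            v = -70.0 + wave + rng.normal(0, 0.05, n)
            sweeps.append(
                Sweep(Trace(v, 0.1), Trace(np.zeros(n), 0.1, "current"),
                      protocol_tag="presyn_train")
            )
        post = Recording("post", "current_clamp", "before", sweeps)
        epsp_pair = PairRecording(pair.pre, post)
        resp = evoked_response(epsp_pair, _presyn_trains(pair), mode="EPSP")
        assert resp.amplitudes.shape == (6, 10)
        assert resp.mean_epsc1 == pytest.approx(truth.analytic_amplitudes[0], rel=0.2)

    def test_mode_channel_mismatch(self, connected_pair):
        pair, _ = connected_pair
        with pytest.raises(ValueError):
            evoked_response(pair, _presyn_trains(pair), mode="EPSP")

    def test_no_spikes(self, connected_pair):
        pair, _ = connected_pair
        empty = [
            detect_spikes(Trace(np.full(10000, -70.0), 0.1))
            for _ in pair.post.sweeps
        ]
        with pytest.raises(ValueError):
            evoked_response(pair, empty)

    def test_failure_averaging_identity(self, connected_pair):
        # mean = (1 - failure rate) * mean(non-failure) on the truth table.
        _, truth = connected_pair
        clean = truth.evoked_amplitudes[:, 0]
        fails = truth.failure_mask[:, 0]
        if fails.any() and (~fails).any():
            assert clean.mean() == pytest.approx(
                (1 - fails.mean()) * clean[~fails].mean()
            )


class TestClassifyConnection:
    def test_connected_example(self):
        resp = _response(np.full((12, 2), 15.0), noise_sd=3.0, latency=2.3)
        call = classify_connection(resp)
        assert call.connected and call.threshold_used == pytest.approx(4.5)

    def test_subthreshold_amplitude(self):
        resp = _response(np.full((12, 2), 4.0), noise_sd=3.0, latency=2.0)
        assert not classify_connection(resp).connected  # 4 < 4.5

    def test_latency_gate(self):
        resp = _response(np.full((12, 2), 15.0), noise_sd=3.0, latency=4.0)
        assert not classify_connection(resp).connected

    def test_population_evoked_inverts_latency(self):
        resp = _response(np.full((12, 2), 15.0), noise_sd=3.0, latency=4.0)
        assert classify_connection(resp, population_evoked=True).connected

    def test_min_trials(self):
        resp = _response(np.full((5, 2), 15.0))
        with pytest.raises(ValueError):
            classify_connection(resp)

    @given(
        amp=st.floats(0.1, 30.0), noise=st.floats(0.5, 10.0),
        bump=st.floats(0.0, 10.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_amplitude_and_noise(self, amp, noise, bump):
        base = classify_connection(_response(np.full((12, 2), amp), noise_sd=noise))
        louder = classify_connection(
            _response(np.full((12, 2), amp + bump), noise_sd=noise)
        )
        noisier = classify_connection(
            _response(np.full((12, 2), amp), noise_sd=noise + bump)
        )
        assert louder.connected or not base.connected
        assert base.connected or not noisier.connected


class TestPPR:
    def test_identical_pulses(self):
        assert paired_pulse_ratio(_response(np.full((12, 2), 10.0))) == 1.0

    def test_generator_matches_recursion(self):
        # Oracle: R_2 = 1 - 0.5 exp(-0.25) evaluated independently; ratio of
        # failure-inclusive means over 500 trials.
        from pairclamp.synth import simulate_evoked_train

        syn = SynapseParams(U=0.5, tau_rec=200.0)
        amps, _ = simulate_evoked_train(syn, n_trials=500, noise_sd=2.0, seed=9)
        resp = _response(amps)
        expected = 1 - 0.5 * np.exp(-0.25)
        sem = 0.03
        assert paired_pulse_ratio(resp) == pytest.approx(expected, abs=3 * sem)

    def test_tm_grid_within_3_sem(self):
        from pairclamp.synth import analytic_amplitudes, simulate_evoked_train

        for u in (0.2, 0.5, 0.8):
            for tau in (100.0, 400.0):
                syn = SynapseParams(U=u, tau_rec=tau)
                amps, _ = simulate_evoked_train(syn, n_trials=400, noise_sd=1.0,
                                                seed=int(u * 10 + tau))
                a = analytic_amplitudes(syn, 2, 20.0)
                ppr = amps[:, 1].mean() / amps[:, 0].mean()
                # Delta-method SE of the ratio of means.
                m1, m2 = amps[:, 0].mean(), amps[:, 1].mean()
                s1 = amps[:, 0].std(ddof=1) / np.sqrt(400)
                s2 = amps[:, 1].std(ddof=1) / np.sqrt(400)
                se = abs(ppr) * np.sqrt((s1 / m1) ** 2 + (s2 / m2) ** 2)
                assert ppr == pytest.approx(a[1] / a[0], abs=3 * se + 1e-9)

    def test_facilitating_response(self):
        amps = np.column_stack([np.full(12, 10.0), np.full(12, 14.0)])
        assert paired_pulse_ratio(_response(amps)) > 1.0

    def test_undefined_at_noise_floor(self):
        resp = _response(np.full((12, 2), 0.5), noise_sd=2.0)
        assert np.isnan(paired_pulse_ratio(resp))

    def test_needs_two_pulses(self):
        with pytest.raises(ValueError):
            paired_pulse_ratio(_response(np.full((12, 1), 10.0)))


def _epsp_trace(rate_per_min, amp_lo, amp_hi, noise_sd, duration_ms, seed):
    rng = np.random.default_rng(seed)
    dt = 0.1
    n = int(duration_ms / dt)
    n_ev = rng.poisson(rate_per_min * duration_ms / 60000.0)
    times = np.sort(rng.uniform(0, duration_ms - 100.0, n_ev))
    amps = rng.uniform(amp_lo, amp_hi, n_ev)
    wave = events_to_wave(times, amps, n, dt, 1.0, 15.0)
    v = -73.0 + wave + rng.normal(0, noise_sd, n)
    return Trace(v, dt), times + kernel_peak_delay(1.0, 15.0)


class TestSpontaneousEpsps:
    def test_recall_precision_rate(self):
        tr, truth_peaks = _epsp_trace(100.0, 0.4, 2.0, 0.1, 120000.0, seed=10)
        events, summary = detect_spontaneous_epsps(tr)
        det = np.array([e.peak_time for e in events])
        tp, fp, fn = match_events(det, truth_peaks, tol_ms=5.0)
        assert tp / (tp + fn) >= 0.9
        assert tp / max(tp + fp, 1) >= 0.9
        assert abs(summary.frequency - truth_peaks.size / 2.0) <= 0.1 * (
            truth_peaks.size / 2.0
        )

    def test_flat_trace_false_positives(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            tr = Trace(-73.0 + rng.normal(0, 0.05, 600000), 0.1)
            _, summary = detect_spontaneous_epsps(tr)
            assert summary.frequency <= 2.0

    def test_sub_floor_events_rejected(self):
        tr, _ = _epsp_trace(100.0, 0.2, 0.2, 0.05, 60000.0, seed=11)
        events, _ = detect_spontaneous_epsps(tr)
        assert len(events) == 0

    def test_amplitude_window_invariant(self):
        tr, _ = _epsp_trace(150.0, 0.1, 5.0, 0.1, 60000.0, seed=12)
        events, _ = detect_spontaneous_epsps(tr)
        assert all(0.3 <= e.amplitude <= 10.0 for e in events)

    def test_too_short(self):
        with pytest.raises(ValueError):
            detect_spontaneous_epsps(Trace(np.zeros(1000), 0.1))

    def test_cutoff_above_nyquist(self):
        tr = Trace(np.zeros(700000), 0.1)
        with pytest.raises(ValueError):
            detect_spontaneous_epsps(tr, cutoff_hz=6000.0)


class TestEpspChange:
    def _summary(self, neuron, bg, seed):
        proto = ProtocolSpec(kind="spontaneous", total_duration=60000.0)
        rec, _ = simulate_neuron(neuron, proto, noise_sd=0.1, seed=seed, background=bg)
        _, summary = detect_spontaneous_epsps(rec.sweeps[0].voltage)
        return summary

    def test_identity(self):
        s = detect_spontaneous_epsps(
            _epsp_trace(100.0, 0.4, 2.0, 0.1, 60000.0, seed=13)[0]
        )[1]
        assert epsp_change(s, s) == (0.0, 0.0)

    def test_rate_increase_detected(self, neuron):
        # Programmed rate scale (127/90): paired Wilcoxon on per-cell
        # frequencies significant in >= 80 % of cohort seeds.
        bg = BackgroundParams()
        bg_after = BackgroundParams(
            rate_per_min=bg.rate_per_min * 127.0 / 90.0,
            amp_median=bg.amp_median * 0.41 / 0.38,
        )
        n_sig = 0
        n_seeds, n_cells = 5, 8
        for seed in range(n_seeds):
            deltas = []
            for cell in range(n_cells):
                s = 10000 + 100 * seed + cell
                before = self._summary(neuron, bg, s)
                after = self._summary(neuron, bg_after, s + 37)
                deltas.append(epsp_change(before, after)[0])
            if wilcoxon_signed_rank(deltas).p_value < 0.05:
                n_sig += 1
        assert n_sig >= 0.8 * n_seeds

    def test_null_type_i_rate(self, neuron):
        bg = BackgroundParams()
        n_sig = 0
        n_seeds, n_cells = 10, 8
        for seed in range(n_seeds):
            deltas = []
            for cell in range(n_cells):
                s = 20000 + 100 * seed + cell
                before = self._summary(neuron, bg, s)
                after = self._summary(neuron, bg, s + 53)
                deltas.append(epsp_change(before, after)[0])
            if wilcoxon_signed_rank(deltas).p_value < 0.05:
                n_sig += 1
        # ~5 % nominal rate; generous binomial bound at 10 runs.
        assert n_sig <= 3

    def test_duration_guard(self):
        s = detect_spontaneous_epsps(
            _epsp_trace(100.0, 0.4, 2.0, 0.1, 60000.0, seed=14)[0]
        )[1]
        short = type(s)(s.frequency, s.mean_amplitude, s.n_events, 0.5)
        with pytest.raises(ValueError):
            epsp_change(short, s)
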