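import numpy as np
import pytest

from conftest import RM_PROTOCOL, match_events
from pairclamp.intrinsic import (
    detect_spikes,
    fi_curve,
    firing_threshold_60pA,
    input_resistance,
    phase_plot,
    resting_potential,
)
from pairclamp.recordings import Recording, Sweep, Trace
from pairclamp.synth import (
    BackgroundParams,
    EffectSpec,
    NeuronParams,
    ProtocolSpec,
    apply_effect,
    make_spike_template,
    simulate_neuron,
)

SINGLE_STEP = ProtocolSpec(kind="iv_steps", step_range=(100.0, 100.0, 20.0))


class TestDetectSpikes:
    def test_flat_trace(self):
        tr = Trace(np.full(20000, -70.0), 0.1)
        assert detect_spikes(tr).n == 0

    def test_noiseless_matches_truth(self, iv_noiseless, neuron):
        rec, truth = iv_noiseless
        for sw, times in zip(rec.sweeps, truth.spike_times):
            st = detect_spikes(sw.voltage)
            assert st.n == times.size
            if st.n:
                assert np.max(np.abs(st.times - times)) <= 0.2
                assert np.max(np.abs(st.thresholds - neuron.V_T)) <= 0.5

    def test_noisy_f1(self, neuron):
        # 50 noisy sweeps at 0.1 mV: F1 >= 0.99 with +/- 1 ms matching.
        tp = fp = fn = 0
        for seed in range(50):
            rec, truth = simulate_neuron(neuron, SINGLE_STEP, noise_sd=0.1, seed=seed)
            st = detect_spikes(rec.sweeps[0].voltage)
            a, b, c = match_events(st.times, truth.spike_times[0], tol_ms=1.0)
            tp, fp, fn = tp + a, fp + b, fn + c
        f1 = 2 * tp / (2 * tp + fp + fn)
        assert f1 >= 0.99

    def test_dc_offset_invariance(self, iv_noisy):
        rec, _ = iv_noisy
        tr = rec.sweeps[9].voltage
        shifted = Trace(tr.samples + 10.0, tr.dt)
        a, b = detect_spikes(tr), detect_spikes(shifted)
        assert np.array_equal(a.times, b.times)
        np.testing.assert_allclose(a.thresholds + 10.0, b.thresholds)

    def test_too_short(self):
        with pytest.raises(ValueError):
            detect_spikes(Trace(np.zeros(3), 0.1))


class TestPhasePlot:
    def test_threshold_point_near_truth(self, iv_noiseless, neuron):
        rec, truth = iv_noiseless
        sw, times = rec.sweeps[10], truth.spike_times[10]
        pp = phase_plot(sw.voltage, float(times[0]))
        assert pp.threshold_point[0] == pytest.approx(neuron.V_T, abs=0.5)
        assert pp.threshold_point[1] >= 1.5

    def test_ramp_has_no_crossing(self):
        tr = Trace(-70.0 + 0.0005 * np.arange(20000), 0.1)
        with pytest.raises(ValueError):
            phase_plot(tr, 500.0)

    def test_time_axis_translation_invariance(self, iv_noiseless):
        rec, truth = iv_noiseless
        sw, t_spk = rec.sweeps[10], float(truth.spike_times[10][0])
        shifted = Trace(sw.voltage.samples, sw.voltage.dt, t0=1000.0)
        a = phase_plot(sw.voltage, t_spk)
        b = phase_plot(shifted, t_spk + 1000.0)
        assert a.threshold_point == pytest.approx(b.threshold_point)

    def test_window_exceeds_trace(self, iv_noiseless):
        rec, _ = iv_noiseless
        with pytest.raises(ValueError):
            phase_plot(rec.sweeps[10].voltage, 1.0)


class TestThreshold60pA:
    def test_recovery(self, iv_noisy, neuron):
        rec, _ = iv_noisy
        est = firing_threshold_60pA(rec)
        assert est.value == pytest.approx(neuron.V_T, abs=0.5)

    def test_shift_recovery(self, neuron):
        after = apply_effect(neuron, EffectSpec(), "after_stim")
        proto = ProtocolSpec(kind="iv_steps")
        diffs = []
        for seed in range(4):
            r1, _ = simulate_neuron(neuron, proto, noise_sd=0.1, seed=100 + seed)
            r2, _ = simulate_neuron(after, proto, noise_sd=0.1, seed=200 + seed)
            diffs.append(
                firing_threshold_60pA(r2).value - firing_threshold_60pA(r1).value
            )
        assert np.mean(diffs) == pytest.approx(-2.7, abs=0.5)

    def test_missing_step_raises(self, neuron):
        rec, _ = simulate_neuron(neuron, SINGLE_STEP, seed=1)
        with pytest.raises(ValueError):
            firing_threshold_60pA(rec)

    def test_no_spike_returns_absent(self):
        # A cell whose rheobase is 80 pA: no spike at the 60 pA step.
        cell = NeuronParams(V_T=-38.0, V_reset=-58.0)
        rec, truth = simulate_neuron(cell, ProtocolSpec(kind="iv_steps"), seed=2)
        assert truth.spike_times[8].size == 0  # 60 pA sweep silent
        est = firing_threshold_60pA(rec)
        assert est.value is None and "no spike" in est.diagnostic


def _spike_at(template, v, dt, t_ms):
    """Place a template so its take-off sample lands at t_ms.

    A 4-ms ramp leads from the baseline into the template start so the
    placement edge itself cannot pass the detector's excursion gate.
    """
    i0 = int(round(t_ms / dt)) - template.take_off_index
    n_ramp = int(round(4.0 / dt))
    v[i0 - n_ramp : i0] = np.linspace(v[i0 - n_ramp - 1], template.samples[0],
                                      n_ramp, endpoint=False)
    v[i0 : i0 + template.samples.size] = template.samples


class TestFICurve:
    def test_arithmetic_from_definition(self):
        # Spikes at 100, 150, 250 ms: count 3, inst freqs {20, 10} Hz,
        # mean 15 Hz, first-two 20 Hz.
        dt = 0.1
        tpl = make_spike_template(-41.0, -61.0, dt)
        v = np.full(7500, -70.0)
        for t in (100.0, 150.0, 250.0):
            _spike_at(tpl, v, dt, t)
        cmd = np.zeros(7500)
        cmd[1000:6000] = 80.0
        sweep = Sweep(Trace(v, dt), Trace(cmd, dt, "current"),
                      protocol_tag="iv_step", step_amplitude=80.0)
        rec = Recording("c", "current_clamp", "before", [sweep],
                        meta={"step_start_ms": 0.0, "step_duration_ms": 500.0})
        fic = fi_curve(rec)
        assert fic.spike_counts[0] == 3
        assert fic.mean_inst_freq[0] == pytest.approx(15.0, rel=0.01)
        assert fic.first_two_freq[0] == pytest.approx(20.0, rel=0.01)
        assert fic.rheobase == 80.0

    def test_degenerate_steps(self, iv_noiseless):
        rec, _ = iv_noiseless
        fic = fi_curve(rec)
        silent = fic.spike_counts == 0
        assert np.all(np.isnan(fic.mean_inst_freq[silent]))
        assert np.all(np.isnan(fic.first_two_freq[silent]))

    def test_monotone_noiseless(self, iv_noiseless):
        rec, _ = iv_noiseless
        fic = fi_curve(rec)
        assert np.all(np.diff(fic.spike_counts) >= 0)

    def test_rheobase_not_higher_after_effect(self, neuron):
        after = apply_effect(neuron, EffectSpec(), "after_stim")
        proto = ProtocolSpec(kind="iv_steps")
        r1, _ = simulate_neuron(neuron, proto, noise_sd=0.0, seed=3)
        r2, _ = simulate_neuron(after, proto, noise_sd=0.0, seed=3)
        assert fi_curve(r2).rheobase <= fi_curve(r1).rheobase

    def test_fi_increase_power(self, neuron):
        # Paired Wilcoxon on per-cell mean counts, before vs after the
        # programmed excitability shift: detected in >= 80 % of cohort seeds.
        from pairclamp.stats import wilcoxon_signed_rank

        after = apply_effect(neuron, EffectSpec(), "after_stim")
        proto = ProtocolSpec(kind="iv_steps")
        n_sig = 0
        n_seeds, n_cells = 5, 8
        for seed in range(n_seeds):
            diffs = []
            for cell in range(n_cells):
                s = 1000 * seed + cell
                r1, _ = simulate_neuron(neuron, proto, noise_sd=0.1, seed=s)
                r2, _ = simulate_neuron(after, proto, noise_sd=0.1, seed=s + 500)
                diffs.append(
                    fi_curve(r2).spike_counts.mean() - fi_curve(r1).spike_counts.mean()
                )
            if wilcoxon_signed_rank(diffs).p_value < 0.05:
                n_sig += 1
        assert n_sig >= 0.8 * n_seeds

    def test_missing_annotations(self, neuron):
        rec, _ = simulate_neuron(neuron, SINGLE_STEP, seed=4)
        rec.meta.pop("step_start_ms")
        with pytest.raises(ValueError):
            fi_curve(rec)


class TestInputResistance:
    def test_noiseless_exact(self, neuron):
        rec, _ = simulate_neuron(neuron, RM_PROTOCOL, noise_sd=0.0, seed=5)
        props = input_resistance(rec)
        assert props.input_resistance == pytest.approx(278.0, rel=1e-3)
        assert props.resting_potential == pytest.approx(-73.0, abs=1e-6)
        assert props.fit_points.shape[1] == 2

    def test_noisy_recovery(self, neuron):
        for seed in range(10):
            rec, _ = simulate_neuron(neuron, RM_PROTOCOL, noise_sd=0.1, seed=seed)
            props = input_resistance(rec)
            assert abs(props.input_resistance - 278.0) / 278.0 < 0.05

    def test_before_after_medians(self, neuron):
        after = apply_effect(neuron, EffectSpec(), "after_stim")
        r_before, r_after = [], []
        for seed in range(6):
            rec, _ = simulate_neuron(neuron, RM_PROTOCOL, noise_sd=0.1, seed=seed)
            r_before.append(input_resistance(rec).input_resistance)
            rec, _ = simulate_neuron(after, RM_PROTOCOL, noise_sd=0.1, seed=seed + 50)
            r_after.append(input_resistance(rec).input_resistance)
        assert np.median(r_before) == pytest.approx(278.0, rel=0.02)
        assert np.median(r_after) == pytest.approx(305.0, rel=0.02)

    def test_too_few_steps(self, neuron):
        proto = ProtocolSpec(kind="iv_steps", step_range=(-20.0, 0.0, 20.0))
        rec, _ = simulate_neuron(neuron, proto, seed=6)
        with pytest.raises(ValueError):
            input_resistance(rec)


class TestRestingPotential:
    def test_constant(self):
        tr = Trace(np.full(200000, -73.0), 0.1)
        assert resting_potential(tr) == -73.0

    def test_too_short(self):
        with pytest.raises(ValueError):
            resting_potential(Trace(np.zeros(1000), 0.1))

    def test_robust_to_epsps(self, neuron):
        bg = BackgroundParams(rate_per_min=100.0, amp_median=0.6, amp_sigma=0.4)
        proto = ProtocolSpec(kind="spontaneous", total_duration=20000.0)
        rec, _ = simulate_neuron(neuron, proto, noise_sd=0.1, seed=7, background=bg)
        est = resting_potential(rec.sweeps[0].voltage)
        assert est == pytest.approx(-73.0, abs=0.3)

    def test_unbiased_under_symmetric_noise(self, neuron):
        proto = ProtocolSpec(kind="spontaneous", total_duration=10000.0)
        errs = []
        for seed in range(20):
            rec, _ = simulate_neuron(neuron, proto, noise_sd=0.2, seed=seed)
            errs.append(resting_potential(rec.sweeps[0].voltage) + 73.0)
        assert abs(np.mean(errs)) < 0.05
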