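import numpy as np
import pytest

from pairclamp.synth import (
    NeuronParams,
    ProtocolSpec,
    SynapseParams,
    simulate_neuron,
    simulate_pair,
)

IV_PROTOCOL = ProtocolSpec(kind="iv_steps")
RM_PROTOCOL = ProtocolSpec(kind="iv_steps", step_range=(-100.0, 40.0, 20.0))


@pytest.fixture(scope="session")
def neuron():
    return NeuronParams()


@pytest.fixture(scope="session")
def iv_noiseless(neuron):
    """Noiseless I-V recording with exact spike-time truth."""
    return simulate_neuron(neuron, IV_PROTOCOL, noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def iv_noisy(neuron):
    return simulate_neuron(neuron, IV_PROTOCOL, noise_sd=0.1, seed=12)


@pytest.fixture(scope="session")
def connected_pair(neuron):
    """30-trial evoked-train pair with a depressing synapse."""
    protocol = ProtocolSpec(kind="presyn_train", n_trials=30)
    return simulate_pair(
        neuron, neuron, synapse=SynapseParams(), protocol=protocol, seed=21
    )


@pytest.fixture(scope="session")
def unconnected_pair(neuron):
    protocol = ProtocolSpec(kind="presyn_train", n_trials=30)
    return simulate_pair(neuron, neuron, synapse=None, protocol=protocol, seed=22)


@pytest.fixture(scope="session")
def small_recording(neuron):
    """Small, fast recording for I/O tests."""
    proto = ProtocolSpec(
        kind="iv_steps", step_range=(-40.0, 40.0, 20.0), step_duration=50.0,
        pre_ms=10.0, post_ms=10.0,
    )
    rec, _ = simulate_neuron(neuron, proto, noise_sd=0.1, seed=31)
    rec.leak_pA = 10.0
    rec.seal_Gohm = 2.0
    return rec


def match_events(detected: np.ndarray, truth: np.ndarray, tol_ms: float):
    """Greedy one-to-one matching; returns (tp, fp, fn)."""
    detected = np.asarray(detected, dtype=float)
    truth = np.asarray(truth, dtype=float)
    used = np.zeros(detected.size, dtype=bool)
    tp = 0
    for t in truth:
        if detected.size == 0:
            break
        d = np.abs(detected - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol_ms:
            tp += 1
            used[j] = True
    return tp, int(detected.size - tp), int(truth.size - tp)
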