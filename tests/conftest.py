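import numpy as np
import pytest

from fsephys.simulate.neuron import FSNeuronParams
from fsephys.simulate.synapse import SynapseParams
from fsephys.sweeps import CellRecording, StepProtocol, StimTrain, Sweep


@pytest.fixture(scope="session")
def quiet_sweep():
    """Constant -70 mV current-clamp trace."""
    return Sweep(
        samples=np.full(5000, -70.0),
        dt=0.02,
        modality="current_clamp",
        stimulus=StepProtocol(0.0, 10.0, 50.0),
        sweep_id="quiet",
    )


def make_spike_train_trace(
    peak_times_ms,
    dt=0.02,
    total_ms=None,
    baseline_mV=-70.0,
    peak_mV=30.0,
    rise_ms=0.3,
    fall_ms=0.5,
):
    """Piecewise-linear (triangular) spikes at known times on a flat
    baseline; returns (Sweep, peak_indices)."""
    if total_ms is None:
        total_ms = max(peak_times_ms) + 20.0
    n = int(round(total_ms / dt))
    v = np.full(n, float(baseline_mV))
    t = np.arange(n) * dt
    for tp in peak_times_ms:
        up = (t >= tp - rise_ms) & (t <= tp)
        down = (t > tp) & (t <= tp + fall_ms)
        v[up] = baseline_mV + (peak_mV - baseline_mV) * (
            1 - (tp - t[up]) / rise_ms
        )
        v[down] = baseline_mV + (peak_mV - baseline_mV) * (
            1 - (t[down] - tp) / fall_ms
        )
    sweep = Sweep(
        samples=v,
        dt=dt,
        modality="current_clamp",
        stimulus=StepProtocol(600.0, 0.0, total_ms),
        sweep_id="spikes",
    )
    idx = np.array([int(round(tp / dt)) for tp in peak_times_ms])
    return sweep, idx


@pytest.fixture(scope="session")
def small_cell():
    """Three-sweep current-clamp cell with increasing AP counts."""
    sweeps = []
    for k, (amp, n_spikes) in enumerate([(300, 3), (400, 8), (500, 12)]):
        times = [20.0 + 10.0 * i for i in range(n_spikes)]
        sw, _ = make_spike_train_trace(times, total_ms=220.0)
        sweeps.append(
            Sweep(
                samples=sw.samples,
                dt=sw.dt,
                modality="current_clamp",
                stimulus=StepProtocol(float(amp), 10.0, 200.0),
                sweep_id=f"s{k}",
            )
        )
    return CellRecording(cell_id="cell0", genotype="WT/WT", sweeps=sweeps)


@pytest.fixture(scope="session")
def fast_neuron_params():
    return FSNeuronParams()


@pytest.fixture(scope="session")
def quiet_synapse_params():
    return SynapseParams(noise_sd_pA=0.0)
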