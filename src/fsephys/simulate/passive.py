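"""Ideal passive-membrane responses for voltage-clamp test pulses.

For a command step of ``delta_V`` across a series resistance into an RC
cell (membrane resistance R_m parallel to C_m) the pipette current is::

    I(t) = I_hold + dV/(R_s + R_m) + [dV/R_s - dV/(R_s + R_m)] exp(-t/tau)

with ``tau = C_m (R_s R_m / (R_s + R_m))`` -- the textbook whole-cell test
pulse used to read series and membrane resistance during a recording.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from ..sweeps import StepProtocol, Sweep

__all__ = ["simulate_test_pulse"]


def simulate_test_pulse(
    R_series_MOhm: float,
    R_membrane_MOhm: float,
    C_m_pF: float,
    delta_V_mV: float = -5.0,
    onset_ms: float = 20.0,
    duration_ms: float = 100.0,
    total_ms: float = 140.0,
    dt: float = 0.1,
    holding_current_pA: float = -40.0,
    noise_sd_pA: float = 0.0,
    seed: Optional[int] = None,
    sweep_id: str = "testpulse",
) -> Sweep:
    """Synthesize a voltage-clamp test-pulse sweep (current in pA)."""
    rs, rm = R_series_MOhm, R_membrane_MOhm
    tau_ms = 1e-3 * C_m_pF * (rs * rm / (rs + rm))
    n = int(round(total_ms / dt))
    t = np.arange(n) * dt
    i_ss = delta_V_mV / (rs + rm) * 1e3  # pA
    i_peak = delta_V_mV / rs * 1e3
    on = (t >= onset_ms) & (t < onset_ms + duration_ms)
    i = np.full(n, float(holding_current_pA))
    tt = t[on] - onset_ms
    i[on] += i_ss + (i_peak - i_ss) * np.exp(-tt / tau_ms)
    # relaxation back after the pulse
    off = t >= onset_ms + duration_ms
    if off.any():
        t_off = t[off] - (onset_ms + duration_ms)
        i_end = i_ss + (i_peak - i_ss) * np.exp(-duration_ms / tau_ms)
        i[off] += (i_end - i_ss - i_peak + i_ss) * np.exp(-t_off / tau_ms)
    if noise_sd_pA > 0:
        rng = np.random.default_rng(seed)
        i = i + rng.normal(0, noise_sd_pA, n)
    return Sweep(
        samples=i,
        dt=dt,
        modality="voltage_clamp",
        stimulus=StepProtocol(
            amplitude_pA=i_peak, onset_ms=onset_ms, duration_ms=duration_ms
        ),
        sweep_id=sweep_id,
    )
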