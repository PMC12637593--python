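"""Depressing GABAergic synapse generator (resource-depletion model).

Release follows the classic depression-only resource recursion: with
utilization U and recovery time constant tau_rec, the available resource
before pulse n obeys

    R_1 = 1,   R_{n+1} = 1 - (1 - R_n (1 - U)) * exp(-dt_n / tau_rec)

and the true underlying amplitude of pulse n is ``unitary_scale * U * R_n``.
For a pulse pair this gives the closed form A2/A1 = 1 - U exp(-dt/tau_rec).
Each release event is convolved with a difference-of-exponentials IPSC
kernel (rise tau_r, decay tau_d, peak-normalized) and written as an inward
(negative) current deflection on top of a holding current, with optional
Gaussian noise.

``release_model='binomial'`` replaces the deterministic mean with per-site
binomial release over ``n_sites`` independent sites, each releasing with
probability U when available and recovering with probability
1 - exp(-dt/tau_rec) between pulses; its expectation equals the
deterministic recursion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from ..sweeps import StimTrain, Sweep

__all__ = [
    "SynapseParams",
    "release_amplitudes",
    "ipsc_kernel",
    "simulate_ipsc_train",
]


@dataclass(frozen=True)
class SynapseParams:
    """Generative parameters of one PV->PYR connection.

    ``unitary_scale_pA`` is the peak IPSC magnitude a full resource pool
    would produce at U = 1; the first-pulse response is
    ``unitary_scale_pA * U``.
    """

    U: float = 0.60
    tau_rec_ms: float = 200.0
    unitary_scale_pA: float = 2000.0
    tau_rise_ms: float = 0.5
    tau_decay_ms: float = 8.0
    release_model: str = "deterministic_mean"
    n_sites: int = 10
    holding_current_pA: float = -50.0
    noise_sd_pA: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.U <= 1):
            raise ValueError("U must be in (0, 1]")
        if min(self.tau_rec_ms, self.tau_rise_ms, self.tau_decay_ms) <= 0:
            raise ValueError("time constants must be > 0")
        if self.tau_decay_ms <= self.tau_rise_ms:
            raise ValueError("tau_decay_ms must exceed tau_rise_ms")
        if self.release_model not in ("deterministic_mean", "binomial"):
            raise ValueError(f"unknown release_model {self.release_model!r}")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")

    def with_(self, **kw) -> "SynapseParams":
        return replace(self, **kw)


def release_amplitudes(
    params: SynapseParams,
    pulse_times_ms,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """True underlying IPSC peak magnitudes (pA, positive) per pulse."""
    times = np.asarray(pulse_times_ms, dtype=float)
    n = times.size
    if params.release_model == "deterministic_mean":
        amps = np.empty(n)
        R = 1.0
        for i in range(n):
            amps[i] = params.unitary_scale_pA * params.U * R
            if i + 1 < n:
                dt = times[i + 1] - times[i]
                R = 1.0 - (1.0 - R * (1.0 - params.U)) * np.exp(
                    -dt / params.tau_rec_ms
                )
        return amps
    if rng is None:
        raise ValueError("binomial release requires an rng")
    # per-site simulation; expectation equals the deterministic recursion
    avail = np.ones(params.n_sites, dtype=bool)
    amps = np.empty(n)
    per_site = params.unitary_scale_pA / params.n_sites
    for i in range(n):
        released = avail & (rng.random(params.n_sites) < params.U)
        amps[i] = per_site * released.sum()
        avail = avail & ~released
        if i + 1 < n:
            dt = times[i + 1] - times[i]
            p_rec = 1.0 - np.exp(-dt / params.tau_rec_ms)
            avail = avail | (rng.random(params.n_sites) < p_rec)
    return amps


def kernel_peak_time_ms(tau_rise_ms: float, tau_decay_ms: float) -> float:
    r, d = tau_rise_ms, tau_decay_ms
    return r * d / (d - r) * np.log(d / r)


def ipsc_kernel(t_ms: np.ndarray, tau_rise_ms: float, tau_decay_ms: float) -> np.ndarray:
    """Peak-normalized difference-of-exponentials, zero for t < 0."""
    t = np.asarray(t_ms, dtype=float)
    k = np.where(
        t >= 0,
        np.exp(-np.maximum(t, 0) / tau_decay_ms)
        - np.exp(-np.maximum(t, 0) / tau_rise_ms),
        0.0,
    )
    tp = kernel_peak_time_ms(tau_rise_ms, tau_decay_ms)
    peak = np.exp(-tp / tau_decay_ms) - np.exp(-tp / tau_rise_ms)
    return k / peak


def simulate_ipsc_train(
    params: SynapseParams,
    stim: StimTrain,
    dt: float = 0.1,
    seed: Optional[int] = None,
    duration_ms: Optional[float] = None,
    sweep_id: str = "ipsc",
) -> Sweep:
    """Synthesize a voltage-clamp sweep of IPSCs evoked by ``stim``.

    Events superpose linearly; deflections are inward (negative).  The sweep
    extends ``10 * tau_decay`` past the last pulse unless ``duration_ms`` is
    given.  Deterministic given ``seed``.
    """
    if dt > 0.1:
        raise ValueError("dt must be <= 0.1 ms (10 kHz or finer)")
    times = np.asarray(stim.pulse_times_ms, dtype=float)
    if np.any(np.diff(times) < dt):
        raise ValueError("pulses closer than one sample interval")
    rng = np.random.default_rng(seed)
    if duration_ms is None:
        duration_ms = times[-1] + 10.0 * params.tau_decay_ms + 5.0
    n = int(np.ceil(duration_ms / dt))
    t = np.arange(n) * dt
    amps = release_amplitudes(params, times, rng)
    current = np.full(n, params.holding_current_pA)
    for t0, a in zip(times, amps):
        current -= a * ipsc_kernel(t - t0, params.tau_rise_ms, params.tau_decay_ms)
    if params.noise_sd_pA > 0:
        current = current + rng.normal(0.0, params.noise_sd_pA, size=n)
    return Sweep(
        samples=current,
        dt=dt,
        modality="voltage_clamp",
        stimulus=stim,
        sweep_id=sweep_id,
    )
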