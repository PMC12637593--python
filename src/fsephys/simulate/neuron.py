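"""Single-compartment conductance-based fast-spiking neuron.

The model is a Hodgkin-Huxley-style fast-spiking template with four ionic
currents:

* leak,
* transient Na (m^3 h),
* a fast high-threshold Kv3-like delayed rectifier (n^2) that supplies the
  rapid repolarization of the fast-spiking phenotype,
* a slow Kv2 delayed rectifier (a^2 h_inact) split into two populations:
  homomeric channels and silent-subunit heteromers.  The two populations
  share activation kinetics; the heteromer steady-state inactivation curve
  is shifted by ``delta_inact_mV`` (hyperpolarized, default -35 mV, in the
  -40..-30 mV range reported for silent-subunit heteromers), so heteromers
  inactivate at interspike potentials where homomers remain available.
  ``f_het`` is the fraction of total Kv2 conductance assembled as
  heteromers; a full knockout corresponds to ``f_het = 0``.

Membrane equation (V in mV, t in ms, conductances in nS, C in pF, currents
in pA)::

    C dV/dt = -g_L (V - E_L) - g_Na m^3 h (V - E_Na)
              - g_Kv3 n^2 (V - E_K)
              - g_Kv2 [(1 - f) h_hom + f h_het] a^2 (V - E_K)
              + I_inj(t) + noise

Integration is fixed-step: forward Euler for V and exponential Euler for
the gating variables, at an internal step of at most 0.005 ms; the trace is
then decimated to the requested sampling interval.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from numba import njit

from ..sweeps import StepProtocol, Sweep

__all__ = ["FSNeuronParams", "simulate_fs_neuron", "SimulationError"]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class FSNeuronParams:
    """Biophysical parameters; defaults reproduce an adult cortical PV-cell
    phenotype (rest near -74.5 mV, ~85 mV spikes of ~0.22 ms half-width,
    input resistance tens of MOhm)."""

    C_pF: float = 110.2805
    g_leak_nS: float = 13.1693
    E_leak_mV: float = -76.7047
    g_Na_nS: float = 17698.7239
    E_Na_mV: float = 62.0
    g_Kv3_nS: float = 1500.0
    E_K_mV: float = -90.0
    g_Kv2_total_nS: float = 1123.6582
    f_het: float = 0.5
    delta_inact_mV: float = -38.7859
    noise_sd_pA: float = 0.0
    V_init_mV: float = -74.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_het <= 1.0):
            raise ValueError("f_het must be in [0, 1]")
        for name in ("C_pF", "g_leak_nS", "g_Na_nS", "g_Kv3_nS"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.g_Kv2_total_nS < 0:
            raise ValueError("g_Kv2_total_nS must be >= 0")

    def with_(self, **kw) -> "FSNeuronParams":
        return replace(self, **kw)


# Gating-kinetics constants shared by every cell (the dataclass carries the
# per-cell conductance/geometry knobs).  Boltzmann midpoints/slopes in mV;
# time constants in ms as (base, amplitude, center, width) Gaussian bells.
KINETICS = np.array(
    [
        # Na activation m: Vhalf, k, tau_base, tau_amp, tau_center, tau_width
        -37.2825, 6.1079, 0.0236, 0.1002, -36.1459, 37.0086,
        # Na inactivation h: Vhalf, k, tau_base, tau_amp, tau_center, tau_width
        -64.8027, 4.3957, 0.1411, 5.2481, -52.0, 20.6839,
        # Kv3 activation n: Vhalf, k, tau_base, tau_amp, tau_center, tau_width
        -1.153, 7.7458, 0.06, 0.9, -40.6747, 19.3896,
        # Kv2 activation a: Vhalf, k, tau_base, tau_amp, tau_center, tau_width
        -25.0, 3.5195, 0.4189, 3.0197, -49.1815, 18.0,
        # Kv2 inactivation: homomer Vhalf, shared slope, tau (ms)
        -32.0, 7.4849, 150.0,
    ]
)

_MAX_INTERNAL_DT_MS = 0.005


@njit(cache=True)
def _boltz(v, vhalf, k):
    return 1.0 / (1.0 + np.exp(-(v - vhalf) / k))


@njit(cache=True)
def _bell(v, base, amp, center, width):
    return base + amp * np.exp(-((v - center) / width) ** 2)


@njit(cache=True)
def _integrate(
    V0,
    dt,
    n_steps,
    i_inj,
    noise,
    C,
    gL,
    EL,
    gNa,
    ENa,
    gKv3,
    EK,
    gKv2,
    f_het,
    d_inact,
    kin,
):
    """Fixed-step integration; returns state trajectories (V and gates)."""
    V = np.empty(n_steps + 1)
    m = np.empty(n_steps + 1)
    h = np.empty(n_steps + 1)
    n = np.empty(n_steps + 1)
    a = np.empty(n_steps + 1)
    hhom = np.empty(n_steps + 1)
    hhet = np.empty(n_steps + 1)

    ivh = kin[24]
    ik = kin[25]
    itau = kin[26]

    v = V0
    # start gates at steady state for V0
    mm = _boltz(v, kin[0], kin[1])
    hh = 1.0 - _boltz(v, kin[6], kin[7])
    nn = _boltz(v, kin[12], kin[13])
    aa = _boltz(v, kin[18], kin[19])
    hom = 1.0 - _boltz(v, ivh, ik)
    het = 1.0 - _boltz(v, ivh + d_inact, ik)

    V[0] = v
    m[0] = mm
    h[0] = hh
    n[0] = nn
    a[0] = aa
    hhom[0] = hom
    hhet[0] = het

    g_hom = gKv2 * (1.0 - f_het)
    g_het = gKv2 * f_het

    for i in range(n_steps):
        # ionic currents at current state
        ina = gNa * mm * mm * mm * hh * (v - ENa)
        ikv3 = gKv3 * nn * nn * (v - EK)
        ikv2 = (g_hom * hom + g_het * het) * aa * aa * (v - EK)
        il = gL * (v - EL)
        dv = (-il - ina - ikv3 - ikv2 + i_inj[i] + noise[i]) / C
        v_new = v + dt * dv
        if not np.isfinite(v_new):
            return V[: i + 1], m[: i + 1], h[: i + 1], n[: i + 1], a[: i + 1], hhom[: i + 1], hhet[: i + 1]

        # gating: exponential Euler toward steady state at the old voltage
        m_inf = _boltz(v, kin[0], kin[1])
        tau_m = _bell(v, kin[2], kin[3], kin[4], kin[5])
        h_inf = 1.0 - _boltz(v, kin[6], kin[7])
        tau_h = _bell(v, kin[8], kin[9], kin[10], kin[11])
        n_inf = _boltz(v, kin[12], kin[13])
        tau_n = _bell(v, kin[14], kin[15], kin[16], kin[17])
        a_inf = _boltz(v, kin[18], kin[19])
        tau_a = _bell(v, kin[20], kin[21], kin[22], kin[23])
        hom_inf = 1.0 - _boltz(v, ivh, ik)
        het_inf = 1.0 - _boltz(v, ivh + d_inact, ik)

        mm += (m_inf - mm) * (1.0 - np.exp(-dt / tau_m))
        hh += (h_inf - hh) * (1.0 - np.exp(-dt / tau_h))
        nn += (n_inf - nn) * (1.0 - np.exp(-dt / tau_n))
        aa += (a_inf - aa) * (1.0 - np.exp(-dt / tau_a))
        hom += (hom_inf - hom) * (1.0 - np.exp(-dt / itau))
        het += (het_inf - het) * (1.0 - np.exp(-dt / itau))

        v = v_new
        V[i + 1] = v
        m[i + 1] = mm
        h[i + 1] = hh
        n[i + 1] = nn
        a[i + 1] = aa
        hhom[i + 1] = hom
        hhet[i + 1] = het

    return V, m, h, n, a, hhom, hhet


def simulate_fs_neuron(
    params: FSNeuronParams,
    protocol: StepProtocol,
    dt: float = 0.02,
    seed: Optional[int] = None,
    total_ms: Optional[float] = None,
    sweep_id: str = "cc",
    return_states: bool = False,
    kinetics=None,
):
    """Simulate one current-clamp sweep under a square current step.

    ``dt`` is the *recorded* sampling interval (<= 0.05 ms, i.e. >= 20 kHz);
    integration runs at an internal step <= 0.005 ms and the voltage trace
    is decimated to ``dt``.  Deterministic given ``seed``.

    With ``return_states=True`` returns ``(sweep, states_dict)`` where the
    states are at the internal resolution (used by conservation checks).
    """
    if dt > 0.05:
        raise ValueError("dt must be <= 0.05 ms (50 kHz or finer)")
    if total_ms is None:
        total_ms = protocol.onset_ms + protocol.duration_ms + 100.0
    if protocol.onset_ms + protocol.duration_ms > total_ms:
        raise ValueError("protocol extends past the sweep")

    # internal step: integer divisor of dt, <= 0.005 ms
    n_sub = int(np.ceil(dt / _MAX_INTERNAL_DT_MS))
    dt_int = dt / n_sub
    n_rec = int(round(total_ms / dt))
    n_steps = n_rec * n_sub

    t_int = np.arange(n_steps) * dt_int
    i_inj = np.where(
        (t_int >= protocol.onset_ms)
        & (t_int < protocol.onset_ms + protocol.duration_ms),
        protocol.amplitude_pA,
        0.0,
    )
    if params.noise_sd_pA > 0:
        rng = np.random.default_rng(seed)
        # white current noise with per-sample SD scaled so the recorded-rate
        # variance is dt-independent
        noise = rng.normal(0.0, params.noise_sd_pA * np.sqrt(0.02 / dt_int), n_steps)
    else:
        noise = np.zeros(n_steps)

    out = _integrate(
        params.V_init_mV,
        dt_int,
        n_steps,
        i_inj,
        noise,
        params.C_pF,
        params.g_leak_nS,
        params.E_leak_mV,
        params.g_Na_nS,
        params.E_Na_mV,
        params.g_Kv3_nS,
        params.E_K_mV,
        params.g_Kv2_total_nS,
        params.f_het,
        params.delta_inact_mV,
        kinetics if kinetics is not None else KINETICS,
    )
    V = out[0]
    if V.size != n_steps + 1:
        t_fail = (V.size - 1) * dt_int
        raise SimulationError(
            f"non-finite voltage at t = {t_fail:.3f} ms "
            f"(internal step {dt_int} ms); reduce the step size"
        )
    sweep = Sweep(
        samples=V[:-1:n_sub].copy(),
        dt=dt,
        modality="current_clamp",
        stimulus=protocol,
        sweep_id=sweep_id,
    )
    if return_states:
        names = ("V", "m", "h", "n", "a", "h_hom", "h_het")
        states = dict(zip(names, out))
        states["dt_ms"] = dt_int
        states["i_inj"] = i_inj
        states["noise"] = noise
        return sweep, states
    return sweep


def ionic_current_pA(params: FSNeuronParams, states: dict, i: int) -> float:
    """Total membrane current (pA) at internal step ``i`` from recorded
    states -- the right-hand side the integrator used, for conservation
    checks."""
    v = states["V"][i]
    m, h, n, a = states["m"][i], states["h"][i], states["n"][i], states["a"][i]
    hom, het = states["h_hom"][i], states["h_het"][i]
    ina = params.g_Na_nS * m**3 * h * (v - params.E_Na_mV)
    ikv3 = params.g_Kv3_nS * n**2 * (v - params.E_K_mV)
    g_hom = params.g_Kv2_total_nS * (1 - params.f_het)
    g_het = params.g_Kv2_total_nS * params.f_het
    ikv2 = (g_hom * hom + g_het * het) * a**2 * (v - params.E_K_mV)
    il = params.g_leak_nS * (v - params.E_leak_mV)
    return -il - ina - ikv3 - ikv2 + states["i_inj"][i] + states["noise"][i]
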