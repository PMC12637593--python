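"""IPSC measurement and short-term-plasticity analysis for voltage-clamp
paired recordings.

Sign conventions: recordings use the amplifier convention (inward current
negative), so GABAergic currents recorded with a high-chloride internal are
inward (negative deflections); all amplitudes are reported as positive
magnitudes.  Conductance traces from :func:`current_to_conductance` deflect
positively, so the same peak-measurement machinery runs on either trace via
a polarity argument.

Paired-pulse overlap is corrected by fitting a mono-exponential to the
first IPSC's decay and subtracting its extrapolated residual from the
second peak; five-pulse trains are deliberately left uncorrected (their
normalized amplitudes therefore carry a quantifiable superposition bias at
short intervals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.optimize import curve_fit

from .sweeps import PassiveProps, StimTrain, Sweep

__all__ = [
    "ConductanceParams",
    "IPSCEvent",
    "DecayFit",
    "PPRResult",
    "TrainResult",
    "MeasurementError",
    "measure_passive",
    "detect_ipsc",
    "fit_first_decay",
    "ppr",
    "train_response",
    "current_to_conductance",
    "unitary_amplitude",
]


class MeasurementError(ValueError):
    pass


@dataclass(frozen=True)
class ConductanceParams:
    """Recording-condition constants for the current->conductance solve.

    Defaults: holding potential -70 mV; effective resting (leak reversal)
    potential -16 mV and inhibitory reversal -2.5 mV as measured for the
    high-chloride internal; excitatory conductance assumed zero (AMPA/NMDA
    pharmacologically blocked).
    """

    V_hold_mV: float = -70.0
    E_rest_mV: float = -16.0
    E_i_mV: float = -2.5
    R_series_MOhm: float = 19.0
    R_membrane_MOhm: float = 210.0
    g_e_is_zero: bool = True

    def __post_init__(self) -> None:
        if self.R_series_MOhm < 0 or self.R_membrane_MOhm <= 0:
            raise ValueError("resistances must be positive (R_series >= 0)")


@dataclass
class IPSCEvent:
    stim_time_ms: float
    baseline: float
    raw_peak: float
    amplitude: float
    peak_time_ms: float
    units: str = "pA"


@dataclass
class DecayFit:
    """Mono-exponential decay anchored at the pre-stimulus baseline:
    f(t) = baseline + A * exp(-(t - t_ref)/tau)."""

    baseline: float
    A: float
    tau_ms: float
    t_ref_ms: float
    rss: float

    def __call__(self, t_ms) -> np.ndarray:
        t = np.asarray(t_ms, dtype=float)
        return self.baseline + self.A * np.exp(-(t - self.t_ref_ms) / self.tau_ms)


@dataclass
class PPRResult:
    delta_t_ms: float
    A1: float
    A2_corrected: float
    A2_uncorrected: float
    ppr: float
    ppr_uncorrected: float
    units: str
    n_repeats: int = 1


@dataclass
class TrainResult:
    delta_t_ms: float
    amplitudes: np.ndarray
    normalized: np.ndarray
    units: str
    correction: str = "none"


@dataclass(frozen=True)
class Windows:
    """Peak-measurement windows relative to each stimulus time (ms)."""

    baseline: tuple = (-5.0, -0.5)
    search: tuple = (0.5, 20.0)  # first 0.5 ms blanked (stimulus artifact)


# ---------------------------------------------------------------------------
# passive properties from a voltage-clamp test pulse


def measure_passive(
    sweep: Sweep,
    delta_V_mV: float,
    onset_ms: float,
    duration_ms: float,
) -> PassiveProps:
    """Series/membrane resistance, time constant and capacitance from a
    voltage-clamp test-pulse sweep (current in pA).

    The capacitive transient ``I(t) = I_ss + A exp(-(t-onset)/tau)`` is fit
    over the early pulse; the onset-extrapolated peak gives
    ``R_series = dV/I_peak`` and the steady-state change gives
    ``R_series + R_membrane``.  ``C_m = tau * (1/R_series + 1/R_membrane)``
    (the clamp time constant sees R_series parallel R_membrane).
    """
    sweep.require_modality("voltage_clamp")
    i = sweep.samples  # pA
    dt = sweep.dt
    i_on = int(round(onset_ms / dt))
    i_off = int(round((onset_ms + duration_ms) / dt))
    if i_on < 2 or i_off - i_on < 10 or i_off > sweep.n_samples:
        raise MeasurementError("test pulse does not fit the sweep")
    baseline = float(np.mean(i[max(0, i_on - int(5 / dt)) : i_on]))
    n_ss = max(1, int(0.2 * (i_off - i_on)))
    i_ss = float(np.mean(i[i_off - n_ss : i_off]))
    d_iss = i_ss - baseline  # pA
    if d_iss == 0:
        raise MeasurementError("no steady-state current change during pulse")

    # transient fit over [onset, onset + min(duration/2, 10 ms)]
    i_fit_end = min(i_off, i_on + int(round(min(duration_ms / 2, 10.0) / dt)))
    t = (np.arange(i_on, i_fit_end) - i_on) * dt
    y = i[i_on:i_fit_end]
    a0 = y[np.argmax(np.abs(y - i_ss))] - i_ss
    if a0 == 0:
        raise MeasurementError("no capacitive transient detected")

    def model(t, A, tau):
        return i_ss + A * np.exp(-t / tau)

    try:
        popt, _ = curve_fit(model, t, y, p0=[a0, 0.5], maxfev=5000)
    except RuntimeError as exc:
        raise MeasurementError(f"transient fit failed: {exc}") from exc
    A_fit, tau = float(popt[0]), float(abs(popt[1]))
    i_peak = i_ss + A_fit  # onset-extrapolated

    # dV in mV over pA gives GOhm; scale to MOhm via nA
    r_s = delta_V_mV / ((i_peak - baseline) * 1e-3)  # MOhm
    r_total = delta_V_mV / (d_iss * 1e-3)
    r_m = r_total - r_s
    if r_m > 1e4:
        warnings.warn("membrane resistance estimate > 10 GOhm", stacklevel=2)
    c_m = 1e3 * tau * (1.0 / r_s + 1.0 / max(r_m, 1e-9))  # pF
    return PassiveProps(
        R_series_MOhm=r_s,
        R_membrane_MOhm=r_m if r_m > 0 else None,
        tau_ms=tau,
        C_m_pF=c_m,
        holding_current_pA=baseline,
    )


# ---------------------------------------------------------------------------
# IPSC peaks and decay


def _window_slice(sweep: Sweep, t0: float, t1: float) -> slice:
    i0 = max(0, int(np.ceil(t0 / sweep.dt)))
    i1 = min(sweep.n_samples, int(np.floor(t1 / sweep.dt)) + 1)
    if i1 <= i0:
        raise MeasurementError(f"empty window [{t0}, {t1}] ms")
    return slice(i0, i1)

def detect_ipsc(
    sweep: Sweep,
    stim_time_ms: float,
    windows: Windows = Windows(),
    polarity: int = -1,
    baseline: Optional[float] = None,
) -> IPSCEvent:
    """Measure one postsynaptic event after ``stim_time_ms``.

    ``polarity=-1`` (default) looks for inward (negative) current
    deflections; ``+1`` for positive deflections (conductance traces).
    Amplitude is the positive magnitude of peak minus baseline.
    """
    sweep.require_modality("voltage_clamp") if sweep.modality == "voltage_clamp" else None
    y = sweep.samples
    if baseline is None:
        b0, b1 = windows.baseline
        baseline = float(np.mean(y[_window_slice(sweep, stim_time_ms + b0,
                                                 stim_time_ms + b1)]))
    s0, s1 = windows.search
    sl = _window_slice(sweep, stim_time_ms + s0, stim_time_ms + s1)
    seg = y[sl]
    k = int(np.argmin(seg)) if polarity < 0 else int(np.argmax(seg))
    peak = float(seg[k])
    return IPSCEvent(
        stim_time_ms=stim_time_ms,
        baseline=baseline,
        raw_peak=peak,
        amplitude=abs(peak - baseline),
        peak_time_ms=(sl.start + k) * sweep.dt,
        units="pA" if sweep.modality == "voltage_clamp" else "a.u.",
    )


def fit_first_decay(
    sweep: Sweep,
    ipsc1: IPSCEvent,
    t_end_ms: float,
    t_offset_ms: float = 1.0,
    tau_bounds_ms: tuple = (0.5, 500.0),
) -> DecayFit:
    """Baseline-anchored mono-exponential fit of the first IPSC's decay over
    ``[peak1 + t_offset, t_end]``; raises :class:`MeasurementError` when the
    fit fails or tau leaves ``tau_bounds_ms`` (caller may fall back to an
    uncorrected ratio)."""
    t0 = ipsc1.peak_time_ms + t_offset_ms
    sl = _window_slice(sweep, t0, t_end_ms)
    if sl.stop - sl.start < 10:
        raise MeasurementError("decay-fit window has fewer than 10 samples")
    t = np.arange(sl.start, sl.stop) * sweep.dt
    y = sweep.samples[sl]
    b = ipsc1.baseline
    a0 = ipsc1.raw_peak - b

    def model(t, A, tau):
        return b + A * np.exp(-(t - ipsc1.peak_time_ms) / tau)

    try:
        popt, _ = curve_fit(model, t, y, p0=[a0, 5.0], maxfev=5000)
    except RuntimeError as exc:
        raise MeasurementError(f"decay fit did not converge: {exc}") from exc
    A, tau = float(popt[0]), float(popt[1])
    if not (tau_bounds_ms[0] < tau < tau_bounds_ms[1]):
        raise MeasurementError(
            f"decay tau {tau:.2f} ms outside {tau_bounds_ms}"
        )
    rss = float(np.sum((model(t, *popt) - y) ** 2))
    return DecayFit(baseline=b, A=A, tau_ms=tau,
                    t_ref_ms=ipsc1.peak_time_ms, rss=rss)


# ---------------------------------------------------------------------------
# conductance conversion


def current_to_conductance(
    sweep: Sweep, params: ConductanceParams
) -> Sweep:
    """Solve the voltage-clamp circuit pointwise for the inhibitory
    conductance trace g_i(t) in nS.

    With measured pipette current I(t) (pA -> nA internally), the membrane
    potential seen by the cell is ``V(t) = V_hold - I(t) R_series`` (series
    resistance drop), the leak component is ``(V - E_rest)/R_membrane``, and
    the synaptic current is the remainder, so
    ``g_i(t) = [I(t) - (V(t) - E_rest)/R_membrane] / (V(t) - E_i)``.
    Excitatory conductance is assumed zero (blocked pharmacologically).
    """
    sweep.require_modality("voltage_clamp")
    i_nA = sweep.samples * 1e-3
    v = params.V_hold_mV - i_nA * params.R_series_MOhm  # mV
    denom = v - params.E_i_mV
    bad = np.abs(denom) < 1.0
    if np.any(bad):
        t_bad = float(np.argmax(bad) * sweep.dt)
        raise MeasurementError(
            f"|V(t) - E_i| < 1 mV at t = {t_bad:.2f} ms; "
            "conductance conversion ill-conditioned"
        )
    i_syn = i_nA - (v - params.E_rest_mV) / params.R_membrane_MOhm  # nA
    g = 1e3 * i_syn / denom  # nA/mV = uS -> nS
    out = Sweep(
        samples=g,
        dt=sweep.dt,
        modality="voltage_clamp",
        stimulus=sweep.stimulus,
        sweep_id=sweep.sweep_id + ":g",
    )
    return out


def conductance_to_current(
    g_nS: np.ndarray, params: ConductanceParams
) -> np.ndarray:
    """Forward model (exact inverse of :func:`current_to_conductance`):
    pipette current (pA) produced by a known conductance waveform."""
    g_uS = np.asarray(g_nS, dtype=float) * 1e-3
    rs, rm = params.R_series_MOhm, params.R_membrane_MOhm
    num = g_uS * (params.V_hold_mV - params.E_i_mV) + (
        params.V_hold_mV - params.E_rest_mV
    ) / rm
    den = 1.0 + g_uS * rs + rs / rm
    return 1e3 * (num / den)  # nA -> pA


# ---------------------------------------------------------------------------
# paired-pulse and train analysis


def _clip_windows(windows: Windows, dt_next_ms: Optional[float]) -> Windows:
    """Clip the peak-search window at the next stimulus so overlapping
    events are not attributed to the wrong pulse."""
    if dt_next_ms is None:
        return windows
    s0, s1 = windows.search
    return Windows(baseline=windows.baseline,
                   search=(s0, min(s1, dt_next_ms - 0.5)))


def _event_pair(
    sweep: Sweep,
    t1: float,
    t2: float,
    windows: Windows,
    polarity: int,
    decay_t_offset_ms: float = 1.0,
) -> tuple:
    """(A1, A2_corrected, A2_uncorrected) on one trace."""
    ev1 = detect_ipsc(sweep, t1, _clip_windows(windows, t2 - t1), polarity)
    # second event measured against the first event's pre-stimulus baseline
    ev2 = detect_ipsc(sweep, t2, windows, polarity, baseline=ev1.baseline)
    a2_raw = ev2.amplitude
    fit_end = min(t2 - 0.5, sweep.duration_ms - sweep.dt)
    try:
        fit = fit_first_decay(sweep, ev1, fit_end, decay_t_offset_ms)
        residual = float(fit(ev2.peak_time_ms) - ev1.baseline)
        corrected = abs((ev2.raw_peak - ev1.baseline) - residual)
    except MeasurementError:
        warnings.warn(
            "first-IPSC decay fit failed; using uncorrected second peak",
            stacklevel=2,
        )
        corrected = a2_raw
    return ev1.amplitude, corrected, a2_raw


def ppr(
    sweeps,
    stim_pair: StimTrain,
    params: Optional[ConductanceParams] = None,
    windows: Windows = Windows(),
    units: str = "current",
    noise_floor: float = 0.0,
) -> PPRResult:
    """Decay-corrected paired-pulse ratio, averaged over repeat sweeps.

    The ratio is computed per sweep and then averaged (robust to slow
    drift).  ``units='conductance'`` converts each sweep with ``params``
    first and measures positive deflections on the g trace.  Sweeps whose
    first amplitude falls below ``noise_floor`` are excluded.
    """
    if isinstance(sweeps, Sweep):
        sweeps = [sweeps]
    if len(stim_pair.pulse_times_ms) != 2:
        raise ValueError("stim_pair must contain exactly two pulses")
    t1, t2 = stim_pair.pulse_times_ms
    polarity = -1
    vals = []
    for sw in sweeps:
        if units == "conductance":
            if params is None:
                raise ValueError("conductance PPR requires ConductanceParams")
            sw = current_to_conductance(sw, params)
            polarity = +1
        a1, a2c, a2r = _event_pair(sw, t1, t2, windows, polarity)
        if a1 <= noise_floor:
            warnings.warn("first IPSC below noise floor; sweep excluded",
                          stacklevel=2)
            continue
        vals.append((a1, a2c, a2r))
    if not vals:
        raise MeasurementError("no usable sweeps for PPR")
    arr = np.array(vals)
    return PPRResult(
        delta_t_ms=t2 - t1,
        A1=float(arr[:, 0].mean()),
        A2_corrected=float(arr[:, 1].mean()),
        A2_uncorrected=float(arr[:, 2].mean()),
        ppr=float((arr[:, 1] / arr[:, 0]).mean()),
        ppr_uncorrected=float((arr[:, 2] / arr[:, 0]).mean()),
        units=units,
        n_repeats=len(vals),
    )


def train_response(
    sweeps,
    stim_train: StimTrain,
    params: Optional[ConductanceParams] = None,
    windows: Windows = Windows(),
    units: str = "current",
) -> TrainResult:
    """Per-pulse amplitudes of a pulse train, normalized to pulse 1.

    Every peak is measured against the pre-train baseline and *no* decay
    correction is applied, matching the standard treatment of 5-pulse
    trains (overlap bias at short intervals is therefore retained).
    """
    if isinstance(sweeps, Sweep):
        sweeps = [sweeps]
    times = stim_train.pulse_times_ms
    dts = np.diff(times)
    delta_t = float(dts[0]) if len(dts) else 0.0
    polarity = -1
    all_amps = []
    for sw in sweeps:
        if units == "conductance":
            if params is None:
                raise ValueError("conductance analysis requires ConductanceParams")
            sw = current_to_conductance(sw, params)
            polarity = +1
        gaps = list(np.diff(times)) + [None]
        ev1 = detect_ipsc(sw, times[0], _clip_windows(windows, gaps[0]),
                          polarity)
        amps = [ev1.amplitude]
        for t, gap in zip(times[1:], gaps[1:]):
            ev = detect_ipsc(sw, t, _clip_windows(windows, gap), polarity,
                             baseline=ev1.baseline)
            amps.append(ev.amplitude)
        all_amps.append(amps)
    mean_amps = np.mean(np.array(all_amps), axis=0)
    if mean_amps[0] == 0:
        raise MeasurementError("first-pulse amplitude is zero")
    return TrainResult(
        delta_t_ms=delta_t,
        amplitudes=mean_amps,
        normalized=mean_amps / mean_amps[0],
        units=units,
    )


def unitary_amplitude(
    single_pulse_sweeps,
    stim_time_ms: float,
    params: Optional[ConductanceParams] = None,
    windows: Windows = Windows(),
) -> dict:
    """Mean single-AP IPSC amplitude over 3-5 repeats, in nA and (when
    ``params`` given) nS."""
    if isinstance(single_pulse_sweeps, Sweep):
        single_pulse_sweeps = [single_pulse_sweeps]
    if not single_pulse_sweeps:
        raise MeasurementError("no single-pulse sweeps")
    amps_pA = [
        detect_ipsc(sw, stim_time_ms, windows, -1).amplitude
        for sw in single_pulse_sweeps
    ]
    out = {"amplitude_nA": float(np.mean(amps_pA)) * 1e-3,
           "n_repeats": len(amps_pA)}
    if params is not None:
        amps_nS = [
            detect_ipsc(
                current_to_conductance(sw, params), stim_time_ms, windows, +1
            ).amplitude
            for sw in single_pulse_sweeps
        ]
        out["conductance_nS"] = float(np.mean(amps_nS))
    return out
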