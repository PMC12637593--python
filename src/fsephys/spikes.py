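"""Per-AP and per-trace waveform features from current-clamp sweeps.

Conventions (all configurable through :class:`DetectConfig` /
:class:`FeatureConfig`):

* APs are local voltage maxima above a peak cutoff (default 0 mV) separated
  by at least a refractory gap (default 1 ms).
* Threshold is the membrane potential at the first upstroke sample where
  dV/dt exceeds 4% of the maximum slope of that upstroke; dV/dt is taken by
  central differences over the window from the preceding interspike minimum
  (or 2 ms before the peak, for the first AP) to the peak.
* Height is peak minus threshold; half-width is the spike width at
  threshold + height/2 with linearly interpolated crossings; the interspike
  potential is the most negative potential between consecutive peaks.
* ``ISI_k`` denotes the interval between AP_k and AP_{k+1}, so
  "ISI_2-3" is ``t(AP_3) - t(AP_2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .sweeps import CellRecording, StepProtocol, Sweep

__all__ = [
    "DetectConfig",
    "FeatureConfig",
    "APEvent",
    "TraceFeatureSummary",
    "AdaptationMetrics",
    "FeatureError",
    "SelectionError",
    "detect_aps",
    "ap_threshold",
    "ap_height",
    "ap_half_width",
    "interspike_potential",
    "extract_events",
    "summarize_trace",
    "select_trace",
    "ahp_amplitude",
    "sag_voltage",
    "iv_fi_curves",
    "rheobase",
    "bin_by_rate",
    "adaptation",
    "METRICS",
]

#: per-AP metrics reported throughout the group analyses
METRICS = (
    "height_mV",
    "half_width_ms",
    "interspike_potential_mV",
    "threshold_V_mV",
    "max_slope_V_per_s",
)


class FeatureError(ValueError):
    """A spike is malformed for the requested feature."""


class SelectionError(ValueError):
    """No sweep satisfies the trace-selection rule."""


@dataclass(frozen=True)
class DetectConfig:
    peak_cutoff_mV: float = 0.0
    min_gap_ms: float = 1.0


@dataclass(frozen=True)
class FeatureConfig:
    detect: DetectConfig = field(default_factory=DetectConfig)
    #: fraction of the maximum upstroke slope defining threshold
    threshold_slope_fraction: float = 0.04
    #: upstroke window before the first AP's peak when there is no
    #: preceding interspike minimum
    first_ap_window_ms: float = 2.0
    #: post-train search window for the AHP trough
    ahp_window_ms: float = 50.0
    #: early-step window searched for the sag minimum
    sag_min_window_ms: float = 200.0
    #: fraction of the step tail averaged for steady-state voltage
    steady_state_fraction: float = 0.2


@dataclass
class APEvent:
    """Feature record for one action potential (1-based ``index``)."""

    index: int
    peak_index: int
    peak_time_ms: float
    peak_V_mV: float
    threshold_V_mV: float
    threshold_time_ms: float
    height_mV: float
    half_width_ms: float
    max_slope_V_per_s: float
    isi_ms: Optional[float] = None
    interspike_potential_mV: Optional[float] = None


@dataclass
class TraceFeatureSummary:
    sweep_id: str
    amplitude_pA: float
    n_APs: int
    firing_rate_Hz: float
    events: list
    is_selected: bool = False

    def metric_at(self, metric: str, ap_index: int) -> Optional[float]:
        """Value of ``metric`` at 1-based AP ``ap_index`` (None if absent)."""
        if ap_index < 1 or ap_index > self.n_APs:
            return None
        return getattr(self.events[ap_index - 1], metric)

    def metric_mean_first(self, metric: str, k: int = 10) -> Optional[float]:
        vals = [
            getattr(ev, metric)
            for ev in self.events[:k]
            if getattr(ev, metric) is not None
        ]
        return float(np.mean(vals)) if vals else None


@dataclass
class AdaptationMetrics:
    sweep_id: Optional[str]
    eligible: bool
    n_APs: int
    delta_isi_ms: Optional[float] = None
    delta_half_width_ms: Optional[float] = None
    delta_interspike_mV: Optional[float] = None


# ---------------------------------------------------------------------------
# detection and per-AP features


def detect_aps(sweep: Sweep, cfg: DetectConfig = DetectConfig()) -> np.ndarray:
    """Indices of AP peaks, ordered in time (empty array when silent)."""
    sweep.require_modality("current_clamp")
    distance = max(1, int(round(cfg.min_gap_ms / sweep.dt)))
    peaks, _ = find_peaks(
        sweep.samples, height=cfg.peak_cutoff_mV, distance=distance
    )
    return peaks.astype(int)


def _upstroke_start(
    v: np.ndarray, peak_idx: int, prev_peak_idx: Optional[int], dt: float, cfg: FeatureConfig
) -> int:
    if prev_peak_idx is not None and peak_idx - prev_peak_idx >= 2:
        seg = v[prev_peak_idx + 1 : peak_idx]
        return prev_peak_idx + 1 + int(np.argmin(seg))
    return max(0, peak_idx - int(round(cfg.first_ap_window_ms / dt)))


def ap_threshold(
    sweep: Sweep,
    peak_index: int,
    prev_peak_index: Optional[int] = None,
    cfg: FeatureConfig = FeatureConfig(),
):
    """Threshold voltage/time and max slope of one AP's upstroke.

    Returns ``(threshold_V_mV, threshold_time_ms, max_slope_V_per_s)``.
    dV/dt in mV/ms is numerically equal to V/s.
    """
    v = sweep.samples
    dt = sweep.dt
    start = _upstroke_start(v, peak_index, prev_peak_index, dt, cfg)
    if peak_index - start < 2:
        raise FeatureError(f"upstroke too short at peak index {peak_index}")
    # central differences on [start, peak]; one-sided at the edges
    seg = v[start : peak_index + 1]
    dvdt = np.gradient(seg, dt)
    max_slope = float(np.max(dvdt))
    if max_slope <= 0:
        raise FeatureError(f"non-positive max slope at peak index {peak_index}")
    above = np.nonzero(dvdt > cfg.threshold_slope_fraction * max_slope)[0]
    i = int(above[0]) if above.size else int(np.argmax(dvdt))
    return float(seg[i]), (start + i) * dt, max_slope


def ap_height(peak_V_mV: float, threshold_V_mV: float) -> float:
    h = peak_V_mV - threshold_V_mV
    if h < 0:
        raise FeatureError("threshold above peak")
    return h


def _cross_time(t0, v0, t1, v1, level):
    """Linear interpolation of the time where v crosses ``level``."""
    if v1 == v0:
        return t0
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def ap_half_width(
    sweep: Sweep,
    peak_index: int,
    threshold_V_mV: float,
    next_peak_index: Optional[int] = None,
    cfg: FeatureConfig = FeatureConfig(),
) -> float:
    """Spike width (ms) at threshold + height/2, interpolated crossings."""
    v = sweep.samples
    dt = sweep.dt
    v_half = threshold_V_mV + ap_height(v[peak_index], threshold_V_mV) / 2.0

    i = peak_index
    while i > 0 and v[i] > v_half:
        i -= 1
    if v[i] > v_half:
        raise FeatureError("rising half-height crossing not found")
    t_rise = _cross_time(i * dt, v[i], (i + 1) * dt, v[i + 1], v_half)

    end = next_peak_index if next_peak_index is not None else len(v) - 1
    j = peak_index
    while j < end and v[j] > v_half:
        j += 1
    if v[j] > v_half:
        raise FeatureError("falling half-height crossing not found")
    t_fall = _cross_time((j - 1) * dt, v[j - 1], j * dt, v[j], v_half)
    return float(t_fall - t_rise)


def interspike_potential(sweep: Sweep, peak_index: int, next_peak_index: int) -> float:
    """Most negative potential strictly between two consecutive peaks."""
    if next_peak_index - peak_index < 2:
        raise FeatureError("no samples between peaks")
    return float(np.min(sweep.samples[peak_index + 1 : next_peak_index]))


def extract_events(sweep: Sweep, cfg: FeatureConfig = FeatureConfig()) -> list:
    """Full per-AP feature table for one sweep."""
    peaks = detect_aps(sweep, cfg.detect)
    v = sweep.samples
    dt = sweep.dt
    events = []
    for k, p in enumerate(peaks):
        prev_p = int(peaks[k - 1]) if k > 0 else None
        next_p = int(peaks[k + 1]) if k + 1 < len(peaks) else None
        thr_v, thr_t, slope = ap_threshold(sweep, int(p), prev_p, cfg)
        ev = APEvent(
            index=k + 1,
            peak_index=int(p),
            peak_time_ms=p * dt,
            peak_V_mV=float(v[p]),
            threshold_V_mV=thr_v,
            threshold_time_ms=thr_t,
            height_mV=ap_height(float(v[p]), thr_v),
            half_width_ms=ap_half_width(sweep, int(p), thr_v, next_p, cfg),
            max_slope_V_per_s=slope,
            isi_ms=(p - prev_p) * dt if prev_p is not None else None,
            interspike_potential_mV=(
                interspike_potential(sweep, int(p), next_p)
                if next_p is not None
                else None
            ),
        )
        events.append(ev)
    return events


def summarize_trace(
    sweep: Sweep, cfg: FeatureConfig = FeatureConfig()
) -> TraceFeatureSummary:
    events = extract_events(sweep, cfg)
    stim = sweep.stimulus
    if isinstance(stim, StepProtocol):
        rate = len(events) / (stim.duration_ms / 1000.0)
        amp = stim.amplitude_pA
    else:
        rate = len(events) / (sweep.duration_ms / 1000.0)
        amp = float("nan")
    return TraceFeatureSummary(
        sweep_id=sweep.sweep_id,
        amplitude_pA=amp,
        n_APs=len(events),
        firing_rate_Hz=rate,
        events=events,
    )


# ---------------------------------------------------------------------------
# trace selection and per-cell metrics


def _step_sweeps_ascending(cell: CellRecording) -> list:
    sweeps = [
        s
        for s in cell.sweeps_of("current_clamp")
        if isinstance(s.stimulus, StepProtocol)
    ]
    return sorted(sweeps, key=lambda s: s.stimulus.amplitude_pA)


def select_trace(
    cell: CellRecording,
    cfg: FeatureConfig = FeatureConfig(),
    min_aps: int = 10,
) -> TraceFeatureSummary:
    """First sweep, in ascending injected-current order, with >= ``min_aps``
    APs; the standard rule analyzes its 2nd and 10th APs."""
    for sweep in _step_sweeps_ascending(cell):
        if sweep.stimulus.amplitude_pA <= 0:
            continue
        summary = summarize_trace(sweep, cfg)
        if summary.n_APs >= min_aps:
            summary.is_selected = True
            return summary
    raise SelectionError(
        f"cell {cell.cell_id!r}: no sweep with >= {min_aps} APs"
    )


def ahp_amplitude(
    sweep: Sweep, events: list, cfg: FeatureConfig = FeatureConfig()
) -> float:
    """Post-train afterhyperpolarization: last-AP threshold minus the
    minimum voltage in a window after the last peak (positive = trough
    below threshold)."""
    if not events:
        raise FeatureError("no APs in trace")
    last = events[-1]
    start = last.peak_index + 1
    stop = start + int(round(cfg.ahp_window_ms / sweep.dt))
    if stop > sweep.n_samples:
        warnings.warn("AHP window truncated at sweep end", stacklevel=2)
        stop = sweep.n_samples
    if start >= stop:
        raise FeatureError("no samples after last AP")
    return float(last.threshold_V_mV - np.min(sweep.samples[start:stop]))


def sag_voltage(sweep: Sweep, cfg: FeatureConfig = FeatureConfig()) -> float:
    """Sag on a hyperpolarizing step: steady-state voltage (mean over the
    final ``steady_state_fraction`` of the step) minus the early minimum
    (first ``sag_min_window_ms`` of the step)."""
    sweep.require_modality("current_clamp")
    stim = sweep.stimulus
    if not isinstance(stim, StepProtocol) or stim.amplitude_pA >= 0:
        raise ValueError("sag requires a hyperpolarizing step")
    dt = sweep.dt
    i0 = int(round(stim.onset_ms / dt))
    i1 = int(round((stim.onset_ms + stim.duration_ms) / dt))
    n_min = int(round(cfg.sag_min_window_ms / dt))
    n_ss = int(round(cfg.steady_state_fraction * (i1 - i0)))
    if i0 + n_min > i1 or n_ss < 1:
        raise ValueError("step too short for sag windows")
    v_min = float(np.min(sweep.samples[i0 : i0 + n_min]))
    v_ss = float(np.mean(sweep.samples[i1 - n_ss : i1]))
    return v_ss - v_min


def iv_fi_curves(cell: CellRecording, cfg: FeatureConfig = FeatureConfig()):
    """I-V (steady-state voltage deflection per subthreshold step) and f-I
    (firing rate per suprathreshold step) tables as DataFrames."""
    iv_rows, fi_rows = [], []
    for sweep in _step_sweeps_ascending(cell):
        stim = sweep.stimulus
        dt = sweep.dt
        i0 = int(round(stim.onset_ms / dt))
        i1 = int(round((stim.onset_ms + stim.duration_ms) / dt))
        baseline = float(np.mean(sweep.samples[:i0])) if i0 > 0 else float(
            sweep.samples[0]
        )
        n_aps = len(detect_aps(sweep, cfg.detect))
        rate = n_aps / (stim.duration_ms / 1000.0)
        fi_rows.append(
            {"sweep_id": sweep.sweep_id, "amplitude_pA": stim.amplitude_pA,
             "n_APs": n_aps, "rate_Hz": rate}
        )
        if n_aps == 0:
            n_ss = max(1, int(round(cfg.steady_state_fraction * (i1 - i0))))
            v_ss = float(np.mean(sweep.samples[i1 - n_ss : i1]))
            iv_rows.append(
                {"sweep_id": sweep.sweep_id, "amplitude_pA": stim.amplitude_pA,
                 "delta_V_mV": v_ss - baseline}
            )
    return pd.DataFrame(iv_rows), pd.DataFrame(fi_rows)


def rheobase(cell: CellRecording, cfg: FeatureConfig = FeatureConfig()) -> float:
    """Smallest step amplitude eliciting at least one AP."""
    for sweep in _step_sweeps_ascending(cell):
        if len(detect_aps(sweep, cfg.detect)) >= 1:
            return float(sweep.stimulus.amplitude_pA)
    raise SelectionError(f"cell {cell.cell_id!r}: no sweep elicited an AP")


# ---------------------------------------------------------------------------
# rate binning and adaptation


def ap_table(
    summaries_by_cell: dict, genotypes: Optional[dict] = None
) -> pd.DataFrame:
    """Tidy AP-level table: one row per AP with its sweep's firing rate."""
    rows = []
    for cell_id, summaries in summaries_by_cell.items():
        for summ in summaries:
            for ev in summ.events:
                row = {
                    "cell_id": cell_id,
                    "sweep_id": summ.sweep_id,
                    "rate_Hz": summ.firing_rate_Hz,
                    "ap_index": ev.index,
                }
                for metric in METRICS:
                    row[metric] = getattr(ev, metric)
                if genotypes is not None:
                    row["genotype"] = genotypes[cell_id]
                rows.append(row)
    return pd.DataFrame(rows)


def bin_by_rate(
    summaries_by_cell: dict,
    n_bins: int,
    genotypes: Optional[dict] = None,
) -> pd.DataFrame:
    """Pool APs across sweeps/cells and bin them into ``n_bins`` quantile
    bins of their sweep firing rate (bins hold comparable AP counts);
    returns per-bin (per-genotype) metric means +/- SEM."""
    table = ap_table(summaries_by_cell, genotypes)
    if table.empty:
        raise ValueError("no APs to bin")
    try:
        table["rate_bin"] = pd.qcut(table["rate_Hz"], n_bins, duplicates="raise")
    except ValueError:
        warnings.warn(
            "fewer distinct rates than bins; merging duplicate bin edges",
            stacklevel=2,
        )
        table["rate_bin"] = pd.qcut(table["rate_Hz"], n_bins, duplicates="drop")
    keys = ["rate_bin"] + (["genotype"] if genotypes is not None else [])
    grouped = table.groupby(keys, observed=True)
    out = grouped.agg(
        n_APs=("ap_index", "size"),
        rate_mean_Hz=("rate_Hz", "mean"),
        **{
            f"{m}_{stat}": (m, stat)
            for m in METRICS
            for stat in ("mean", "sem")
        },
    ).reset_index()
    return out


def adaptation(
    cell: CellRecording,
    cfg: FeatureConfig = FeatureConfig(),
    min_aps: int = 50,
) -> AdaptationMetrics:
    """Within-train adaptation on the first sweep containing >= 50 APs:
    Delta ISI = ISI_49-50 - ISI_2-3 and per-metric AP_50 - AP_2.

    The interspike-potential difference needs the potential following
    AP_50, hence >= 51 APs; it is left None otherwise.
    """
    for sweep in _step_sweeps_ascending(cell):
        if sweep.stimulus.amplitude_pA <= 0:
            continue
        summ = summarize_trace(sweep, cfg)
        if summ.n_APs >= min_aps:
            ev = summ.events
            # ISI_k = t(AP_{k+1}) - t(AP_k): stored on AP_{k+1} as isi_ms
            d_isi = ev[49].isi_ms - ev[2].isi_ms
            d_hw = ev[49].half_width_ms - ev[1].half_width_ms
            d_isp = None
            if summ.n_APs >= 51:
                d_isp = (
                    ev[49].interspike_potential_mV
                    - ev[1].interspike_potential_mV
                )
            return AdaptationMetrics(
                sweep_id=summ.sweep_id,
                eligible=True,
                n_APs=summ.n_APs,
                delta_isi_ms=float(d_isi),
                delta_half_width_ms=float(d_hw),
                delta_interspike_mV=None if d_isp is None else float(d_isp),
            )
    return AdaptationMetrics(sweep_id=None, eligible=False, n_APs=0)
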