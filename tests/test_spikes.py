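import numpy as np
import pytest

from fsephys.spikes import (
    AdaptationMetrics,
    DetectConfig,
    FeatureConfig,
    FeatureError,
    SelectionError,
    adaptation,
    ahp_amplitude,
    ap_half_width,
    ap_height,
    ap_threshold,
    bin_by_rate,
    detect_aps,
    extract_events,
    interspike_potential,
    iv_fi_curves,
    rheobase,
    sag_voltage,
    select_trace,
    summarize_trace,
)
from fsephys.sweeps import CellRecording, StepProtocol, Sweep

from conftest import make_spike_train_trace


def oracle_detect(v, dt, cutoff=0.0, gap_ms=1.0):
    """Exhaustive scan: strict local maxima above cutoff with enforced
    minimum separation (keeping the earlier peak)."""
    idx = [
        i
        for i in range(1, len(v) - 1)
        if v[i] > cutoff and v[i] > v[i - 1] and v[i] > v[i + 1]
    ]
    out = []
    for i in idx:
        if not out or (i - out[-1]) * dt >= gap_ms:
            out.append(i)
    return np.array(out, dtype=int)


class TestDetect:
    def test_flat_trace_has_no_aps(self, quiet_sweep):
        assert detect_aps(quiet_sweep).size == 0

    def test_twelve_templates_found_at_peaks(self):
        times = [20.0 + 12.0 * i for i in range(12)]
        sweep, idx = make_spike_train_trace(times)
        found = detect_aps(sweep)
        np.testing.assert_array_equal(found, idx)

    def test_matches_oracle_on_randomized_trains(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(3, 15))
            times = np.cumsum(rng.uniform(3.0, 20.0, n)) + 10.0
            sweep, _ = make_spike_train_trace(
                times, peak_mV=float(rng.uniform(5, 40))
            )
            found = detect_aps(sweep)
            expect = oracle_detect(sweep.samples, sweep.dt)
            np.testing.assert_array_equal(found, expect)

    def test_rejects_voltage_clamp(self):
        sw = Sweep(np.zeros(100), 0.1, "voltage_clamp",
                   StepProtocol(0, 0, 1), "x")
        with pytest.raises(ValueError):
            detect_aps(sw)


class TestThreshold:
    def test_constant_slope_upstroke_threshold_at_first_sample(self):
        # linear ramp: every sample has dV/dt = S > 0.04 S
        dt = 0.02
        v = np.concatenate([np.full(100, -70.0),
                            -70 + np.arange(100) * 1.0,  # 50 V/s
                            np.full(100, 30.0) - np.arange(100) * 1.0])
        sw = Sweep(v, dt, "current_clamp", StepProtocol(0, 0, 1), "x")
        peak = int(np.argmax(v))
        thr_v, thr_t, slope = ap_threshold(sw, peak)
        cfg_window_start = peak - int(round(2.0 / dt))
        assert thr_v <= -69.0  # first sample of the rising limb region
        assert slope == pytest.approx(50.0, rel=0.05)

    def test_exponential_upstroke_closed_form(self):
        # V = V0 + A exp((t - tp)/tau): threshold where V - V0 = 0.04 (Vp - V0)
        dt = 0.005
        tau = 0.5
        t = np.arange(0, 6.0, dt)
        tp = 4.0
        V0, A = -70.0, 100.0
        v = V0 + A * np.exp((t - tp) / tau)
        v = np.minimum(v, V0 + A)
        sw = Sweep(v, dt, "current_clamp", StepProtocol(0, 0, 1), "x")
        peak = int(np.argmin(np.abs(t - tp)))
        cfg = FeatureConfig(first_ap_window_ms=4.0)
        thr_v, _, slope = ap_threshold(sw, peak, cfg=cfg)
        expect = V0 + 0.04 * A
        # one-sample tolerance on an exponential
        assert abs(thr_v - expect) < A / tau * dt * 2

    def test_malformed_spike_raises(self):
        v = np.linspace(0, -50, 200)  # monotone falling: no upstroke
        sw = Sweep(v, 0.02, "current_clamp", StepProtocol(0, 0, 1), "x")
        with pytest.raises(FeatureError):
            ap_threshold(sw, 150)


class TestHeightAndWidth:
    def test_height_is_peak_minus_threshold(self):
        assert ap_height(43.0, -42.0) == pytest.approx(85.0)
        assert ap_height(-42.0, -42.0) == 0.0
        with pytest.raises(FeatureError):
            ap_height(-50.0, -42.0)

    def test_triangular_spike_half_width(self):
        # isoceles triangle with 1.0 ms base at threshold -> 0.5 ms at half
        dt = 0.002
        t = np.arange(0, 10, dt)
        tp = 5.0
        v = np.full_like(t, -60.0)
        rise = (t >= tp - 0.5) & (t <= tp)
        fall = (t > tp) & (t <= tp + 0.5)
        v[rise] = -60 + 80 * (1 - (tp - t[rise]) / 0.5)
        v[fall] = -60 + 80 * (1 - (t[fall] - tp) / 0.5)
        sw = Sweep(v, dt, "current_clamp", StepProtocol(0, 0, 1), "x")
        peak = int(round(tp / dt))
        hw = ap_half_width(sw, peak, threshold_V_mV=-60.0)
        assert hw == pytest.approx(0.5, abs=2 * dt)

    def test_gaussian_spike_closed_form(self):
        dt = 0.002
        t = np.arange(0, 10, dt)
        sigma = 0.15
        thr = -55.0
        v = thr + 90.0 * np.exp(-((t - 5.0) ** 2) / (2 * sigma**2))
        sw = Sweep(v, dt, "current_clamp", StepProtocol(0, 0, 1), "x")
        hw = ap_half_width(sw, int(round(5.0 / dt)), threshold_V_mV=thr)
        assert hw == pytest.approx(2 * sigma * np.sqrt(2 * np.log(2)),
                                   abs=2 * dt)

    def test_translation_invariance(self):
        times = [20.0 + 8.0 * i for i in range(12)]
        base, _ = make_spike_train_trace(times)
        ev0 = extract_events(base)
        shifted = Sweep(base.samples + 13.0, base.dt, "current_clamp",
                        base.stimulus, "shift")
        ev1 = extract_events(shifted)
        for a, b in zip(ev0, ev1):
            assert b.threshold_V_mV - a.threshold_V_mV == pytest.approx(13.0, abs=1e-9)
            assert b.peak_V_mV - a.peak_V_mV == pytest.approx(13.0)
            assert b.height_mV == pytest.approx(a.height_mV, abs=1e-9)
            assert b.half_width_ms == pytest.approx(a.half_width_ms, abs=1e-9)
            assert b.max_slope_V_per_s == pytest.approx(a.max_slope_V_per_s)
            if a.interspike_potential_mV is not None:
                assert (b.interspike_potential_mV
                        - a.interspike_potential_mV) == pytest.approx(13.0)


class TestInterspike:
    def test_flat_segment(self):
        times = [20.0, 40.0]
        sweep, idx = make_spike_train_trace(times)
        assert interspike_potential(sweep, idx[0], idx[1]) == -70.0

    def test_half_sine_trough(self):
        dt = 0.02
        t = np.arange(0, 60, dt)
        v = np.full_like(t, -60.0)
        # spikes at 20 and 40, trough of known depth between
        for tp in (20.0, 40.0):
            m = np.abs(t - tp) < 0.3
            v[m] = 10.0
        between = (t > 21) & (t < 39)
        v[between] = -60 - 8.0 * np.sin(np.pi * (t[between] - 21) / 18.0)
        sw = Sweep(v, dt, "current_clamp", StepProtocol(0, 0, 1), "x")
        i1, i2 = int(20 / dt), int(40 / dt)
        assert interspike_potential(sw, i1, i2) == pytest.approx(-68.0,
                                                                 abs=0.01)


class TestSelection:
    def test_selects_first_sweep_with_ten_aps(self):
        counts = [3, 8, 12, 20]
        sweeps = []
        for k, c in enumerate(counts):
            times = [20.0 + 10 * i for i in range(c)]
            sw, _ = make_spike_train_trace(times, total_ms=320.0)
            sweeps.append(Sweep(sw.samples, sw.dt, "current_clamp",
                                StepProtocol(200.0 + 100 * k, 10, 300), f"s{k}"))
        cell = CellRecording("c", "WT/WT", sweeps)
        sel = select_trace(cell)
        assert sel.n_APs == 12
        assert sel.sweep_id == "s2"

    def test_exactly_ten_wins_over_thirty(self):
        sweeps = []
        for k, c in enumerate([10, 30]):
            times = [20.0 + 8 * i for i in range(c)]
            sw, _ = make_spike_train_trace(times, total_ms=300.0)
            sweeps.append(Sweep(sw.samples, sw.dt, "current_clamp",
                                StepProtocol(300.0 + 100 * k, 10, 280), f"s{k}"))
        cell = CellRecording("c", "WT/WT", sweeps)
        sel = select_trace(cell)
        assert sel.sweep_id == "s0"
        assert sel.n_APs == 10
        # AP_10 is the last AP of the selected sweep
        assert sel.metric_at("half_width_ms", 10) is not None
        assert sel.metric_at("half_width_ms", 11) is None

    def test_no_eligible_sweep_raises(self, small_cell):
        cell = CellRecording("c", "WT/WT", small_cell.sweeps[:2])
        with pytest.raises(SelectionError):
            select_trace(cell)


class TestAHPandSag:
    def test_flat_posttrain_gives_zero(self):
        times = [20.0, 30.0]
        sweep, _ = make_spike_train_trace(times, total_ms=120.0)
        ev = extract_events(sweep)
        # baseline sits at -70; threshold is close to baseline for the
        # triangular templates, so AHP ~ threshold - (-70)
        val = ahp_amplitude(sweep, ev)
        assert val == pytest.approx(ev[-1].threshold_V_mV + 70.0, abs=1e-6)

    def test_synthetic_trough_depth_and_linearity(self):
        dt = 0.02
        times = [20.0, 30.0]
        sweep, idx = make_spike_train_trace(times, total_ms=120.0)
        ev = extract_events(sweep)
        for delta in (8.0, 12.0):
            v = sweep.samples.copy()
            trough = (np.arange(len(v)) * dt > 35) & (
                np.arange(len(v)) * dt < 45
            )
            v[trough] = -70.0 - delta
            sw = Sweep(v, dt, "current_clamp", sweep.stimulus, "x")
            val = ahp_amplitude(sw, extract_events(sw))
            base = ev[-1].threshold_V_mV + 70.0
            assert val == pytest.approx(base + delta, abs=1e-6)

    def test_truncated_window_warns(self):
        times = [20.0]
        sweep, _ = make_spike_train_trace(times, total_ms=30.0)
        ev = extract_events(sweep)
        with pytest.warns(UserWarning, match="truncated"):
            ahp_amplitude(sweep, ev)

    def test_pure_rc_response_has_no_sag(self):
        dt = 0.02
        t = np.arange(0, 900, dt)
        tau = 10.0
        v = np.full_like(t, -70.0)
        on = (t >= 100) & (t < 700)
        v[on] = -70 - 20 * (1 - np.exp(-(t[on] - 100) / tau))
        off = t >= 700
        v[off] = -90 + 20 * (1 - np.exp(-(t[off] - 700) / tau))
        sw = Sweep(v, dt, "current_clamp", StepProtocol(-200, 100, 600), "x")
        assert sag_voltage(sw) == pytest.approx(0.0, abs=0.01)

    def test_exponential_rebound_recovered_and_offset_invariant(self):
        dt = 0.02
        t = np.arange(0, 900, dt)
        tau = 10.0
        v = np.full_like(t, -70.0)
        on = (t >= 100) & (t < 700)
        tt = t[on] - 100
        # immediate drop to -90, then 3 mV exponential rebound (sag)
        v[on] = np.where(tt < 100, -90.0,
                         -90.0 + 3.0 * (1 - np.exp(-(tt - 100) / 50.0)))
        sw = Sweep(v, dt, "current_clamp", StepProtocol(-200, 100, 600), "x")
        val = sag_voltage(sw)
        assert val == pytest.approx(3.0, abs=0.15)
        sw2 = Sweep(v + 11.0, dt, "current_clamp", sw.stimulus, "y")
        assert sag_voltage(sw2) == pytest.approx(val, abs=1e-9)


class TestIVFICurves:
    def test_passive_ohms_law(self):
        # R_m = 100 MOhm, -40 pA -> -4 mV steady-state deflection
        dt = 0.02
        t = np.arange(0, 900, dt)
        v = np.full_like(t, -70.0)
        on = (t >= 100) & (t < 700)
        v[on] = -70 - 4 * (1 - np.exp(-(t[on] - 100) / 10.0))
        sw = Sweep(v, dt, "current_clamp", StepProtocol(-40, 100, 600), "s")
        cell = CellRecording("c", "WT/WT", [sw])
        iv, fi = iv_fi_curves(cell)
        assert iv.delta_V_mV.iloc[0] == pytest.approx(-4.0, abs=0.01)

    def test_firing_rate_arithmetic(self):
        times = [120.0 + 30 * i for i in range(15)]  # inside a 500 ms step
        sw, _ = make_spike_train_trace(times, total_ms=700.0)
        sw = Sweep(sw.samples, sw.dt, "current_clamp",
                   StepProtocol(600, 100, 500), "s")
        cell = CellRecording("c", "WT/WT", [sw])
        _, fi = iv_fi_curves(cell)
        assert fi.rate_Hz.iloc[0] == pytest.approx(30.0)

    def test_rheobase_rule(self):
        sweeps = []
        for k, amp in enumerate(range(200, 1300, 100)):
            if amp >= 400:
                times = [20.0 + 10 * i for i in range(amp // 200)]
                sw, _ = make_spike_train_trace(times, total_ms=220.0)
                samples = sw.samples
            else:
                samples = np.full(11000, -70.0)
            sweeps.append(Sweep(samples, 0.02, "current_clamp",
                                StepProtocol(float(amp), 10, 200), f"s{k}"))
        cell = CellRecording("c", "WT/WT", sweeps)
        assert rheobase(cell) == 400.0


class TestRateBinning:
    def _summaries(self, n_aps_per_sweep, rates):
        summaries = []
        for k, (n, r) in enumerate(zip(n_aps_per_sweep, rates)):
            times = [20.0 + 1000.0 / r * i for i in range(n)]
            sw, _ = make_spike_train_trace(times,
                                           total_ms=times[-1] + 20)
            sw = Sweep(sw.samples, sw.dt, "current_clamp",
                       StepProtocol(600, 0, 1000.0 * n / r), f"s{k}")
            summaries.append(summarize_trace(sw))
        return summaries

    def test_single_bin_holds_all_aps(self):
        summaries = self._summaries([5, 5], [20.0, 40.0])
        out = bin_by_rate({"c": summaries}, 1)
        assert out.n_APs.sum() == 10
        assert len(out) == 1

    def test_quartile_bins_hold_equal_counts(self):
        # 100 APs across sweeps with all-distinct rates
        rng = np.random.default_rng(0)
        rates = rng.uniform(10, 200, 20)
        summaries = self._summaries([5] * 20, rates)
        out = bin_by_rate({"c": summaries}, 4)
        assert sorted(out.n_APs) == [25, 25, 25, 25]
        assert out.rate_mean_Hz.is_monotonic_increasing

    def test_merged_bins_warn(self):
        summaries = self._summaries([5, 5], [30.0, 30.0])
        with pytest.warns(UserWarning, match="merg"):
            bin_by_rate({"c": summaries}, 4)


class TestAdaptation:
    def _cell(self, isis, total_extra=50.0):
        times = np.concatenate([[20.0], 20.0 + np.cumsum(isis)])
        sw, _ = make_spike_train_trace(times, total_ms=times[-1] + total_extra)
        sw = Sweep(sw.samples, sw.dt, "current_clamp",
                   StepProtocol(600, 10, times[-1] + 20), "s0")
        return CellRecording("c", "WT/WT", [sw])

    def test_periodic_train_has_zero_delta_isi(self):
        cell = self._cell(np.full(51, 8.0))
        am = adaptation(cell)
        assert am.eligible
        assert am.delta_isi_ms == pytest.approx(0.0, abs=1e-9)
        assert am.delta_half_width_ms == pytest.approx(0.0, abs=1e-3)

    def test_linearly_growing_isi(self):
        # ISI_k = 5 + 0.1 (k-1): ISI_49-50 - ISI_2-3 = 0.1 * 47 = 4.7 ms
        isis = 5.0 + 0.1 * np.arange(52)
        cell = self._cell(isis)
        am = adaptation(cell)
        assert am.delta_isi_ms == pytest.approx(4.7, abs=0.02)

    def test_below_fifty_aps_ineligible(self):
        cell = self._cell(np.full(40, 8.0))
        am = adaptation(cell)
        assert not am.eligible
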