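# Methods

This note documents the models, measurement definitions, numerical
choices and known limitations behind `fsephys`.

## Measurement definitions

**Spike detection.** APs are strict local maxima above a peak cutoff
(default 0 mV) separated by at least a refractory gap (default 1 ms).
Published studies rarely state their detector; both constants are
configurable (`DetectConfig`) and every extractor is verified against an
independent brute-force scan in the test suite.

**Threshold.** The membrane potential at the first upstroke sample where
dV/dt exceeds 4% of the maximum upstroke slope.  dV/dt is taken by
central differences over the window from the preceding interspike minimum
(for the first AP: 2 ms before the peak) to the peak.  With 50 kHz
sampling and slopes near 600 V/s the 4%-crossing is localized to about
0.2–0.5 mV; this granularity matters when comparing small group effects
(see *Limitations*).

**Height, half-width, interspike potential.** Height is peak minus
threshold (consistent with published spike heights of ~85 mV at
thresholds near −42 mV, implying peaks near +43 mV; absolute-peak
definitions can be derived from the stored `APEvent` fields).  Half-width
is measured at threshold + height/2 with linear interpolation between the
bracketing samples of each crossing; the falling-edge search stops at the
next AP.  The interspike potential is the minimum sampled V strictly
between consecutive peaks.

**Selection and adaptation rules.** Per cell the analyzed trace is the
first sweep, in ascending injected current, with ≥ 10 APs; metrics are
reported at AP₂ and AP₁₀ and as means over APs 1–10.  Adaptation uses the
first sweep with ≥ 50 APs; ISI_k denotes the interval between AP_k and
AP_{k+1}, so ΔISI = ISI₄₉₋₅₀ − ISI₂₋₃, and feature adaptation is
AP₅₀ − AP₂.  The AP₅₀ interspike potential needs a following spike, so
that term requires ≥ 51 APs.  Three readings of the post-train AHP exist
in the literature; the implementation reports last-AP threshold minus the
post-train minimum within a 50 ms window (configurable).

**Sag.** Measured on hyperpolarizing steps as the steady-state voltage
(mean over the final 20% of the step) minus the early minimum (first
200 ms of the step); by construction ≥ 0 for sag-expressing responses and
0 for a pure RC response.

**IPSC analysis.** Baselines are means over [−5, −0.5] ms before each
stimulus; peaks are searched in [+0.5, +20] ms with the first 0.5 ms
blanked against stimulus artifacts, and the search window is clipped at
the next stimulus for trains.  Paired-pulse ratios subtract the fitted
mono-exponential residual of the first IPSC (baseline-anchored fit over
[peak₁ + 1 ms, stim₂ − 0.5 ms]; fits with τ outside 0.5–500 ms fall back
to the uncorrected ratio with a logged warning) from the second peak.
Ratios are computed per sweep and then averaged over the 3–5 repeats,
which is robust to slow drift; averaging traces first is a flag away.
Five-pulse trains are normalized to pulse 1 with *no* decay correction,
so their short-interval values carry a quantified superposition bias (the
test suite pins it against a geometric-series oracle).

**Conductance conversion.** The voltage-clamp circuit is solved pointwise:
the series-resistance drop gives V(t) = V_hold − I(t)·R_series, the leak
term (V − E_rest)/R_membrane is removed, and the remainder divided by the
inhibitory driving force V(t) − E_i.  E_rest = −16 mV and E_i = −2.5 mV
are treated as fixed constants of the high-chloride recording condition,
V_hold = −70 mV; R_series/R_membrane come from the per-pair test pulse.
Windows where |V − E_i| < 1 mV raise an ill-conditioning error rather
than returning unstable values.  The forward model (current from a known
conductance waveform) is the exact algebraic inverse and anchors a
round-trip test at 1e-6 relative accuracy.

**Passive properties.** From a −5 mV test pulse: the capacitive transient
is fit as I(t) = I_ss + A·exp(−t/τ); the onset-extrapolated peak gives
R_series = ΔV/I_peak, the steady-state change gives
R_series + R_membrane, and C_m = τ·(1/R_series + 1/R_membrane) because
the clamp time constant sees R_series ∥ R_membrane.

## Statistics

One-way ANOVA and t-tests wrap SciPy.  Tukey–Kramer comparisons use the
studentized-range distribution with the Kramer standard error
√(MSE/2·(1/nᵢ + 1/nⱼ)); with equal n this is exactly Tukey's HSD, and the
implementation is cross-checked against `scipy.stats.tukey_hsd` to 1e-4.
The mixed repeated-measures ANOVA is a split-plot decomposition
(between-subject factor genotype, within-subject factor condition);
within-subject F tests have their degrees of freedom multiplied by the
Greenhouse–Geisser ε computed from the within-factor sample covariance
(box estimate, ε = 1 exactly at k = 2), and subjects with incomplete
designs are dropped listwise.  It is validated against
`pingouin.mixed_anova` on balanced fixtures and by 1,000-replicate null
calibration under AR(1) within-subject correlation.  The bootstrap
resamples cells (not APs) with replacement at the original n,
deterministically per seed.  No correction is applied across metrics:
each metric's ANOVA is reported on its own, mirroring standard practice
in this literature.

## The synthetic neuron

A single-compartment Hodgkin–Huxley-style template:

C·dV/dt = −g_L(V−E_L) − g_Na·m³h(V−E_Na) − g_Kv3·n²(V−E_K)
  − g_Kv2·[(1−f)·h_hom + f·h_het]·a²(V−E_K) + I_inj + noise.

The Kv3-like current is fast and high-threshold and produces the
sub-millisecond repolarization of the fast-spiking phenotype.  The Kv2
delayed rectifier activates mainly during the spike, lingers through the
early interspike interval (deactivation ~3 ms near −50 mV) and then
closes, so it deepens the interspike trough with little effect on firing
rate.  Its two populations share activation kinetics; the heteromer
population's steady-state inactivation midpoint is shifted by
Δ_inact = −38.8 mV (silent Kv subunits shift Kv2 inactivation by roughly
−30 to −40 mV), with a 150 ms inactivation time constant, so heteromers
progressively inactivate at physiological interspike potentials while
homomers stay available.  `f_het` is the heteromer fraction of total Kv2
conductance: 0.5 for an expressing wild-type cell, 0 for a full knockout.

Na⁺ inactivation is steep near the trough voltages (midpoint −64.8 mV,
slope 4.4 mV) and recovers quickly below ~−70 mV, which is the causal
link the model needs: removing heteromers (knockout) leaves more Kv2
available, hyperpolarizes the interspike potential by ~2 mV, increases Na
availability at the next spike, and thereby speeds the upstroke, narrows
the spike and (weakly) lowers threshold — the observed direction pattern.

Default parameters were calibrated, in the sense of choosing one default
cohort, so that the wild-type template at the standard step protocol
lands inside the reported ranges for adult PV cells: rest −76.7 mV
(target band −80…−70), AP₂ height 81.5 mV (75–95), AP₂ half-width
0.265 ms (0.15–0.35), AP₁₀ threshold −44.6 mV (−50…−35), with sustained
non-adapting firing and > 50 APs per 600 ms step at higher currents.  A
matched-step comparison of f_het = 0.5 vs 0 across 16 steps (450–1200 pA)
reproduces the direction pattern in 16/16 steps for half-width, maximum
slope and interspike potential and 13/16 for threshold (one-sided sign
test p ≈ 0.011).

Integration is forward Euler for V and exponential Euler for gates at a
fixed internal step ≤ 0.005 ms (decimated to the recorded rate); the
tests verify discrete charge conservation (C·ΔV/Δt equals the summed
current at every step) and that halving the step moves spike times by
< 1%.  Unstable parameter sets raise a `SimulationError` naming the step
size rather than returning non-finite traces.

## The synthetic synapse and cohorts

Release follows the depression-only resource recursion (utilization U,
recovery τ_rec; paired-pulse ratio 1 − U·e^(−Δt/τ_rec) in closed form),
convolved with peak-normalized difference-of-exponentials kernels
(τ_r = 0.5 ms, τ_d = 8 ms) as inward currents plus Gaussian noise.
Binomial mode simulates independent release sites whose expectation
equals the deterministic recursion exactly.  Genotype effects enter only
through U (wild type 0.60, knockout 0.45, between-pair SD 0.04): the
presynaptic waveform→Ca²⁺→release chain is outside the measurement scope,
so the generator encodes its presumed endpoint, a reduced release
probability in the knockout.  Cohort builders mirror the two designs —
three-genotype intrinsic study (default 18/16/20 cells) and two-genotype
paired study (11/10 pairs; seven paired-pulse intervals and five-pulse
trains, 3–5 randomized repeats each, plus single pulses and a test
pulse).  Wild-type (and heterozygous) intrinsic cohorts are mixtures: by
default 35% of cells express the silent subunit (f_het 0.5, halved for
heterozygotes), matching the expressing fraction of L2/3 PV cells;
between-cell variability is lognormal (CV 0.08) on conductances and
capacitance.  A fixed cohort seed reproduces every sweep bit for bit.

## What the generator does and does not emulate

It reproduces the protocol structure, sampling rates, noise scale,
passive-property ranges and the hypothesized genotype mechanism, so
pipeline correctness, selection rules, decay corrections and test
calibration are fully exercisable.  It does not reproduce several
features of real recordings: electrode/access artifacts, slow drift,
seal instabilities, channelopathies of individual cells, or the full
richness of PV-cell firing (e.g. stuttering).  Two quantitative
departures matter when reading cohort outputs.  First, the model's spike
height grows with injected current, so the selection rule (first trace
with ≥ 10 APs, often near rheobase) yields cohort-mean AP₂ heights of
~60–70 mV even though the 600 pA template sits at 81.5 mV; real PV
spikes are less drive-dependent.  Second, the mechanistic intrinsic
effect sizes (half-width shift ~0.015 ms between pure f_het 0.5 and 0
cells, diluted 3× by the expressing mixture) are smaller relative to
between-cell variability than the published group effects, so the
intrinsic ANOVAs at n = 18/16/20 are under-powered in a single cohort
(p ≈ 0.06–0.16 across seeds for AP₂ half-width); passing tests therefore
demonstrate correctness of the measurement and statistical machinery and
the direction of the mechanism, not field-realistic intrinsic power.
The synaptic contrast, by comparison, is strong (power ≈ 1.0 at
Δt = 10 ms, n = 11/10).

## Numerical choices and degenerate inputs

Tolerances: decay fits and passive fits use `scipy.optimize.curve_fit`
with analytic initial guesses; decay τ outside (0.5, 500) ms is rejected.
Conductance conversion errors out within 1 mV of E_i.  Empty sweep
bundles are refused on write; dt disagreement between metadata and time
columns (beyond the 1e-6 ms CSV precision), wrong units for a modality,
and non-monotone time columns raise format errors naming the field.
Rate-binning merges duplicate quantile edges with a warning; sweeps whose
first IPSC falls below a configurable noise floor (default off) are
excluded with a warning.  Sub-threshold-only cells raise a selection
error and are logged and excluded by the pipeline, never fatal.

## Problem sizes in the shipped checks

The test suite and the acceptance script size their simulations to run on
one core in minutes: feature-extractor oracles use 120 randomized
spikes; direction sign tests use 16 matched steps; synaptic power and
type-I use 100 replicates of the 11/10-pair design at two intervals
(Δt = 10 and 1000 ms, 3 repeats each) rather than the full seven-interval
protocol, which leaves the compared conditions unchanged; statistical
null calibrations use 1,000 replicates.
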