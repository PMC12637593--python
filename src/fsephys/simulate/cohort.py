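"""Seeded cohort builders mirroring the two study designs.

*Intrinsic design*: per cell, both current-step families (-200..200 pA in
40 pA increments and 200..1200 pA in 100 pA increments) recorded in
current clamp at 50 kHz.

*Synaptic design*: per PV->PYR pair, a passive test pulse, 3-5 single-AP
sweeps, repeated paired-pulse sweeps at the seven interstimulus intervals
(10..1000 ms) and five-pulse trains, recorded in voltage clamp at 10 kHz.

Genotype knob: a ``Kcng4``-expressing cell carries heteromer fraction
``f_het_expressing``; wild-type cohorts are a mixture of expressing and
non-expressing cells (about a third of L2/3 PV cells express the silent
subunit), heterozygotes carry half the expressing heteromer fraction, and
homozygous knockouts carry none.  Synaptic genotype effects enter through
the release utilization U only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np

from ..sweeps import CellRecording, StepProtocol, StimTrain
from .neuron import FSNeuronParams, simulate_fs_neuron
from .passive import simulate_test_pulse
from .synapse import SynapseParams, simulate_ipsc_train

__all__ = [
    "CohortSpec",
    "INTRINSIC_SUBTHRESHOLD_PA",
    "INTRINSIC_SUPRATHRESHOLD_PA",
    "PPR_INTERVALS_MS",
    "genotype_f_het",
    "genotype_synapse_params",
    "generate_intrinsic_cell",
    "generate_synaptic_pair",
    "generate_cohort",
]

INTRINSIC_SUBTHRESHOLD_PA = tuple(range(-200, 201, 40))  # 11 steps
INTRINSIC_SUPRATHRESHOLD_PA = tuple(range(200, 1201, 100))  # 11 steps
PPR_INTERVALS_MS = (10.0, 20.0, 50.0, 100.0, 200.0, 500.0, 1000.0)


@dataclass(frozen=True)
class CohortSpec:
    """Design and parameter distributions for one simulated cohort.

    ``n_cells``: mapping genotype -> count (e.g. the 18/16/20-cell
    intrinsic design or the 11/10-pair synaptic design).
    Between-cell variability is lognormal on conductances/capacitance
    (coefficient of variation ``cv``) and additive on reversal potentials.
    """

    n_cells: Dict[str, int]
    design: str = "intrinsic"  # or "synaptic"
    seed: int = 0
    # intrinsic design
    neuron: FSNeuronParams = field(default_factory=FSNeuronParams)
    cv: float = 0.08
    e_leak_sd_mV: float = 1.0
    f_het_expressing: float = 0.5
    #: fraction of wild-type (and heterozygous) cells that express the
    #: silent subunit at all -- about a third of L2/3 PV cells
    expressing_fraction: float = 0.35
    step_duration_ms: float = 600.0
    step_onset_ms: float = 100.0
    dt_cc_ms: float = 0.02
    # synaptic design
    synapse_by_genotype: Dict[str, SynapseParams] = field(
        default_factory=lambda: {
            "WT/WT": SynapseParams(U=0.60),
            "Cre/Cre": SynapseParams(U=0.45),
        }
    )
    synapse_cv: float = 0.10
    u_sd: float = 0.04
    n_single_pulse: int = 3
    n_repeats: int = 3
    train_intervals_ms: tuple = (10.0, 100.0)
    dt_vc_ms: float = 0.1

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_cells.values()):
            raise ValueError("n_cells must be >= 1 per genotype")
        if self.design not in ("intrinsic", "synaptic"):
            raise ValueError(f"unknown design {self.design!r}")
        if not (0 <= self.expressing_fraction <= 1):
            raise ValueError("expressing_fraction must be in [0, 1]")


def genotype_f_het(
    genotype: str, spec: CohortSpec, rng: np.random.Generator
) -> float:
    """Heteromer fraction for one sampled cell of the given genotype."""
    if genotype == "Cre/Cre":
        return 0.0
    expressing = rng.random() < spec.expressing_fraction
    if not expressing:
        return 0.0
    if genotype == "Cre/WT":
        return 0.5 * spec.f_het_expressing
    return spec.f_het_expressing


def _jitter_neuron(
    base: FSNeuronParams, spec: CohortSpec, rng: np.random.Generator
) -> FSNeuronParams:
    def ln(x):
        return float(x * rng.lognormal(0.0, spec.cv))

    return base.with_(
        C_pF=ln(base.C_pF),
        g_leak_nS=ln(base.g_leak_nS),
        g_Na_nS=ln(base.g_Na_nS),
        g_Kv3_nS=ln(base.g_Kv3_nS),
        g_Kv2_total_nS=ln(base.g_Kv2_total_nS),
        E_leak_mV=float(base.E_leak_mV + rng.normal(0, spec.e_leak_sd_mV)),
    )


def generate_intrinsic_cell(
    cell_id: str,
    genotype: str,
    spec: CohortSpec,
    seed: int,
) -> CellRecording:
    """One cell's full intrinsic protocol (both step families)."""
    rng = np.random.default_rng(seed)
    params = _jitter_neuron(spec.neuron, spec, rng).with_(
        f_het=genotype_f_het(genotype, spec, rng)
    )
    sweeps = []
    amplitudes = list(INTRINSIC_SUBTHRESHOLD_PA) + list(
        INTRINSIC_SUPRATHRESHOLD_PA
    )
    for k, amp in enumerate(amplitudes):
        proto = StepProtocol(
            amplitude_pA=float(amp),
            onset_ms=spec.step_onset_ms,
            duration_ms=spec.step_duration_ms,
        )
        sweeps.append(
            simulate_fs_neuron(
                params,
                proto,
                dt=spec.dt_cc_ms,
                seed=int(rng.integers(0, 2**31 - 1)),
                sweep_id=f"{cell_id}_step{k:02d}_{amp:+05d}pA",
            )
        )
    return CellRecording(cell_id=cell_id, genotype=genotype, sweeps=sweeps)


def genotype_synapse_params(
    genotype: str, spec: CohortSpec, rng: np.random.Generator
) -> SynapseParams:
    base = spec.synapse_by_genotype.get(genotype)
    if base is None:
        raise ValueError(f"no synapse parameters for genotype {genotype!r}")
    u = float(np.clip(rng.normal(base.U, spec.u_sd), 0.05, 0.95))
    return replace(
        base,
        U=u,
        unitary_scale_pA=float(
            base.unitary_scale_pA * rng.lognormal(0.0, spec.synapse_cv)
        ),
        tau_rec_ms=float(base.tau_rec_ms * rng.lognormal(0.0, spec.synapse_cv)),
    )


def generate_synaptic_pair(
    pair_id: str,
    genotype: str,
    spec: CohortSpec,
    seed: int,
) -> CellRecording:
    """One PV->PYR pair: test pulse, single pulses, paired pulses at the
    seven intervals, and five-pulse trains; repeat order randomized."""
    rng = np.random.default_rng(seed)
    syn = genotype_synapse_params(genotype, spec, rng)
    sweeps = [
        simulate_test_pulse(
            R_series_MOhm=float(19.0 * rng.lognormal(0, 0.05)),
            R_membrane_MOhm=float(210.0 * rng.lognormal(0, 0.1)),
            C_m_pF=float(120.0 * rng.lognormal(0, 0.1)),
            noise_sd_pA=syn.noise_sd_pA * 0.2,
            seed=int(rng.integers(0, 2**31 - 1)),
            dt=spec.dt_vc_ms,
            sweep_id=f"{pair_id}_testpulse",
        )
    ]
    t0 = 20.0
    for k in range(spec.n_single_pulse):
        stim = StimTrain(pulse_times_ms=(t0,))
        sweeps.append(
            simulate_ipsc_train(
                syn, stim, dt=spec.dt_vc_ms,
                seed=int(rng.integers(0, 2**31 - 1)),
                sweep_id=f"{pair_id}_single{k}",
            )
        )
    protocols = []
    for dt_ms in PPR_INTERVALS_MS:
        for r in range(spec.n_repeats):
            protocols.append(("pp", dt_ms, r))
    for dt_ms in spec.train_intervals_ms:
        for r in range(spec.n_repeats):
            protocols.append(("train5", dt_ms, r))
    order = rng.permutation(len(protocols))
    for idx in order:
        kind, dt_ms, r = protocols[idx]
        if kind == "pp":
            times = (t0, t0 + dt_ms)
        else:
            times = tuple(t0 + i * dt_ms for i in range(5))
        stim = StimTrain(pulse_times_ms=times)
        sweeps.append(
            simulate_ipsc_train(
                syn, stim, dt=spec.dt_vc_ms,
                seed=int(rng.integers(0, 2**31 - 1)),
                sweep_id=f"{pair_id}_{kind}_{int(dt_ms):04d}ms_r{r}",
            )
        )
    return CellRecording(
        cell_id=pair_id,
        genotype=genotype,
        sweeps=sweeps,
        holding_condition="held_minus70",
    )


def generate_cohort(spec: CohortSpec) -> list:
    """All cells/pairs of the cohort, fully reproducible from
    ``spec.seed``; returns a list of :class:`CellRecording`."""
    root = np.random.default_rng(spec.seed)
    cells = []
    for genotype in sorted(spec.n_cells):
        for i in range(spec.n_cells[genotype]):
            cell_seed = int(root.integers(0, 2**31 - 1))
            cid = f"{spec.design}_{genotype.replace('/', '')}_{i:03d}"
            if spec.design == "intrinsic":
                cells.append(
                    generate_intrinsic_cell(cid, genotype, spec, cell_seed)
                )
            else:
                cells.append(
                    generate_synaptic_pair(cid, genotype, spec, cell_seed)
                )
    return cells
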