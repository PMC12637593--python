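"""Data model and disk format for per-cell patch-clamp sweep collections.

A *sweep bundle* is one directory per cell holding ``metadata.json`` plus one
``sweep_<k>.csv`` per digitized trace (columns ``time_ms,value``; value in mV
for current clamp, pA for voltage clamp).  Time is in milliseconds, zero at
sweep start; stimulus metadata lives in the same frame.  Voltage-clamp
currents are stored in amplifier convention (inward negative); downstream
analyses report amplitudes as positive magnitudes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np

__all__ = [
    "Sweep",
    "StepProtocol",
    "StimTrain",
    "PassiveProps",
    "CellRecording",
    "QCFlag",
    "FormatError",
    "load_cell",
    "save_cell",
    "qc_cell",
    "GENOTYPES",
]

GENOTYPES = ("WT/WT", "Cre/WT", "Cre/Cre")

#: QC bounds from standard whole-cell acceptance rules: access resistance
#: caps of 20 MOhm (current clamp) / 30 MOhm (voltage clamp) and a 200 pA
#: holding-current cap at -70 mV.
R_SERIES_MAX_CC_MOHM = 20.0
R_SERIES_MAX_VC_MOHM = 30.0
HOLDING_CURRENT_MAX_PA = 200.0

_FLOAT_FMT = "%.6f"


class FormatError(ValueError):
    """A sweep bundle violates the on-disk contract."""


@dataclass(frozen=True)
class StepProtocol:
    """Square current step: ``amplitude_pA`` injected over
    [onset_ms, onset_ms + duration_ms)."""

    amplitude_pA: float
    onset_ms: float
    duration_ms: float

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be > 0")
        if self.onset_ms < 0:
            raise ValueError("onset_ms must be >= 0")


@dataclass(frozen=True)
class StimTrain:
    """Presynaptic stimulation pattern: brief (~1 ms) suprathreshold current
    pulses at ``pulse_times_ms`` evoking one presynaptic AP each."""

    pulse_times_ms: tuple
    pulse_amplitude_nA: float = 1.5
    pulse_width_ms: float = 1.0

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.pulse_times_ms)
        object.__setattr__(self, "pulse_times_ms", times)
        if len(times) == 0:
            raise ValueError("need at least one pulse")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("pulse_times_ms must be strictly increasing")
        if self.pulse_width_ms <= 0:
            raise ValueError("pulse_width_ms must be > 0")


Stimulus = Union[StepProtocol, StimTrain]


@dataclass(frozen=True)
class PassiveProps:
    R_series_MOhm: Optional[float] = None
    R_membrane_MOhm: Optional[float] = None
    tau_ms: Optional[float] = None
    C_m_pF: Optional[float] = None
    V_rest_mV: Optional[float] = None
    holding_current_pA: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("R_series_MOhm", "R_membrane_MOhm"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class Sweep:
    """One digitized trace with uniform sampling and stimulus metadata.

    ``samples`` are mV for ``modality='current_clamp'`` and pA for
    ``'voltage_clamp'``; ``dt`` is the sampling interval in ms.
    """

    samples: np.ndarray
    dt: float
    modality: str
    stimulus: Stimulus
    sweep_id: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.modality not in ("current_clamp", "voltage_clamp"):
            raise ValueError(f"unknown modality {self.modality!r}")
        end = self.samples.size * self.dt
        for t in self._stim_event_times():
            if not (0 <= t < end):
                raise ValueError(
                    f"stimulus event at {t} ms outside sweep [0, {end}) ms"
                )

    def _stim_event_times(self):
        if isinstance(self.stimulus, StepProtocol):
            return (self.stimulus.onset_ms,)
        if isinstance(self.stimulus, StimTrain):
            return self.stimulus.pulse_times_ms
        return ()

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_ms(self) -> float:
        return self.n_samples * self.dt

    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    def require_modality(self, modality: str) -> "Sweep":
        if self.modality != modality:
            raise ValueError(
                f"sweep {self.sweep_id!r} is {self.modality}, "
                f"operation requires {modality}"
            )
        return self


@dataclass
class CellRecording:
    """Ordered sweeps from one cell (or one synaptically connected pair),
    with genotype and recording-condition labels."""

    cell_id: str
    genotype: str
    sweeps: list = field(default_factory=list)
    region: str = "S1"
    layer: str = "L2/3"
    holding_condition: str = "endogenous_rest"
    passive: Optional[PassiveProps] = None

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(
                f"genotype must be one of {GENOTYPES}, got {self.genotype!r}"
            )
        if self.holding_condition not in ("endogenous_rest", "held_minus70"):
            raise ValueError(f"bad holding_condition {self.holding_condition!r}")

    def sweeps_of(self, modality: str) -> list:
        return [s for s in self.sweeps if s.modality == modality]


# ---------------------------------------------------------------------------
# serialization


def _stimulus_to_json(stim: Stimulus) -> dict:
    if isinstance(stim, StepProtocol):
        return {"kind": "step", **asdict(stim)}
    if isinstance(stim, StimTrain):
        d = asdict(stim)
        d["pulse_times_ms"] = list(d["pulse_times_ms"])
        return {"kind": "train", **d}
    raise TypeError(f"unknown stimulus {stim!r}")


def _stimulus_from_json(d: dict) -> Stimulus:
    kind = d.get("kind")
    rest = {k: v for k, v in d.items() if k != "kind"}
    if kind == "step":
        return StepProtocol(**rest)
    if kind == "train":
        rest["pulse_times_ms"] = tuple(rest["pulse_times_ms"])
        return StimTrain(**rest)
    raise FormatError(f"unknown stimulus kind {kind!r}")


def save_cell(cell: CellRecording, bundle_path) -> Path:
    """Write ``cell`` as a sweep bundle directory; returns the bundle path.

    Float formatting is fixed, so save -> load -> save is byte-identical.
    """
    if not cell.sweeps:
        raise ValueError("refusing to write an empty bundle")
    bundle = Path(bundle_path)
    bundle.mkdir(parents=True, exist_ok=True)

    meta = {
        "cell_id": cell.cell_id,
        "genotype": cell.genotype,
        "region": cell.region,
        "layer": cell.layer,
        "holding_condition": cell.holding_condition,
        "passive": None if cell.passive is None else asdict(cell.passive),
        "sweeps": [],
    }
    for k, sw in enumerate(cell.sweeps):
        fname = f"sweep_{k:03d}.csv"
        meta["sweeps"].append(
            {
                "sweep_id": sw.sweep_id,
                "file": fname,
                "modality": sw.modality,
                "dt_ms": sw.dt,
                "units": "mV" if sw.modality == "current_clamp" else "pA",
                "stimulus": _stimulus_to_json(sw.stimulus),
            }
        )
        t = sw.time_ms()
        with open(bundle / fname, "w", newline="\n") as fh:
            fh.write("time_ms,value\n")
            for ti, vi in zip(t, sw.samples):
                fh.write((_FLOAT_FMT % ti) + "," + (_FLOAT_FMT % vi) + "\n")
    with open(bundle / "metadata.json", "w", newline="\n") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return bundle


def load_cell(bundle_path) -> CellRecording:
    """Read a sweep bundle back into a :class:`CellRecording`.

    Validates units, dt consistency between metadata and the time column, and
    time-column monotonicity; raises :class:`FormatError` naming the
    offending field otherwise.
    """
    bundle = Path(bundle_path)
    meta_path = bundle / "metadata.json"
    if not meta_path.exists():
        raise FormatError(f"missing metadata.json in {bundle}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    for key in ("cell_id", "genotype", "sweeps"):
        if key not in meta:
            raise FormatError(f"metadata.json missing field {key!r}")
    if not meta["sweeps"]:
        raise FormatError("metadata.json lists no sweeps")

    sweeps = []
    for rec in meta["sweeps"]:
        for key in ("sweep_id", "file", "modality", "dt_ms", "units", "stimulus"):
            if key not in rec:
                raise FormatError(f"sweep record missing field {key!r}")
        expected_units = "mV" if rec["modality"] == "current_clamp" else "pA"
        if rec["units"] != expected_units:
            raise FormatError(
                f"sweep {rec['sweep_id']!r}: units {rec['units']!r} do not "
                f"match modality {rec['modality']!r} (expected {expected_units!r})"
            )
        data = np.genfromtxt(
            bundle / rec["file"], delimiter=",", names=True, dtype=float
        )
        t = np.atleast_1d(data["time_ms"])
        v = np.atleast_1d(data["value"])
        if t.size > 1:
            dts = np.diff(t)
            if np.any(dts <= 0):
                raise FormatError(
                    f"sweep {rec['sweep_id']!r}: time_ms column not "
                    "strictly increasing"
                )
            # time column is written at 1e-6 ms precision
            if not np.allclose(dts, rec["dt_ms"], rtol=1e-6, atol=2.1e-6):
                raise FormatError(
                    f"sweep {rec['sweep_id']!r}: dt_ms metadata "
                    f"({rec['dt_ms']}) disagrees with time column"
                )
        sweeps.append(
            Sweep(
                samples=v,
                dt=float(rec["dt_ms"]),
                modality=rec["modality"],
                stimulus=_stimulus_from_json(rec["stimulus"]),
                sweep_id=rec["sweep_id"],
            )
        )

    passive = meta.get("passive")
    return CellRecording(
        cell_id=meta["cell_id"],
        genotype=meta["genotype"],
        sweeps=sweeps,
        region=meta.get("region", "S1"),
        layer=meta.get("layer", "L2/3"),
        holding_condition=meta.get("holding_condition", "endogenous_rest"),
        passive=None if passive is None else PassiveProps(**passive),
    )


# ---------------------------------------------------------------------------
# QC


@dataclass(frozen=True)
class QCFlag:
    rule: str
    status: str  # "pass" | "fail" | "not_evaluated"
    value: Optional[float] = None
    bound: Optional[float] = None


def qc_cell(cell: CellRecording) -> list:
    """Evaluate whole-cell quality-control rules; never mutates the data.

    Rules: series resistance below the per-modality cap, and holding current
    magnitude below 200 pA.  Missing passive properties yield
    ``not_evaluated`` flags rather than errors.
    """
    modalities = {s.modality for s in cell.sweeps}
    rs_bound = (
        R_SERIES_MAX_VC_MOHM
        if modalities == {"voltage_clamp"}
        else R_SERIES_MAX_CC_MOHM
    )
    flags = []
    p = cell.passive
    if p is None or p.R_series_MOhm is None:
        flags.append(QCFlag("series_resistance", "not_evaluated", bound=rs_bound))
    else:
        ok = p.R_series_MOhm <= rs_bound
        flags.append(
            QCFlag(
                "series_resistance",
                "pass" if ok else "fail",
                value=p.R_series_MOhm,
                bound=rs_bound,
            )
        )
    if p is None or p.holding_current_pA is None:
        flags.append(
            QCFlag("holding_current", "not_evaluated", bound=HOLDING_CURRENT_MAX_PA)
        )
    else:
        ok = abs(p.holding_current_pA) <= HOLDING_CURRENT_MAX_PA
        flags.append(
            QCFlag(
                "holding_current",
                "pass" if ok else "fail",
                value=p.holding_current_pA,
                bound=HOLDING_CURRENT_MAX_PA,
            )
        )
    return flags
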