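"""Reading, writing and slicing monitor-export recordings.

The depth-of-anesthesia monitor emulated here exports a single frontal EEG
channel sampled at 128 Hz as a two-column TSV (``time_s``, ``uV``) and a
slow table of processed parameters (BIS, SEF95, SR, EMGlow) at a nominal
3-s cadence.  This module parses both formats, cuts a recording into
consecutive 8-s analysis epochs, pairs each epoch with the slow parameter
records that fall inside it, and extracts the 7-minute phase windows
(induction / maintenance / emergence) used throughout the analysis.

Time convention: seconds, 0-based sample index, sample ``k`` of a signal
lives at ``t0 + k / rate``; all epoch and phase windows are half-open
``[t_start, t_end)``.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Signal",
    "ParamRecord",
    "PhaseWindow",
    "FormatError",
    "NonUniformSamplingError",
    "RangeError",
    "PHASES",
    "read_eeg_tsv",
    "write_eeg_tsv",
    "read_params_tsv",
    "write_params_tsv",
    "iter_epochs",
    "align_params",
    "select_phase",
    "load_phase_windows",
    "write_phase_windows",
    "params_to_frame",
]

PHASES = ("induction", "maintenance", "emergence")

#: Relative jitter above which a time axis is rejected as non-uniform.
JITTER_TOL = 1e-6


class FormatError(ValueError):
    """A monitor-export file violates the expected TSV dialect."""


class NonUniformSamplingError(FormatError):
    """The EEG time axis is not uniformly sampled."""


class RangeError(ValueError):
    """A parameter value lies outside its physically valid range."""


@dataclass
class Signal:
    """A uniformly sampled single-channel EEG trace in microvolts.

    Sample ``k`` (0-based) is located at time ``t0 + k / rate`` seconds.
    """

    samples: np.ndarray
    rate: float
    t0: float = 0.0
    patient_id: str = ""
    truncated: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.rate > 0:
            raise ValueError(f"rate must be positive, got {self.rate}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Length of the trace in seconds."""
        return len(self.samples) / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.rate


@dataclass(frozen=True)
class ParamRecord:
    """One 3-s processed-parameter record from the monitor.

    ``bis`` is the dimensionless 0-100 depth index, ``sef95`` the 95%
    spectral edge frequency in Hz, ``sr`` the suppression ratio in percent
    and ``emglow`` the frontal EMG power in dB.  Missing values are NaN.
    """

    t: float
    bis: float
    sef95: float
    sr: float
    emglow: float

    def validate(self) -> None:
        if not math.isnan(self.bis) and not 0.0 <= self.bis <= 100.0:
            raise RangeError(f"bis={self.bis} outside [0, 100] at t={self.t}")
        if not math.isnan(self.sr) and not 0.0 <= self.sr <= 100.0:
            raise RangeError(f"sr={self.sr} outside [0, 100] at t={self.t}")
        if not math.isnan(self.sef95) and self.sef95 < 0.0:
            raise RangeError(f"sef95={self.sef95} negative at t={self.t}")


@dataclass(frozen=True)
class PhaseWindow:
    """A 7-minute (420 s) analysis window of one anesthesia phase.

    A window may be shorter than 420 s only when the source recording ends
    early, in which case the selected sub-signal is flagged ``truncated``.
    """

    phase: str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}; expected one of {PHASES}")
        if not self.t_end > self.t_start:
            raise ValueError("t_end must exceed t_start")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


PARAM_COLUMNS = ("time_s", "bis", "sef95", "sr", "emglow")
EEG_COLUMNS = ("time_s", "uV")


def _read_tsv(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty (expected a header line)")
    if list(df.columns) != list(columns):
        raise FormatError(
            f"{path}: expected columns {list(columns)}, found {list(df.columns)}"
        )
    out = {}
    for col in columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        raw_nan = df[col].isna()
        bad = vals.isna() & ~raw_nan
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise FormatError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r} at line {line}"
            )
        out[col] = vals.to_numpy(dtype=float)
    return pd.DataFrame(out)


def read_eeg_tsv(path: str | Path, patient_id: str = "") -> Signal:
    """Parse an EEG export (``time_s``, ``uV``) into a :class:`Signal`.

    The sampling rate is inferred from the median inter-sample interval;
    relative jitter beyond ``1e-6`` is rejected as non-uniform sampling.
    """
    df = _read_tsv(path, EEG_COLUMNS)
    if len(df) < 2:
        raise FormatError(f"{path}: need at least 2 samples to infer a rate")
    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    med = float(np.median(dt))
    if med <= 0:
        raise NonUniformSamplingError(f"{path}: time column is not increasing")
    if np.max(np.abs(dt - med)) / med > JITTER_TOL:
        raise NonUniformSamplingError(
            f"{path}: non-uniform sampling (relative jitter "
            f"{np.max(np.abs(dt - med)) / med:.3g} > {JITTER_TOL:g})"
        )
    return Signal(df["uV"].to_numpy(), rate=1.0 / med, t0=float(t[0]),
                  patient_id=patient_id)


def write_eeg_tsv(signal: Signal, path: str | Path) -> None:
    """Write a :class:`Signal` in the monitor-export EEG dialect."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("time_s\tuV\n")
        for t, v in zip(signal.times, signal.samples):
            fh.write(f"{t:.10f}\t{v:.6f}\n")


def read_params_tsv(path: str | Path) -> list[ParamRecord]:
    """Parse a processed-parameter export into sorted :class:`ParamRecord` s.

    Gaps in the nominal 3-s cadence are allowed and preserved; an empty
    (header-only) file yields an empty list with a warning.
    """
    df = _read_tsv(path, PARAM_COLUMNS)
    if len(df) == 0:
        warnings.warn(f"{path}: parameter file has no records", stacklevel=2)
        return []
    df = df.sort_values("time_s", kind="stable")
    records = [
        ParamRecord(t=row.time_s, bis=row.bis, sef95=row.sef95,
                    sr=row.sr, emglow=row.emglow)
        for row in df.itertuples()
    ]
    for rec in records:
        rec.validate()
    return records


def write_params_tsv(records: Sequence[ParamRecord], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(PARAM_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.t:.3f}\t{r.bis:.3f}\t{r.sef95:.3f}\t"
                     f"{r.sr:.3f}\t{r.emglow:.3f}\n")


def params_to_frame(records: Sequence[ParamRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_s": [r.t for r in records],
            "bis": [r.bis for r in records],
            "sef95": [r.sef95 for r in records],
            "sr": [r.sr for r in records],
            "emglow": [r.emglow for r in records],
        }
    )


def iter_epochs(signal: Signal, epoch_s: float = 8.0,
                overlap_s: float = 0.0) -> Iterator[Signal]:
    """Cut a signal into consecutive half-open epochs ``[t, t + epoch_s)``.

    Epochs are non-overlapping by default (the analysis cadence is one
    update every 8 s); a trailing partial epoch is dropped.  A signal
    shorter than one epoch yields nothing, with a warning.
    """
    n_per = epoch_s * signal.rate
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError(
            f"epoch_s * rate = {n_per} is not an integer number of samples"
        )
    n_per = int(round(n_per))
    if not 0.0 <= overlap_s < epoch_s:
        raise ValueError("overlap_s must lie in [0, epoch_s)")
    step = int(round((epoch_s - overlap_s) * signal.rate))
    if len(signal) < n_per:
        warnings.warn(
            f"signal of {signal.duration:.3g} s shorter than one "
            f"{epoch_s:g}-s epoch; no epochs produced", stacklevel=2,
        )
        return
    for start in range(0, len(signal) - n_per + 1, step):
        yield Signal(
            signal.samples[start:start + n_per],
            rate=signal.rate,
            t0=signal.t0 + start / signal.rate,
            patient_id=signal.patient_id,
        )


def align_params(epochs: Sequence[Signal],
                 params: Sequence[ParamRecord]) -> list[ParamRecord]:
    """Assign each epoch the median of the records inside its window.

    For each epoch ``[t0, t0 + duration)`` the per-field median over the
    parameter records whose timestamp falls inside the window is returned;
    epochs containing no record get all-NaN fields.  The result is
    independent of the input record order.
    """
    if not params:
        t_rec = np.empty(0)
    else:
        t_rec = np.array([r.t for r in params])
    order = np.argsort(t_rec, kind="stable")
    fields = {
        name: np.array([getattr(params[i], name) for i in order])
        for name in ("bis", "sef95", "sr", "emglow")
    }
    t_rec = t_rec[order]
    out = []
    for ep in epochs:
        lo, hi = ep.t0, ep.t0 + ep.duration
        sel = (t_rec >= lo) & (t_rec < hi)
        if sel.any():
            med = {k: float(np.nanmedian(v[sel])) if not np.all(np.isnan(v[sel]))
                   else math.nan
                   for k, v in fields.items()}
        else:
            med = {k: math.nan for k in fields}
        out.append(ParamRecord(t=ep.t0, **med))
    return out


def select_phase(signal: Signal, window: PhaseWindow) -> Signal:
    """Extract the sub-signal covering ``[t_start, t_end)`` of a phase window.

    A window running past either end of the recording is truncated and the
    returned signal flagged; a window with no overlap at all is an error.
    """
    i0 = int(round((window.t_start - signal.t0) * signal.rate))
    i1 = int(round((window.t_end - signal.t0) * signal.rate))
    i0_c, i1_c = max(i0, 0), min(i1, len(signal))
    if i0_c >= i1_c:
        raise ValueError(
            f"{window.phase} window [{window.t_start}, {window.t_end}) does "
            f"not overlap recording [{signal.t0}, {signal.t0 + signal.duration})"
        )
    return Signal(
        signal.samples[i0_c:i1_c],
        rate=signal.rate,
        t0=signal.t0 + i0_c / signal.rate,
        patient_id=signal.patient_id,
        truncated=(i0_c != i0 or i1_c != i1),
    )


def load_phase_windows(path: str | Path) -> dict[str, dict[str, PhaseWindow]]:
    """Load the JSON phase-window config: patient_id -> phase -> [t0, t1]."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    out: dict[str, dict[str, PhaseWindow]] = {}
    for patient, phases in raw.items():
        out[patient] = {
            phase: PhaseWindow(phase, float(t0), float(t1))
            for phase, (t0, t1) in phases.items()
        }
    return out


def write_phase_windows(windows: dict[str, dict[str, PhaseWindow]],
                        path: str | Path) -> None:
    raw = {
        patient: {ph: [w.t_start, w.t_end] for ph, w in phases.items()}
        for patient, phases in windows.items()
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(raw, fh, indent=2, sort_keys=True)
        fh.write("\n")
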