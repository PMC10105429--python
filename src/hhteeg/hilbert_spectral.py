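"""Analytic signal, instantaneous frequency, and Hilbert spectra of IMFs.

For each intrinsic mode function ``c(t)`` the analytic signal is
``Z(t) = c(t) + i H[c](t)`` with ``H`` the Hilbert transform (computed in
the frequency domain).  Its modulus gives the instantaneous amplitude
``a(t)`` and the time derivative of its unwrapped phase the instantaneous
frequency ``f(t)``.  Negative instantaneous frequencies are physically
meaningless for a well-separated mode and are masked out (never clamped),
as are samples at near-zero amplitude — where the phase is pure noise —
and a short trim at each epoch edge where the transform's end effects
dominate.

An epoch is summarised per IMF by the amplitude-weighted mean of the
masked-in frequencies (HHT_IF); the Hilbert spectrogram accumulates
``a(t)^2`` into 0.5 Hz x 1 s cells, and the marginal spectrum is its time
sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert as _scipy_hilbert

from .io_stream import Signal

__all__ = [
    "IFTrace",
    "HilbertSpectrum",
    "EpochSummary",
    "analytic_signal",
    "instantaneous_freq_amp",
    "epoch_hht_if",
    "epoch_hht_amp",
    "hilbert_spectrum",
    "classify_band",
]

#: seconds excluded at each epoch end when summarising (Hilbert end effects)
DEFAULT_EDGE_TRIM_S = 0.5
#: amplitude floor as a fraction of the mode's RMS, below which phase is noise
DEFAULT_AMP_FLOOR_REL = 1e-3
#: minimum fraction of masked-in samples for an epoch summary to be reported
DEFAULT_MIN_VALID_FRAC = 0.25


def analytic_signal(imf, rate: float | None = None) -> np.ndarray:
    """Analytic signal ``Z = c + iH[c]`` via the frequency-domain method.

    The real part equals the input exactly.
    """
    x = imf.samples if isinstance(imf, Signal) else np.asarray(imf, dtype=float)
    if len(x) == 0:
        return np.empty(0, dtype=complex)
    z = _scipy_hilbert(x)
    # guard the identity Re(Z) = x against any fft round-trip residue
    z = x + 1j * z.imag
    return z


@dataclass
class IFTrace:
    """Per-sample instantaneous amplitude/frequency of one IMF.

    ``valid_mask`` is False where the frequency is negative or beyond
    Nyquist, the amplitude sits below the noise floor, or the sample lies
    within the edge trim.
    """

    imf_index: int
    amplitude: np.ndarray
    frequency: np.ndarray
    valid_mask: np.ndarray
    rate: float

    @property
    def valid_fraction(self) -> float:
        return float(np.mean(self.valid_mask)) if len(self.valid_mask) else 0.0

    @property
    def negative_fraction(self) -> float:
        """Fraction of samples with negative instantaneous frequency."""
        if len(self.frequency) == 0:
            return 0.0
        return float(np.mean(self.frequency < 0))


def instantaneous_freq_amp(z: np.ndarray, rate: float, imf_index: int = 0,
                           edge_trim_s: float = DEFAULT_EDGE_TRIM_S,
                           amp_floor_rel: float = DEFAULT_AMP_FLOOR_REL,
                           ) -> IFTrace:
    """Instantaneous amplitude and frequency from an analytic signal.

    The phase is the unwrapped argument of ``Z``; the frequency its
    central-difference derivative over 2*pi, in Hz.
    """
    z = np.asarray(z, dtype=complex)
    n = len(z)
    amp = np.abs(z)
    if n < 3:
        return IFTrace(imf_index, amp, np.zeros(n), np.zeros(n, dtype=bool), rate)
    phase = np.unwrap(np.angle(z))
    freq = np.gradient(phase) * rate / (2.0 * np.pi)
    rms = float(np.sqrt(np.mean(z.real**2)))
    floor = amp_floor_rel * rms
    valid = (freq >= 0.0) & (freq <= rate / 2.0) & (amp >= floor)
    trim = int(round(edge_trim_s * rate))
    if trim > 0:
        valid[:trim] = False
        valid[n - trim:] = False
    return IFTrace(imf_index, amp, freq, valid, rate)


def epoch_hht_if(trace: IFTrace, method: str = "amplitude_weighted",
                 min_valid_frac: float = DEFAULT_MIN_VALID_FRAC) -> float:
    """Scalar HHT_IF of one epoch: summary of the masked-in frequencies.

    Default is the amplitude-weighted mean; ``method="median"`` gives the
    unweighted median.  NaN when fewer than ``min_valid_frac`` of the
    samples are masked-in.
    """
    m = trace.valid_mask
    if len(m) == 0 or np.mean(m) < min_valid_frac:
        return math.nan
    f = trace.frequency[m]
    if method == "amplitude_weighted":
        w = trace.amplitude[m]
        tot = float(np.sum(w))
        if tot <= 0:
            return math.nan
        return float(np.sum(w * f) / tot)
    if method == "median":
        return float(np.median(f))
    raise ValueError(f"unknown HHT_IF method {method!r}")


def epoch_hht_amp(trace: IFTrace,
                  min_valid_frac: float = DEFAULT_MIN_VALID_FRAC) -> float:
    """Mean instantaneous amplitude over the masked-in samples (uV)."""
    m = trace.valid_mask
    if len(m) == 0 or np.mean(m) < min_valid_frac:
        return math.nan
    return float(np.mean(trace.amplitude[m]))


@dataclass
class HilbertSpectrum:
    """Time-frequency amplitude-squared distribution of one epoch."""

    freq_edges: np.ndarray
    time_edges: np.ndarray
    power: np.ndarray  # (n_freq_bins, n_time_bins)
    marginal: np.ndarray  # time sum per frequency bin

    @property
    def freq_centers(self) -> np.ndarray:
        return 0.5 * (self.freq_edges[:-1] + self.freq_edges[1:])

    def band_fraction(self, f_lo: float, f_hi: float) -> float:
        """Fraction of total power carried by bins inside [f_lo, f_hi)."""
        total = float(self.power.sum())
        if total == 0:
            return 0.0
        c = self.freq_centers
        sel = (c >= f_lo) & (c < f_hi)
        return float(self.power[sel].sum() / total)


def hilbert_spectrum(traces: list[IFTrace], duration_s: float,
                     freq_res: float = 0.5, time_res: float = 1.0,
                     f_max: float | None = None) -> HilbertSpectrum:
    """Accumulate masked-in samples of all traces into a Hilbert spectrogram.

    Each masked-in sample contributes its amplitude squared to the cell
    indexed by its instantaneous frequency (0.5 Hz bins up to Nyquist by
    default) and its time (1 s bins).  The marginal spectrum is the exact
    time sum of the grid.
    """
    if not traces:
        raise ValueError("need at least one IF trace")
    rate = traces[0].rate
    if f_max is None:
        f_max = rate / 2.0
    freq_edges = np.arange(0.0, f_max + freq_res / 2, freq_res)
    time_edges = np.arange(0.0, duration_s + time_res / 2, time_res)
    power = np.zeros((len(freq_edges) - 1, len(time_edges) - 1))
    for tr in traces:
        m = tr.valid_mask
        if not m.any():
            continue
        t = np.arange(len(m))[m] / rate
        f = tr.frequency[m]
        w = tr.amplitude[m] ** 2
        hist, _, _ = np.histogram2d(f, t, bins=(freq_edges, time_edges),
                                    weights=w)
        power += hist
    return HilbertSpectrum(freq_edges=freq_edges, time_edges=time_edges,
                           power=power, marginal=power.sum(axis=1))


#: EEG band edges in Hz; half-open upward within each named range.
BAND_EDGES = (
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 7.0),
    ("alpha", 8.0, 12.0),
    ("beta", 13.0, 25.0),
)


def classify_band(freq: float) -> str:
    """Name the EEG band of a frequency: delta [1,4), theta [4,7),
    alpha [8,12), beta [13,25), gamma above 25; gaps and sub-delta are
    "other".  Negative input is an error."""
    if freq < 0:
        raise ValueError(f"frequency must be non-negative, got {freq}")
    for name, lo, hi in BAND_EDGES:
        if lo <= freq < hi:
            return name
    if freq >= 25.0:
        return "gamma"
    return "other"


@dataclass
class EpochSummary:
    """Per-epoch, per-IMF scalars aligned with the slow parameter records.

    ``hht_if[k]`` / ``hht_amp[k]`` hold the summary for IMF k+1 (NaN when
    that IMF is empty or almost fully masked); the monitor parameters are
    the within-epoch medians.
    """

    patient_id: str
    phase: str
    epoch_start: float
    hht_if: np.ndarray = field(default_factory=lambda: np.full(6, np.nan))
    hht_amp: np.ndarray = field(default_factory=lambda: np.full(6, np.nan))
    bis: float = math.nan
    sef95: float = math.nan
    sr: float = math.nan
    emglow: float = math.nan

    def as_row(self) -> dict:
        row = {
            "patient": self.patient_id,
            "phase": self.phase,
            "epoch_start_s": self.epoch_start,
        }
        for k in range(len(self.hht_if)):
            row[f"hht_if{k + 1}"] = self.hht_if[k]
        for k in range(len(self.hht_amp)):
            row[f"hht_amp{k + 1}"] = self.hht_amp[k]
        row.update(bis=self.bis, sef95=self.sef95, sr=self.sr,
                   emglow=self.emglow)
        return row
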