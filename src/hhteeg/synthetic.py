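"""Seeded synthetic anesthesia-EEG cohort generator.

No public recording of the study setting exists, so this module emulates
it: per patient, three 7-minute single-channel 128 Hz EEG phases
(induction, maintenance, emergence) plus the monitor's 3-s parameter
records.  The generator is built around an arousal level ``u(t)`` in
[0, 1] (1 = awake) that ramps 1 -> 0 over induction, stays 0 during
maintenance, and ramps 0 -> 1 over emergence:

* awake EEG mixes two beta-band oscillations (a fast beta/low-gamma
  component near the patient's ``beta_fast`` in 25.5-28.5 Hz and a
  coherent low-beta partner near ``beta_slow`` in 14-16 Hz) with weak
  broadband 31-45 Hz EMG-like noise — the desynchronised, low-amplitude
  pattern of wakefulness, in which mode decomposition finds beta in both
  of its first two modes;
* anesthetised EEG mixes a frontal alpha oscillation at the patient's
  ``alpha_center`` (8.5-11.5 Hz) with a strong slow-delta wave and a
  faint spindle-like tone above the alpha peak — the classic propofol
  pattern, decomposing into a weak fast mode over an alpha-dominated
  second mode;
* samples are ``u * awake + (1 - u) * anesthetised`` plus pink (1/f)
  background noise at 10% of the oscillation RMS.

Oscillations are narrow-band (slow random frequency drift, waxing-waning
amplitude) rather than pure sinusoids so that mode decomposition behaves
as it does on real EEG.  Companion records: BIS is an affine stand-in
``43 + 52 u`` calibrated to the awake/maintained medians 95 and 43 (it is
not the proprietary index), EMGlow is ``27.5 + 17.4 u`` dB, SEF95 is the
actual 95% spectral edge of the generated EEG, and the suppression ratio
is identically zero (burst suppression is not simulated).  Everything is
a pure function of the master seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, sosfiltfilt, welch

from .io_stream import (
    ParamRecord,
    PhaseWindow,
    Signal,
    write_eeg_tsv,
    write_params_tsv,
    write_phase_windows,
)

__all__ = [
    "SyntheticPatient",
    "Component",
    "PhaseProfile",
    "Cohort",
    "draw_patient",
    "make_profile",
    "synth_eeg",
    "synth_params",
    "synth_cohort",
    "write_cohort",
    "spectral_edge",
]

RATE = 128.0
PHASE_DURATION_S = 420.0
PARAM_CADENCE_S = 3.0
#: nominal window starts: induction at intubation prep, maintenance 30 min
#: after incision, emergence at wake-up call — spaced as in a short case
PHASE_STARTS = {"induction": 0.0, "maintenance": 1800.0, "emergence": 3600.0}
_PHASE_INDEX = {"induction": 0, "maintenance": 1, "emergence": 2}

#: BIS stand-in endpoints: awake and maintained-anesthesia medians
BIS_ANESTHETIZED = 43.0
BIS_AWAKE = 95.0
EMGLOW_ANESTHETIZED = 27.5
EMGLOW_AWAKE = 44.9

#: pink-noise amplitude relative to the oscillatory mixture RMS
PINK_FRACTION = 0.1
#: default narrow-band tone frequency-drift bandwidth (Hz)
TONE_DRIFT_BW = 0.3
#: default depth of the slow waxing-waning amplitude modulation
TONE_AM_DEPTH = 0.1
#: spindle-like residue frequency as a multiple of the alpha peak; at this
#: ratio and near-alpha amplitude the modes separate while the maintained
#: fast mode stays clearly below the awake beta modes
SPINDLE_RATIO = 1.7


@dataclass(frozen=True)
class SyntheticPatient:
    """Per-patient spectral parameters, reproducible from the seed."""

    patient_id: str
    alpha_center: float  # Hz, drawn in [8.5, 11.5]
    beta_fast: float  # Hz, drawn in [25.5, 28.5]
    beta_slow: float  # Hz, drawn in [14, 16]
    delta_center: float  # Hz, drawn in [0.8, 1.8]
    amp_scale: float  # lognormal multiplier on all amplitudes
    seed: int


@dataclass(frozen=True)
class Component:
    """One spectral ingredient: a drifting tone or a band of noise."""

    label: str
    center_hz: float
    amplitude_uv: float  # tone peak amplitude, or band-noise RMS
    bandwidth_hz: float
    kind: str = "tone"  # "tone" | "noise"
    am_depth: float = TONE_AM_DEPTH


@dataclass
class PhaseProfile:
    """Recipe for one phase of one patient: arousal path plus mixtures."""

    phase: str
    patient: SyntheticPatient
    duration_s: float
    awake: list[Component]
    anesthetized: list[Component]
    noise_sd: float | None  # pink-noise RMS in uV; None = 10% of mixture RMS
    seed: int

    def u(self, t: np.ndarray) -> np.ndarray:
        """Arousal level over time: smooth cosine ramps, monotone."""
        t = np.asarray(t, dtype=float)
        tau = np.clip(t / self.duration_s, 0.0, 1.0)
        if self.phase == "induction":
            return 0.5 * (1.0 + np.cos(np.pi * tau))
        if self.phase == "maintenance":
            return np.zeros_like(tau)
        if self.phase == "emergence":
            return 0.5 * (1.0 - np.cos(np.pi * tau))
        raise ValueError(f"unknown phase {self.phase!r}")


def draw_patient(patient_id: str, rng: np.random.Generator,
                 seed: int) -> SyntheticPatient:
    return SyntheticPatient(
        patient_id=patient_id,
        alpha_center=float(rng.uniform(8.5, 11.5)),
        beta_fast=float(rng.uniform(25.5, 28.5)),
        beta_slow=float(rng.uniform(14.0, 16.0)),
        delta_center=float(rng.uniform(0.8, 1.8)),
        amp_scale=float(rng.lognormal(0.0, 0.15)),
        seed=int(seed),
    )


def make_profile(phase: str, patient: SyntheticPatient,
                 duration_s: float = PHASE_DURATION_S,
                 noise_sd: float | None = None) -> PhaseProfile:
    """Build the spectral recipe for one phase of one patient.

    Mixture amplitudes and drift widths are calibrated so that the
    cohort's decomposed instantaneous-frequency medians land where
    intraoperative frontal EEG puts them: fast + low beta awake (modes 1
    and 2 both in the beta band), alpha over slow-delta when anesthetised
    (a faint spindle-like residue occupies mode 1 so that alpha appears
    in mode 2).
    """
    if phase not in _PHASE_INDEX:
        raise ValueError(f"unknown phase {phase!r}")
    s = patient.amp_scale
    awake = [
        Component("beta_fast", patient.beta_fast, 6.5 * s, 0.5),
        Component("beta_slow", patient.beta_slow, 8.0 * s, 0.2,
                  am_depth=0.05),
        Component("emg", 38.0, 1.2 * s, 14.0, "noise"),
    ]
    anesthetized = [
        Component("spindle_residue", SPINDLE_RATIO * patient.alpha_center,
                  13.0 * s, 0.5),
        Component("alpha", patient.alpha_center, 18.0 * s, 0.25),
        Component("slow_delta", patient.delta_center, 11.0 * s, 0.3),
    ]
    return PhaseProfile(
        phase=phase,
        patient=patient,
        duration_s=float(duration_s),
        awake=awake,
        anesthetized=anesthetized,
        noise_sd=noise_sd,
        seed=(patient.seed * 8 + _PHASE_INDEX[phase]) % (2**31),
    )


def _drifting_tone(rng: np.random.Generator, n: int, rate: float,
                   comp: Component) -> np.ndarray:
    """Narrow-band oscillation: slow frequency drift + waxing-waning AM."""
    sigma = rate / (2.0 * np.pi * max(comp.bandwidth_hz, 1e-3))
    drift = gaussian_filter1d(rng.standard_normal(n), sigma=sigma,
                              mode="reflect")
    sd = float(drift.std())
    if sd > 0:
        drift *= (comp.bandwidth_hz / 2.0) / sd
    phase = (2.0 * np.pi * np.cumsum(comp.center_hz + drift) / rate
             + rng.uniform(0.0, 2.0 * np.pi))
    am = gaussian_filter1d(rng.standard_normal(n),
                           sigma=rate / (2.0 * np.pi * 0.2), mode="reflect")
    sd = float(am.std())
    if sd > 0:
        am = 1.0 + comp.am_depth * am / sd
    else:
        am = np.ones(n)
    return comp.amplitude_uv * np.clip(am, 0.3, None) * np.cos(phase)


def _band_noise(rng: np.random.Generator, n: int, rate: float,
                comp: Component) -> np.ndarray:
    """Zero-mean Gaussian noise band-limited to the component's band."""
    lo = max(comp.center_hz - comp.bandwidth_hz / 2.0, 0.1)
    hi = min(comp.center_hz + comp.bandwidth_hz / 2.0, rate / 2.0 - 0.5)
    sos = butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    sd = float(x.std())
    if sd > 0:
        x *= comp.amplitude_uv / sd
    return x


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-RMS 1/f noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = 1.0 / np.sqrt(f[nz])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    sd = float(x.std())
    return x / sd if sd > 0 else x


def _render_mixture(components: list[Component], rng_children, n: int,
                    rate: float) -> np.ndarray:
    out = np.zeros(n)
    for comp, child in zip(components, rng_children):
        rng = np.random.default_rng(child)
        if comp.kind == "tone":
            out += _drifting_tone(rng, n, rate, comp)
        elif comp.kind == "noise":
            out += _band_noise(rng, n, rate, comp)
        else:
            raise ValueError(f"unknown component kind {comp.kind!r}")
    return out


def synth_eeg(profile: PhaseProfile, rate: float = RATE,
              t0: float | None = None) -> Signal:
    """Render the phase's EEG: arousal-blended mixtures plus pink noise."""
    n = int(round(profile.duration_s * rate))
    eeg_ss, _ = np.random.SeedSequence(profile.seed).spawn(2)
    children = eeg_ss.spawn(len(profile.awake) + len(profile.anesthetized) + 1)
    k = len(profile.awake)
    awake = _render_mixture(profile.awake, children[:k], n, rate)
    anes = _render_mixture(profile.anesthetized, children[k:-1], n, rate)
    t = np.arange(n) / rate
    u = profile.u(t)
    osc = u * awake + (1.0 - u) * anes
    if profile.noise_sd is None:
        pink_rms = PINK_FRACTION * float(np.sqrt(np.mean(osc**2)))
    else:
        pink_rms = profile.noise_sd
    x = osc + pink_rms * _pink_noise(np.random.default_rng(children[-1]), n)
    if t0 is None:
        t0 = PHASE_STARTS[profile.phase]
    return Signal(x, rate=rate, t0=t0, patient_id=profile.patient.patient_id)


def spectral_edge(signal: Signal, t_center: float, window_s: float = 8.0,
                  edge: float = 0.95) -> float:
    """95% spectral-edge frequency of the signal around ``t_center`` (s)."""
    i0 = int(round((t_center - signal.t0 - window_s / 2) * signal.rate))
    i1 = int(round((t_center - signal.t0 + window_s / 2) * signal.rate))
    i0, i1 = max(i0, 0), min(i1, len(signal))
    seg = signal.samples[i0:i1]
    if len(seg) < int(signal.rate):
        return math.nan
    f, psd = welch(seg, fs=signal.rate, nperseg=min(len(seg), 512))
    cum = np.cumsum(psd)
    if cum[-1] <= 0:
        return math.nan
    idx = int(np.searchsorted(cum, edge * cum[-1]))
    return float(f[min(idx, len(f) - 1)])


def synth_params(profile: PhaseProfile, signal: Signal | None = None,
                 noise: bool = True, rate: float = RATE) -> list[ParamRecord]:
    """Companion 3-s monitor records for a phase.

    BIS and EMGlow are affine in the arousal level with small Gaussian
    jitter (sd 2 index points and 1.5 dB); SEF95 is computed from the
    generated EEG itself in a sliding 8-s window; SR is identically zero.
    """
    if signal is None:
        signal = synth_eeg(profile, rate=rate)
    _, par_ss = np.random.SeedSequence(profile.seed).spawn(2)
    rng = np.random.default_rng(par_ss)
    times = np.arange(0.0, profile.duration_s - 1e-9, PARAM_CADENCE_S)
    u = profile.u(times)
    bis = BIS_ANESTHETIZED + (BIS_AWAKE - BIS_ANESTHETIZED) * u
    emg = EMGLOW_ANESTHETIZED + (EMGLOW_AWAKE - EMGLOW_ANESTHETIZED) * u
    if noise:
        bis = bis + rng.normal(0.0, 2.0, len(times))
        emg = emg + rng.normal(0.0, 1.5, len(times))
    bis = np.clip(bis, 0.0, 100.0)
    records = []
    for i, t in enumerate(times):
        sef = spectral_edge(signal, signal.t0 + t)
        records.append(ParamRecord(t=signal.t0 + float(t), bis=float(bis[i]),
                                   sef95=sef, sr=0.0, emglow=float(emg[i])))
    return records


@dataclass
class Cohort:
    """A full synthetic study: per-patient phase recordings and records."""

    patients: list[SyntheticPatient]
    recordings: dict  # patient_id -> phase -> (Signal, list[ParamRecord])
    windows: dict  # patient_id -> phase -> PhaseWindow
    manifest: dict = field(default_factory=dict)


def synth_cohort(n_patients: int, master_seed: int,
                 duration_s: float = PHASE_DURATION_S,
                 param_noise: bool = True) -> Cohort:
    """Generate a seeded cohort: three phase recordings per patient.

    Pure function of ``(n_patients, master_seed, duration_s)``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n_patients)
    patients = []
    recordings: dict = {}
    windows: dict = {}
    for i, child in enumerate(children):
        pid = f"P{i + 1:02d}"
        seed = int(child.generate_state(1)[0] % (2**31))
        patient = draw_patient(pid, np.random.default_rng(child), seed)
        patients.append(patient)
        recordings[pid] = {}
        windows[pid] = {}
        for phase, start in PHASE_STARTS.items():
            profile = make_profile(phase, patient, duration_s=duration_s)
            sig = synth_eeg(profile, t0=start)
            params = synth_params(profile, signal=sig, noise=param_noise)
            recordings[pid][phase] = (sig, params)
            windows[pid][phase] = PhaseWindow(phase, start, start + duration_s)
    manifest = {
        "n_patients": n_patients,
        "master_seed": master_seed,
        "duration_s": duration_s,
        "rate_hz": RATE,
        "param_cadence_s": PARAM_CADENCE_S,
        "patients": [
            {
                "patient_id": p.patient_id,
                "seed": p.seed,
                "alpha_center_hz": p.alpha_center,
                "beta_fast_hz": p.beta_fast,
                "beta_slow_hz": p.beta_slow,
                "delta_center_hz": p.delta_center,
                "amp_scale": p.amp_scale,
            }
            for p in patients
        ],
    }
    return Cohort(patients=patients, recordings=recordings, windows=windows,
                  manifest=manifest)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write the cohort in the monitor-export TSV formats plus a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for pid, phases in cohort.recordings.items():
        for phase, (sig, params) in phases.items():
            write_eeg_tsv(sig, out_dir / f"{pid}_{phase}_eeg.tsv")
            write_params_tsv(params, out_dir / f"{pid}_{phase}_params.tsv")
    write_phase_windows(cohort.windows, out_dir / "phase_windows.json")
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(cohort.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out_dir
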