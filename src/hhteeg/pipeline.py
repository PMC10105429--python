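"""End-to-end study orchestration.

Composes the stages on a cohort (synthetic or monitor-export files):
epoch the three 7-minute phases into 8-s windows, decompose each epoch
into up to six IMFs, summarise per-IMF instantaneous frequency (HHT_IF)
aligned with the monitor parameters, run the first/last signed-rank trend
table per phase, and regress BIS on the chosen IMF's HHT_IF during
emergence with a 20/10 patient split.  Every number in the report is a
pure function of the run configuration (seeds included).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .emd import decompose
from .hilbert_spectral import (
    EpochSummary,
    analytic_signal,
    epoch_hht_amp,
    epoch_hht_if,
    hilbert_spectrum,
    instantaneous_freq_amp,
)
from .io_stream import (
    ParamRecord,
    PhaseWindow,
    Signal,
    align_params,
    iter_epochs,
    load_phase_windows,
    read_eeg_tsv,
    read_params_tsv,
    select_phase,
)
from .synthetic import Cohort, synth_cohort, write_cohort
from .trend_stats import IF_VARIABLES, PARAM_VARIABLES, median_iqr_table
from . import gpr_model

log = logging.getLogger("hhteeg")

__all__ = [
    "RunConfig",
    "StudyReport",
    "analyze_epoch",
    "summarize_phase",
    "summarize_cohort",
    "assemble_gpr_dataset",
    "run_gpr_stage",
    "run_study",
    "run_single_epoch",
    "load_cohort_dir",
]


@dataclass
class RunConfig:
    """Configuration of one full study run."""

    n_patients: int = 30
    master_seed: int = 7
    duration_s: float = 420.0
    epoch_s: float = 8.0
    max_imfs: int = 6
    if_method: str = "amplitude_weighted"
    gpr_imf: int = 2  # 1-based IMF whose HHT_IF is regressed against BIS
    gpr_n_train: int = 20
    gpr_points_per_patient: int = 50
    gpr_n_restarts: int = 5
    input_dir: str | None = None  # monitor-export cohort; None = synthetic
    out_dir: str | None = None
    make_figures: bool = False

    @staticmethod
    def from_file(path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix in {".yaml", ".yml"}:
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return RunConfig(**raw)


@dataclass
class StudyReport:
    """All artefacts of one run, regenerable from config + seeds."""

    config: RunConfig
    summaries: pd.DataFrame
    trend_table: pd.DataFrame
    gpr_fit: "gpr_model.GPRFit | None"
    gpr_eval: pd.DataFrame | None
    gpr_split: tuple[list, list] | None
    provenance: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.summaries.to_csv(out_dir / "epoch_summaries.tsv", sep="\t",
                              index=False, float_format="%.6g")
        self.trend_table.to_csv(out_dir / "trend_table.tsv", sep="\t",
                                index=False, float_format="%.6g")
        self.trend_table.to_json(out_dir / "trend_table.json",
                                 orient="records", indent=2)
        if self.gpr_fit is not None:
            gpr_model.save_fit(self.gpr_fit, out_dir / "gpr_fit.json")
            self.gpr_eval.to_csv(out_dir / "gpr_eval.tsv", sep="\t",
                                 index=False, float_format="%.6g")
        with open(out_dir / "provenance.json", "w", encoding="utf-8") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return out_dir


def analyze_epoch(epoch: Signal, params: ParamRecord | None = None,
                  phase: str = "", max_imfs: int = 6,
                  if_method: str = "amplitude_weighted") -> EpochSummary:
    """Decompose one 8-s epoch and summarise each IMF's HHT_IF/amplitude."""
    imfset = decompose(epoch, max_imfs=max_imfs)
    hht_if = np.full(max_imfs, np.nan)
    hht_amp = np.full(max_imfs, np.nan)
    for k, imf in enumerate(imfset.imfs):
        z = analytic_signal(imf)
        trace = instantaneous_freq_amp(z, epoch.rate, imf_index=k + 1)
        hht_if[k] = epoch_hht_if(trace, method=if_method)
        hht_amp[k] = epoch_hht_amp(trace)
    summary = EpochSummary(
        patient_id=epoch.patient_id, phase=phase, epoch_start=epoch.t0,
        hht_if=hht_if, hht_amp=hht_amp,
    )
    if params is not None:
        summary.bis = params.bis
        summary.sef95 = params.sef95
        summary.sr = params.sr
        summary.emglow = params.emglow
    return summary


def summarize_phase(signal: Signal, params: list[ParamRecord], phase: str,
                    epoch_s: float = 8.0, max_imfs: int = 6,
                    if_method: str = "amplitude_weighted",
                    ) -> list[EpochSummary]:
    """Epoch a phase recording and analyse every epoch."""
    epochs = list(iter_epochs(signal, epoch_s=epoch_s))
    aligned = align_params(epochs, params)
    return [
        analyze_epoch(ep, par, phase=phase, max_imfs=max_imfs,
                      if_method=if_method)
        for ep, par in zip(epochs, aligned)
    ]


def summarize_cohort(cohort: Cohort, config: RunConfig) -> pd.DataFrame:
    """Epoch summaries for every patient and phase of a cohort."""
    from .trend_stats import summaries_to_frame

    rows: list[EpochSummary] = []
    for pid in sorted(cohort.recordings):
        for phase in ("induction", "maintenance", "emergence"):
            sig, params = cohort.recordings[pid][phase]
            window = cohort.windows[pid][phase]
            sub = select_phase(sig, window)
            rows.extend(
                summarize_phase(sub, params, phase, epoch_s=config.epoch_s,
                                max_imfs=config.max_imfs,
                                if_method=config.if_method)
            )
        log.info("summarised patient %s", pid)
    return summaries_to_frame(rows)


def assemble_gpr_dataset(summaries: pd.DataFrame, imf: int = 2,
                         points_per_patient: int = 50,
                         phase: str = "emergence") -> dict:
    """Per-patient (HHT_IF, BIS) pairs from the first epochs of a phase.

    Takes each patient's first ``points_per_patient`` epochs with both the
    chosen IMF's HHT_IF and BIS present.
    """
    col = f"hht_if{imf}"
    out = {}
    sub = summaries[summaries["phase"] == phase]
    for pid, grp in sub.groupby("patient", sort=True):
        grp = grp.sort_values("epoch_start_s")
        ok = grp[[col, "bis"]].dropna()
        ok = ok.iloc[:points_per_patient]
        if len(ok) >= 2:
            out[pid] = (ok[col].to_numpy(), ok["bis"].to_numpy())
    return out


def run_gpr_stage(summaries: pd.DataFrame, config: RunConfig):
    """Fit the emergence BIS ~ HHT_IF GP on the train split and evaluate.

    Returns ``(fit, eval_frame, (train_ids, test_ids))`` or
    ``(None, None, None)`` when the cohort is too small for the split.
    """
    data = assemble_gpr_dataset(summaries, imf=config.gpr_imf,
                                points_per_patient=config.gpr_points_per_patient)
    try:
        train_ids, test_ids = gpr_model.split_cohort(
            sorted(data), n_train=config.gpr_n_train, seed=config.master_seed)
    except ValueError as exc:
        log.warning("GPR stage skipped: %s", exc)
        return None, None, None
    x = np.concatenate([data[p][0] for p in train_ids])
    y = np.concatenate([data[p][1] for p in train_ids])
    fit = gpr_model.fit(x, y, seed=config.master_seed,
                        n_restarts=config.gpr_n_restarts)
    eval_frame = gpr_model.evaluate(fit, {p: data[p] for p in test_ids})
    # constant-predictor baseline: per-patient sd of the held-out targets
    eval_frame["baseline_sd"] = [
        float(np.std(data[p][1])) for p in sorted(test_ids)
    ]
    eval_frame["beats_constant"] = eval_frame["rmse"] < eval_frame["baseline_sd"]
    return fit, eval_frame, (train_ids, test_ids)


def load_cohort_dir(input_dir: str | Path) -> Cohort:
    """Load a monitor-export cohort directory written by ``write_cohort``.

    Expects ``<patient>_<phase>_eeg.tsv`` / ``_params.tsv`` pairs plus
    ``phase_windows.json``.
    """
    input_dir = Path(input_dir)
    windows = load_phase_windows(input_dir / "phase_windows.json")
    recordings: dict = {}
    for pid, phases in windows.items():
        recordings[pid] = {}
        for phase in phases:
            sig = read_eeg_tsv(input_dir / f"{pid}_{phase}_eeg.tsv",
                               patient_id=pid)
            params = read_params_tsv(input_dir / f"{pid}_{phase}_params.tsv")
            recordings[pid][phase] = (sig, params)
    manifest_path = input_dir / "manifest.json"
    manifest = (json.loads(manifest_path.read_text())
                if manifest_path.exists() else {})
    return Cohort(patients=[], recordings=recordings, windows=windows,
                  manifest=manifest)


def run_study(config: RunConfig) -> StudyReport:
    """Execute the full pipeline and return (optionally write) the report."""
    if config.input_dir is not None:
        cohort = load_cohort_dir(config.input_dir)
    else:
        cohort = synth_cohort(config.n_patients, config.master_seed,
                              duration_s=config.duration_s)
    summaries = summarize_cohort(cohort, config)
    trend = median_iqr_table(summaries,
                             variables=IF_VARIABLES + PARAM_VARIABLES)
    fit, eval_frame, split = run_gpr_stage(summaries, config)
    report = StudyReport(
        config=config,
        summaries=summaries,
        trend_table=trend,
        gpr_fit=fit,
        gpr_eval=eval_frame,
        gpr_split=split,
        provenance={
            "package_version": __version__,
            "config": dataclasses.asdict(config),
            "gpr_split": (None if split is None
                          else {"train": split[0], "test": split[1]}),
        },
    )
    if config.out_dir is not None:
        report.write(config.out_dir)
        if config.make_figures:
            from . import plotting

            plotting.save_report_figures(report, config.out_dir)
    return report


def run_single_epoch(signal: Signal | str | Path, t_start: float,
                     out_dir: str | Path | None = None, epoch_s: float = 8.0,
                     max_imfs: int = 6):
    """The worked-example workflow on one 8-s epoch.

    Decomposes the epoch starting at ``t_start`` seconds, derives the IF
    traces and the Hilbert spectrogram, and (optionally) writes the IMF
    TSV, the IF TSV and the spectrogram matrix.  The epoch must lie fully
    inside the recording.
    """
    if not isinstance(signal, Signal):
        signal = read_eeg_tsv(signal)
    window = PhaseWindow("maintenance", t_start, t_start + epoch_s)
    epoch = select_phase(signal, window)
    if epoch.truncated or abs(epoch.duration - epoch_s) > 1e-9:
        raise ValueError(
            f"epoch [{t_start}, {t_start + epoch_s}) crosses the recording "
            f"boundary [{signal.t0}, {signal.t0 + signal.duration})"
        )
    imfset = decompose(epoch, max_imfs=max_imfs)
    traces = []
    for k, imf in enumerate(imfset.imfs):
        z = analytic_signal(imf)
        traces.append(instantaneous_freq_amp(z, epoch.rate, imf_index=k + 1))
    spectrum = (hilbert_spectrum(traces, epoch.duration)
                if traces else None)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        t = epoch.times
        mat, empty = imfset.as_matrix(max_imfs)
        imf_df = pd.DataFrame({"time_s": t})
        for k in range(max_imfs):
            imf_df[f"imf{k + 1}"] = mat[k]
        imf_df["residual"] = imfset.residual
        imf_df.to_csv(out_dir / "imfs.tsv", sep="\t", index=False,
                      float_format="%.6g")
        if_df = pd.DataFrame({"time_s": t})
        for tr in traces:
            if_df[f"if{tr.imf_index}_hz"] = np.where(tr.valid_mask,
                                                     tr.frequency, np.nan)
            if_df[f"amp{tr.imf_index}_uv"] = tr.amplitude
        if_df.to_csv(out_dir / "if_traces.tsv", sep="\t", index=False,
                     float_format="%.6g")
        if spectrum is not None:
            pd.DataFrame(
                spectrum.power,
                index=spectrum.freq_centers,
                columns=spectrum.time_edges[:-1],
            ).to_csv(out_dir / "spectrogram.tsv", sep="\t",
                     float_format="%.6g")
    return imfset, traces, spectrum
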