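"""Cohort-level phase-trend analysis.

For each variable (per-IMF HHT_IF, BIS, SEF95, EMGlow) and each anesthesia
phase, the value at a patient's first analysis epoch is paired with the
value at their last epoch of the 7-minute window, and the paired change is
tested with the Wilcoxon matched-pairs signed-rank test.  Summaries are
reported as median (Q1, Q3) across patients with the conventional
significance stars (* p<0.05, ** p<0.01, *** p<0.001).

The signed-rank null distribution is computed exactly by enumerating sign
assignments (via a generating-function convolution over midranks, so ties
are handled) for n <= 25 pairs, and by the normal approximation with
continuity and tie corrections above that.  Zero differences are dropped
before ranking (Wilcoxon's original convention).  No multiple-testing
correction is applied: p-values are reported per variable, raw.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .hilbert_spectral import EpochSummary

__all__ = [
    "PairedSample",
    "TrendResult",
    "summaries_to_frame",
    "first_last_pairs",
    "wilcoxon_signed_rank",
    "exact_signed_rank_p",
    "median_iqr_table",
    "significance_stars",
]

#: largest n for which the exact signed-rank null is enumerated
EXACT_MAX_N = 25

IF_VARIABLES = tuple(f"hht_if{k}" for k in range(1, 7))
PARAM_VARIABLES = ("bis", "sef95", "emglow")


@dataclass(frozen=True)
class PairedSample:
    patient_id: str
    variable: str
    first_value: float
    last_value: float

    @property
    def difference(self) -> float:
        return self.last_value - self.first_value


@dataclass
class TrendResult:
    """One row of the phase-trend table."""

    variable: str
    phase: str
    n_pairs: int
    first_median: float = math.nan
    first_q1: float = math.nan
    first_q3: float = math.nan
    last_median: float = math.nan
    last_q1: float = math.nan
    last_q3: float = math.nan
    statistic: float = math.nan  # W+ = sum of ranks of positive differences
    p_value: float = math.nan
    stars: str = ""
    undefined: bool = False
    n_excluded: int = 0


def significance_stars(p: float) -> str:
    if math.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def summaries_to_frame(summaries: Iterable[EpochSummary]) -> pd.DataFrame:
    """Flatten epoch summaries into one row per epoch."""
    return pd.DataFrame([s.as_row() for s in summaries])


def first_last_pairs(frame: pd.DataFrame, variable: str,
                     phase: str) -> tuple[list[PairedSample], int]:
    """Pair each patient's earliest and latest epoch values in a phase.

    Patients with fewer than two epochs, or with a missing value at either
    end point, are excluded; the exclusion count is returned alongside.
    """
    sub = frame[frame["phase"] == phase]
    pairs: list[PairedSample] = []
    excluded = 0
    for pid, grp in sub.groupby("patient", sort=True):
        grp = grp.sort_values("epoch_start_s")
        if len(grp) < 2:
            warnings.warn(f"patient {pid}: fewer than 2 epochs in {phase}; "
                          "excluded", stacklevel=2)
            excluded += 1
            continue
        first = float(grp[variable].iloc[0])
        last = float(grp[variable].iloc[-1])
        if math.isnan(first) or math.isnan(last):
            excluded += 1
            continue
        pairs.append(PairedSample(str(pid), variable, first, last))
    return pairs, excluded


def _signed_ranks(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midranks of |d| and the signs, after dropping zero differences."""
    d = diffs[diffs != 0.0]
    ranks = _st.rankdata(np.abs(d))  # midranks for ties
    return ranks, np.sign(d)


def exact_signed_rank_p(diffs: Sequence[float]) -> tuple[float, float]:
    """Exact two-sided signed-rank p by enumerating all sign assignments.

    Works on the doubled midranks (integers even under ties) with a
    generating-function convolution, which is equivalent to summing over
    all 2^n sign patterns.  Returns ``(W_plus, p)``; two-sided
    ``p = min(1, 2 * min(P(W <= w), P(W >= w)))``.
    """
    diffs = np.asarray(diffs, dtype=float)
    ranks, signs = _signed_ranks(diffs)
    n = len(ranks)
    if n == 0:
        return math.nan, math.nan
    doubled = np.rint(2.0 * ranks).astype(int)
    w2 = int(np.sum(doubled[signs > 0]))
    total = int(doubled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:len(counts) - r]
        counts = counts + shifted
    counts /= counts.sum()
    p_le = float(counts[: w2 + 1].sum())
    p_ge = float(counts[w2:].sum())
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return float(np.sum(ranks[signs > 0])), p


def _normal_approx_p(diffs: np.ndarray) -> tuple[float, float]:
    """Two-sided p via the normal approximation with continuity and ties."""
    ranks, signs = _signed_ranks(diffs)
    n = len(ranks)
    w_plus = float(np.sum(ranks[signs > 0]))
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    if var <= 0:
        return w_plus, math.nan
    # continuity correction toward the mean
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
    return w_plus, float(2.0 * _st.norm.sf(abs(z)))


def wilcoxon_signed_rank(pairs: Sequence[PairedSample], phase: str = "",
                         exact_max_n: int = EXACT_MAX_N) -> TrendResult:
    """Wilcoxon matched-pairs signed-rank test on first/last pairs.

    Exact enumeration null up to ``exact_max_n`` non-zero differences,
    normal approximation above.  All-zero differences make the test
    undefined (reported as such, not as p = 1).
    """
    if not pairs:
        return TrendResult(variable="", phase=phase, n_pairs=0, undefined=True)
    variable = pairs[0].variable
    firsts = np.array([p.first_value for p in pairs])
    lasts = np.array([p.last_value for p in pairs])
    diffs = lasts - firsts
    result = TrendResult(
        variable=variable, phase=phase, n_pairs=len(pairs),
        first_median=float(np.median(firsts)),
        first_q1=float(np.quantile(firsts, 0.25)),
        first_q3=float(np.quantile(firsts, 0.75)),
        last_median=float(np.median(lasts)),
        last_q1=float(np.quantile(lasts, 0.25)),
        last_q3=float(np.quantile(lasts, 0.75)),
    )
    n_nonzero = int(np.count_nonzero(diffs))
    if n_nonzero == 0:
        result.undefined = True
        return result
    if n_nonzero <= exact_max_n:
        w, p = exact_signed_rank_p(diffs)
    else:
        w, p = _normal_approx_p(diffs)
    result.statistic = w
    result.p_value = p
    result.stars = significance_stars(p)
    return result


def median_iqr_table(frame: pd.DataFrame,
                     variables: Sequence[str] = IF_VARIABLES + PARAM_VARIABLES,
                     phases: Sequence[str] = ("induction", "maintenance",
                                              "emergence"),
                     ) -> pd.DataFrame:
    """First/last median (Q1, Q3) and signed-rank test per variable x phase.

    Quartiles use linear interpolation (the type-7 convention).  Layout:
    one row per (variable, phase) with first/last summaries, W+, p and
    stars — the per-IMF rows mirror a six-IMF x three-phase trend table.
    """
    rows = []
    for variable in variables:
        for phase in phases:
            pairs, excluded = first_last_pairs(frame, variable, phase)
            res = wilcoxon_signed_rank(pairs, phase=phase)
            res.variable = variable
            res.n_excluded = excluded
            rows.append(
                {
                    "variable": variable,
                    "phase": phase,
                    "n_pairs": res.n_pairs,
                    "n_excluded": excluded,
                    "first_median": res.first_median,
                    "first_q1": res.first_q1,
                    "first_q3": res.first_q3,
                    "last_median": res.last_median,
                    "last_q1": res.last_q1,
                    "last_q3": res.last_q3,
                    "W": res.statistic,
                    "p_value": res.p_value,
                    "stars": res.stars,
                    "undefined": res.undefined,
                }
            )
    return pd.DataFrame(rows)
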