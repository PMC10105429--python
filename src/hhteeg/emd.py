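"""Empirical mode decomposition by envelope sifting.

EMD peels a signal into intrinsic mode functions (IMFs) from the highest
oscillation frequency downward.  Each sifting step subtracts the mean of
the upper and lower extrema envelopes from the running candidate; an
admissible IMF has (1) zero-crossing and extrema counts differing by at
most one and (2) envelopes locally symmetric about zero.  The decomposition
is complete by construction: the IMFs plus the final residual sum back to
the input exactly (up to floating-point error).

Conventions chosen here (the classical ones, all configurable):

* envelopes are natural cubic splines through the maxima / minima, with
  the two nearest extrema mirror-reflected beyond each end of the signal
  to tame boundary swing;
* sifting stops on a Cauchy-type criterion ``sum(m^2)/sum(h^2) < sd_tol``
  (default 0.2) — accepted only once the candidate also meets the
  zero-crossing/extrema count criterion, otherwise sifting continues —
  or when the counts have been stable and admissible for ``s_number``
  (default 3) consecutive sifts, whichever fires first, capped at
  ``max_sifts`` (default 50);
* plateau extrema contribute their midpoint index once; elsewhere extrema
  are strict-neighbour comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .io_stream import Signal

__all__ = [
    "ExtremaSet",
    "SiftResult",
    "IMFSet",
    "TrendComponentError",
    "find_extrema",
    "envelope_mean",
    "count_zero_crossings",
    "is_imf",
    "sift_to_imf",
    "decompose",
    "orthogonality_index",
]


class TrendComponentError(ValueError):
    """The series is a monotone/trend component: too few extrema to envelope."""


@dataclass
class ExtremaSet:
    """Indices and values of the local maxima and minima of a series."""

    max_idx: np.ndarray
    max_val: np.ndarray
    min_idx: np.ndarray
    min_val: np.ndarray

    @property
    def n_max(self) -> int:
        return len(self.max_idx)

    @property
    def n_min(self) -> int:
        return len(self.min_idx)

    @property
    def n_extrema(self) -> int:
        return self.n_max + self.n_min


def _as_array(x) -> np.ndarray:
    if isinstance(x, Signal):
        x = x.samples
    return np.asarray(x, dtype=float)


def find_extrema(x) -> ExtremaSet:
    """Locate interior local maxima and minima by strict comparison.

    A flat plateau bounded by opposite slopes counts once, at its midpoint
    index.  Endpoints are never extrema; constant and strictly monotone
    series have none.
    """
    x = _as_array(x)
    if len(x) < 3:
        return ExtremaSet(*(np.empty(0, dtype=int), np.empty(0)) * 2)
    dx = np.diff(x)
    nz = np.nonzero(dx)[0]
    if len(nz) < 2:
        empty = (np.empty(0, dtype=int), np.empty(0))
        return ExtremaSet(*empty, *empty)
    signs = np.sign(dx[nz])
    flips = np.nonzero(np.diff(signs))[0]
    max_idx, min_idx = [], []
    for j in flips:
        # plateau spans samples nz[j]+1 .. nz[j+1] (a single point if no flat)
        mid = (nz[j] + 1 + nz[j + 1]) // 2
        (max_idx if signs[j] > 0 else min_idx).append(mid)
    max_idx = np.asarray(max_idx, dtype=int)
    min_idx = np.asarray(min_idx, dtype=int)
    return ExtremaSet(max_idx, x[max_idx], min_idx, x[min_idx])


def _mirror_extend(idx: np.ndarray, val: np.ndarray, n: int):
    """Mirror the two extrema nearest each end across the signal boundaries."""
    left_i, left_v = [], []
    for i in range(min(2, len(idx))):
        if idx[i] > 0:
            left_i.append(-idx[i])
            left_v.append(val[i])
    right_i, right_v = [], []
    for i in range(max(0, len(idx) - 2), len(idx)):
        if idx[i] < n - 1:
            right_i.append(2 * (n - 1) - idx[i])
            right_v.append(val[i])
    ext_i = np.concatenate([left_i[::-1], idx, right_i[::-1]])
    ext_v = np.concatenate([left_v[::-1], val, right_v[::-1]])
    keep = np.concatenate([[True], np.diff(ext_i) > 0])
    return ext_i[keep], ext_v[keep]


def envelope_mean(x, extrema: ExtremaSet | None = None) -> np.ndarray:
    """Pointwise mean of the upper and lower cubic-spline envelopes.

    Raises :class:`TrendComponentError` when fewer than two maxima or two
    minima exist — the caller then treats the series as a residual trend.
    """
    x = _as_array(x)
    ext = extrema if extrema is not None else find_extrema(x)
    if ext.n_max < 2 or ext.n_min < 2:
        raise TrendComponentError(
            f"monotone/trend component: {ext.n_max} maxima, {ext.n_min} minima"
        )
    n = len(x)
    grid = np.arange(n)
    ui, uv = _mirror_extend(ext.max_idx, ext.max_val, n)
    li, lv = _mirror_extend(ext.min_idx, ext.min_val, n)
    upper = CubicSpline(ui, uv, bc_type="natural")(grid)
    lower = CubicSpline(li, lv, bc_type="natural")(grid)
    return 0.5 * (upper + lower)


def count_zero_crossings(x) -> int:
    """Number of sign changes, with exact zeros attached to the prior sign."""
    x = _as_array(x)
    s = np.sign(x)
    s = s[s != 0]
    if len(s) < 2:
        return 0
    return int(np.count_nonzero(np.diff(s)))


def is_imf(x, symmetry_tol: float = 0.3) -> tuple[bool, dict]:
    """Check the two IMF admissibility criteria; returns (ok, diagnostics).

    Criterion 1: ``|#zero-crossings - #extrema| <= 1``.  Criterion 2
    (local symmetry about zero): RMS of the envelope mean at most
    ``symmetry_tol`` times the RMS of the series.  Series with fewer than
    two extrema of either kind fail outright.

    The count criterion is the sharp detector (it catches offsets and
    mode mixing); the symmetry bound is a gross-asymmetry catch.  Under
    the default stopping rule a legitimately sifted mode retains an
    envelope-mean RMS of roughly 5-20% of the series RMS, so the default
    tolerance sits above that operating range.
    """
    x = _as_array(x)
    ext = find_extrema(x)
    zc = count_zero_crossings(x)
    diag = {
        "n_zero_crossings": zc,
        "n_extrema": ext.n_extrema,
        "n_maxima": ext.n_max,
        "n_minima": ext.n_min,
        "count_ok": abs(zc - ext.n_extrema) <= 1,
        "symmetry_ratio": np.inf,
        "symmetry_ok": False,
    }
    if ext.n_max < 2 or ext.n_min < 2:
        return False, diag
    rms = float(np.sqrt(np.mean(x**2)))
    if rms == 0.0:
        return False, diag
    m = envelope_mean(x, ext)
    ratio = float(np.sqrt(np.mean(m**2)) / rms)
    diag["symmetry_ratio"] = ratio
    diag["symmetry_ok"] = ratio <= symmetry_tol
    return bool(diag["count_ok"] and diag["symmetry_ok"]), diag


@dataclass
class SiftResult:
    imf: np.ndarray
    remainder: np.ndarray
    sift_count: int
    converged: bool


def sift_to_imf(x, max_sifts: int = 50, sd_tol: float = 0.2,
                s_number: int = 3) -> SiftResult:
    """Iterate ``h <- h - envelope_mean(h)`` until the stopping rule fires.

    Stops on the Cauchy criterion ``sum((h_prev - h)^2)/sum(h_prev^2) <
    sd_tol`` once the candidate also satisfies the zero-crossing/extrema
    count criterion (a small correction alone does not make an IMF), or
    after the counts have stayed fixed and admissible for ``s_number``
    consecutive sifts.  Hitting ``max_sifts`` returns the current
    candidate flagged non-converged.  A series without two extrema of
    each kind raises :class:`TrendComponentError` (it is a trend, not an
    oscillation).
    """
    x = _as_array(x)
    h = x.copy()
    stable = 0
    prev_counts = None
    converged = False
    count = 0
    for count in range(1, max_sifts + 1):
        ext = find_extrema(h)
        if ext.n_max < 2 or ext.n_min < 2:
            if count == 1:
                raise TrendComponentError(
                    "series lost to trend before first sift"
                )
            converged = True  # nothing left to sift
            count -= 1
            break
        m = envelope_mean(h, ext)
        h_new = h - m
        denom = float(np.sum(h**2))
        sd = float(np.sum(m**2)) / denom if denom > 0 else 0.0
        ext_new = find_extrema(h_new)
        zc_new = count_zero_crossings(h_new)
        counts = (ext_new.n_max, ext_new.n_min, zc_new)
        admissible = abs(zc_new - ext_new.n_extrema) <= 1
        if counts == prev_counts and admissible:
            stable += 1
        else:
            stable = 0
        prev_counts = counts
        h = h_new
        if (sd < sd_tol and admissible) or stable >= s_number:
            converged = True
            break
    return SiftResult(imf=h, remainder=x - h, sift_count=count,
                      converged=converged)


@dataclass
class IMFSet:
    """Ordered IMFs plus residual from one epoch.

    ``imfs[k]`` is the (k+1)-th mode, highest frequency first.  The sum of
    all IMFs and the residual reproduces the input to floating-point
    accuracy (``reconstruction_error`` records the worst deviation).
    ``as_matrix`` pads to a fixed number of rows (all-zero, flagged empty)
    so downstream tables always carry six IMF slots.
    """

    imfs: list[np.ndarray]
    residual: np.ndarray
    sift_counts: list[int] = field(default_factory=list)
    converged: list[bool] = field(default_factory=list)
    imf_ok: list[bool] = field(default_factory=list)
    reconstruction_error: float = 0.0

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def as_matrix(self, n_rows: int = 6) -> tuple[np.ndarray, np.ndarray]:
        """(n_rows, n_samples) IMF matrix zero-padded, plus empty-row mask."""
        n = len(self.residual)
        mat = np.zeros((n_rows, n))
        empty = np.ones(n_rows, dtype=bool)
        for k, imf in enumerate(self.imfs[:n_rows]):
            mat[k] = imf
            empty[k] = False
        return mat, empty


def decompose(signal, max_imfs: int = 6, max_sifts: int = 50,
              sd_tol: float = 0.2, s_number: int = 3,
              symmetry_tol: float = 0.3) -> IMFSet:
    """Full EMD of one epoch into at most ``max_imfs`` IMFs plus a residual.

    Modes are extracted from the running remainder until it has fewer than
    two extrema of either kind (it becomes the residual trend) or the mode
    budget is exhausted.  Degenerate inputs (constant, monotone) yield zero
    IMFs with the input as residual.
    """
    x = _as_array(signal)
    if len(x) < 3:
        raise ValueError("need at least 3 samples to decompose")
    remainder = x.copy()
    imfs: list[np.ndarray] = []
    counts: list[int] = []
    conv: list[bool] = []
    ok: list[bool] = []
    for _ in range(max_imfs):
        ext = find_extrema(remainder)
        if ext.n_max < 2 or ext.n_min < 2:
            break
        res = sift_to_imf(remainder, max_sifts=max_sifts, sd_tol=sd_tol,
                          s_number=s_number)
        imfs.append(res.imf)
        counts.append(res.sift_count)
        conv.append(res.converged)
        ok.append(is_imf(res.imf, symmetry_tol=symmetry_tol)[0])
        remainder = res.remainder
    recon = np.sum(imfs, axis=0) + remainder if imfs else remainder
    err = float(np.max(np.abs(x - recon)))
    return IMFSet(imfs=imfs, residual=remainder, sift_counts=counts,
                  converged=conv, imf_ok=ok, reconstruction_error=err)


def orthogonality_index(imfset: IMFSet, x=None) -> float:
    """Worst pairwise overlap ``|sum imf_i imf_j| / sum x^2`` over i != j."""
    if imfset.n_imfs < 2:
        return 0.0
    if x is None:
        x = np.sum(imfset.imfs, axis=0) + imfset.residual
    x = _as_array(x)
    denom = float(np.sum(x**2))
    if denom == 0:
        return 0.0
    worst = 0.0
    for i in range(imfset.n_imfs):
        for j in range(i + 1, imfset.n_imfs):
            worst = max(worst, abs(float(np.sum(imfset.imfs[i] * imfset.imfs[j]))) / denom)
    return worst
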