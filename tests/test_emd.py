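"""Empirical mode decomposition: extrema, envelopes, sifting, completeness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hhteeg.emd import (
    TrendComponentError,
    count_zero_crossings,
    decompose,
    envelope_mean,
    find_extrema,
    is_imf,
    orthogonality_index,
    sift_to_imf,
)
from hhteeg.hilbert_spectral import (
    analytic_signal,
    epoch_hht_if,
    instantaneous_freq_amp,
)

RATE = 128.0


def _tone(freq, n=1024, amp=1.0, phase=0.0):
    return amp * np.cos(2 * np.pi * freq * np.arange(n) / RATE + phase)


class TestFindExtrema:
    def test_two_hz_sine_has_16_of_each(self):
        # maxima of sin(2 pi 2 t) at t = 0.125 + 0.5 k over 8 s: 16 of them
        x = np.sin(2 * np.pi * 2.0 * np.arange(1024) / RATE)
        ext = find_extrema(x)
        assert ext.n_max == 16
        assert ext.n_min == 16
        np.testing.assert_allclose(ext.max_idx / RATE,
                                   0.125 + 0.5 * np.arange(16), atol=1 / RATE)

    def test_constant_and_ramp_have_none(self):
        assert find_extrema(np.ones(100)).n_extrema == 0
        assert find_extrema(np.linspace(0, 1, 100)).n_extrema == 0

    def test_plateau_counts_once_at_midpoint(self):
        x = np.array([0, 1, 2, 2, 2, 1, 0, -1, 0], dtype=float)
        ext = find_extrema(x)
        assert list(ext.max_idx) == [3]
        assert list(ext.min_idx) == [7]

    def test_maxima_minima_interleave(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=512)
        ext = find_extrema(x)
        merged = sorted([(i, "M") for i in ext.max_idx] +
                        [(i, "m") for i in ext.min_idx])
        kinds = [k for _, k in merged]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))


class TestEnvelopeMean:
    def test_sine_interior_mean_near_zero(self):
        x = _tone(10.0)
        m = envelope_mean(x)
        sl = slice(102, 922)  # interior 80%
        assert np.abs(m[sl]).max() <= 0.05

    def test_shift_equivariance(self):
        x = _tone(10.0)
        m0 = envelope_mean(x)
        m3 = envelope_mean(x + 3.0)
        np.testing.assert_allclose(m3, m0 + 3.0, atol=1e-9)

    def test_too_few_extrema_raises(self):
        # one maximum, one minimum: a single slow half-cycle pair
        x = np.sin(2 * np.pi * np.arange(128) / 128.0)
        ext = find_extrema(x)
        assert ext.n_max == 1 and ext.n_min == 1
        with pytest.raises(TrendComponentError):
            envelope_mean(x)


class TestIsIMF:
    def test_pure_sine_is_imf(self):
        ok, diag = is_imf(_tone(10.0))
        assert ok
        assert diag["count_ok"] and diag["symmetry_ok"]

    def test_offset_sine_fails_count(self):
        # amplitude 1 tone shifted by 10: no zero crossings but a full set
        # of extrema (31 interior ones — endpoints are never counted)
        x = _tone(2.0) + 10.0
        ok, diag = is_imf(x)
        assert not ok
        assert diag["n_zero_crossings"] == 0
        assert diag["n_extrema"] == 31
        assert not diag["count_ok"]

    def test_ramp_is_not_imf(self):
        ok, _ = is_imf(np.linspace(-1, 1, 256))
        assert not ok

    def test_zero_crossings_counter(self):
        assert count_zero_crossings(np.array([1.0, -1, 1, -1])) == 3
        assert count_zero_crossings(np.array([1.0, 0.0, -1.0])) == 1


class TestSift:
    def test_single_tone_passes_through(self):
        x = _tone(10.0)
        res = sift_to_imf(x)
        rel = np.linalg.norm(res.imf - x) / np.linalg.norm(x)
        assert rel <= 0.02
        assert np.abs(res.remainder).max() <= 0.1

    def test_two_tone_sift_extracts_fast_component(self):
        x = _tone(25.0) + _tone(10.0)
        res = sift_to_imf(x)
        f, p = __import__("scipy.signal", fromlist=["periodogram"]).periodogram(
            res.imf, fs=RATE)
        assert 24.0 <= f[np.argmax(p)] <= 26.0

    def test_ramp_propagates_trend_error(self):
        with pytest.raises(TrendComponentError):
            sift_to_imf(np.linspace(0, 1, 256))


class TestDecompose:
    def test_completeness_on_noise(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 20, 1024)
        s = decompose(x)
        recon = np.sum(s.imfs, axis=0) + s.residual
        assert np.abs(x - recon).max() <= 1e-8 * np.abs(x).max()

    def test_two_tone_imf_frequencies(self):
        x = _tone(25.0) + _tone(10.0)
        s = decompose(x)
        meds = []
        for k in range(2):
            tr = instantaneous_freq_amp(analytic_signal(s.imfs[k]), RATE)
            meds.append(np.median(tr.frequency[tr.valid_mask]))
        assert meds[0] == pytest.approx(25.0, abs=1.0)
        assert meds[1] == pytest.approx(10.0, abs=1.0)

    def test_constant_input_all_residual(self):
        s = decompose(np.full(256, 3.0))
        assert s.n_imfs == 0
        np.testing.assert_array_equal(s.residual, np.full(256, 3.0))

    def test_max_imfs_respected_and_matrix_padding(self):
        rng = np.random.default_rng(3)
        s = decompose(rng.normal(size=1024), max_imfs=6)
        assert s.n_imfs <= 6
        mat, empty = s.as_matrix(6)
        assert mat.shape == (6, 1024)
        assert empty.sum() == 6 - s.n_imfs

    def test_frequency_ordering_on_tone_mixture(self):
        x = _tone(40.0) + _tone(20.0) + _tone(8.0) + _tone(3.0)
        s = decompose(x)
        meds = []
        for imf in s.imfs:
            tr = instantaneous_freq_amp(analytic_signal(imf), RATE)
            if tr.valid_mask.mean() > 0.25:
                meds.append(float(np.median(tr.frequency[tr.valid_mask])))
        assert all(a > b for a, b in zip(meds, meds[1:]))

    def test_orthogonality_on_tone_mixture(self):
        x = _tone(25.0) + _tone(10.0) + _tone(3.0)
        s = decompose(x)
        assert orthogonality_index(s, x) <= 0.1

    def test_admissibility_flags_recorded(self):
        rng = np.random.default_rng(11)
        s = decompose(rng.normal(size=1024))
        assert len(s.imf_ok) == s.n_imfs
        assert len(s.converged) == s.n_imfs

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_completeness_property(self, seed):
        """Reconstruction is exact for tones, chirps and noise mixtures."""
        rng = np.random.default_rng(seed)
        t = np.arange(1024) / RATE
        kind = seed % 3
        if kind == 0:
            x = rng.normal(0, 10, 1024)
        elif kind == 1:
            x = 10 * np.cos(2 * np.pi * rng.uniform(5, 30) * t) + rng.normal(
                0, 2, 1024)
        else:
            from scipy.signal import chirp

            x = 10 * chirp(t, rng.uniform(2, 8), 8, rng.uniform(15, 40))
        s = decompose(x)
        recon = (np.sum(s.imfs, axis=0) if s.imfs else 0) + s.residual
        assert np.abs(x - recon).max() <= 1e-8 * np.abs(x).max()
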