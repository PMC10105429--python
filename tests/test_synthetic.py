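"""Synthetic anesthesia-cohort generator: determinism, spectra, records."""

import numpy as np
import pytest
from scipy.signal import welch

from hhteeg.io_stream import read_eeg_tsv, read_params_tsv
from hhteeg.synthetic import (
    draw_patient,
    make_profile,
    synth_cohort,
    synth_eeg,
    synth_params,
    write_cohort,
)


def _patient(i):
    ss = np.random.SeedSequence(5000 + i)
    return draw_patient(f"X{i}", np.random.default_rng(ss),
                        int(ss.generate_state(1)[0] % 2**31))


def _dominant_peak(x, rate=128.0):
    f, p = welch(x, fs=rate, nperseg=256)
    return f[np.argmax(p)]


class TestArousalPath:
    @pytest.mark.parametrize("phase,u0,u1", [
        ("induction", 1.0, 0.0),
        ("maintenance", 0.0, 0.0),
        ("emergence", 0.0, 1.0),
    ])
    def test_endpoints_and_monotonicity(self, phase, u0, u1):
        prof = make_profile(phase, _patient(0))
        t = np.linspace(0, 420, 500)
        u = prof.u(t)
        assert u[0] == pytest.approx(u0, abs=1e-9)
        assert u[-1] == pytest.approx(u1, abs=1e-9)
        du = np.diff(u)
        if phase == "induction":
            assert np.all(du <= 1e-12)
        elif phase == "emergence":
            assert np.all(du >= -1e-12)
        else:
            assert np.all(u == 0)

    def test_unknown_phase_rejected(self):
        with pytest.raises(ValueError, match="phase"):
            make_profile("recovery", _patient(0))

    def test_alpha_center_passthrough(self):
        pat = _patient(3)
        prof = make_profile("emergence", pat)
        alpha = [c for c in prof.anesthetized if c.label == "alpha"]
        assert alpha[0].center_hz == pat.alpha_center
        assert 8.5 <= pat.alpha_center <= 11.5


class TestSynthEEG:
    def test_seeded_determinism(self):
        prof = make_profile("maintenance", _patient(1), duration_s=8.0)
        a = synth_eeg(prof).samples
        b = synth_eeg(prof).samples
        np.testing.assert_array_equal(a, b)

    def test_rate_and_length(self):
        sig = synth_eeg(make_profile("maintenance", _patient(1),
                                     duration_s=8.0))
        assert sig.rate == 128.0
        assert len(sig) == 1024

    def test_maintenance_peak_in_alpha(self):
        sig = synth_eeg(make_profile("maintenance", _patient(2),
                                     duration_s=8.0))
        assert 8.0 <= _dominant_peak(sig.samples) <= 12.0

    def test_awake_peak_in_beta(self):
        # the first 8 s of induction are effectively awake (u ~ 1)
        sig = synth_eeg(make_profile("induction", _patient(2)))
        assert 13.0 <= _dominant_peak(sig.samples[:1024]) <= 25.0

    def test_spectral_fidelity_across_seeds(self):
        """>= 95% of seeded epochs put the dominant peak in the state band."""
        n = 60
        ok_maint = sum(
            8.0 <= _dominant_peak(
                synth_eeg(make_profile("maintenance", _patient(i),
                                       duration_s=8.0)).samples) <= 12.0
            for i in range(n)
        )
        ok_awake = sum(
            13.0 <= _dominant_peak(
                synth_eeg(make_profile("induction", _patient(i))
                          ).samples[:1024]) <= 25.0
            for i in range(n)
        )
        assert ok_maint >= 0.95 * n
        assert ok_awake >= 0.95 * n


class TestSynthParams:
    def test_bis_endpoints_without_noise(self):
        pat = _patient(4)
        maint = make_profile("maintenance", pat, duration_s=30.0)
        recs = synth_params(maint, noise=False)
        assert all(r.bis == pytest.approx(43.0) for r in recs)
        # end of emergence is fully awake
        emer = make_profile("emergence", pat, duration_s=30.0)
        recs = synth_params(emer, noise=False)
        assert recs[0].bis == pytest.approx(43.0)
        u_last = emer.u(np.array([recs[-1].t - 3600.0]))[0]
        assert recs[-1].bis == pytest.approx(43.0 + 52.0 * u_last)

    def test_bis_and_emglow_monotone_in_arousal(self):
        prof = make_profile("emergence", _patient(4), duration_s=60.0)
        recs = synth_params(prof, noise=False)
        bis = [r.bis for r in recs]
        emg = [r.emglow for r in recs]
        assert np.all(np.diff(bis) >= -1e-9)
        assert np.all(np.diff(emg) >= -1e-9)

    def test_cadence_and_count(self):
        recs = synth_params(make_profile("maintenance", _patient(5),
                                         duration_s=420.0))
        assert len(recs) == 140
        assert np.allclose(np.diff([r.t for r in recs]), 3.0)

    def test_sr_is_zero_and_sef95_positive(self):
        recs = synth_params(make_profile("maintenance", _patient(5),
                                         duration_s=30.0))
        assert all(r.sr == 0.0 for r in recs)
        assert all(r.sef95 > 0 for r in recs)


class TestCohort:
    def test_cohort_files_roundtrip(self, tmp_path):
        cohort = synth_cohort(2, 11, duration_s=24.0)
        out = write_cohort(cohort, tmp_path / "cohort")
        for pid in ("P01", "P02"):
            for phase in ("induction", "maintenance", "emergence"):
                sig = read_eeg_tsv(out / f"{pid}_{phase}_eeg.tsv")
                assert sig.rate == pytest.approx(128.0, rel=1e-9)
                recs = read_params_tsv(out / f"{pid}_{phase}_params.tsv")
                assert len(recs) == 8  # 24 s / 3 s

    def test_cohort_pure_function_of_seed(self, tmp_path):
        a = write_cohort(synth_cohort(2, 11, duration_s=24.0), tmp_path / "a")
        b = write_cohort(synth_cohort(2, 11, duration_s=24.0), tmp_path / "b")
        for fa in sorted(a.iterdir()):
            assert fa.read_bytes() == (b / fa.name).read_bytes()

    def test_different_seeds_differ(self):
        a = synth_cohort(1, 11, duration_s=16.0)
        b = synth_cohort(1, 12, duration_s=16.0)
        sa = a.recordings["P01"]["maintenance"][0].samples
        sb = b.recordings["P01"]["maintenance"][0].samples
        assert not np.array_equal(sa, sb)

    def test_patient_draws_within_ranges(self):
        cohort = synth_cohort(10, 3, duration_s=16.0)
        for p in cohort.patients:
            assert 8.5 <= p.alpha_center <= 11.5
            assert 25.5 <= p.beta_fast <= 28.5
            assert 14.0 <= p.beta_slow <= 16.0

    def test_n_patients_validation(self):
        with pytest.raises(ValueError):
            synth_cohort(0, 1)
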