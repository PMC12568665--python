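"""Complexity indices: features, aggregations, zero cases and orderings."""

import numpy as np
import pytest

from mousedisco import (
    AudioFixtureSpec,
    AudioSignal,
    InsufficientDataError,
    UndefinedStatisticError,
    chroma_cqt,
    complexity_indices,
    dynamic_complexity,
    gen_audio,
    harmonic_complexity,
    onset_envelope,
    rank_tracks,
    recurrence_matrix,
    rhythmic_complexity,
    segmented_complexity,
    spectral_complexity,
    spectral_contrast,
    stft_spectrogram,
    tempogram,
)
from mousedisco.complexity import ComplexityIndices

RATE = 22_050.0


def _sig(x, rate=RATE):
    return AudioSignal(np.asarray(x, float), rate)


def _harmonic_stack(dur=3.0, f0=220.0, rate=RATE):
    t = np.arange(int(dur * rate)) / rate
    x = sum((0.5**k) * np.sin(2 * np.pi * (k + 1) * f0 * t) for k in range(6))
    return _sig(x / np.max(np.abs(x)), rate)


class TestSpectralContrast:
    def test_constant_spectrum_frame_has_zero_contrast(self, white_noise):
        spec = stft_spectrogram(white_noise)
        spec.magnitudes[:] = 0.3  # flat spectrum: peak equals valley
        sc = spectral_contrast(spec)
        assert np.allclose(sc, 0.0)

    def test_harmonic_stack_beats_white_noise(self, white_noise):
        noisy = spectral_complexity(stft_spectrogram(white_noise))
        tonal = spectral_complexity(stft_spectrogram(_harmonic_stack()))
        assert tonal > noisy

    def test_pure_tone_beats_white_noise(self, white_noise, tone_1k):
        noisy = spectral_complexity(stft_spectrogram(white_noise))
        tonal = spectral_complexity(stft_spectrogram(tone_1k))
        assert tonal > noisy

    def test_global_gain_cancels(self, tone_1k):
        a = spectral_complexity(stft_spectrogram(tone_1k))
        quiet = _sig(tone_1k.samples * 0.125, tone_1k.rate)
        b = spectral_complexity(stft_spectrogram(quiet))
        assert a == pytest.approx(b, abs=1e-9)

    def test_melodic_fixture_beats_noise_fixture(self, white_noise):
        melody = gen_audio(
            AudioFixtureSpec(
                "chord_sequence", 6.0, RATE, 2,
                {"chords": [[262, 330], [294, 370], [330, 415], [349, 440]],
                 "chord_s": 0.5},
            )
        )
        assert spectral_complexity(stft_spectrogram(melody)) > spectral_complexity(
            stft_spectrogram(white_noise)
        )


class TestOnsetEnvelope:
    def test_steady_tone_has_no_onsets(self, tone_1k):
        # phase interference between FFT lobes leaves ~1e-5 relative flux
        spec = stft_spectrogram(tone_1k)
        env, _, _ = onset_envelope(spec)
        assert np.max(env[2:]) <= 1e-4 * np.sum(spec.magnitudes[:, 0])

    def test_click_train_peaks_every_half_second(self, click_120bpm):
        spec = stft_spectrogram(click_120bpm)
        env, times, _ = onset_envelope(spec)
        thresh = 0.5 * np.max(env)
        peak_times = []
        for i in range(1, env.size - 1):
            if env[i] >= thresh and env[i] >= env[i - 1] and env[i] > env[i + 1]:
                peak_times.append(times[i])
        gaps = np.diff(peak_times)
        assert np.all(np.abs(gaps - 0.5) <= spec.hop_s + 1e-9)

    def test_amplitude_step_gives_single_peak(self):
        t = np.arange(int(2 * RATE)) / RATE
        x = np.sin(2 * np.pi * 500 * t) * np.where(t < 1.0, 0.2, 0.9)
        env, times, _ = onset_envelope(stft_spectrogram(_sig(x)))
        assert abs(times[np.argmax(env)] - 1.0) < 0.05


class TestTempogram:
    def test_periodic_train_near_one_at_its_tempo(self, click_120bpm):
        spec = stft_spectrogram(click_120bpm)
        env, _, fr = onset_envelope(spec)
        tg = tempogram(env, fr)
        near = np.abs(tg.bpm_axis - 120.0) < 6.0
        per_window = tg.autocorr[near][:, tg.valid].max(axis=0)
        assert np.all(per_window >= 0.9)

    def test_poisson_clicks_score_below_periodic(self, click_120bpm):
        rng = np.random.default_rng(5)
        n = int(30 * RATE)
        x = np.zeros(n)
        click = np.hanning(90) * rng.standard_normal(90)
        for t in np.cumsum(rng.exponential(0.5, 120)):
            i = int(t * RATE)
            if i + 90 < n:
                x[i : i + 90] += click
        pois = stft_spectrogram(_sig(x / np.max(np.abs(x))))
        penv, _, pfr = onset_envelope(pois)
        ptg = tempogram(penv, pfr)

        spec = stft_spectrogram(click_120bpm)
        env, _, fr = onset_envelope(spec)
        tg = tempogram(env, fr)
        assert ptg.autocorr[:, ptg.valid].max() < tg.autocorr[:, tg.valid].max()

    def test_silence_flagged_degenerate(self):
        tg = tempogram(np.zeros(2000), 43.0)
        assert tg.degenerate
        with pytest.raises(UndefinedStatisticError):
            rhythmic_complexity(tg)


class TestRhythmicComplexity:
    def test_metronome_is_flat(self, click_120bpm):
        spec = stft_spectrogram(click_120bpm)
        env, _, fr = onset_envelope(spec)
        assert rhythmic_complexity(tempogram(env, fr)) <= 0.02

    def test_alternating_tempi_beat_constant_tempo(self, click_120bpm):
        parts = [
            {"kind": "click_train", "duration_s": 10.0, "params": {"bpm": bpm}}
            for bpm in (90, 140, 90)
        ]
        alt = gen_audio(AudioFixtureSpec("composite", 30.0, RATE, 9, {"parts": parts}))
        aenv, _, afr = onset_envelope(stft_spectrogram(alt))
        senv, _, sfr = onset_envelope(stft_spectrogram(click_120bpm))
        assert rhythmic_complexity(tempogram(aenv, afr)) > rhythmic_complexity(
            tempogram(senv, sfr)
        )

    def test_concatenation_inflates_over_either_part(self):
        def rhy(sig):
            env, _, fr = onset_envelope(stft_spectrogram(sig))
            return rhythmic_complexity(tempogram(env, fr))

        a = gen_audio(AudioFixtureSpec("click_train", 20.0, RATE, 1, {"bpm": 90}))
        b = gen_audio(AudioFixtureSpec("click_train", 20.0, RATE, 2, {"bpm": 150}))
        both = _sig(np.concatenate([a.samples, b.samples]))
        assert rhy(both) > max(rhy(a), rhy(b))


class TestChroma:
    def test_a440_concentrates_in_class_a(self):
        sig = gen_audio(AudioFixtureSpec("tone", 3.0, RATE, 0, {"frequency": 440.0}))
        cm = chroma_cqt(sig)
        frac = (cm.energy[9, cm.valid] >= 0.5).mean()
        assert frac >= 0.9

    def test_c_major_triad_occupies_its_classes(self):
        sig = gen_audio(
            AudioFixtureSpec(
                "chord_sequence", 3.0, RATE, 0,
                {"chords": [[261.63, 329.63, 392.0]], "chord_s": 3.0},
            )
        )
        cm = chroma_cqt(sig)
        share = cm.energy[[0, 4, 7]][:, cm.valid].sum(axis=0).mean()
        assert share >= 0.7

    def test_octave_shift_leaves_chroma_invariant(self):
        lo = gen_audio(AudioFixtureSpec("tone", 3.0, RATE, 0, {"frequency": 440.0}))
        hi = gen_audio(AudioFixtureSpec("tone", 3.0, RATE, 0, {"frequency": 880.0}))
        a = chroma_cqt(lo)
        b = chroma_cqt(hi)
        pa = a.energy[:, a.valid].mean(axis=1)
        pb = b.energy[:, b.valid].mean(axis=1)
        assert np.corrcoef(pa, pb)[0, 1] >= 0.95

    def test_too_short_signal_rejected(self):
        sig = _sig(np.sin(np.arange(2000) * 0.1))
        with pytest.raises(InsufficientDataError):
            chroma_cqt(sig)

    def test_frame_columns_sum_to_one(self):
        sig = _harmonic_stack()
        cm = chroma_cqt(sig)
        sums = cm.energy[:, cm.valid].sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-6)


class TestHarmonicComplexity:
    def test_sustained_chord_is_static(self):
        sig = gen_audio(
            AudioFixtureSpec(
                "chord_sequence", 5.0, RATE, 0,
                {"chords": [[261.63, 329.63, 392.0]], "chord_s": 5.0},
            )
        )
        assert harmonic_complexity(chroma_cqt(sig)) <= 0.02

    def test_cycling_pitch_classes_beat_sustained_chord(self):
        freqs = 440.0 * 2 ** (np.arange(12) / 12)
        cyc = gen_audio(
            AudioFixtureSpec(
                "chord_sequence", 12.0, RATE, 0,
                {"chords": [[f] for f in freqs], "chord_s": 1.0},
            )
        )
        sus = gen_audio(
            AudioFixtureSpec(
                "chord_sequence", 12.0, RATE, 0,
                {"chords": [[261.63, 329.63, 392.0]], "chord_s": 12.0},
            )
        )
        assert harmonic_complexity(chroma_cqt(cyc)) > harmonic_complexity(
            chroma_cqt(sus)
        )

    def test_frame_permutation_invariance(self):
        cm = chroma_cqt(_harmonic_stack(dur=5.0))
        before = harmonic_complexity(cm)
        rng = np.random.default_rng(0)
        perm = rng.permutation(cm.energy.shape[1])
        cm.energy = cm.energy[:, perm]
        cm.valid = cm.valid[perm]
        assert harmonic_complexity(cm) == pytest.approx(before, abs=1e-9)


class TestDynamicComplexity:
    def test_constant_tone_is_zero(self, tone_1k):
        # frame of integer cycle count so RMS is exactly constant
        assert dynamic_complexity(tone_1k, frame_s=0.05) <= 1e-6

    def test_square_modulation_matches_closed_form(self):
        # levels 0.2 / 0.8 with equal dwell; peak normalization maps them to
        # 0.25 / 1.0; frame RMS = level/sqrt(2); two-point std = |a-b|/2.
        # 0.04 s frames are an integer sample count at 22.05 kHz and divide
        # the 0.2 s dwell exactly, so no frame straddles a level switch.
        rate = RATE
        t = np.arange(int(4 * rate)) / rate
        carrier = np.sin(2 * np.pi * 1000 * t)
        level = np.where(np.mod(t, 0.4) < 0.2, 0.2, 0.8)
        sig = _sig(carrier * level)
        expected = (1.0 - 0.25) / np.sqrt(2) / 2
        assert dynamic_complexity(sig, frame_s=0.04) == pytest.approx(
            expected, abs=2e-3
        )

    def test_global_gain_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(int(2 * RATE)) * np.linspace(0.2, 1.0, int(2 * RATE))
        a = dynamic_complexity(_sig(x))
        b = dynamic_complexity(_sig(0.5 * x))
        assert a == pytest.approx(b, abs=1e-9)

    def test_silence_returns_zero_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert dynamic_complexity(_sig(np.zeros(int(RATE)))) == 0.0


class TestRecurrence:
    def test_looped_segment_shows_lag_stripes(self):
        rng = np.random.default_rng(6)
        base = rng.random((40, 12))
        feats = np.tile(base, (4, 1))  # 4 exact repetitions
        rm = recurrence_matrix(feats, k_nn=8)
        lag = 40
        stripe = np.diagonal(rm.similarity, offset=lag)
        assert stripe.mean() >= 0.8

    def test_distinct_segments_stay_decorrelated(self):
        rng = np.random.default_rng(7)
        feats = rng.random((160, 12))
        rm = recurrence_matrix(feats, k_nn=8)
        off = rm.similarity.copy()
        np.fill_diagonal(off, 0.0)
        blocks = []
        for i in range(4):
            for j in range(4):
                if i != j:
                    blocks.append(off[i * 40 : (i + 1) * 40, j * 40 : (j + 1) * 40].mean())
        assert max(blocks) <= 0.2

    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(8)
        feats = rng.random((50, 12))
        rm = recurrence_matrix(feats, k_nn=5)
        assert np.allclose(rm.similarity, rm.similarity.T, atol=1e-9)
        assert np.allclose(np.diag(rm.similarity), 1.0)

    def test_zero_norm_frames_excluded(self):
        feats = np.ones((10, 4))
        feats[3] = 0.0
        with pytest.warns(UserWarning, match="zero-norm"):
            rm = recurrence_matrix(feats, k_nn=2)
        assert 3 not in rm.kept_frames


class TestSegmentsAndRanking:
    def test_segment_count_and_aggregate(self):
        sig = gen_audio(
            AudioFixtureSpec("band_noise", 75.0, RATE, 0, {"band": (100.0, 8000.0)})
        )
        out = segmented_complexity(sig, segment_s=20.0)
        assert len(out) == 3 + 1  # 75 s -> 3 full segments, remainder dropped
        assert out[-1].segment_id == "full"
        assert [o.segment_id for o in out[:-1]] == ["seg000", "seg001", "seg002"]

    def test_stationary_fixture_has_stable_segments(self):
        sig = gen_audio(
            AudioFixtureSpec("band_noise", 80.0, RATE, 1, {"band": (200.0, 6000.0)})
        )
        out = segmented_complexity(sig, segment_s=20.0)
        full = out[-1]
        for seg in out[:-1]:
            assert seg.spectral == pytest.approx(full.spectral, rel=0.10)
            assert seg.dynamic == pytest.approx(full.dynamic, rel=0.25)

    def test_two_song_concatenation_inflates_full_track_rhythm(self):
        parts = [
            {"kind": "click_train", "duration_s": 30.0, "params": {"bpm": 90.0}},
            {"kind": "click_train", "duration_s": 30.0, "params": {"bpm": 150.0}},
        ]
        sig = gen_audio(AudioFixtureSpec("composite", 60.0, RATE, 4, {"parts": parts}))
        out = segmented_complexity(sig, segment_s=30.0)
        full = out[-1]
        assert full.rhythmic >= max(o.rhythmic for o in out[:-1])

    def test_rank_tracks_constructed_ordering(self):
        a = ComplexityIndices(spectral=5.0, rhythmic=0.1, harmonic=0.2, dynamic=0.01)
        b = ComplexityIndices(spectral=3.0, rhythmic=0.2, harmonic=0.1, dynamic=0.09)
        ranks = rank_tracks({"a": a, "b": b})
        assert ranks.loc["a", "spectral"] == 1
        assert ranks.loc["a", "dynamic"] == 2

    def test_identical_tracks_tie_by_name(self):
        ci = ComplexityIndices(spectral=1.0, rhythmic=1.0, harmonic=1.0, dynamic=1.0)
        ranks = rank_tracks({"zeta": ci, "alpha": ci})
        assert ranks.loc["alpha", "spectral"] == 1
        assert ranks.loc["zeta", "spectral"] == 2

    def test_single_track_ranks_first_everywhere(self):
        ci = ComplexityIndices(spectral=1.0, rhythmic=1.0, harmonic=1.0, dynamic=1.0)
        ranks = rank_tracks({"only": ci})
        assert (ranks.loc["only"] == 1).all()
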