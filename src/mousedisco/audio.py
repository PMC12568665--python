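"""Audio I/O, spectral decomposition, species audibility, octave transposition.

The analysis questions this module answers are simple but species-critical:
given a music stimulus, where does its spectral energy sit relative to an
animal's hearing range?  Mice hear roughly 2–100 kHz while humans hear
20 Hz – 20 kHz, so a piece that sounds full-bodied to an experimenter may be
almost inaudible to the animal.  The module provides

* :func:`load_wav` / :func:`save_wav` — PCM WAV I/O (8/16/24/32-bit int and
  float32, mono or stereo) onto a normalized mono float representation;
* :func:`stft_spectrogram` — short-time Fourier magnitude spectrogram;
* :func:`average_frequency` — the amplitude-weighted mean frequency of a
  spectrogram (the "average frequency" line drawn over stimulus spectrograms);
* :func:`audible_energy_fraction` — the fraction of spectral energy that
  falls inside a species' hearing range;
* :func:`pitch_shift_octaves` — octave ("vertical") transposition that
  multiplies every frequency by ``2**k`` while preserving playback duration,
  via a phase-vocoder time stretch followed by decimation.

Digital amplitudes are relative throughout; a playback level in dB SPL is
carried as metadata only and never enters any computation.
"""

from __future__ import annotations

import logging
import wave
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.io import wavfile
from scipy.signal import get_window, resample_poly

from ._errors import (
    AudioFormatError,
    EmptyInputError,
    InsufficientDataError,
    ParameterError,
    UndefinedStatisticError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AudioSignal",
    "HearingRange",
    "Spectrogram",
    "AudibilityProfile",
    "MOUSE_RANGE",
    "HUMAN_RANGE",
    "load_wav",
    "save_wav",
    "stft_spectrogram",
    "average_frequency",
    "audible_energy_fraction",
    "audibility_profile",
    "pitch_shift_octaves",
]


@dataclass
class AudioSignal:
    """A sampled mono waveform.

    Parameters
    ----------
    samples
        Amplitude values, dimensionless, nominal range [-1, 1].
    rate
        Sampling frequency in Hz.
    meta
        Free-form provenance (source path, original bit depth, nominal
        playback level in dB SPL, ...). Never used in computation.
    """

    samples: np.ndarray
    rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ParameterError("AudioSignal samples must be one-dimensional")
        if self.rate <= 0:
            raise ParameterError("sampling rate must be positive")
        if self.samples.size == 0:
            raise EmptyInputError("zero-length audio")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate

    def normalized(self) -> "AudioSignal":
        """Peak-normalize to max |sample| = 1 (silence is returned unchanged)."""
        peak = np.max(np.abs(self.samples))
        if peak == 0:
            return AudioSignal(self.samples.copy(), self.rate, dict(self.meta))
        return AudioSignal(self.samples / peak, self.rate, dict(self.meta))


@dataclass(frozen=True)
class HearingRange:
    """Audible band of a species: ``low_hz <= f <= high_hz``."""

    low_hz: float
    high_hz: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.low_hz < self.high_hz):
            raise ParameterError("require 0 <= low_hz < high_hz")


#: Mouse hearing range, approximately 2 kHz – 100 kHz.
MOUSE_RANGE = HearingRange(2_000.0, 100_000.0, "mouse")
#: Human hearing range, approximately 20 Hz – 20 kHz.
HUMAN_RANGE = HearingRange(20.0, 20_000.0, "human")


@dataclass
class Spectrogram:
    """Short-time Fourier magnitude spectrogram.

    ``magnitudes`` is indexed ``[frequency bin, time frame]`` and is
    non-negative; ``freqs_hz`` are the bin-center frequencies (strictly
    increasing, bounded by the Nyquist frequency).
    """

    magnitudes: np.ndarray
    freqs_hz: np.ndarray
    times_s: np.ndarray
    window_s: float
    hop_s: float
    rate: float

    @property
    def n_frames(self) -> int:
        return self.magnitudes.shape[1]

    def energy(self) -> float:
        """Total summed squared magnitude."""
        return float(np.sum(self.magnitudes**2))


@dataclass(frozen=True)
class AudibilityProfile:
    """Summary of a stimulus relative to one species' hearing range."""

    average_frequency_hz: float
    audible_fraction: float
    range_used: HearingRange

    def to_dict(self) -> dict:
        return {
            "average_frequency_hz": self.average_frequency_hz,
            "audible_fraction": self.audible_fraction,
            "range_label": self.range_used.label,
            "range_low_hz": self.range_used.low_hz,
            "range_high_hz": self.range_used.high_hz,
        }


# ---------------------------------------------------------------------------
# WAV I/O
# ---------------------------------------------------------------------------

_INT_SCALE = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31}


def load_wav(path, target_rate: float | None = None) -> AudioSignal:
    """Read a PCM WAV file into a normalized mono :class:`AudioSignal`.

    Stereo is downmixed by the channel mean.  Integer samples are rescaled to
    [-1, 1] by the full-scale value of their bit depth (scipy returns 24-bit
    PCM as int32 with the low byte zero, so the int32 scale applies).  If
    ``target_rate`` is given and differs from the file rate, the signal is
    resampled with a polyphase filter.
    """
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError as exc:
        raise AudioFormatError(f"WAV file not found: {path}") from exc
    except EOFError as exc:  # truncated header
        raise AudioFormatError(f"truncated WAV file: {path}") from exc
    except ValueError as exc:
        raise AudioFormatError(f"unreadable WAV file: {path}: {exc}") from exc
    if data.size == 0:
        raise EmptyInputError(f"zero-length audio: {path}")

    dtype = data.dtype
    if dtype == np.uint8:  # 8-bit WAV is unsigned
        x = (data.astype(np.float64) - 128.0) / 128.0
        bit_depth = 8
    elif dtype in _INT_SCALE:
        x = data.astype(np.float64) / _INT_SCALE[dtype]
        bit_depth = 8 * dtype.itemsize
    elif dtype in (np.float32, np.float64):
        x = data.astype(np.float64)
        bit_depth = 8 * dtype.itemsize
    else:
        raise AudioFormatError(f"unsupported WAV sample format {dtype} in {path}")

    if x.ndim == 2:  # downmix by channel mean
        x = x.mean(axis=1)

    meta = {"source": str(path), "original_rate": float(rate), "bit_depth": bit_depth}
    logger.info(
        "loaded %s: %d samples @ %g Hz, %d-bit", path, x.size, rate, bit_depth
    )

    out_rate = float(rate)
    if target_rate is not None and float(target_rate) != out_rate:
        frac = Fraction(float(target_rate) / out_rate).limit_denominator(1000)
        x = resample_poly(x, frac.numerator, frac.denominator)
        out_rate = out_rate * frac.numerator / frac.denominator
        meta["resampled_to"] = out_rate
    return AudioSignal(x, out_rate, meta)


def save_wav(path, sig: AudioSignal, bit_depth: int = 16) -> None:
    """Write a mono PCM WAV (16- or 24-bit) — the fixture/export writer."""
    x = np.clip(sig.samples, -1.0, 1.0)
    rate = int(round(sig.rate))
    if bit_depth == 16:
        wavfile.write(path, rate, (x * 32767.0).round().astype(np.int16))
    elif bit_depth == 24:
        ints = (x * (2**23 - 1)).round().astype(np.int32)
        raw = ints.astype("<i4").tobytes()
        # keep the low three bytes of each little-endian int32
        frames = b"".join(raw[i : i + 3] for i in range(0, len(raw), 4))
        with wave.open(str(path), "wb") as fh:
            fh.setnchannels(1)
            fh.setsampwidth(3)
            fh.setframerate(rate)
            fh.writeframes(frames)
    else:
        raise ParameterError("bit_depth must be 16 or 24")


# ---------------------------------------------------------------------------
# Spectrogram
# ---------------------------------------------------------------------------


def stft_spectrogram(
    sig: AudioSignal,
    window_s: float | None = None,
    hop_s: float | None = None,
    window: str = "hann",
) -> Spectrogram:
    """Short-time Fourier magnitude spectrogram.

    Defaults to a 2048-sample window with a 512-sample hop (about 46 ms /
    12 ms at 44.1 kHz), standard music-analysis settings.  Frames are taken
    without zero padding, so the frame count is
    ``floor((n_samples - window) / hop) + 1``.
    """
    if window_s is None:
        window_s = 2048 / sig.rate
    if hop_s is None:
        hop_s = 512 / sig.rate
    if not (0 < hop_s <= window_s):
        raise ParameterError("require 0 < hop_s <= window_s")
    win_n = int(round(window_s * sig.rate))
    hop_n = max(1, int(round(hop_s * sig.rate)))
    if win_n > sig.samples.size:
        raise InsufficientDataError(
            f"window ({win_n} samples) longer than signal ({sig.samples.size})"
        )
    if window == "rectangular":
        w = np.ones(win_n)
    else:
        w = get_window(window, win_n, fftbins=True)

    n_frames = (sig.samples.size - win_n) // hop_n + 1
    idx = hop_n * np.arange(n_frames)[:, None] + np.arange(win_n)[None, :]
    frames = sig.samples[idx] * w
    mags = np.abs(np.fft.rfft(frames, axis=1)).T  # [bin, frame]

    freqs = np.fft.rfftfreq(win_n, d=1.0 / sig.rate)
    times = (hop_n * np.arange(n_frames) + win_n / 2) / sig.rate
    return Spectrogram(mags, freqs, times, win_n / sig.rate, hop_n / sig.rate, sig.rate)


def average_frequency(spec: Spectrogram, weighting: str = "amplitude") -> float:
    """Weighted mean frequency of a spectrogram, in Hz.

    ``weighting="amplitude"`` (default) weights each time–frequency cell by
    its magnitude; ``"power"`` weights by squared magnitude.  The amplitude
    convention matches drawing the mean over an amplitude spectrogram; the
    choice is logged so it can be audited.
    """
    if weighting == "amplitude":
        w = spec.magnitudes
    elif weighting == "power":
        w = spec.magnitudes**2
    else:
        raise ParameterError("weighting must be 'amplitude' or 'power'")
    total = np.sum(w)
    if total == 0:
        raise UndefinedStatisticError("average frequency of an all-zero spectrogram")
    logger.debug("average_frequency using %s weighting", weighting)
    return float(np.sum(spec.freqs_hz @ w) / total)


def audible_energy_fraction(spec: Spectrogram, hearing: HearingRange) -> float:
    """Fraction of spectral energy audible within a species' hearing range.

    Energy is the summed squared magnitude; a bin belongs to the range iff
    its center frequency satisfies ``low_hz <= f <= high_hz``.
    """
    power = spec.magnitudes**2
    total = np.sum(power)
    if total == 0:
        raise UndefinedStatisticError("audible fraction of an all-zero spectrogram")
    mask = (spec.freqs_hz >= hearing.low_hz) & (spec.freqs_hz <= hearing.high_hz)
    return float(np.sum(power[mask, :]) / total)


def audibility_profile(
    sig: AudioSignal,
    hearing: HearingRange,
    window_s: float | None = None,
    hop_s: float | None = None,
) -> AudibilityProfile:
    """Convenience wrapper: spectrogram + mean frequency + audible fraction."""
    spec = stft_spectrogram(sig, window_s=window_s, hop_s=hop_s)
    return AudibilityProfile(
        average_frequency_hz=average_frequency(spec),
        audible_fraction=audible_energy_fraction(spec, hearing),
        range_used=hearing,
    )


# ---------------------------------------------------------------------------
# Octave pitch transposition
# ---------------------------------------------------------------------------


def _phase_vocoder(x: np.ndarray, stretch: float, win_n: int = 2048, hop_n: int = 512):
    """Time-stretch ``x`` by ``stretch`` (>1 = longer) at constant pitch."""
    w = get_window("hann", win_n, fftbins=True)
    n_frames = max(1, (x.size - win_n) // hop_n + 1)
    idx = hop_n * np.arange(n_frames)[:, None] + np.arange(win_n)[None, :]
    D = np.fft.rfft(x[idx] * w, axis=1).T  # [bin, frame]

    steps = np.arange(0, n_frames - 1, 1.0 / stretch)
    omega = 2 * np.pi * hop_n * np.arange(D.shape[0]) / win_n  # expected advance
    out = np.empty((D.shape[0], steps.size), dtype=complex)
    phase = np.angle(D[:, 0])
    for i, s in enumerate(steps):
        j = int(np.floor(s))
        frac = s - j
        mag = (1 - frac) * np.abs(D[:, j]) + frac * np.abs(D[:, j + 1])
        out[:, i] = mag * np.exp(1j * phase)
        dphi = np.angle(D[:, j + 1]) - np.angle(D[:, j]) - omega
        dphi -= 2 * np.pi * np.round(dphi / (2 * np.pi))
        phase = phase + omega + dphi

    # overlap-add inverse STFT with squared-window normalization
    y_len = win_n + hop_n * (out.shape[1] - 1)
    y = np.zeros(y_len)
    norm = np.zeros(y_len)
    frames_t = np.fft.irfft(out, n=win_n, axis=0).T * w
    for i in range(out.shape[1]):
        a = i * hop_n
        y[a : a + win_n] += frames_t[i]
        norm[a : a + win_n] += w**2
    good = norm > 1e-8
    y[good] /= norm[good]
    return y


def pitch_shift_octaves(sig: AudioSignal, octaves: int) -> AudioSignal:
    """Transpose every spectral component up by ``octaves`` octaves.

    A component at frequency ``f`` moves to ``2**octaves * f`` while the
    playback duration is preserved (to within one analysis hop): the signal
    is first time-stretched by ``2**octaves`` with a phase vocoder, then
    decimated by the same factor.  Content above ``rate / 2**(octaves+1)``
    would alias and triggers a fold-over warning before being low-passed away
    by the decimation filter.  Downward shifts are out of scope.
    """
    if int(octaves) != octaves or octaves < 0:
        raise ParameterError("octaves must be a non-negative integer")
    octaves = int(octaves)
    if octaves == 0:
        return AudioSignal(sig.samples.copy(), sig.rate, dict(sig.meta))

    factor = 2**octaves
    # fold-over check: significant content above rate / (2 * factor)?
    spectrum = np.abs(np.fft.rfft(sig.samples))
    freqs = np.fft.rfftfreq(sig.samples.size, d=1.0 / sig.rate)
    significant = spectrum > 1e-3 * spectrum.max()
    if significant.any() and freqs[significant].max() * factor > sig.rate / 2:
        warnings.warn(
            "significant spectral content above rate/2^(octaves+1); "
            "fold-over components are removed by the anti-alias filter",
            stacklevel=2,
        )

    win_n = min(2048, 2 ** int(np.floor(np.log2(max(8, sig.samples.size // 4)))))
    stretched = _phase_vocoder(sig.samples, float(factor), win_n=win_n, hop_n=win_n // 4)
    shifted = resample_poly(stretched, 1, factor)
    # pad/trim to the original length (duration preserved within one hop)
    if shifted.size < sig.samples.size:
        shifted = np.pad(shifted, (0, sig.samples.size - shifted.size))
    else:
        shifted = shifted[: sig.samples.size]
    meta = dict(sig.meta)
    meta["pitch_shift_octaves"] = octaves
    return AudioSignal(shifted, sig.rate, meta)
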