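"""Four-dimensional music-complexity indices and structure features.

A music stimulus is scored along four orthogonal axes, each a scalar:

spectral
    Timbral/melodic richness, measured as mean *spectral contrast*: the
    per-frame, per-octave-band gap between log peak and log valley
    magnitudes.  Peaky harmonic spectra score high, flat noise low.
rhythmic
    Tempo/beat variability, measured as the temporal fluctuation of the
    *tempogram* (windowed autocorrelation of the onset envelope).  A
    metronomic track has a time-invariant rhythm profile and scores ~0.
harmonic
    Tonal diversity, measured as the temporal fluctuation of unit-sum
    *chroma* (12 pitch-class energies from a constant-Q transform).  A
    single sustained chord scores ~0; changing harmony scores high.
dynamic
    Loudness variation, the standard deviation over frames of RMS energy of
    the peak-normalized signal.

The aggregation formulas are deliberately explicit and parameterized: the
feature families are standard, and each index is a documented reduction over
them, so alternates can be swapped without touching the features.

Also provided: the recurrence (self-similarity) matrix, per-segment scoring,
and per-dimension track ranking.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import (
    InsufficientDataError,
    ParameterError,
    UndefinedStatisticError,
)
from .audio import AudioSignal, Spectrogram, stft_spectrogram

logger = logging.getLogger(__name__)

__all__ = [
    "ChromaMatrix",
    "Tempogram",
    "RecurrenceMatrix",
    "ComplexityIndices",
    "spectral_contrast",
    "spectral_complexity",
    "onset_envelope",
    "tempogram",
    "rhythmic_complexity",
    "chroma_cqt",
    "harmonic_complexity",
    "dynamic_complexity",
    "recurrence_matrix",
    "complexity_indices",
    "segmented_complexity",
    "rank_tracks",
]

PITCH_CLASSES = ["C", "C#", "D", "D#", "E", "F", "F#", "G", "G#", "A", "A#", "B"]

#: Silence threshold on frame RMS; silent frames are excluded from chroma.
SILENT_FRAME_RMS = 1e-5


@dataclass
class ChromaMatrix:
    """Pitch-class energy over time, per-frame normalized to unit sum.

    ``energy`` is ``[12, n_frames]`` (rows ordered C..B).  Frames whose
    time-domain RMS falls below the silence threshold are flagged in
    ``valid`` and hold all-zero columns; they are excluded from indices.
    """

    energy: np.ndarray
    times_s: np.ndarray
    tuning_ref_hz: float
    valid: np.ndarray  # boolean mask over frames

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class Tempogram:
    """Rhythm-periodicity profile over time.

    ``autocorr`` is ``[tempo lag, time window]``; each window's
    autocorrelation is normalized by its lag-zero value, so a perfectly
    regular beat yields a value near 1 at its tempo lag.  ``bpm_axis`` is
    positive and decreasing in lag index.  All-silent windows are flagged.
    """

    autocorr: np.ndarray
    bpm_axis: np.ndarray
    times_s: np.ndarray
    valid: np.ndarray

    @property
    def degenerate(self) -> bool:
        return not bool(self.valid.any())


@dataclass
class RecurrenceMatrix:
    """Frame-by-frame similarity, sparsified by mutual k-nearest neighbors."""

    similarity: np.ndarray
    feature_used: str
    kept_frames: np.ndarray  # indices of frames with nonzero feature norm


@dataclass
class ComplexityIndices:
    """The four scalar indices for one audio segment."""

    spectral: float
    rhythmic: float
    harmonic: float
    dynamic: float
    segment_id: str = "full"
    start_s: float = 0.0
    end_s: float = 0.0
    flags: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "segment_id": self.segment_id,
            "start_s": self.start_s,
            "end_s": self.end_s,
            "spectral": self.spectral,
            "rhythmic": self.rhythmic,
            "harmonic": self.harmonic,
            "dynamic": self.dynamic,
        }


DIMENSIONS = ("spectral", "rhythmic", "harmonic", "dynamic")


# ---------------------------------------------------------------------------
# Spectral contrast
# ---------------------------------------------------------------------------


def _octave_band_edges(n_bands: int, fmin: float, nyquist: float) -> list[tuple[float, float]]:
    edges = []
    lo = fmin
    for b in range(n_bands):
        hi = min(lo * 2, nyquist) if b < n_bands - 1 else nyquist
        edges.append((lo, hi))
        lo = hi
    return edges


def spectral_contrast(
    spec: Spectrogram,
    n_bands: int = 6,
    quantile: float = 0.02,
    fmin: float = 200.0,
    floor: float = 1e-10,
) -> np.ndarray:
    """Per-frame, per-octave-band peak/valley contrast, shape ``[band, frame]``.

    For each frame and band, contrast is
    ``log(mean of top-quantile magnitudes) - log(mean of bottom-quantile
    magnitudes)`` (natural log, floored at ``floor`` to avoid log 0).  Bands
    are octaves starting at ``fmin``, the last band extending to Nyquist.
    Because it is a log-ratio, the contrast is invariant to global gain.
    """
    if n_bands < 2:
        raise ParameterError("n_bands must be >= 2")
    if not (0 < quantile <= 0.5):
        raise ParameterError("quantile must be in (0, 0.5]")
    nyquist = spec.rate / 2
    if fmin * 2 ** (n_bands - 1) >= nyquist:
        raise ParameterError(
            f"spectrogram does not cover {n_bands} octave bands above {fmin} Hz"
        )
    bands = _octave_band_edges(n_bands, fmin, nyquist)
    # normalize by the global peak so the floor is relative and a global
    # gain cancels exactly, not just approximately
    scale = spec.magnitudes.max()
    mags = spec.magnitudes / scale if scale > 0 else spec.magnitudes
    out = np.empty((n_bands, spec.n_frames))
    for b, (lo, hi) in enumerate(bands):
        mask = (spec.freqs_hz >= lo) & (spec.freqs_hz < hi)
        nb = int(mask.sum())
        if nb < 2:
            raise ParameterError(
                f"band {lo:.0f}-{hi:.0f} Hz has {nb} bins; decrease n_bands "
                "or use a longer analysis window"
            )
        k = max(1, int(round(quantile * nb)))
        sorted_mags = np.sort(mags[mask, :], axis=0)
        valley = sorted_mags[:k, :].mean(axis=0)
        peak = sorted_mags[-k:, :].mean(axis=0)
        out[b] = np.log(peak + floor) - np.log(valley + floor)
    return out


def spectral_complexity(
    spec: Spectrogram, n_bands: int = 6, quantile: float = 0.02, fmin: float = 200.0
) -> float:
    """Mean spectral contrast over all frames and bands (deterministic)."""
    return float(spectral_contrast(spec, n_bands=n_bands, quantile=quantile, fmin=fmin).mean())


# ---------------------------------------------------------------------------
# Onset envelope and tempogram
# ---------------------------------------------------------------------------


def onset_envelope(spec: Spectrogram) -> tuple[np.ndarray, np.ndarray, float]:
    """Onset-strength time series: half-wave-rectified positive spectral flux.

    Returns ``(envelope, times_s, frame_rate_hz)``.  The first frame has no
    predecessor and gets strength 0.
    """
    if spec.n_frames < 2:
        raise InsufficientDataError("onset envelope needs >= 2 frames")
    flux = np.diff(spec.magnitudes, axis=1)
    env = np.concatenate([[0.0], np.clip(flux, 0, None).sum(axis=0)])
    return env, spec.times_s, 1.0 / spec.hop_s


def tempogram(
    onsets: np.ndarray,
    frame_rate: float,
    window_s: float = 8.0,
    bpm_range: tuple[float, float] = (30.0, 300.0),
    smooth_frames: int = 9,
) -> Tempogram:
    """Windowed autocorrelation of the onset envelope, mapped to BPM.

    The envelope is lightly smoothed (moving Hann of ``smooth_frames``
    frames) so that beat periods that are non-integer in frames still
    concentrate on the nearest lag.  Each window's autocorrelation is
    normalized by its lag-zero value; lags map to tempo via
    ``BPM = 60 / lag_s`` and are restricted to ``bpm_range``.  Windows with
    zero envelope energy are flagged invalid (their column is zero).
    """
    lo_bpm, hi_bpm = bpm_range
    if not (0 < lo_bpm < hi_bpm):
        raise ParameterError("require 0 < min_bpm < max_bpm")
    env = np.asarray(onsets, dtype=float)
    win_n = int(round(window_s * frame_rate))
    if win_n > env.size:
        raise InsufficientDataError("tempogram window longer than onset series")
    if smooth_frames > 1:
        w = np.hanning(smooth_frames + 2)[1:-1]
        env = np.convolve(env, w / w.sum(), mode="same")

    hop_w = max(1, win_n // 2)
    n_windows = (env.size - win_n) // hop_w + 1
    max_lag = min(win_n - 1, int(np.ceil(60.0 * frame_rate / lo_bpm)))
    lags = np.arange(1, max_lag + 1)
    bpm = 60.0 * frame_rate / lags
    keep = (bpm >= lo_bpm) & (bpm <= hi_bpm)
    lags, bpm = lags[keep], bpm[keep]

    ac = np.zeros((lags.size, n_windows))
    valid = np.zeros(n_windows, dtype=bool)
    times = np.empty(n_windows)
    for i in range(n_windows):
        seg = env[i * hop_w : i * hop_w + win_n]
        times[i] = (i * hop_w + win_n / 2) / frame_rate
        r0 = float(np.dot(seg, seg))
        if r0 <= 0:
            continue
        valid[i] = True
        full = np.correlate(seg, seg, mode="full")[win_n - 1 :]
        ac[:, i] = full[lags] / r0
    if not valid.any():
        logger.warning("tempogram: all windows silent; flagged degenerate")
    return Tempogram(ac, bpm, times, valid)


def rhythmic_complexity(tg: Tempogram) -> float:
    """Tempogram fluctuation: mean over tempo lags of the temporal std.

    High when the rhythm-periodicity profile changes over time (tempo drift,
    alternating tempi, heterogeneous material); ~0 for a metronomic track.
    Note that concatenating two internally steady tracks with different
    tempi *inflates* this index relative to either track alone — scoring in
    shorter segments exposes that.
    """
    if tg.degenerate:
        raise UndefinedStatisticError("rhythmic complexity of a silent tempogram")
    cols = tg.autocorr[:, tg.valid]
    if cols.shape[1] < 2:
        raise InsufficientDataError("rhythmic complexity needs >= 2 windows")
    return float(cols.std(axis=1, ddof=0).mean())


# ---------------------------------------------------------------------------
# Constant-Q chroma
# ---------------------------------------------------------------------------


def _cqt_kernels(
    rate: float,
    fmin: float,
    n_bins: int,
    bins_per_octave: int,
    filter_scale: float = 2.0,
):
    """Sparse spectral-domain constant-Q kernels (classic FFT-kernel method).

    ``filter_scale > 1`` lengthens every kernel by that factor, trading time
    resolution for sharper semitone separation (neighboring pitch classes of
    a pure tone then receive almost no leakage).
    """
    q = filter_scale / (2 ** (1.0 / bins_per_octave) - 1)
    freqs = fmin * 2 ** (np.arange(n_bins) / bins_per_octave)
    if freqs[-1] >= rate / 2:
        raise ParameterError("highest constant-Q bin exceeds Nyquist")
    lengths = np.ceil(q * rate / freqs).astype(int)
    fft_n = int(2 ** np.ceil(np.log2(lengths[0])))
    kernels = np.zeros((n_bins, fft_n), dtype=complex)
    for k in range(n_bins):
        n = lengths[k]
        t = np.arange(n)
        win = np.hanning(n)
        atom = win * np.exp(2j * np.pi * freqs[k] * t / rate) / n
        start = (fft_n - n) // 2
        buf = np.zeros(fft_n, dtype=complex)
        buf[start : start + n] = atom
        kernels[k] = np.conj(np.fft.fft(buf)) / fft_n
    kernels[np.abs(kernels) < 1e-6 * np.abs(kernels).max()] = 0
    return kernels, fft_n, freqs


def chroma_cqt(
    sig: AudioSignal,
    tuning_ref_hz: float = 440.0,
    n_octaves: int = 6,
    hop_s: float | None = None,
) -> ChromaMatrix:
    """12-class chroma from a constant-Q transform (12 bins/octave).

    The lowest bin is the C two octaves below the tuning reference's octave
    (C2 ≈ 65.4 Hz for A4 = 440 Hz); ``n_octaves`` octaves are analyzed and
    the squared constant-Q magnitudes (energies) folded onto pitch classes
    C..B.  Valid (non-silent) frames are normalized to unit sum.
    """
    fmin = tuning_ref_hz * 2 ** (-9 / 12) / 4  # C2 relative to A4
    n_bins = 12 * n_octaves
    kernels, fft_n, _ = _cqt_kernels(sig.rate, fmin, n_bins, 12)
    if sig.samples.size < fft_n:
        raise InsufficientDataError(
            f"signal too short for constant-Q analysis (needs {fft_n} samples)"
        )
    hop_n = fft_n // 4 if hop_s is None else max(1, int(round(hop_s * sig.rate)))
    n_frames = (sig.samples.size - fft_n) // hop_n + 1
    idx = hop_n * np.arange(n_frames)[:, None] + np.arange(fft_n)[None, :]
    frames = sig.samples[idx]
    rms = np.sqrt(np.mean(frames**2, axis=1))
    spectra = np.fft.fft(frames, axis=1)
    cqt_pow = np.abs(spectra @ kernels.T).T ** 2  # [cq bin, frame], energy

    chroma = np.zeros((12, n_frames))
    for k in range(n_bins):
        chroma[k % 12] += cqt_pow[k]
    valid = rms >= SILENT_FRAME_RMS
    sums = chroma.sum(axis=0)
    valid &= sums > 0
    chroma[:, valid] /= sums[valid]
    chroma[:, ~valid] = 0.0
    times = (hop_n * np.arange(n_frames) + fft_n / 2) / sig.rate
    return ChromaMatrix(chroma, times, tuning_ref_hz, valid)


def harmonic_complexity(cm: ChromaMatrix) -> float:
    """Chroma diversity: mean over the 12 classes of the temporal std.

    Zero iff the normalized chroma vector is constant over (valid) time;
    larger when pitch-class usage shifts between frames.
    """
    if cm.n_valid < 2:
        raise UndefinedStatisticError("harmonic complexity needs >= 2 non-silent frames")
    cols = cm.energy[:, cm.valid]
    return float(cols.std(axis=1, ddof=0).mean())


# ---------------------------------------------------------------------------
# Dynamic complexity
# ---------------------------------------------------------------------------


def frame_rms(x: np.ndarray, frame_n: int) -> np.ndarray:
    """RMS of consecutive non-overlapping frames (remainder dropped)."""
    n = (x.size // frame_n) * frame_n
    if n == 0:
        raise InsufficientDataError("signal shorter than one RMS frame")
    frames = x[:n].reshape(-1, frame_n)
    return np.sqrt(np.mean(frames**2, axis=1))


def dynamic_complexity(sig: AudioSignal, frame_s: float = 0.05) -> float:
    """Std over frames of RMS amplitude of the peak-normalized signal.

    Zero for any constant-envelope signal; invariant to global gain because
    of the peak normalization.  A fully silent signal returns 0 with a
    warning rather than failing.
    """
    peak = np.max(np.abs(sig.samples))
    if peak == 0:
        warnings.warn("dynamic complexity of silence is degenerate; returning 0",
                      stacklevel=2)
        return 0.0
    frame_n = max(1, int(round(frame_s * sig.rate)))
    rms = frame_rms(sig.samples / peak, frame_n)
    if rms.size < 2:
        raise InsufficientDataError("dynamic complexity needs >= 2 frames")
    return float(rms.std(ddof=0))


# ---------------------------------------------------------------------------
# Recurrence matrix
# ---------------------------------------------------------------------------


def recurrence_matrix(
    features: np.ndarray, k_nn: int | None = None, feature_used: str = "chroma"
) -> RecurrenceMatrix:
    """Cosine self-similarity of frame features, mutual-kNN sparsified.

    ``features`` is ``[n_frames, n_features]``.  Similarity between frames i
    and j is kept only when each is among the other's ``k_nn`` nearest
    neighbors (mutual filtering); the result is symmetrized by the
    elementwise maximum and given a unit diagonal.  Frames with zero feature
    norm are excluded (with a warning); ``kept_frames`` records the survivors.
    """
    feats = np.asarray(features, dtype=float)
    if feats.ndim != 2 or feats.shape[0] < 2:
        raise InsufficientDataError("recurrence needs >= 2 feature frames")
    norms = np.linalg.norm(feats, axis=1)
    kept = np.nonzero(norms > 0)[0]
    if kept.size < feats.shape[0]:
        warnings.warn(
            f"excluding {feats.shape[0] - kept.size} zero-norm frames from "
            "the recurrence matrix", stacklevel=2,
        )
    if kept.size < 2:
        raise InsufficientDataError("fewer than 2 nonzero frames for recurrence")
    unit = feats[kept] / norms[kept, None]
    sim = np.clip(unit @ unit.T, -1.0, 1.0)
    n = sim.shape[0]
    if k_nn is None:
        k_nn = max(1, int(round(0.05 * n)))
    if not (1 <= k_nn < n):
        raise ParameterError("require 1 <= k_nn < number of frames")

    off = sim.copy()
    np.fill_diagonal(off, -np.inf)
    nbr_rank = np.argsort(-off, axis=1)[:, :k_nn]
    is_nbr = np.zeros_like(sim, dtype=bool)
    rows = np.repeat(np.arange(n), k_nn)
    is_nbr[rows, nbr_rank.ravel()] = True
    mutual = is_nbr & is_nbr.T
    out = np.where(mutual, sim, 0.0)
    out = np.maximum(out, out.T)
    out = np.clip(out, 0.0, 1.0)
    np.fill_diagonal(out, 1.0)
    return RecurrenceMatrix(out, feature_used, kept)


# ---------------------------------------------------------------------------
# Aggregate and segmented scoring
# ---------------------------------------------------------------------------


def complexity_indices(
    sig: AudioSignal,
    segment_id: str = "full",
    start_s: float = 0.0,
    tempo_window_s: float = 8.0,
) -> ComplexityIndices:
    """All four indices for one signal (or one segment of it)."""
    norm = sig.normalized()
    spec = stft_spectrogram(norm)
    flags: dict = {}

    spectral = spectral_complexity(spec)

    env, _, fr = onset_envelope(spec)
    try:
        tg = tempogram(env, fr, window_s=tempo_window_s)
        rhythmic = rhythmic_complexity(tg)
    except (UndefinedStatisticError, InsufficientDataError) as exc:
        flags["rhythmic"] = str(exc)
        rhythmic = float("nan")

    try:
        cm = chroma_cqt(norm)
        harmonic = harmonic_complexity(cm)
    except (UndefinedStatisticError, InsufficientDataError) as exc:
        flags["harmonic"] = str(exc)
        harmonic = float("nan")

    dynamic = dynamic_complexity(norm)
    return ComplexityIndices(
        spectral=spectral,
        rhythmic=rhythmic,
        harmonic=harmonic,
        dynamic=dynamic,
        segment_id=segment_id,
        start_s=start_s,
        end_s=start_s + norm.duration_s,
        flags=flags,
    )


def segmented_complexity(
    sig: AudioSignal, segment_s: float = 120.0
) -> list[ComplexityIndices]:
    """Indices per non-overlapping ``segment_s`` window plus the full track.

    The trailing remainder shorter than ``segment_s`` is dropped (padding
    would bias the RMS and contrast statistics); the drop is logged.  The
    full-track aggregate comes last with ``segment_id='full'``.
    """
    if sig.duration_s < segment_s:
        raise InsufficientDataError("signal shorter than one segment")
    seg_n = int(round(segment_s * sig.rate))
    n_seg = sig.samples.size // seg_n
    dropped = sig.samples.size - n_seg * seg_n
    if dropped:
        logger.info("segmented_complexity: dropping %.2f s trailing remainder",
                    dropped / sig.rate)
    out = []
    for i in range(n_seg):
        seg = AudioSignal(sig.samples[i * seg_n : (i + 1) * seg_n], sig.rate)
        out.append(
            complexity_indices(seg, segment_id=f"seg{i:03d}", start_s=i * segment_s)
        )
    out.append(complexity_indices(sig, segment_id="full"))
    return out


def rank_tracks(indices: dict[str, ComplexityIndices]) -> pd.DataFrame:
    """Per-dimension ranking of tracks (rank 1 = highest index value).

    Ties are broken by track name, so the ranking is stable and
    deterministic.  Returns a DataFrame indexed by track with one integer
    rank column per dimension.
    """
    if len(indices) < 1:
        raise ParameterError("rank_tracks needs at least one track")
    names = sorted(indices)
    ranks = pd.DataFrame(index=pd.Index(names, name="track"), dtype=int)
    for dim in DIMENSIONS:
        order = sorted(names, key=lambda t: (-getattr(indices[t], dim), t))
        ranks[dim] = [order.index(t) + 1 for t in names]
    return ranks
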