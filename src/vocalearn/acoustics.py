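"""Acoustic parameter extraction for vocalization stimuli.

Five parameters describe each call: duration, spectral center of gravity
(CoG), dominant frequency, percentage of voiced frames, and median
harmonics-to-noise ratio (HNR).  CoG and dominant frequency come from a
single whole-call amplitude spectrum; voicing and harmonicity come from a
framed normalized-autocorrelation analysis in the style of standard
phonetics tooling, with the classical pitch search range of 50-400 Hz for
phocid calls.

The pitch/harmonicity backend is pluggable (`PitchBackend` protocol) so an
external phonetics engine can be swapped in for cross-validation; the
shipped backend is the native autocorrelation implementation below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Protocol

import numpy as np

from .io_formats import AnnotatedInterval, Waveform

__all__ = [
    "Spectrum",
    "PitchTrack",
    "FeatureVector",
    "FEATURE_NAMES",
    "compute_spectrum",
    "spectral_center_of_gravity",
    "dominant_frequency",
    "pitch_track",
    "percentage_voiced",
    "median_harmonicity",
    "extract_features",
    "scale_intensity",
    "AutocorrelationBackend",
]

FEATURE_NAMES = ["duration", "cog", "dominant_freq", "pct_voiced", "median_hnr"]

#: Reference pressure for dB SPL scaling (Pa), the usual airborne-acoustics 20 µPa.
REFERENCE_PRESSURE = 2e-5


@dataclass
class Spectrum:
    """One-sided amplitude spectrum of a whole call."""

    freqs: np.ndarray  # bin center frequencies, 0 .. rate/2
    values: np.ndarray  # complex rFFT coefficients
    rate: int
    n_samples: int  # length of the analysed signal (pre-padding)
    n_fft: int  # transform length (>= n_samples when zero-padded)

    @property
    def bin_width(self) -> float:
        return float(self.freqs[1] - self.freqs[0]) if self.freqs.size > 1 else self.rate / 2

    @property
    def power(self) -> np.ndarray:
        """Per-bin power, normalized so that sum(power) == mean(x**2) (Parseval)."""
        w = np.full(self.values.size, 2.0)
        w[0] = 1.0
        if self.n_fft % 2 == 0:  # real Nyquist bin is not doubled
            w[-1] = 1.0
        return w * np.abs(self.values) ** 2 / (self.n_fft * self.n_samples)


@dataclass
class PitchTrack:
    """Frame-based voicing and fundamental-frequency track."""

    times: np.ndarray  # frame centers (s)
    voiced: np.ndarray  # bool per frame
    f0: np.ndarray  # Hz, NaN where unvoiced
    floor: float
    ceiling: float

    @property
    def n_frames(self) -> int:
        return self.times.size


@dataclass
class FeatureVector:
    duration: float  # s
    cog: float  # Hz
    dominant_freq: float  # Hz
    pct_voiced: float  # % of frames, 0..100
    median_hnr: float  # dB; NaN when no analyzable frames

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


# --------------------------------------------------------------------------
# Whole-call spectrum
# --------------------------------------------------------------------------


def compute_spectrum(w: Waveform, pad_to_fast_length: bool = False) -> Spectrum:
    """Single amplitude spectrum of the whole call (no framing).

    With ``pad_to_fast_length`` the signal is zero-padded to the next
    5-smooth length before the FFT; this refines the bin grid without
    changing total power.
    """
    x = w.samples
    n = x.size
    n_fft = _next_fast_len(n) if pad_to_fast_length else n
    values = np.fft.rfft(x, n=n_fft)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / w.rate)
    return Spectrum(freqs=freqs, values=values, rate=w.rate, n_samples=n, n_fft=n_fft)


def _next_fast_len(n: int) -> int:
    from scipy.fft import next_fast_len

    return int(next_fast_len(n))


def spectral_center_of_gravity(spectrum: Spectrum, power_exponent: float = 2.0) -> float:
    """Power-weighted mean frequency: sum f*|S(f)|^p / sum |S(f)|^p.

    The default exponent p=2 weights by spectral power, the standard choice.
    """
    mag = np.abs(spectrum.values)
    if not np.any(mag > 0):
        raise ValueError("all-zero spectrum has no center of gravity")
    weights = mag**power_exponent
    return float(np.sum(spectrum.freqs * weights) / np.sum(weights))


def dominant_frequency(spectrum: Spectrum) -> float:
    """Center frequency of the highest-power bin; ties go to the lowest bin."""
    power = spectrum.power
    if not np.any(power > 0):
        raise ValueError("all-zero spectrum has no dominant frequency")
    return float(spectrum.freqs[int(np.argmax(power))])  # argmax takes first max


# --------------------------------------------------------------------------
# Framed normalized autocorrelation (shared by pitch and harmonicity)
# --------------------------------------------------------------------------


def _framed_normalized_autocorrelation(
    x: np.ndarray,
    frame_len: int,
    hop: int,
    min_lag: int,
    max_lag: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per frame: best normalized autocorrelation peak in a lag range.

    r(tau) = sum x[t] x[t+tau] / sqrt(e0(tau) e1(tau)), where e0/e1 are the
    energies of the two overlapping segments; this is the normalized
    cross-correlation form, robust to amplitude envelopes.  Returns
    (frame_start_indices, best_r, best_lag_fractional); the best lag is the
    smallest local maximum within 0.02 of the global one (favouring the true
    period over its subharmonic multiples) with parabolic refinement.
    """
    n = x.size
    if n < frame_len or max_lag >= frame_len:
        return np.array([], dtype=int), np.array([]), np.array([])
    starts = np.arange(0, n - frame_len + 1, hop)
    idx = starts[:, None] + np.arange(frame_len)[None, :]
    frames = x[idx]
    frames = frames - frames.mean(axis=1, keepdims=True)
    # FFT-based full autocorrelation per frame
    n_fft = _next_fast_len(2 * frame_len)
    spec = np.fft.rfft(frames, n=n_fft, axis=1)
    acf = np.fft.irfft(spec * np.conj(spec), n=n_fft, axis=1)[:, : max_lag + 1]
    # segment energies from cumulative sums of squares
    csq = np.concatenate(
        [np.zeros((frames.shape[0], 1)), np.cumsum(frames**2, axis=1)], axis=1
    )
    lags = np.arange(max_lag + 1)
    e0 = csq[:, frame_len - lags] - csq[:, [0]]  # energy of x[0 : N-lag]
    e1 = csq[:, [frame_len]] - csq[:, lags]  # energy of x[lag : N]
    denom = np.sqrt(np.maximum(e0 * e1, 1e-300))
    r = acf / denom
    r[:, :min_lag] = -np.inf
    best_r = np.full(frames.shape[0], -np.inf)
    best_lag = np.zeros(frames.shape[0])
    # local maxima in the admissible lag range
    seg = r[:, min_lag : max_lag + 1]
    interior = (seg[:, 1:-1] >= seg[:, :-2]) & (seg[:, 1:-1] >= seg[:, 2:])
    for i in range(frames.shape[0]):
        peaks = np.flatnonzero(interior[i]) + 1 + min_lag
        if peaks.size == 0:
            peaks = np.array([min_lag + int(np.argmax(seg[i]))])
        # parabolic refinement of every peak: the true (fractional) period lag
        # may fall between samples, and without refinement an integer multiple
        # of the period can look spuriously stronger than the period itself
        ref_lags = np.empty(peaks.size)
        ref_rs = np.empty(peaks.size)
        for j, lag in enumerate(peaks):
            lag = int(lag)
            if min_lag < lag < max_lag:
                y0, y1, y2 = r[i, lag - 1], r[i, lag], r[i, lag + 1]
                denom_p = y0 - 2 * y1 + y2
                if abs(denom_p) > 1e-12:
                    delta = float(np.clip(0.5 * (y0 - y2) / denom_p, -0.5, 0.5))
                    ref_lags[j] = lag + delta
                    ref_rs[j] = y1 - 0.25 * (y0 - y2) * delta
                    continue
            ref_lags[j] = lag
            ref_rs[j] = r[i, lag]
        rmax = ref_rs.max()
        k = int(np.argmax(ref_rs >= rmax - 0.02))  # smallest refined lag within margin
        best_lag[i] = ref_lags[k]
        best_r[i] = min(ref_rs[k], 1.0)
    return starts, best_r, best_lag


class PitchBackend(Protocol):
    """Adapter protocol so an external phonetics engine can replace the native analysis."""

    def pitch_track(self, w: Waveform, floor: float, ceiling: float) -> PitchTrack: ...

    def harmonicity_frames(self, w: Waveform, min_pitch: float) -> np.ndarray: ...


class AutocorrelationBackend:
    """Native framed normalized-autocorrelation pitch and harmonicity analysis.

    Voicing follows the classical two-threshold rule: a frame is voiced when
    its best normalized autocorrelation exceeds ``voicing_threshold`` and its
    amplitude exceeds ``silence_threshold`` times the global peak.  Analysis
    windows span three periods of the pitch floor with a hop of 0.75/floor,
    so every admissible lag fits with at least two periods of overlap.
    """

    def __init__(self, voicing_threshold: float = 0.45, silence_threshold: float = 0.03):
        self.voicing_threshold = voicing_threshold
        self.silence_threshold = silence_threshold

    def pitch_track(self, w: Waveform, floor: float = 50.0, ceiling: float = 400.0) -> PitchTrack:
        if not (0 < floor < ceiling):
            raise ValueError("need 0 < floor < ceiling")
        frame_len = int(round(3.0 * w.rate / floor))
        hop = max(1, int(round(0.75 * w.rate / floor)))
        min_lag = max(2, int(math.floor(w.rate / ceiling)))
        max_lag = int(math.ceil(w.rate / floor))
        starts, best_r, best_lag = _framed_normalized_autocorrelation(
            w.samples, frame_len, hop, min_lag, max_lag
        )
        if starts.size == 0:
            return PitchTrack(
                times=np.array([]), voiced=np.array([], dtype=bool),
                f0=np.array([]), floor=floor, ceiling=ceiling,
            )
        peak = np.max(np.abs(w.samples))
        idx = starts[:, None] + np.arange(frame_len)[None, :]
        frame_peaks = np.max(np.abs(w.samples[idx]), axis=1)
        loud = frame_peaks > self.silence_threshold * peak if peak > 0 else np.zeros_like(best_r, bool)
        voiced = (best_r > self.voicing_threshold) & loud
        f0 = np.where(
            voiced, np.clip(w.rate / np.maximum(best_lag, 1e-9), floor, ceiling), np.nan
        )
        times = (starts + frame_len / 2) / w.rate
        return PitchTrack(times=times, voiced=voiced, f0=f0, floor=floor, ceiling=ceiling)

    def harmonicity_frames(self, w: Waveform, min_pitch: float = 50.0) -> np.ndarray:
        """Per-frame HNR in dB: 10*log10(r / (1-r)) from the best peak r."""
        if min_pitch <= 0:
            raise ValueError("min_pitch must be positive")
        frame_len = int(round(2.0 * w.rate / min_pitch))
        hop = max(1, int(round(0.5 * w.rate / min_pitch)))
        min_lag = max(2, int(math.floor(w.rate / 600.0)))
        max_lag = int(math.ceil(w.rate / min_pitch))
        _, best_r, _ = _framed_normalized_autocorrelation(
            w.samples, frame_len, hop, min_lag, max_lag
        )
        if best_r.size == 0:
            return np.array([])
        r = np.clip(best_r, 1e-15, 1 - 1e-15)
        return 10.0 * np.log10(r / (1.0 - r))


_DEFAULT_BACKEND = AutocorrelationBackend()


# --------------------------------------------------------------------------
# Public feature operations
# --------------------------------------------------------------------------


def pitch_track(
    w: Waveform,
    floor: float = 50.0,
    ceiling: float = 400.0,
    backend: PitchBackend | None = None,
) -> PitchTrack:
    """Frame-based voicing decision and f0 within [floor, ceiling] Hz."""
    return (backend or _DEFAULT_BACKEND).pitch_track(w, floor, ceiling)


def percentage_voiced(pt: PitchTrack) -> float:
    """100 * (voiced frames) / (all frames)."""
    if pt.n_frames == 0:
        raise ValueError("pitch track has no frames (signal too short for the floor)")
    return 100.0 * float(np.count_nonzero(pt.voiced)) / pt.n_frames


def median_harmonicity(
    w: Waveform, min_pitch: float = 50.0, backend: PitchBackend | None = None
) -> float:
    """Median frame-wise harmonics-to-noise ratio in dB; NaN when no frames fit."""
    frames = (backend or _DEFAULT_BACKEND).harmonicity_frames(w, min_pitch)
    if frames.size == 0:
        return float("nan")
    return float(np.median(frames))


def extract_features(
    w: Waveform,
    iv: AnnotatedInterval,
    pitch_floor: float = 50.0,
    pitch_ceiling: float = 400.0,
    min_pitch_hnr: float = 50.0,
    cog_power: float = 2.0,
    backend: PitchBackend | None = None,
) -> FeatureVector:
    """All five call parameters on the annotated interval of a recording."""
    call = w.slice(iv.start, iv.end)
    spec = compute_spectrum(call)
    pt = pitch_track(call, pitch_floor, pitch_ceiling, backend=backend)
    pct = percentage_voiced(pt) if pt.n_frames > 0 else float("nan")
    return FeatureVector(
        duration=iv.duration,
        cog=spectral_center_of_gravity(spec, cog_power),
        dominant_freq=dominant_frequency(spec),
        pct_voiced=pct,
        median_hnr=median_harmonicity(call, min_pitch_hnr, backend=backend),
    )


def scale_intensity(w: Waveform, target_db: float) -> Waveform:
    """Scale to a target RMS intensity in dB SPL re 20 µPa.

    Equalizing all stimuli to one target level removes intensity as a cue.
    Raises on silent input; warns (via ValueError-free report) when the
    scaled peak exceeds full scale.
    """
    import warnings as _warnings

    rms = float(np.sqrt(np.mean(w.samples**2)))
    if rms == 0:
        raise ValueError("cannot scale a silent signal")
    target_rms = REFERENCE_PRESSURE * 10.0 ** (target_db / 20.0)
    scaled = w.samples * (target_rms / rms)
    peak = float(np.max(np.abs(scaled)))
    if peak > 1.0:
        _warnings.warn(
            f"intensity scaling to {target_db} dB drives peak to {peak:.3f} (> 1.0); "
            "samples will clip if written as PCM",
            stacklevel=2,
        )
    return Waveform(scaled, w.rate)
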