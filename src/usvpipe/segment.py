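"""Amplitude-threshold segmenter producing elements with frequency tracks.

Four-step scheme: (1) exponential-mean background subtraction on the dB
spectrogram, (2) spectral-envelope estimation from a handful of cepstral DCT
coefficients, (3) per-frame extraction of the three strongest spectral peaks
(m1-m3 amplitudes, f1-f3 frequencies), (4) hysteresis segmentation on the
strongest peak with minimum-duration and gap-merge post-processing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct, idct

from usvpipe.errors import ConfigError, EmptyInputError
from usvpipe.frontend import SpectrogramParams, _stft_power
from usvpipe.synth import FrequencyTrack


@dataclass(frozen=True)
class SegmenterParams:
    """Thresholds are dB above the running background estimate."""

    o1_on: float = 25.0
    o1_off: float = 18.0
    oo_enabled: bool = False
    oo_on: float = 22.0
    oo_off: float = 16.0
    exp_mean_alpha: float = 0.002
    n_cepstral: int = 7
    min_duration: float = 0.0015
    min_gap: float = 0.010

    def __post_init__(self) -> None:
        if self.o1_on < self.o1_off:
            raise ConfigError("o1_on must be >= o1_off")
        if self.oo_on < self.oo_off:
            raise ConfigError("oo_on must be >= oo_off")
        if not 0 < self.exp_mean_alpha < 1:
            raise ConfigError("exp_mean_alpha must lie in (0, 1)")


@dataclass
class FramePeaks:
    """Per-frame peak amplitudes (dB) and frequencies (Hz); NaN = missing."""

    m: np.ndarray  # (n_frames, 3), m1 >= m2 >= m3
    f: np.ndarray  # (n_frames, 3)
    hop_s: float

    @property
    def n_frames(self) -> int:
        return self.m.shape[0]


@dataclass
class Element:
    """One detected segment."""

    start: float
    end: float
    frequency_track: FrequencyTrack | None = None
    label: str | None = None

    @property
    def duration(self) -> float:
        return self.end - self.start


def denoise_spectrogram(spectrogram: np.ndarray, alpha: float) -> np.ndarray:
    """Subtract a per-row causal exponential-mean background estimate.

    ``bg[t] = (1 - alpha) * bg[t-1] + alpha * x[t]`` with ``bg[0] = x[0]``;
    returns ``x - bg``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    x = np.asarray(spectrogram, dtype=float)
    if x.size == 0:
        raise EmptyInputError("empty spectrogram")
    bg = np.empty_like(x)
    # warm-start from a short leading average so the estimate is unbiased on
    # short recordings; a single frame's fluctuations would otherwise leak
    # into every residual until the mean converges
    warm = min(50, x.shape[1])
    bg[:, 0] = x[:, :warm].mean(axis=1) if warm > 1 else x[:, 0]
    one_minus = 1.0 - alpha
    for t in range(1, x.shape[1]):
        bg[:, t] = one_minus * bg[:, t - 1] + alpha * x[:, t]
    return x - bg


def spectral_envelope(frame: np.ndarray, n_cepstral: int) -> np.ndarray:
    """Smooth spectral envelope from the first ``n_cepstral`` DCT coefficients."""
    coeffs = dct(np.asarray(frame, dtype=float), norm="ortho")
    coeffs[n_cepstral:] = 0.0
    return idct(coeffs, norm="ortho")


def frame_peaks(frame: np.ndarray, n_cepstral: int,
                freqs: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Three largest local maxima of (frame - envelope), sorted by amplitude.

    Returns ``(m, f)`` arrays of length 3; missing peaks are NaN, never
    fabricated.
    """
    frame = np.asarray(frame, dtype=float)
    if len(frame) < 16:
        raise ValueError("frame too short for envelope estimation")
    if freqs is None:
        freqs = np.arange(len(frame), dtype=float)
    residual = frame - spectral_envelope(frame, n_cepstral)
    interior = residual[1:-1]
    is_max = (interior > residual[:-2]) & (interior > residual[2:])
    peak_idx = np.flatnonzero(is_max) + 1
    m = np.full(3, np.nan)
    f = np.full(3, np.nan)
    if len(peak_idx) > 0:
        order = np.argsort(residual[peak_idx])[::-1][:3]
        chosen = peak_idx[order]
        m[: len(chosen)] = residual[chosen]
        f[: len(chosen)] = freqs[chosen]
    return m, f


def compute_frame_peaks(spectrogram_db: np.ndarray, freqs: np.ndarray,
                        params: SegmenterParams, hop_s: float) -> FramePeaks:
    """Denoise a dB spectrogram and extract per-frame peaks."""
    denoised = denoise_spectrogram(spectrogram_db, params.exp_mean_alpha)
    n_frames = denoised.shape[1]
    m = np.full((n_frames, 3), np.nan)
    f = np.full((n_frames, 3), np.nan)
    for t in range(n_frames):
        m[t], f[t] = frame_peaks(denoised[:, t], params.n_cepstral, freqs)
    return FramePeaks(m=m, f=f, hop_s=hop_s)


def _hysteresis(values: np.ndarray, on: float, off: float) -> np.ndarray:
    """Boolean activation: open at >= on, close at < off (NaN closes)."""
    active = np.zeros(len(values), dtype=bool)
    state = False
    for t, v in enumerate(values):
        if np.isnan(v):
            state = False
        elif state:
            state = v >= off
        else:
            state = v >= on
        active[t] = state
    return active


def segment_elements(peaks: FramePeaks, params: SegmenterParams,
                     window_s: float = 750 / 300_000) -> list[Element]:
    """Hysteresis segmentation of the peak track into elements.

    ``window_s`` is the STFT window length; element bounds compensate for the
    window's spread (start = right edge of the first active window, end =
    left edge of the last).
    """
    if peaks.n_frames == 0:
        raise EmptyInputError("no frames")
    active = _hysteresis(peaks.m[:, 0], params.o1_on, params.o1_off)
    if params.oo_enabled:
        active |= _hysteresis(peaks.m[:, 1], params.oo_on, params.oo_off)
    # contiguous active runs -> frame index intervals
    padded = np.concatenate(([False], active, [False])).astype(int)
    rises = np.flatnonzero(np.diff(padded) == 1)
    falls = np.flatnonzero(np.diff(padded) == -1)
    runs = list(zip(rises, falls))  # frames [k0, k1)

    hop = peaks.hop_s
    # drop sub-minimum runs first (kills single-frame noise excursions), then
    # merge runs separated by short silences (frequency-jump components)
    min_frames = max(2, int(round(params.min_duration / hop)))
    runs = [r for r in runs if r[1] - r[0] >= min_frames]
    merged: list[list[int]] = []
    for k0, k1 in runs:
        if merged and (k0 - merged[-1][1]) * hop < params.min_gap:
            merged[-1][1] = k1
        else:
            merged.append([k0, k1])

    elements = []
    half_window = window_s / 2
    for k0, k1 in merged:
        # refine bounds with a threshold relative to the run's peak level:
        # the Hamming taper plus the syllables' own onset/offset ramps make
        # absolute-threshold frames a biased estimate of the true interval
        m_run = peaks.m[k0:k1, 0]
        peak_level = np.nanmax(m_run)
        sel = np.flatnonzero(m_run >= peak_level - 24.0)
        f0 = k0 + (sel.min() if len(sel) else 0)
        f1 = k0 + (sel.max() if len(sel) else k1 - k0 - 1)
        start = f0 * hop + half_window - hop
        end = f1 * hop + half_window + 2 * hop
        track = _element_track(peaks, k0, k1)
        elements.append(Element(start=start, end=end, frequency_track=track))
    return elements


def _element_track(peaks: FramePeaks, k0: int, k1: int) -> FrequencyTrack:
    """f1 path over the element's frames, 3-frame median smoothed."""
    f1 = peaks.f[k0:k1, 0].astype(float).copy()
    valid = ~np.isnan(f1)
    if valid.sum() >= 3:
        vals = f1[valid]
        sm = vals.copy()
        sm[1:-1] = np.median(
            np.stack([vals[:-2], vals[1:-1], vals[2:]]), axis=0)
        f1[valid] = sm
    return FrequencyTrack(values=f1, hop_s=peaks.hop_s)


def detect_elements(waveform: np.ndarray, sample_rate: int = 300_000,
                    params: SegmenterParams | None = None,
                    spec_params: SpectrogramParams | None = None) -> list[Element]:
    """Full detection pipeline: waveform -> list of elements."""
    params = params or SegmenterParams()
    spec_params = spec_params or SpectrogramParams(sample_rate=sample_rate)
    power = _stft_power(waveform, spec_params)
    band = power[spec_params.band_bins(), :]
    db = 10.0 * np.log10(np.maximum(band, 1e-20))
    peaks = compute_frame_peaks(db, spec_params.band_freqs(), params,
                                spec_params.hop_s)
    return segment_elements(peaks, params,
                            window_s=spec_params.nfft / spec_params.sample_rate)
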