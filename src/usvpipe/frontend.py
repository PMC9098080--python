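"""Gammatone-spectrogram frontend.

Pipeline per element: band-limited squared-modulus STFT (NFFT 750, 0.8
Hamming overlap, 20-120 kHz -> 251 bins at 300 kHz) -> 64-channel Gammatone
filterbank pooling -> noise floor + log10 -> order-1 ARMA smoothing ->
3x3 median filter -> fixed 64x401 canvas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from usvpipe.errors import ConfigError, EmptyInputError

#: Noise floor applied before the log, and its log10.
NOISE_FLOOR = 1e-3
LOG_FLOOR = -3.0

#: Canvas size of a Gammatone spectrogram.
GS_SHAPE = (64, 401)


@dataclass(frozen=True)
class SpectrogramParams:
    nfft: int = 750
    overlap: float = 0.8
    sample_rate: int = 300_000
    band_low: float = 20_000.0
    band_high: float = 120_000.0

    def __post_init__(self) -> None:
        if not 0 < self.overlap < 1:
            raise ConfigError("overlap must lie in (0, 1)")
        if not self.band_low < self.band_high <= self.sample_rate / 2:
            raise ConfigError("need band_low < band_high <= Nyquist")

    @property
    def hop(self) -> int:
        return int(round(self.nfft * (1 - self.overlap)))

    @property
    def hop_s(self) -> float:
        return self.hop / self.sample_rate

    def band_bins(self) -> np.ndarray:
        """Indices of FFT bins whose centers lie inside the analysis band."""
        freqs = np.fft.rfftfreq(self.nfft, d=1.0 / self.sample_rate)
        return np.flatnonzero((freqs >= self.band_low) & (freqs <= self.band_high))

    def band_freqs(self) -> np.ndarray:
        freqs = np.fft.rfftfreq(self.nfft, d=1.0 / self.sample_rate)
        return freqs[self.band_bins()]


@dataclass(frozen=True)
class FilterBankParams:
    n_channels: int = 64
    filter_order: int = 4
    midpoint_freq: float = 68_000.0
    band_low: float = 20_000.0
    band_high: float = 120_000.0
    #: bandwidth model b(fc) = bw_offset + bw_slope * fc (grows with fc)
    bw_offset: float = 300.0
    bw_slope: float = 0.05

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ConfigError("need at least 2 Gammatone channels")
        if not self.band_low < self.midpoint_freq < self.band_high:
            raise ConfigError("midpoint frequency outside the analysis band")


@dataclass
class GammatoneSpectrogram:
    """64x401 denoised log time-frequency image; sole classifier input."""

    values: np.ndarray
    channel_center_freqs: np.ndarray
    frame_hop: float
    element_id: str | None = None
    label: str | None = None

    def normalized(self) -> np.ndarray:
        """Per-image min-max normalization to [0, 1] (classifier input)."""
        v = self.values
        lo, hi = float(v.min()), float(v.max())
        if hi - lo < 1e-12:
            return np.zeros_like(v)
        return (v - lo) / (hi - lo)


def _stft_power(waveform: np.ndarray, params: SpectrogramParams) -> np.ndarray:
    """Full squared-modulus STFT, shape (nfft//2+1, n_frames)."""
    x = np.asarray(waveform, dtype=float)
    if len(x) < params.nfft:
        x = np.pad(x, (0, params.nfft - len(x)))
    win = signal.get_window("hamming", params.nfft, fftbins=True)
    n_frames = 1 + (len(x) - params.nfft) // params.hop
    frames = np.lib.stride_tricks.sliding_window_view(x, params.nfft)[:: params.hop]
    frames = frames[:n_frames]
    spec = np.fft.rfft(frames * win, axis=1)
    return (np.abs(spec) ** 2).T


def stft_frame_times(n_frames: int, params: SpectrogramParams) -> np.ndarray:
    """Center time of each STFT frame [s] (frame k spans k*hop .. k*hop+nfft)."""
    return (np.arange(n_frames) * params.hop + params.nfft / 2) / params.sample_rate


def compute_windowed_stft(waveform: np.ndarray, params: SpectrogramParams,
                          element=None) -> np.ndarray:
    """Band-limited power STFT, optionally restricted to an element's frames.

    ``element`` is anything with ``start``/``end`` attributes in seconds, or a
    ``(start, end)`` tuple.  Frames whose window overlaps [start, end) are
    kept; bins with centers in [band_low, band_high] are kept (251 at
    defaults).
    """
    if len(np.asarray(waveform)) == 0:
        raise EmptyInputError("empty waveform")
    power = _stft_power(waveform, params)
    band = power[params.band_bins(), :]
    if element is None:
        return band
    if isinstance(element, tuple):
        start, end = element
    else:
        start, end = element.start, element.end
    duration = len(waveform) / params.sample_rate
    if start < 0 or end > duration + params.nfft / params.sample_rate or end <= start:
        raise ValueError(
            f"element [{start}, {end}) outside waveform of {duration:.3f} s"
        )
    n_frames = band.shape[1]
    t0 = np.arange(n_frames) * params.hop / params.sample_rate
    t1 = t0 + params.nfft / params.sample_rate
    keep = (t1 > start) & (t0 < end)
    if not keep.any():
        keep = np.zeros(n_frames, bool)
        keep[min(int(start / params.hop_s), n_frames - 1)] = True
    return band[:, keep]


def gammatone_center_freqs(params: FilterBankParams) -> np.ndarray:
    """Channel center frequencies under a compressive warp.

    Channels are spaced uniformly in the warped coordinate
    ``w(f) = sign(f - fm) * sqrt(|f - fm|)``, which concentrates channel
    density around the midpoint frequency ``fm`` and is strictly increasing.
    """
    fm = params.midpoint_freq

    def warp(f):
        return np.sign(f - fm) * np.sqrt(np.abs(f - fm))

    def unwarp(w):
        return fm + np.sign(w) * w ** 2

    w = np.linspace(warp(params.band_low), warp(params.band_high),
                    params.n_channels)
    centers = unwarp(w)
    centers[0] = params.band_low
    centers[-1] = params.band_high
    return centers


def gammatone_response(freqs: np.ndarray, center: float, bandwidth: float,
                       order: int) -> np.ndarray:
    """Magnitude response of one Gammatone channel on a frequency grid."""
    return (1.0 + ((freqs - center) / bandwidth) ** 2) ** (-order / 2.0)


def build_gammatone_bank(params: FilterBankParams,
                         stft_params: SpectrogramParams | None = None) -> np.ndarray:
    """Filter weight matrix (n_channels x n_band_bins), rows sum to 1."""
    if stft_params is None:
        stft_params = SpectrogramParams(band_low=params.band_low,
                                        band_high=params.band_high)
    if not (stft_params.band_low <= params.band_low
            and params.band_high <= stft_params.band_high):
        raise ConfigError("filterbank band must lie inside the STFT band")
    freqs = stft_params.band_freqs()
    centers = gammatone_center_freqs(params)
    bank = np.empty((params.n_channels, len(freqs)))
    for i, fc in enumerate(centers):
        bw = params.bw_offset + params.bw_slope * fc
        row = gammatone_response(freqs, fc, bw, params.filter_order)
        bank[i] = row / row.sum()
    return bank


def arma_smooth(x: np.ndarray, coeff: float = 0.1) -> np.ndarray:
    """Order-1 forward-backward autoregressive smoothing along time (axis 1)."""
    b = [coeff]
    a = [1.0, -(1.0 - coeff)]
    padlen = min(x.shape[1] - 1, 6)
    return signal.filtfilt(b, a, x, axis=1, padtype="even", padlen=padlen)


def gs_transform(stft_band: np.ndarray, bank: np.ndarray,
                 arma_coeff: float = 0.1, median_size: int = 3,
                 n_frames_out: int = GS_SHAPE[1],
                 channel_center_freqs: np.ndarray | None = None,
                 frame_hop: float = 150 / 300_000,
                 element_id: str | None = None,
                 label: str | None = None) -> GammatoneSpectrogram:
    """Reduce a band-limited power STFT to a fixed-size Gammatone spectrogram."""
    if stft_band.shape[0] != bank.shape[1]:
        raise ValueError(
            f"STFT has {stft_band.shape[0]} rows, bank expects {bank.shape[1]}"
        )
    gt = bank @ stft_band
    logged = np.log10(np.maximum(gt, NOISE_FLOOR))
    if logged.shape[1] >= 3:
        smoothed = arma_smooth(logged, arma_coeff)
    else:
        smoothed = logged
    smoothed = ndimage.median_filter(smoothed, size=(median_size, median_size),
                                     mode="nearest")
    smoothed = np.maximum(smoothed, LOG_FLOOR)
    n = smoothed.shape[1]
    if n > n_frames_out:  # center-crop long elements
        off = (n - n_frames_out) // 2
        canvas = smoothed[:, off:off + n_frames_out]
    else:  # right-pad with the log floor
        canvas = np.full((bank.shape[0], n_frames_out), LOG_FLOOR)
        canvas[:, :n] = smoothed
    if channel_center_freqs is None:
        channel_center_freqs = np.zeros(bank.shape[0])
    return GammatoneSpectrogram(values=canvas,
                                channel_center_freqs=channel_center_freqs,
                                frame_hop=frame_hop, element_id=element_id,
                                label=label)


def elements_to_gs(waveform: np.ndarray, elements,
                   spec_params: SpectrogramParams | None = None,
                   bank_params: FilterBankParams | None = None) -> list[GammatoneSpectrogram]:
    """Compute one Gammatone spectrogram per detected element.

    The full-recording STFT is computed once and sliced per element.
    """
    spec_params = spec_params or SpectrogramParams()
    bank_params = bank_params or FilterBankParams(
        band_low=spec_params.band_low, band_high=spec_params.band_high)
    bank = build_gammatone_bank(bank_params, spec_params)
    centers = gammatone_center_freqs(bank_params)
    power = _stft_power(waveform, spec_params)
    band = power[spec_params.band_bins(), :]
    n_frames = band.shape[1]
    t0 = np.arange(n_frames) * spec_params.hop / spec_params.sample_rate
    t1 = t0 + spec_params.nfft / spec_params.sample_rate
    out = []
    for i, el in enumerate(elements):
        start, end = (el if isinstance(el, tuple) else (el.start, el.end))
        keep = (t1 > start) & (t0 < end)
        if not keep.any():
            keep = np.zeros(n_frames, bool)
            keep[min(int(start / spec_params.hop_s), n_frames - 1)] = True
        label = getattr(el, "label", None)
        out.append(gs_transform(band[:, keep], bank,
                                channel_center_freqs=centers,
                                frame_hop=spec_params.hop_s,
                                element_id=str(i), label=label))
    return out
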