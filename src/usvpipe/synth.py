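"""Seeded generator of synthetic ultrasonic recordings with ground-truth labels.

Syllables are rendered as frequency-modulated sinusoids over broadband
Gaussian background noise.  Thirteen syllable classes are supported plus a
broadband false-positive (``FP``) class standing in for cage/movement noise.
Class geometry follows the frequency-trajectory rules used for manual
annotation: net rises/falls of more than 5 kHz (``up``/``d``), u-shaped and
inverted-u trajectories (``u``/``ui``), two or more direction changes (``c``),
2-5 components separated by breaks in the frequency track (``c2``-``c5``),
flat syllables split by duration (``us`` < 5 ms, ``s`` 5-10 ms, ``f``
otherwise) and harmonic syllables (``h``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from usvpipe.errors import (
    EmptyInputError,
    InvalidClassLabelError,
    SampleRateError,
)

#: Syllable classes (without the false-positive class), in canonical order.
SYLLABLE_CLASSES = (
    "c", "c2", "c3", "c4", "c5", "h", "d", "up", "u", "f", "us", "s", "ui",
)
#: All element classes, including false positives.
ALL_CLASSES = SYLLABLE_CLASSES + ("FP",)

#: Default sample rate [Hz].  With NFFT = 750 this yields 400 Hz bin spacing
#: and a 251-bin band over 20-120 kHz in the frontend.
DEFAULT_SAMPLE_RATE = 300_000

#: Frame hop of the analysis frontend [s] (NFFT 750, 0.8 overlap, 300 kHz).
FRAME_HOP_S = 150 / DEFAULT_SAMPLE_RATE

#: Analysis band [Hz].
BAND_LOW = 20_000.0
BAND_HIGH = 120_000.0

#: Frequency-modulation threshold separating flat from shaped syllables [Hz].
MODULATION_THRESHOLD_HZ = 5_000.0

#: Duration thresholds for the short classes [s].
US_MAX_DURATION = 0.005
S_MAX_DURATION = 0.010

#: Hysteresis tolerance when counting direction changes on a track [Hz].
REVERSAL_TOLERANCE_HZ = 1_000.0

_COMPONENT_CLASSES = {"c2": 2, "c3": 3, "c4": 4, "c5": 5}
_GAP_TO_CLASS = {1: "c2", 2: "c3", 3: "c4", 4: "c5"}


@dataclass(frozen=True)
class UsvSpec:
    """Ground-truth description of one synthetic element."""

    class_label: str
    duration: float
    f_start: float = 60_000.0
    f_end: float = 60_000.0
    f_min: float = 55_000.0
    f_max: float = 75_000.0
    n_components: int = 1
    n_direction_changes: int = 0
    has_harmonic: bool = False
    amplitude_db: float = 30.0

    def __post_init__(self) -> None:
        if self.class_label not in ALL_CLASSES:
            raise InvalidClassLabelError(
                f"unknown class label {self.class_label!r}; "
                f"expected one of {ALL_CLASSES}"
            )
        if self.class_label == "FP":
            return
        for f in (self.f_start, self.f_end, self.f_min, self.f_max):
            if not (BAND_LOW <= f <= BAND_HIGH):
                raise ValueError(f"frequency {f} Hz outside [20, 120] kHz")
        if self.class_label == "us" and not self.duration < US_MAX_DURATION:
            raise ValueError("'us' syllables must be shorter than 5 ms")
        if self.class_label == "s" and not (
            US_MAX_DURATION <= self.duration <= S_MAX_DURATION
        ):
            raise ValueError("'s' syllables must last 5-10 ms")
        expected = _COMPONENT_CLASSES.get(self.class_label)
        if expected is not None and self.n_components != expected:
            raise ValueError(
                f"class {self.class_label!r} requires "
                f"{expected} components, got {self.n_components}"
            )
        if self.class_label == "c" and self.n_direction_changes < 2:
            raise ValueError("'c' syllables need >= 2 direction changes")
        if self.class_label == "f" and (self.f_max - self.f_min) >= MODULATION_THRESHOLD_HZ:
            raise ValueError("'f' syllables must modulate by < 5 kHz")

    @staticmethod
    def random(class_label: str, rng: np.random.Generator) -> "UsvSpec":
        """Draw a class-conformant spec with randomized free parameters."""
        if class_label not in ALL_CLASSES:
            raise InvalidClassLabelError(f"unknown class label {class_label!r}")
        amp = float(rng.uniform(25.0, 35.0))
        if class_label == "FP":
            return UsvSpec("FP", float(rng.uniform(0.005, 0.030)),
                           amplitude_db=float(rng.uniform(8.0, 14.0)))
        if class_label == "us":
            dur = float(rng.uniform(0.002, 0.0045))
        elif class_label == "s":
            dur = float(rng.uniform(0.0055, 0.0095))
        elif class_label in _COMPONENT_CLASSES:
            k = _COMPONENT_CLASSES[class_label]
            dur = float(rng.uniform(0.015 * k, 0.025 * k))
        else:
            dur = float(rng.uniform(0.020, 0.080))
        if class_label in ("f", "s", "us"):
            c = float(rng.uniform(40_000, 90_000))
            drift = float(rng.uniform(500, 3_000))
            return UsvSpec(class_label, dur, f_start=c, f_end=c + drift,
                           f_min=c, f_max=c + drift, amplitude_db=amp)
        if class_label == "up":
            f0 = float(rng.uniform(35_000, 80_000))
            rise = float(rng.uniform(8_000, 30_000))
            return UsvSpec("up", dur, f_start=f0, f_end=f0 + rise,
                           f_min=f0, f_max=f0 + rise, amplitude_db=amp)
        if class_label == "d":
            f0 = float(rng.uniform(55_000, 100_000))
            fall = float(rng.uniform(8_000, 30_000))
            return UsvSpec("d", dur, f_start=f0, f_end=f0 - fall,
                           f_min=f0 - fall, f_max=f0, amplitude_db=amp)
        if class_label in ("u", "ui"):
            lo = float(rng.uniform(40_000, 70_000))
            depth = float(rng.uniform(8_000, 25_000))
            return UsvSpec(class_label, dur, f_start=lo, f_end=lo,
                           f_min=lo, f_max=lo + depth, amplitude_db=amp)
        if class_label == "c":
            lo = float(rng.uniform(45_000, 70_000))
            depth = float(rng.uniform(8_000, 20_000))
            nc = int(rng.integers(2, 5))
            return UsvSpec("c", dur, f_start=lo, f_end=lo, f_min=lo,
                           f_max=lo + depth, n_direction_changes=nc,
                           amplitude_db=amp)
        if class_label in _COMPONENT_CLASSES:
            k = _COMPONENT_CLASSES[class_label]
            lo = float(rng.uniform(40_000, 55_000))
            return UsvSpec(class_label, dur, f_start=lo, f_end=lo,
                           f_min=lo, f_max=min(lo + 12_000.0 * k, BAND_HIGH),
                           n_components=k, amplitude_db=amp)
        # 'h': fundamental kept low enough for the 2x band to stay in range
        f0 = float(rng.uniform(35_000, 52_000))
        rise = float(rng.uniform(2_000, 6_000))
        return UsvSpec("h", dur, f_start=f0, f_end=f0 + rise, f_min=f0,
                       f_max=f0 + rise, has_harmonic=True, amplitude_db=amp)


@dataclass
class FrequencyTrack:
    """Per-frame instantaneous-frequency estimate of one element.

    ``values`` holds one frequency in Hz per frame; component breaks are
    encoded as NaN frames.
    """

    values: np.ndarray
    hop_s: float = FRAME_HOP_S
    has_harmonic: bool = False

    @property
    def n_frames(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        return self.n_frames * self.hop_s

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def n_gaps(self) -> int:
        """Number of interior NaN runs separating defined components."""
        mask = self.defined()
        if not mask.any():
            return 0
        first, last = np.flatnonzero(mask)[[0, -1]]
        interior = ~mask[first:last + 1]
        # count runs of True in `interior`
        padded = np.concatenate(([False], interior, [False]))
        return int(np.sum(np.diff(padded.astype(int)) == 1))


@dataclass
class SyntheticRecording:
    """A synthetic waveform with its ground-truth annotations."""

    waveform: np.ndarray
    sample_rate: int
    annotations: list  # of (start_s, end_s, class_label)
    seed: int
    snr_db: float

    @property
    def duration(self) -> float:
        return len(self.waveform) / self.sample_rate


def count_direction_changes(values: np.ndarray,
                            tol: float = REVERSAL_TOLERANCE_HZ) -> int:
    """Count trajectory reversals larger than ``tol`` (turning-point scan)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 3:
        return 0
    changes = 0
    direction = 0
    ext = v[0]
    for x in v[1:]:
        if direction == 0:
            if x >= ext + tol:
                direction = 1
                ext = x
            elif x <= ext - tol:
                direction = -1
                ext = x
        elif direction == 1:
            if x > ext:
                ext = x
            elif x <= ext - tol:
                changes += 1
                direction = -1
                ext = x
        else:
            if x < ext:
                ext = x
            elif x >= ext + tol:
                changes += 1
                direction = 1
                ext = x
    return changes


def _n_frames(duration: float, hop_s: float) -> int:
    return max(3, int(round(duration / hop_s)))


def generate_frequency_track(spec: UsvSpec, seed: int,
                             hop_s: float = FRAME_HOP_S) -> FrequencyTrack:
    """Realize the class geometry of ``spec`` as a per-frame frequency track."""
    if spec.class_label == "FP":
        raise InvalidClassLabelError("'FP' elements carry no frequency track")
    rng = np.random.default_rng(seed)
    n = _n_frames(spec.duration, hop_s)
    t = np.linspace(0.0, 1.0, n)
    label = spec.class_label

    if label in ("f", "s", "us"):
        drift = np.clip(spec.f_end - spec.f_start,
                        -MODULATION_THRESHOLD_HZ * 0.8,
                        MODULATION_THRESHOLD_HZ * 0.8)
        values = spec.f_start + drift * t
    elif label in ("up", "h"):
        values = spec.f_start + (spec.f_end - spec.f_start) * (
            1 - np.cos(np.pi * t)) / 2
        if label == "h" and abs(spec.f_end - spec.f_start) < 1.0:
            values = np.full(n, spec.f_start)
    elif label == "d":
        values = spec.f_start + (spec.f_end - spec.f_start) * (
            1 - np.cos(np.pi * t)) / 2
    elif label == "u":
        depth = spec.f_max - spec.f_min
        values = spec.f_max - depth * np.sin(np.pi * t)
    elif label == "ui":
        depth = spec.f_max - spec.f_min
        values = spec.f_min + depth * np.sin(np.pi * t)
    elif label == "c":
        amp = (spec.f_max - spec.f_min) / 2
        center = (spec.f_max + spec.f_min) / 2
        k = spec.n_direction_changes + 1
        values = center + amp * np.cos(np.pi * k * t)
    elif label in _COMPONENT_CLASSES:
        k = _COMPONENT_CLASSES[label]
        gap_frames = max(2, int(round(0.0015 / hop_s)))
        needed = k * 3 + (k - 1) * gap_frames
        if n < needed:
            n = needed
        comp_frames = (n - (k - 1) * gap_frames) // k
        values = np.full(n, np.nan)
        span = spec.f_max - spec.f_min
        # components jump up/down across the available span
        offsets = spec.f_min + span * ((np.arange(k) * 0.61) % 1.0)
        pos = 0
        for j in range(k):
            stop = pos + comp_frames if j < k - 1 else n
            m = stop - pos
            tt = np.linspace(0.0, 1.0, m)
            values[pos:stop] = offsets[j] + 2_000.0 * tt
            pos = stop + gap_frames if j < k - 1 else stop
        values = np.clip(values, BAND_LOW, BAND_HIGH)
    else:  # pragma: no cover - guarded by UsvSpec validation
        raise InvalidClassLabelError(f"unknown class label {label!r}")

    # sub-threshold jitter keeps tracks from being artificially exact while
    # never flipping any rule decision
    jitter = rng.normal(0.0, 50.0, size=len(values))
    mask = ~np.isnan(values)
    out = values.copy()
    out[mask] = np.clip(values[mask] + jitter[mask], BAND_LOW, BAND_HIGH)
    if label in ("up", "d"):
        # monotone classes stay strictly monotone
        out = values
    return FrequencyTrack(out, hop_s=hop_s, has_harmonic=spec.has_harmonic)


def rule_label(track: FrequencyTrack, duration: float | None = None,
               has_harmonic: bool | None = None) -> str:
    """Deterministic rule cascade assigning a syllable class to a track."""
    values = np.asarray(track.values, dtype=float)
    mask = ~np.isnan(values)
    if len(values) == 0 or not mask.any():
        raise EmptyInputError("frequency track has no defined frames")
    if duration is None:
        duration = track.duration
    if has_harmonic is None:
        has_harmonic = track.has_harmonic
    if has_harmonic:
        return "h"
    n_gaps = track.n_gaps()
    if n_gaps in _GAP_TO_CLASS:
        return _GAP_TO_CLASS[n_gaps]
    v = values[mask]
    n_changes = count_direction_changes(v)
    if n_changes >= 2:
        return "c"
    spread = float(v.max() - v.min())
    if n_changes == 1 and spread >= MODULATION_THRESHOLD_HZ:
        i_min = int(np.argmin(v))
        i_max = int(np.argmax(v))
        if 0 < i_min < len(v) - 1 and not (0 < i_max < len(v) - 1):
            return "u"
        if 0 < i_max < len(v) - 1:
            return "ui"
    if spread >= MODULATION_THRESHOLD_HZ:
        net = float(v[-1] - v[0])
        return "up" if net > 0 else "d"
    if duration < US_MAX_DURATION:
        return "us"
    if duration <= S_MAX_DURATION:
        return "s"
    return "f"


def _raised_cosine_envelope(n: int, ramp_frac: float = 0.1) -> np.ndarray:
    """Unit envelope with raised-cosine onset/offset ramps."""
    env = np.ones(n)
    ramp = max(2, int(round(ramp_frac * n)))
    ramp = min(ramp, n // 2)
    if ramp > 0:
        r = (1 - np.cos(np.pi * np.arange(ramp) / ramp)) / 2
        env[:ramp] = r
        env[-ramp:] = r[::-1]
    return env


def _render_tonal(spec: UsvSpec, track: FrequencyTrack, sample_rate: int,
                  amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Render one tonal syllable (possibly multi-component / harmonic)."""
    n_samples = int(round(track.n_frames * track.hop_s * sample_rate))
    out = np.zeros(n_samples)
    mask = track.defined()
    frame_times = (np.arange(track.n_frames) + 0.5) * track.hop_s
    # iterate over contiguous defined runs (components)
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return out
    splits = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, splits + 1)
    nyquist = sample_rate / 2
    for run in runs:
        t0 = run[0] * track.hop_s
        t1 = (run[-1] + 1) * track.hop_s
        s0 = int(round(t0 * sample_rate))
        s1 = min(int(round(t1 * sample_rate)), n_samples)
        m = s1 - s0
        if m <= 0:
            continue
        ts = s0 / sample_rate + np.arange(m) / sample_rate
        freq = np.interp(ts, frame_times[run], track.values[run])
        phase = 2 * np.pi * np.cumsum(freq) / sample_rate
        phase += rng.uniform(0, 2 * np.pi)
        env = _raised_cosine_envelope(m)
        seg = amplitude * env * np.sin(phase)
        if track.has_harmonic:
            h_ok = 2 * freq < nyquist
            seg = seg + (amplitude * 0.5) * env * np.sin(2 * phase) * h_ok
        out[s0:s1] += seg
    return out


def _render_fp(spec: UsvSpec, sample_rate: int, amplitude_rms: float,
               rng: np.random.Generator) -> np.ndarray:
    """Render a broadband false-positive burst (band-passed noise)."""
    n = max(16, int(round(spec.duration * sample_rate)))
    burst = rng.normal(0.0, 1.0, n)
    sos = signal.butter(4, [BAND_LOW, BAND_HIGH], btype="bandpass",
                        fs=sample_rate, output="sos")
    burst = signal.sosfiltfilt(sos, burst)
    burst *= amplitude_rms / max(np.sqrt(np.mean(burst ** 2)), 1e-12)
    return burst * _raised_cosine_envelope(n)


#: RMS of the broadband background noise in waveform units.
NOISE_FLOOR_RMS = 0.01


def synthesize_recording(specs: list[UsvSpec], sample_rate: int = DEFAULT_SAMPLE_RATE,
                         snr_db: float = 30.0, min_gap: float = 0.03,
                         seed: int = 0,
                         pad: float = 0.05) -> SyntheticRecording:
    """Render ``specs`` sequentially over Gaussian background noise.

    Each spec's ``amplitude_db`` (dB relative to the noise floor power) sets
    its level; identical ``(specs, seed)`` give bit-identical output.
    """
    if sample_rate < 2 * BAND_HIGH:
        raise SampleRateError(
            f"sample rate {sample_rate} Hz cannot represent 120 kHz content"
        )
    if min_gap <= 0:
        raise ValueError("min_gap must be positive")
    rng = np.random.default_rng(seed)

    hop_s = FRAME_HOP_S  # track frames on the frontend hop grid
    gaps = min_gap + rng.uniform(0.0, min_gap, size=max(len(specs), 1))
    starts = []
    t = pad
    durations = []
    tracks = []
    for i, spec in enumerate(specs):
        if spec.class_label == "FP":
            dur = spec.duration
            tracks.append(None)
        else:
            track = generate_frequency_track(spec, seed=int(rng.integers(2 ** 31)),
                                             hop_s=hop_s)
            tracks.append(track)
            dur = track.n_frames * hop_s
        starts.append(t)
        durations.append(dur)
        t += dur + gaps[i]
    total = t + pad
    n_total = int(round(total * sample_rate))
    waveform = rng.normal(0.0, NOISE_FLOOR_RMS, n_total)

    annotations = []
    for spec, start, dur, track in zip(specs, starts, durations, tracks):
        s0 = int(round(start * sample_rate))
        if spec.class_label == "FP":
            amp_rms = NOISE_FLOOR_RMS * 10 ** (spec.amplitude_db / 20)
            seg = _render_fp(spec, sample_rate, amp_rms, rng)
        else:
            amp = NOISE_FLOOR_RMS * np.sqrt(2.0) * 10 ** (spec.amplitude_db / 20)
            seg = _render_tonal(spec, track, sample_rate, amp, rng)
        s1 = min(s0 + len(seg), n_total)
        waveform[s0:s1] += seg[: s1 - s0]
        annotations.append((start, start + (s1 - s0) / sample_rate,
                            spec.class_label))
    return SyntheticRecording(waveform=waveform, sample_rate=sample_rate,
                              annotations=annotations, seed=seed,
                              snr_db=snr_db)


def random_specs(n: int, seed: int, classes=SYLLABLE_CLASSES,
                 fp_fraction: float = 0.0) -> list[UsvSpec]:
    """Draw ``n`` random class-conformant specs (convenience for fixtures)."""
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n):
        if fp_fraction > 0 and rng.uniform() < fp_fraction:
            specs.append(UsvSpec.random("FP", rng))
        else:
            specs.append(UsvSpec.random(str(rng.choice(classes)), rng))
    return specs
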