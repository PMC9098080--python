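"""Labeled Gammatone-spectrogram datasets built from the synthetic generator.

Renders each element in its own short clip (no segmentation involved), so
classifier experiments are decoupled from detector behavior.
"""

from __future__ import annotations

import numpy as np

from usvpipe.frontend import (
    FilterBankParams,
    SpectrogramParams,
    build_gammatone_bank,
    gammatone_center_freqs,
    gs_transform,
    _stft_power,
)
from usvpipe.synth import ALL_CLASSES, UsvSpec, synthesize_recording


def gs_for_spec(spec: UsvSpec, seed: int, bank: np.ndarray,
                spec_params: SpectrogramParams,
                snr_db: float | None = None) -> np.ndarray:
    """Render one element in isolation and return its normalized GS image."""
    if snr_db is not None:
        spec = UsvSpec(**{**spec.__dict__, "amplitude_db": snr_db})
    rec = synthesize_recording([spec], sample_rate=spec_params.sample_rate,
                               min_gap=0.005, seed=seed, pad=0.004)
    start, end, _ = rec.annotations[0]
    power = _stft_power(rec.waveform, spec_params)
    band = power[spec_params.band_bins(), :]
    n_frames = band.shape[1]
    t0 = np.arange(n_frames) * spec_params.hop / spec_params.sample_rate
    t1 = t0 + spec_params.nfft / spec_params.sample_rate
    keep = (t1 > start) & (t0 < end)
    gs = gs_transform(band[:, keep], bank, frame_hop=spec_params.hop_s,
                      label=spec.class_label)
    return gs.normalized().astype(np.float32)


def build_gs_dataset(n_per_class: int, seed: int,
                     classes=ALL_CLASSES,
                     snr_range: tuple[float, float] = (22.0, 35.0),
                     sample_rate: int = 300_000) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Return (images, integer labels, class names); fully seeded."""
    classes = list(classes)
    spec_params = SpectrogramParams(sample_rate=sample_rate)
    bank_params = FilterBankParams()
    bank = build_gammatone_bank(bank_params, spec_params)
    rng = np.random.default_rng(seed)
    images = []
    labels = []
    for ci, cls in enumerate(classes):
        for _ in range(n_per_class):
            spec = UsvSpec.random(cls, rng)
            if cls != "FP":
                spec = UsvSpec(**{**spec.__dict__,
                                  "amplitude_db": float(rng.uniform(*snr_range))})
            images.append(gs_for_spec(spec, int(rng.integers(2 ** 31)), bank,
                                      spec_params))
            labels.append(ci)
    x = np.stack(images)
    y = np.asarray(labels, dtype=np.int64)
    perm = np.random.default_rng(seed + 1).permutation(len(x))
    return x[perm], y[perm], classes


def train_test_split_stratified(x: np.ndarray, y: np.ndarray, test_frac: float,
                                seed: int) -> tuple:
    """Seeded stratified split preserving per-class proportions."""
    rng = np.random.default_rng(seed)
    test_idx = []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        n_test = max(1, int(round(test_frac * len(idx))))
        test_idx.append(rng.choice(idx, size=n_test, replace=False))
    test_idx = np.concatenate(test_idx)
    mask = np.zeros(len(y), dtype=bool)
    mask[test_idx] = True
    return x[~mask], y[~mask], x[mask], y[mask]


def stratified_kfold_indices(y: np.ndarray, n_folds: int, seed: int) -> list[np.ndarray]:
    """Per-fold test index arrays, stratified by class, seeded."""
    rng = np.random.default_rng(seed)
    folds = [[] for _ in range(n_folds)]
    for c in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == c))
        for i, chunk in enumerate(np.array_split(idx, n_folds)):
            folds[i].extend(chunk.tolist())
    return [np.sort(np.asarray(f)) for f in folds]
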