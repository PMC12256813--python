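"""Baseline comparison features: band powers, Hjorth parameters,
wavelet time-frequency descriptors, and PCA reduction.

These are the conventional spectral / time-frequency EEG features the
sink-index marker is benchmarked against:

* absolute band power in delta (1–4), theta (4–8), alpha (8–12) and beta
  (12–30 Hz), averaged within the FT and CPO electrode groups, plus the
  per-band FT/CPO ratio (the alpha ratio is the classification feature);
* Hjorth parameters — activity (variance), mobility (RMS frequency of the
  signal, in rad/sample), complexity (mobility of the derivative over
  mobility of the signal);
* a 5-level dyadic wavelet decomposition per channel over 8 s windows with
  50% overlap, with the Hjorth triplet computed on each detail subband:
  19 channels × 5 subbands × 3 parameters = 285 raw features, reduced to 5
  per subject by PCA fitted on training folds only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal
from sklearn.decomposition import PCA

from .exceptions import ConfigError, DegenerateInputError
from .io import Recording
from .sink import RegionScheme

BANDS = {"delta": (1.0, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 12.0), "beta": (12.0, 30.0)}
WAVELET_TEMPLATES = ("sym4", "coif2", "haar", "db4")
N_WAVELET_LEVELS = 5
N_HJORTH = 3


@dataclass
class BandPowerFeatures:
    ft_power: dict[str, float]
    cpo_power: dict[str, float]
    ratio: dict[str, float]


def _segment_starts(n_samples: int, win: int, hop: int) -> list[int]:
    if n_samples < win:
        raise DegenerateInputError(
            f"recording of {n_samples} samples shorter than one {win}-sample segment"
        )
    return list(range(0, n_samples - win + 1, hop))


def band_power(
    rec: Recording,
    scheme: RegionScheme | None = None,
    win_s: float = 8.0,
    overlap: float = 0.5,
) -> BandPowerFeatures:
    """Per-band mean power for the FT and CPO groups and their ratio.

    Power spectra are squared FFT magnitudes averaged over successive
    windows (Welch periodogram averaging with a Hann taper), integrated
    over each band.
    """
    scheme = scheme or RegionScheme()
    nperseg = int(round(win_s * rec.fs))
    noverlap = int(round(nperseg * overlap))
    if rec.n_samples < nperseg:
        raise DegenerateInputError("recording shorter than one analysis segment")
    freqs, psd = signal.welch(rec.data, fs=rec.fs, nperseg=nperseg, noverlap=noverlap, axis=1)

    labels = np.asarray(rec.channel_labels)
    ft_mask = np.isin(labels, list(scheme.ft_channels))
    cpo_mask = np.isin(labels, list(scheme.cpo_channels))

    ft_power, cpo_power, ratio = {}, {}, {}
    for band, (lo, hi) in BANDS.items():
        sel = (freqs >= lo) & (freqs < hi)
        chan_power = np.trapezoid(psd[:, sel], freqs[sel], axis=1)
        ft_power[band] = float(chan_power[ft_mask].mean())
        cpo_power[band] = float(chan_power[cpo_mask].mean())
        ratio[band] = ft_power[band] / cpo_power[band] if cpo_power[band] > 0 else np.nan
    return BandPowerFeatures(ft_power, cpo_power, ratio)


def hjorth(x: np.ndarray) -> tuple[float, float, float]:
    """Hjorth activity, mobility and complexity of a single-channel signal.

    activity = var(x); mobility = sqrt(var(Δx)/var(x));
    complexity = mobility(Δx)/mobility(x). For a pure tone of angular
    frequency ω rad/sample, mobility → ω and complexity → 1.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 3:
        raise DegenerateInputError("need at least 3 samples")
    var_x = float(np.var(x))
    if var_x <= 0:
        raise DegenerateInputError("zero-variance signal")
    dx = np.diff(x)
    ddx = np.diff(dx)
    var_dx = float(np.var(dx))
    var_ddx = float(np.var(ddx))
    mobility = np.sqrt(var_dx / var_x)
    mobility_dx = np.sqrt(var_ddx / var_dx) if var_dx > 0 else 0.0
    complexity = mobility_dx / mobility if mobility > 0 else 0.0
    return var_x, float(mobility), float(complexity)


def timefreq_features(
    rec: Recording,
    template: str = "db4",
    win_s: float = 8.0,
    overlap: float = 0.5,
) -> np.ndarray:
    """285-element wavelet/Hjorth feature vector (19ch × 5 subbands × 3).

    Per 8 s window (50% hop) and per channel, the signal is decomposed to 5
    dyadic levels; the Hjorth triplet is computed on each of the 5 detail
    subbands, then averaged across windows. Output is ordered
    channel-major: (channel, level, parameter).
    """
    if template not in WAVELET_TEMPLATES:
        raise ConfigError(f"unknown wavelet template {template!r}; use one of {WAVELET_TEMPLATES}")
    win = int(round(win_s * rec.fs))
    hop = int(round(win * (1.0 - overlap)))
    starts = _segment_starts(rec.n_samples, win, hop)

    n_ch = rec.n_channels
    acc = np.zeros((n_ch, N_WAVELET_LEVELS, N_HJORTH))
    for s in starts:
        seg = rec.data[:, s : s + win]
        for ci in range(n_ch):
            coeffs = pywt.wavedec(seg[ci], template, level=N_WAVELET_LEVELS)
            details = coeffs[1:]  # cD5 … cD1, coarsest first
            for li, d in enumerate(details):
                acc[ci, li] += np.asarray(hjorth(d))
    acc /= len(starts)
    return acc.reshape(-1)


def pca_reduce(
    train_features: np.ndarray,
    test_features: np.ndarray,
    k: int = 5,
) -> tuple[np.ndarray, np.ndarray, PCA]:
    """Project train and test feature matrices onto k components.

    The components are fitted on the training rows only (no test leakage)
    and are orthonormal.
    """
    train = np.atleast_2d(np.asarray(train_features, dtype=np.float64))
    test = np.atleast_2d(np.asarray(test_features, dtype=np.float64))
    if k > train.shape[1]:
        raise ConfigError(f"k={k} exceeds feature dimension {train.shape[1]}")
    if train.shape[0] < k:
        raise ConfigError(f"need at least k={k} training rows, got {train.shape[0]}")
    pca = PCA(n_components=k, svd_solver="full")
    reduced_train = pca.fit_transform(train)
    reduced_test = pca.transform(test)
    return reduced_train, reduced_test, pca
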