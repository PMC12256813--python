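"""Preprocessing chain: resample, band-pass, notch the line frequency.

The chain mirrors common clinical resting-state EEG practice: downsample
to 250 Hz (with the resampler's own anti-alias filtering), 0.5–48 Hz
Butterworth band-pass, then notch filters at the 50 Hz mains frequency and
every harmonic below Nyquist, each with a 2 Hz stopband. All filtering is
zero-phase (forward-backward second-order sections), so filter delays
cannot bias the windowed dynamic-model fits downstream.

Heavy artefact removal (ASR, ICA) is deliberately not reimplemented; an
``artefact_hook`` slot accepts an external cleaning callable and defaults
to identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable

import numpy as np
from scipy import signal

from .exceptions import ConfigError, DegenerateInputError
from .io import Recording


@dataclass
class PreprocessConfig:
    target_fs: float = 250.0
    bp_lo: float = 0.5
    bp_hi: float = 48.0
    notch_base: float = 50.0
    notch_stop_bw: float = 2.0
    filter_order: int = 4
    artefact_hook: Callable[[Recording], Recording] | None = None

    def validate(self) -> None:
        nyq = self.target_fs / 2
        if not 0 < self.bp_lo < self.bp_hi < nyq:
            raise ConfigError(
                f"band-pass {self.bp_lo}–{self.bp_hi} Hz invalid for Nyquist {nyq} Hz"
            )
        if not self.notch_base < nyq:
            raise ConfigError("notch base frequency at or above Nyquist")
        if self.filter_order < 1:
            raise ConfigError("filter order must be >= 1")


def notch_harmonics(cfg: PreprocessConfig) -> list[float]:
    """Line frequency and its harmonics strictly below Nyquist."""
    nyq = cfg.target_fs / 2
    freqs = []
    f = cfg.notch_base
    while f + cfg.notch_stop_bw / 2 < nyq:
        freqs.append(f)
        f += cfg.notch_base
    return freqs


def _resample(data: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    frac = Fraction(target_fs / fs).limit_denominator(1000)
    return signal.resample_poly(data, frac.numerator, frac.denominator, axis=1)


def preprocess(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Apply resample → band-pass → notch (→ artefact hook) to a recording."""
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    if rec.fs < cfg.target_fs:
        raise ConfigError(
            f"cannot upsample: recording at {rec.fs} Hz below target {cfg.target_fs} Hz"
        )

    min_len = 10 * 3 * cfg.filter_order  # rough filter length bound for filtfilt padding
    if rec.n_samples < min_len:
        raise DegenerateInputError(
            f"recording of {rec.n_samples} samples too short to filter"
        )

    duration = rec.duration_s
    # demean first: a large DC offset would otherwise leak through the
    # high-pass as filtfilt edge transients
    data = rec.data - rec.data.mean(axis=1, keepdims=True)
    if rec.fs != cfg.target_fs:
        data = _resample(data, rec.fs, cfg.target_fs)
    expected = int(round(duration * cfg.target_fs))
    data = data[:, :expected]

    sos_bp = signal.butter(
        cfg.filter_order,
        [cfg.bp_lo, cfg.bp_hi],
        btype="bandpass",
        fs=cfg.target_fs,
        output="sos",
    )
    data = signal.sosfiltfilt(sos_bp, data, axis=1)

    for f0 in notch_harmonics(cfg):
        sos_notch = signal.butter(
            cfg.filter_order,
            [f0 - cfg.notch_stop_bw / 2, f0 + cfg.notch_stop_bw / 2],
            btype="bandstop",
            fs=cfg.target_fs,
            output="sos",
        )
        data = signal.sosfiltfilt(sos_notch, data, axis=1)

    # remove the residual sample mean left by filter edge transients: the
    # pass band starts at bp_lo, so true content below it is already gone
    data = data - data.mean(axis=1, keepdims=True)

    out = Recording(rec.subject_id, list(rec.channel_labels), cfg.target_fs, data)
    if cfg.artefact_hook is not None:
        out = cfg.artefact_hook(out)
    return out
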