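"""Preprocessing chain for 1 s sEMG analysis windows.

Order of operations: slice into non-overlapping 1 s windows, remove a
degree-<=4 polynomial trend per channel, zero-phase 4th-order Butterworth
high-pass at 10 Hz (baseline drift and 1-10 Hz motion artifacts), adaptive
spectral notch of 50 Hz powerline interference and its harmonics, then reject
any window whose absolute amplitude exceeds 2000 uV on any channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, StageOrderError
from .synthetic_data import RawRecording

logger = logging.getLogger(__name__)

STAGES = ("raw", "detrended", "highpassed", "notched")


@dataclass
class PreprocessConfig:
    window_length: float = 1.0  # s
    window_stride: float = 1.0  # s (equal to length: non-overlapping)
    detrend_degree: int = 4
    hp_cutoff: float = 10.0  # Hz
    hp_order: int = 4
    notch_base: float = 50.0  # Hz
    notch_max: float = 450.0  # Hz, highest harmonic considered
    #: Notch triggers when centre-band mean magnitude exceeds this multiple
    #: of the flanking-band median.
    notch_threshold_ratio: float = 2.0
    amp_threshold: float = 2000.0  # uV
    #: Apply amplitude rejection per 1 s window (True) or drop the whole
    #: recording when any window trips (False).
    reject_per_window: bool = True

    def __post_init__(self) -> None:
        if self.window_length <= 0 or self.window_stride <= 0:
            raise ConfigError("window length and stride must be positive")
        if self.amp_threshold <= 0:
            raise ConfigError("amp_threshold must be positive")
        if self.detrend_degree > 4:
            raise ConfigError("detrend degree must be <= 4")


@dataclass
class WindowSample:
    """One 1 s, multichannel segment in uV with label and provenance."""

    samples: np.ndarray  # [n_channels x L]
    fs: float
    label: str
    provenance: dict = field(default_factory=dict)
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.stage not in STAGES:
            raise ConfigError(f"unknown stage {self.stage!r}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def length(self) -> int:
        return self.samples.shape[1]


def _require_stage(window: WindowSample, expected: str) -> None:
    if window.stage != expected:
        raise StageOrderError(
            f"expected a {expected!r} window, got {window.stage!r}"
        )


def slice_windows(recording: RawRecording, config: PreprocessConfig) -> list[WindowSample]:
    """Cut a recording into windows in temporal order.

    Stride defaults to the window length (non-overlapping); a trailing
    partial window is discarded.
    """
    L = round(config.window_length * recording.fs)
    stride = round(config.window_stride * recording.fs)
    T = recording.samples.shape[1]
    windows: list[WindowSample] = []
    idx = 0
    for start in range(0, T - L + 1, stride):
        windows.append(
            WindowSample(
                samples=recording.samples[:, start : start + L].copy(),
                fs=recording.fs,
                label=recording.taste,
                provenance={
                    "participant": recording.participant_id,
                    "session": recording.session_id,
                    "trial": recording.trial,
                    "window": idx,
                    "start_sample": start,
                },
                stage="raw",
            )
        )
        idx += 1
    if not windows:
        logger.warning(
            "recording shorter than one window (%d < %d samples): no windows", T, L
        )
    return windows


def detrend_poly(window: WindowSample, degree: int = 4) -> WindowSample:
    """Subtract a least-squares polynomial trend per channel.

    The fit uses a time axis normalized to [-1, 1] for conditioning, so any
    input that is itself a degree-<=``degree`` polynomial is annihilated to
    numerical precision.
    """
    _require_stage(window, "raw")
    if degree > 4:
        raise ConfigError("trend degree must be <= 4")
    if not np.all(np.isfinite(window.samples)):
        raise ConfigError("window contains non-finite values")
    L = window.length
    t = np.linspace(-1.0, 1.0, L)
    V = np.polynomial.polynomial.polyvander(t, degree)
    coeffs, *_ = np.linalg.lstsq(V, window.samples.T, rcond=None)
    detrended = window.samples - (V @ coeffs).T
    return replace(window, samples=detrended, stage="detrended")


def highpass_butterworth(
    window: WindowSample, cutoff: float = 10.0, order: int = 4
) -> WindowSample:
    """Zero-phase Butterworth high-pass (forward and reverse passes).

    The effective magnitude response is the squared one-pass response, so
    attenuation in the stopband is doubled in dB and the passband stays
    maximally flat.  Initial conditions use Gustafsson's method, which
    minimizes the edge transients that default padding produces on short
    (1 s) windows of oscillatory signal.
    """
    _require_stage(window, "detrended")
    if cutoff >= window.fs / 2:
        raise ConfigError(f"cutoff {cutoff} Hz >= Nyquist {window.fs / 2} Hz")
    b, a = sps.butter(order, cutoff, btype="highpass", fs=window.fs)
    filtered = sps.filtfilt(b, a, window.samples, axis=1, method="gust")
    return replace(window, samples=filtered, stage="highpassed")


def _notch_channel(
    x: np.ndarray, fs: float, config: PreprocessConfig
) -> np.ndarray:
    spectrum = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), 1.0 / fs)
    mags = np.abs(spectrum)
    f0 = config.notch_base
    while f0 <= min(config.notch_max, fs / 2 - 1e-9):
        centre = np.abs(freqs - f0) <= 1.0
        flank = (np.abs(freqs - f0) >= 2.0) & (np.abs(freqs - f0) <= 10.0)
        if centre.any() and flank.any():
            c = mags[centre].mean()
            b = np.median(mags[flank])
            if c > config.notch_threshold_ratio * b:
                idx = np.where(centre)[0]
                nonzero = mags[idx] > 0
                spectrum[idx[nonzero]] *= b / mags[idx[nonzero]]
        f0 += config.notch_base
    return np.fft.irfft(spectrum, n=len(x))


def adaptive_notch(window: WindowSample, config: PreprocessConfig) -> WindowSample:
    """Adaptive spectral notch of the powerline frequency and harmonics.

    For each target frequency (50, 100, ... up to ``notch_max`` Hz) and
    channel, the mean DFT magnitude in the +-1 Hz centre band is compared to
    the median magnitude over the +-2..10 Hz flanks; when the centre exceeds
    ``notch_threshold_ratio`` times the flank level, the centre coefficients
    are rescaled to the flank magnitude, preserving phase.  Untouched spectra
    pass through bit-for-bit up to the DFT round trip.
    """
    _require_stage(window, "highpassed")
    out = np.vstack(
        [_notch_channel(window.samples[ch], window.fs, config) for ch in range(window.n_channels)]
    )
    return replace(window, samples=out, stage="notched")


def reject_abnormal(
    windows: list[WindowSample], amp_threshold: float = 2000.0
) -> tuple[list[WindowSample], list[WindowSample]]:
    """Partition windows into (kept, dropped) by peak absolute amplitude.

    A window is kept iff every channel stays within +-``amp_threshold`` uV.
    Sample values are never modified.
    """
    kept: list[WindowSample] = []
    dropped: list[WindowSample] = []
    for w in windows:
        if np.max(np.abs(w.samples)) <= amp_threshold:
            kept.append(w)
        else:
            dropped.append(w)
    for w in dropped:
        logger.info("rejected window %s: |amplitude| > %g uV", w.provenance, amp_threshold)
    return kept, dropped


def preprocess_pipeline(
    recording: RawRecording, config: PreprocessConfig | None = None
) -> list[WindowSample]:
    """slice -> detrend -> high-pass -> notch -> reject; returns kept windows."""
    kept, _ = preprocess_pipeline_full(recording, config)
    return kept


def preprocess_pipeline_full(
    recording: RawRecording, config: PreprocessConfig | None = None
) -> tuple[list[WindowSample], list[WindowSample]]:
    """Full pipeline returning both kept and rejected windows."""
    config = config or PreprocessConfig()
    windows = slice_windows(recording, config)
    processed = []
    for w in windows:
        w = detrend_poly(w, config.detrend_degree)
        w = highpass_butterworth(w, config.hp_cutoff, config.hp_order)
        w = adaptive_notch(w, config)
        processed.append(w)
    if config.reject_per_window:
        kept, dropped = reject_abnormal(processed, config.amp_threshold)
    else:
        kept, dropped = reject_abnormal(processed, config.amp_threshold)
        if dropped:
            dropped = processed
            kept = []
    logger.info(
        "preprocessed %s/%s/%s: %d windows sliced, %d kept, %d rejected",
        recording.participant_id,
        recording.session_id,
        recording.taste,
        len(windows),
        len(kept),
        len(dropped),
    )
    return kept, dropped
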