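"""Per-window feature extraction: 21 features per channel, 126 per window.

Per channel the feature vector holds, in order:

* F1-F13   spectrum average amplitudes over the 13 bands (nine 10 Hz bands
           from 10-100 Hz, four 100 Hz bands from 100-500 Hz),
* F14      frequency centroid (FC),
* F15      magnitude-weighted second moment of frequency about zero ("RMSF",
           implemented as printed in the source formulas, without the root),
* F16      magnitude-weighted variance of frequency about the centroid
           ("RVF", likewise without the root),
* F17-F21  time-domain RMS, zero-crossing statistic (sign-change count / 10),
           MAV, kurtosis and skewness (population moments).

Spectral features use the unnormalized one-sided magnitude of the length-L
DFT; at the default 1000 Hz / 1 s window the bin width is exactly 1 Hz so bin
index equals frequency in Hz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, FeatureUndefinedError
from .preprocessing import WindowSample
from .synthetic_data import BAND_EDGES, N_BANDS

logger = logging.getLogger(__name__)

N_FEATURE_TYPES = 21
#: Feature-type names in vector order (F1..F21).
FEATURE_TYPE_NAMES: tuple[str, ...] = tuple(
    [f"band_{int(BAND_EDGES[b])}_{int(BAND_EDGES[b + 1])}" for b in range(N_BANDS)]
    + ["FC", "RMSF", "RVF", "RMS", "ZCR", "MAV", "Ku", "Sk"]
)


@dataclass
class SpectrumView:
    """One-sided DFT magnitude of one channel of one window."""

    magnitudes: np.ndarray  # f(i), i = 0..L/2
    bin_width: float  # Hz, fs / L
    channel: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if np.any(self.magnitudes < 0):
            raise ConfigError("spectrum magnitudes must be non-negative")

    @property
    def freqs(self) -> np.ndarray:
        return np.arange(len(self.magnitudes)) * self.bin_width


@dataclass
class ChannelMoments:
    """Mean and population standard deviation (divisor L) of a channel."""

    mu: float
    sigma: float


def compute_spectrum(x: np.ndarray, fs: float, channel: int = 0, provenance: dict | None = None) -> SpectrumView:
    """Unnormalized one-sided DFT magnitude f(i), i = 0..L/2."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ConfigError("channel samples contain non-finite values")
    mags = np.abs(np.fft.rfft(x))
    return SpectrumView(
        magnitudes=mags,
        bin_width=fs / len(x),
        channel=channel,
        provenance=provenance or {},
    )


def band_average_features(spec: SpectrumView) -> np.ndarray:
    """Mean spectrum magnitude per band, F1..F13.

    Bands are defined in Hz; at 1 Hz bin width band n averages bins
    10n..10(n+1)-1 (n <= 9) and 100(n-9)..100(n-8)-1 (n >= 10).
    """
    if spec.freqs[-1] < BAND_EDGES[-1] - spec.bin_width:
        raise ConfigError(
            f"spectrum reaches only {spec.freqs[-1]:g} Hz; bands need "
            f"{BAND_EDGES[-1]:g} Hz"
        )
    freqs = spec.freqs
    out = np.empty(N_BANDS)
    for b in range(N_BANDS):
        mask = (freqs >= BAND_EDGES[b]) & (freqs < BAND_EDGES[b + 1])
        out[b] = spec.magnitudes[mask].mean()
    return out


def spectral_moment_features(spec: SpectrumView, apply_root: bool = False) -> np.ndarray:
    """F14..F16: centroid, second moment about zero, variance about centroid.

    Sums run over bins 1..L/2 (DC excluded).  ``apply_root`` optionally takes
    the square root of the second-moment features, which their conventional
    names suggest; the default keeps the plain printed form.
    """
    f = spec.magnitudes[1:]
    freqs = spec.freqs[1:]
    total = f.sum()
    if total <= 0:
        raise FeatureUndefinedError("zero spectrum: frequency centroid undefined")
    fc = float((f * freqs).sum() / total)
    m2 = float((f * freqs**2).sum() / total)
    var = float((f * (freqs - fc) ** 2).sum() / total)
    if apply_root:
        m2, var = np.sqrt(m2), np.sqrt(var)
    return np.array([fc, m2, var])


def channel_moments(x: np.ndarray) -> ChannelMoments:
    x = np.asarray(x, dtype=float)
    return ChannelMoments(mu=float(x.mean()), sigma=float(x.std()))


def time_features(x: np.ndarray) -> np.ndarray:
    """F17..F21: RMS, ZCR, MAV, kurtosis, skewness.

    ZCR is the strict sign-change count divided by 10 (as printed in the
    source formulation for the 1000-sample window).  Kurtosis and skewness
    use population moments and are undefined for constant input.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ConfigError("need at least two samples")
    rms = float(np.sqrt(np.mean(x**2)))
    zcr = float(np.count_nonzero(x[:-1] * x[1:] < 0) / 10.0)
    mav = float(np.mean(np.abs(x)))
    mom = channel_moments(x)
    if mom.sigma == 0:
        raise FeatureUndefinedError("zero variance: kurtosis/skewness undefined")
    z = (x - mom.mu) / mom.sigma
    ku = float(np.mean(z**4))
    sk = float(np.mean(z**3))
    return np.array([rms, zcr, mav, ku, sk])


@dataclass
class FeatureVector:
    """Channel-major feature row: ch1 F1..F21, ch2 F1..F21, ..."""

    values: np.ndarray
    label: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ConfigError("feature vector contains non-finite values")


def feature_names(n_channels: int = 6) -> list[str]:
    """Column names ch{c}_F{n} in vector order."""
    return [f"ch{c + 1}_F{n + 1}" for c in range(n_channels) for n in range(N_FEATURE_TYPES)]


def extract_features(window: WindowSample, apply_root: bool = False) -> FeatureVector:
    """Full per-window vector: n_channels x 21 values, channel-major.

    Raises FeatureUndefinedError when any channel has a zero spectrum or zero
    variance; callers building tables exclude such windows with a logged
    reason.
    """
    parts = []
    for ch in range(window.n_channels):
        x = window.samples[ch]
        spec = compute_spectrum(x, window.fs, channel=ch, provenance=window.provenance)
        parts.append(
            np.concatenate(
                [
                    band_average_features(spec),
                    spectral_moment_features(spec, apply_root=apply_root),
                    time_features(x),
                ]
            )
        )
    return FeatureVector(
        values=np.concatenate(parts), label=window.label, provenance=dict(window.provenance)
    )


def extract_feature_table(windows: list[WindowSample], apply_root: bool = False) -> pd.DataFrame:
    """Feature matrix for a window collection as a tidy DataFrame.

    Columns: ch{c}_F{n} per feature, plus label / participant / session /
    trial / window provenance.  Windows with undefined features are excluded
    and logged.
    """
    rows = []
    n_excluded = 0
    for w in windows:
        try:
            fv = extract_features(w, apply_root=apply_root)
        except FeatureUndefinedError as exc:
            n_excluded += 1
            logger.warning("excluding window %s: %s", w.provenance, exc)
            continue
        row = dict(zip(feature_names(w.n_channels), fv.values))
        row["label"] = fv.label
        row["participant"] = fv.provenance.get("participant")
        row["session"] = fv.provenance.get("session")
        row["trial"] = fv.provenance.get("trial")
        row["window"] = fv.provenance.get("window")
        rows.append(row)
    if n_excluded:
        logger.info("excluded %d window(s) with undefined features", n_excluded)
    return pd.DataFrame(rows)
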