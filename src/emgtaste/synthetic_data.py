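"""Synthetic facial-sEMG generator.

Produces labelled multichannel recordings with the statistical structure the
downstream analysis assumes: a stationary Gaussian EMG component shaped in the
frequency domain by a per-taste band-amplitude profile, slow polynomial
baseline drift, 50 Hz powerline interference with decaying odd harmonics,
band-limited (1-10 Hz) motion artifacts, and occasional high-amplitude
electrode bursts beyond the +-2000 uV acceptance range.

Band profiles are expressed in the same units the feature extractor measures:
the expected one-sided DFT magnitude (in uV, unnormalized length-L transform)
of a 1 s analysis window within each band.  For a stationary Gaussian process
the window-DFT magnitude at a bin is Rayleigh distributed; synthesis therefore
scales the trial-length spectrum so that the Rayleigh *mean* per bin equals
the configured profile value.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .errors import ConfigError

logger = logging.getLogger(__name__)

#: Six-state electronic-taste label set (legend order: no taste, sour,
#: sprite, bitter, mint, salty).
TASTES_6: tuple[str, ...] = ("no", "sr", "sp", "bt", "mt", "st")
#: Four-state set used when comparing electronic against actual tastants.
TASTES_4: tuple[str, ...] = ("no", "sr", "bt", "st")

#: Spectral band edges (Hz) shared with the feature extractor: nine 10 Hz
#: intervals from 10-100 Hz, then four 100 Hz intervals up to 500 Hz.
BAND_EDGES: tuple[float, ...] = (10, 20, 30, 40, 50, 60, 70, 80, 90, 100, 200, 300, 400, 500)
N_BANDS = len(BAND_EDGES) - 1

# Internal keys that decorrelate the per-purpose RNG streams spawned from the
# root seed (arbitrary constants, fixed forever for reproducibility).
_KEY_TRIAL = 0x7A11
_KEY_PARTICIPANT = 0x9E7E


def make_band_profiles(
    tastes: Sequence[str] = TASTES_6,
    low_amp: float = 900.0,
    high_amp: float = 120.0,
    separation: float = 0.25,
) -> dict[str, np.ndarray]:
    """Build per-taste band-amplitude profiles (uV window-DFT magnitude).

    Energy is concentrated below 100 Hz: the nine low bands start near
    ``low_amp`` and decay gently, the four bands above 100 Hz near
    ``high_amp``.  Each taste modulates a deterministic pair of low bands by
    ``(1 + separation)`` (and damps a third), so ``separation`` controls class
    separability: 0 gives identical classes, large values nearly disjoint
    ones.
    """
    base = np.concatenate(
        [
            low_amp * (1.0 - 0.06 * np.arange(9)),
            high_amp * 0.9 ** np.arange(4),
        ]
    )
    profiles: dict[str, np.ndarray] = {}
    for t, taste in enumerate(tastes):
        prof = base.copy()
        prof[t % 9] *= 1.0 + separation
        prof[(3 * t + 2) % 9] *= 1.0 + separation
        prof[(t + 4) % 9] /= 1.0 + separation
        profiles[taste] = prof
    return profiles


@dataclass
class SynthConfig:
    """Study-design and signal-model parameters for the generator.

    Defaults mirror the acquisition protocol the pipeline targets: 8
    participants, 4 sessions, six taste states, 8 s trials sampled at
    1000 Hz on 6 channels.
    """

    n_participants: int = 8
    tastes: tuple[str, ...] = TASTES_6
    trials_per_taste_per_session: int = 1
    sessions: int = 4
    trial_duration: float = 8.0
    fs: float = 1000.0
    n_channels: int = 6
    #: Per-taste expected window-DFT band magnitude (uV), 13 bands 10-500 Hz.
    class_band_profiles: dict[str, np.ndarray] | None = None
    #: Log-normal sigma of the per-participant multiplicative band
    #: perturbation; 0 makes participants exchangeable.
    participant_heterogeneity: float = 0.3
    #: Std dev (uV) of the i.i.d. coefficients of the degree-4 drift
    #: polynomial on a [-1, 1] time axis.
    drift_coeff_scale: float = 300.0
    powerline_amp: float = 20.0
    #: Number of odd harmonics: 1 -> 50 Hz only, 3 -> 50/150/250 Hz.
    powerline_harmonics: int = 3
    artifact_band: tuple[float, float] = (1.0, 10.0)
    #: RMS amplitude (uV) of the band-limited motion artifact.
    artifact_amp: float = 30.0
    #: Probability that a trial contains one >2000 uV burst.
    outlier_prob: float = 0.02
    drift_degree: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigError("fs must be positive")
        n = self.trial_duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ConfigError(
                f"trial_duration x fs = {n} is not an integer sample count"
            )
        if not 0.0 <= self.outlier_prob <= 1.0:
            raise ConfigError("outlier_prob must lie in [0, 1]")
        if self.participant_heterogeneity < 0:
            raise ConfigError("participant_heterogeneity must be >= 0")
        if self.n_participants < 1 or self.sessions < 1:
            raise ConfigError("need at least one participant and one session")
        if self.class_band_profiles is None:
            self.class_band_profiles = make_band_profiles(self.tastes)
        for taste in self.tastes:
            if taste not in self.class_band_profiles:
                raise ConfigError(f"taste {taste!r} has no band profile")
            prof = np.asarray(self.class_band_profiles[taste], dtype=float)
            if prof.shape != (N_BANDS,):
                raise ConfigError(
                    f"band profile for {taste!r} must have {N_BANDS} entries"
                )
            self.class_band_profiles[taste] = prof

    @property
    def n_samples(self) -> int:
        return round(self.trial_duration * self.fs)

    def participant_ids(self) -> list[str]:
        return [f"P{i + 1}" for i in range(self.n_participants)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["class_band_profiles"] = {
            k: np.asarray(v).tolist() for k, v in self.class_band_profiles.items()
        }
        d["tastes"] = list(self.tastes)
        d["artifact_band"] = list(self.artifact_band)
        return d


@dataclass
class RawRecording:
    """One trial: ``samples`` is an [n_channels x T] array in uV."""

    samples: np.ndarray
    fs: float
    participant_id: str
    session_id: int
    taste: str
    duration: float
    trial: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ConfigError("samples must be a 2-D [channels x time] array")
        if self.samples.shape[1] != round(self.duration * self.fs):
            raise ConfigError("sample count does not match duration x fs")
        if not np.all(np.isfinite(self.samples)):
            raise ConfigError("recording contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]


def participant_index(participant_id: str | int) -> int:
    """Map a participant id ('P3' or 3-like) to a 0-based index."""
    if isinstance(participant_id, (int, np.integer)):
        return int(participant_id)
    s = str(participant_id)
    if s.startswith("P"):
        s = s[1:]
    try:
        return int(s) - 1
    except ValueError as exc:
        raise ConfigError(f"cannot parse participant id {participant_id!r}") from exc


def participant_band_multipliers(config: SynthConfig, participant_id: str | int) -> np.ndarray:
    """Per-participant multiplicative band perturbation (log-normal).

    Deterministic in (config.seed, participant); all ones when
    ``participant_heterogeneity`` is zero.
    """
    if config.participant_heterogeneity == 0:
        return np.ones(N_BANDS)
    idx = participant_index(participant_id)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _KEY_PARTICIPANT, idx])
    )
    return np.exp(rng.normal(0.0, config.participant_heterogeneity, N_BANDS))


def _band_amplitude_per_bin(freqs: np.ndarray, profile: np.ndarray) -> np.ndarray:
    """Map each DFT-bin frequency to its band's profile amplitude (0 outside)."""
    amp = np.zeros_like(freqs)
    for b in range(N_BANDS):
        lo, hi = BAND_EDGES[b], BAND_EDGES[b + 1]
        amp[(freqs >= lo) & (freqs < hi)] = profile[b]
    return amp


def _synth_emg(
    rng: np.random.Generator,
    profile: np.ndarray,
    n_samples: int,
    fs: float,
    window_len: int,
) -> np.ndarray:
    """One channel of stationary Gaussian EMG with the given band profile.

    Random-phase/random-amplitude inverse-DFT synthesis.  The trial-spectrum
    scale is chosen so that the mean one-sided DFT magnitude of a
    ``window_len``-sample analysis window equals the profile per band:
    E|X_k|^2 = (4/pi) * B^2 * T / L makes the window-bin magnitude Rayleigh
    with mean B.
    """
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    bin_amp = _band_amplitude_per_bin(freqs, profile)
    scale = np.sqrt(4.0 * n_samples / (np.pi * window_len))
    z = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    spectrum = bin_amp * scale * z / np.sqrt(2.0)
    spectrum[0] = 0.0
    if n_samples % 2 == 0:
        spectrum[-1] = spectrum[-1].real  # Nyquist bin must be real
    return np.fft.irfft(spectrum, n=n_samples)


def _synth_artifact(
    rng: np.random.Generator,
    band: tuple[float, float],
    amp_rms: float,
    n_samples: int,
    fs: float,
) -> np.ndarray:
    """Band-limited motion-artifact noise with the requested RMS."""
    white = rng.standard_normal(n_samples)
    if amp_rms == 0:
        return np.zeros(n_samples)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(x**2))
    return x * (amp_rms / rms) if rms > 0 else x


def generate_recording(
    config: SynthConfig,
    participant_id: str | int,
    session_id: int,
    taste: str,
    rng_state: int | np.random.SeedSequence | np.random.Generator,
    trial: int = 0,
) -> RawRecording:
    """Synthesize one labelled trial.

    The recording is the sum of the band-shaped EMG component (per-taste
    profile scaled by the participant's heterogeneity multipliers), a
    degree-<=4 polynomial drift, powerline sinusoids at 50 Hz and decaying odd
    harmonics (common across channels), band-limited motion artifact, and --
    with probability ``outlier_prob`` -- a 50 ms half-sine burst of
    2500-5000 uV confined to a single 1 s analysis window of one channel.
    Bitwise deterministic for a fixed ``rng_state``.
    """
    if taste not in config.tastes:
        raise ConfigError(f"unknown taste {taste!r}; configured: {config.tastes}")
    rng = np.random.default_rng(rng_state)
    T = config.n_samples
    fs = config.fs
    window_len = round(fs)  # 1 s analysis window defines the profile units
    profile = config.class_band_profiles[taste] * participant_band_multipliers(
        config, participant_id
    )

    samples = np.empty((config.n_channels, T))
    t_norm = np.linspace(-1.0, 1.0, T)
    t_sec = np.arange(T) / fs

    # Powerline interference is common-mode: identical on every channel.
    powerline = np.zeros(T)
    for m in range(1, config.powerline_harmonics + 1):
        k = 2 * m - 1  # odd harmonic order: 50, 150, 250 Hz ...
        f0 = k * 50.0
        phase = rng.uniform(0.0, 2.0 * np.pi)
        powerline += (config.powerline_amp / k) * np.sin(2.0 * np.pi * f0 * t_sec + phase)

    for ch in range(config.n_channels):
        emg = _synth_emg(rng, profile, T, fs, window_len)
        coeffs = rng.normal(0.0, config.drift_coeff_scale, config.drift_degree + 1)
        drift = np.polynomial.polynomial.polyval(t_norm, coeffs)
        artifact = _synth_artifact(rng, config.artifact_band, config.artifact_amp, T, fs)
        samples[ch] = emg + drift + powerline + artifact

    if rng.random() < config.outlier_prob:
        burst_len = max(2, round(0.05 * fs))
        n_windows = T // window_len
        ch = rng.integers(config.n_channels)
        w = rng.integers(max(1, n_windows))
        offset = w * window_len + rng.integers(window_len - burst_len + 1)
        amp = rng.uniform(2500.0, 5000.0) * rng.choice([-1.0, 1.0])
        n = np.arange(burst_len)
        # Half-sine envelope on an 80 Hz carrier: the excursion sits in the
        # filter passband, so it survives detrending and the 10 Hz high-pass
        # and reliably trips the downstream amplitude rejection.
        burst = amp * np.sin(np.pi * n / burst_len) * np.sin(2.0 * np.pi * 80.0 * n / fs)
        samples[ch, offset : offset + burst_len] += burst

    return RawRecording(
        samples=samples,
        fs=fs,
        participant_id=f"P{participant_index(participant_id) + 1}",
        session_id=int(session_id),
        taste=taste,
        duration=config.trial_duration,
        trial=trial,
    )


def trial_seed_sequence(config: SynthConfig, p: int, s: int, t: int, trial: int) -> np.random.SeedSequence:
    """Deterministic per-trial seed derived from the root seed and grid indices."""
    return np.random.SeedSequence([config.seed, _KEY_TRIAL, p, s, t, trial])


def build_manifest(config: SynthConfig) -> dict:
    """Enumerate the full provenance grid without synthesizing any signal.

    The manifest's config snapshot suffices to regenerate the dataset
    bitwise; its summary records the session/trial arithmetic of the design
    (participant-experiments x sessions x tastes x trials).
    """
    trials = []
    for p, pid in enumerate(config.participant_ids()):
        for s in range(config.sessions):
            for t, taste in enumerate(config.tastes):
                for k in range(config.trials_per_taste_per_session):
                    trials.append(
                        {
                            "participant": pid,
                            "session": s + 1,
                            "taste": taste,
                            "trial": k + 1,
                            "seed_key": [config.seed, _KEY_TRIAL, p, s, t, k],
                            "path": None,
                        }
                    )
    n_sessions = config.n_participants * config.sessions
    return {
        "schema_version": 1,
        "config": config.to_dict(),
        "participant_band_multipliers": {
            pid: participant_band_multipliers(config, pid).tolist()
            for pid in config.participant_ids()
        },
        "summary": {
            "n_experiments": config.n_participants,
            "n_sessions": n_sessions,
            "n_recordings": len(trials),
            "trials_per_session": len(config.tastes) * config.trials_per_taste_per_session,
        },
        "trials": trials,
    }


def generate_dataset(config: SynthConfig) -> tuple[list[RawRecording], dict]:
    """Generate one recording per (participant, session, taste, trial).

    Returns the recordings in manifest order together with the manifest.
    Reproducible bitwise for a fixed ``config.seed``.
    """
    manifest = build_manifest(config)
    recordings: list[RawRecording] = []
    for rec in manifest["trials"]:
        p = participant_index(rec["participant"])
        s = rec["session"] - 1
        t = config.tastes.index(rec["taste"])
        k = rec["trial"] - 1
        recordings.append(
            generate_recording(
                config,
                rec["participant"],
                rec["session"],
                rec["taste"],
                trial_seed_sequence(config, p, s, t, k),
                trial=rec["trial"],
            )
        )
    logger.info(
        "generated %d recordings (%d participants x %d sessions x %d tastes x %d trials)",
        len(recordings),
        config.n_participants,
        config.sessions,
        len(config.tastes),
        config.trials_per_taste_per_session,
    )
    return recordings, manifest
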