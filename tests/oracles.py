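"""Independent brute-force oracles for the per-channel features.

Literal loop transcriptions of the defining formulas, kept deliberately
separate from the package implementation: spectra come from the plain DFT
magnitude, and every feature below is computed with explicit Python loops.
"""

import math

import numpy as np


def oracle_spectrum(x):
    """One-sided DFT magnitude f(i), i = 0..L/2 (unnormalized)."""
    return np.abs(np.fft.rfft(np.asarray(x, dtype=float)))


def oracle_band_averages(f):
    """F[1..13]: mean magnitude over 10 Hz bands 10-100 and 100 Hz bands 100-500."""
    out = []
    for n in range(1, 10):
        s = 0.0
        for i in range(n * 10, (n + 1) * 10):
            s += f[i]
        out.append(s / 10.0)
    for n in range(10, 14):
        s = 0.0
        for i in range((n - 9) * 100, (n - 8) * 100):
            s += f[i]
        out.append(s / 100.0)
    return out


def oracle_spectral_moments(f, fs, L):
    """F[14..16]: centroid, second moment about zero, variance about centroid."""
    num_fc = den = 0.0
    for i in range(1, L // 2 + 1):
        num_fc += f[i] * (i * fs / L)
        den += f[i]
    fc = num_fc / den
    m2 = 0.0
    var = 0.0
    for i in range(1, L // 2 + 1):
        m2 += f[i] * (i * fs / L) ** 2
        var += f[i] * (i * fs / L - fc) ** 2
    return [fc, m2 / den, var / den]


def oracle_time_features(x):
    """F[17..21]: RMS, ZCR (sign changes / 10), MAV, kurtosis, skewness."""
    L = len(x)
    s2 = 0.0
    for xi in x:
        s2 += xi * xi
    rms = math.sqrt(s2 / L)
    zc = 0
    for i in range(L - 1):
        if x[i] * x[i + 1] < 0:
            zc += 1
    zcr = zc / 10.0
    sa = 0.0
    for xi in x:
        sa += abs(xi)
    mav = sa / L
    mu = 0.0
    for xi in x:
        mu += xi
    mu /= L
    var = 0.0
    for xi in x:
        var += (xi - mu) ** 2
    sigma = math.sqrt(var / L)
    ku = 0.0
    sk = 0.0
    for xi in x:
        z = (xi - mu) / sigma
        ku += z**4
        sk += z**3
    return [rms, zcr, mav, ku / L, sk / L]


def oracle_channel_features(x, fs):
    """All 21 features of one channel in vector order."""
    x = np.asarray(x, dtype=float)
    f = oracle_spectrum(x)
    L = len(x)
    return (
        oracle_band_averages(f)
        + oracle_spectral_moments(f, fs, L)
        + oracle_time_features(x)
    )
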