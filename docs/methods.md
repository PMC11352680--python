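# Methods

## Signal model of the synthetic generator

Each trial is the sum of five components on 6 channels, 8 s at 1000 Hz, in μV.

**EMG component.** A stationary Gaussian process shaped in the frequency
domain by a per-taste band profile over 13 bands (nine 10 Hz bands from
10–100 Hz, four 100 Hz bands from 100–500 Hz; zero outside). Profiles are
stated in the units the feature extractor measures: the expected one-sided
DFT magnitude of a 1 s window. For stationary Gaussian noise the window-DFT
magnitude at a bin is Rayleigh; synthesis therefore draws trial-spectrum
coefficients with E|X_k|² = (4/π)·B²·T/L so the Rayleigh *mean* per window
bin equals the profile value B (T trial samples, L = 1000 window samples).
The tests verify the calibration to 5 % per band over ≥100 windows. Default
profiles put ~900 μV (window-DFT units) in the low bands decaying to
~120 μV above 100 Hz — about 20 μV RMS per channel, a plausible scale for
relaxed facial muscle and comfortably inside the ±2000 μV acceptance range.
Each taste multiplies a deterministic pair of low bands by (1 + separation)
and damps a third; `separation` (default 0.25) is the class-separability
dial, 0 giving identical classes.

**Participant heterogeneity.** Per participant, a log-normal multiplier
exp(N(0, σ²)) per band, σ = `participant_heterogeneity` (default 0.3),
identical across that participant's sessions and tastes. σ = 0 makes
participants exchangeable (verified by two-sample KS tests over all 126
features); large σ makes the class geometry participant-specific, which is
what drives accuracy down as participants are pooled.

**Drift.** A degree-4 polynomial over the trial with i.i.d. N(0, 300 μV)
coefficients on a [−1, 1] time axis. Restricted to any sub-window this is
still a degree-4 polynomial in the window's own normalised axis, so the
detrender's model class contains it exactly and the removal is testable to
numerical precision.

**Powerline.** Sinusoids at 50 Hz and decaying odd harmonics (50, 150,
250 Hz at amplitude A/k for harmonic order k, default A = 20 μV), random
phase per trial, identical on all channels (common-mode pickup).

**Motion artifact.** White noise band-passed to 1–10 Hz and scaled to
30 μV RMS; entirely inside the high-pass stopband.

**Amplitude outliers.** With probability `outlier_prob` per trial, one 50 ms
burst of 2500–5000 μV at a random offset confined to a single 1 s window of
one channel. The burst is a half-sine *envelope on an 80 Hz carrier* rather
than a plain low-frequency pulse: a pulse concentrated below ~30 Hz would be
attenuated under the 2000 μV threshold by the 10 Hz high-pass itself
(measured: 2500 → ~1000 μV) and could never trigger the rejection stage,
which operates on the fully filtered signal; the in-band burst survives
essentially unattenuated (2500 → ~2450 μV) and trips rejection in exactly
one window.

All randomness flows from one root seed through per-purpose
`SeedSequence([seed, key, indices…])` streams, so datasets are bitwise
reproducible and any single trial can be regenerated in isolation.

**What the generator does not emulate:** motor-unit action-potential
shapes, nonstationarity within a trial (onset/offset of the taste reaction),
electrode-impedance drift across sessions, cross-channel correlation of the
EMG component, or label noise. Passing tests therefore demonstrate that the
pipeline recovers structure *of this stationary band-profile form*; they do
not certify accuracy levels on clinical recordings, whose class structure
may live in features this model holds fixed.

## Preprocessing choices

* **Order**: slice → detrend → high-pass → notch → reject. Rejection is
  applied per 1 s window on the fully filtered signal (a
  `reject_per_window=False` flag drops the whole recording instead).
* **Zero-phase filtering** (forward–backward) is used because the analysis
  is offline; the effective magnitude response is the squared single-pass
  response. Note the consequence at the band edge: the 10 Hz cutoff is the
  half-power point of one pass, so the zero-phase *energy* gain at 10 Hz is
  0.25 and integrated 1–10 Hz energy falls by roughly two orders of
  magnitude, not more. Attenuation beyond 1e-4 holds below ~5 Hz.
* **Initial conditions**: Gustafsson's method rather than signal-extension
  padding. On 1 s windows of oscillatory signal, default padding leaves
  multi-μV edge transients (measured ~3 μV RMS on a powerline-only window);
  Gustafsson reduces this to ~0.1 μV, which is what makes the
  "drift + powerline in, sub-μV out" property hold.
* **Detrend** uses least squares on a [−1, 1]-normalised axis for
  conditioning. Degree-≤4 polynomials are annihilated to < 1e-6 μV. The fit
  also absorbs a *small* projection of oscillatory content (≈0.06 μV for a
  unit 50 Hz tone; ~1 % of the amplitude of broadband noise), which is why
  the chain is only *nearly* idempotent: re-running it on its own output
  changes passband tones by ~1–2 % of peak amplitude. The notch stage alone
  is exactly idempotent.
* **Notch algorithm**: the centre/flank comparison (mean over f₀ ± 1 Hz vs
  median over f₀ ± 2…10 Hz, threshold ratio 2.0, centre rescaled to the
  flank median, phase preserved) is the simplest fully testable realisation
  of an amplitude-adaptive notch; the median makes the flank estimate robust
  to a neighbouring genuine spectral line. Harmonics are notched at all
  multiples of 50 Hz up to 450 Hz (below Nyquist).

## Feature conventions

* Spectra are unnormalised one-sided DFT magnitudes; at L = 1000, fs = 1000
  the bin width is exactly 1 Hz and bin index equals frequency. For other
  L/fs the bands are defined in Hz and bins rescaled.
* The second-moment features keep their plain printed form (no square
  root) despite names suggesting one; `apply_root=True` opts into the
  rooted variants. The centroid/moment sums exclude the DC bin.
* The zero-crossing statistic is the strict sign-change count divided by 10,
  kept literal for the 1 s/1000 Hz protocol (a per-second rate would need
  no factor).
* σ is the population standard deviation (divisor L), matching the plain
  averages in the kurtosis/skewness definitions.
* Windows with a zero spectrum or zero variance (impossible on realistic
  data, constructible in tests) are excluded with a logged reason rather
  than imputed.

## Evaluation choices

* Random forest: 100 trees, √D feature subsampling, unlimited depth, fixed
  seed; all exposed in `EvalConfig`.
* Default folding is stratified at the window level. Windows of one trial
  are nearly independent under the generator (random spectral phases per
  bin), but on real data they share slow physiological state, so a
  `by_session` group-folding scheme is provided; the default matches the
  pooled-window protocol the experiments assume.
* The feature sweep adds feature *types* (each type contributing its 6
  channel columns), 1 through 21, in a seed-determined order; an explicit
  order can be passed for designed experiments.
* Participant grouping evaluates every non-empty subset (guarded at
  P ≤ 12), averaging mean CV accuracy per subset size; subsets with fewer
  than n_folds rows of some class are skipped and logged.
* Confusion matrices are accumulated over test folds and row-normalised.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the full stack at reduced
scale chosen to exercise every contract: 2–8 participants, 1 session, 1–13
trials per taste, forests of 10–100 trees. The grouping experiments use
P = 8 for the 255-subset enumeration, P = 5 with heterogeneity σ = 1.0 for
the declining-accuracy trend, and P = 4 with σ = 0 and saturated class
separation (0.8) for the flat-curve check — flatness under exchangeability
is only observable once accuracy is not data-limited, i.e. on the plateau of
the learning curve, which is why that scenario uses stronger separation.

## Known limitations

* The paper-scale experiment grid (90 experiment units × 4 sessions) is
  enumerated by the manifest generator but not synthesised by default; all
  sample counts are configuration, since published totals for this protocol
  are internally inconsistent (e.g. 13,440 ≠ 6 × 2520).
* Chance-level and trend checks are stochastic properties verified at fixed
  seeds; they hold with margin at the documented scales but are not
  closed-form guarantees.
* The adaptive notch operates on whole windows in the frequency domain and
  is not suitable for streaming use.
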