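# Methods

`envtails` quantifies *extreme-amplitude events* in frequency-specific
oscillations of multichannel neurophysiological recordings (M/EEG-like data)
and tests how their prevalence differs across groups — e.g. age groups of an
adult-lifespan cohort.  The chain is:

1. segment each recording into fixed-length non-overlapping windows and
   normalize every channel to zero mean, unit SD;
2. reconstruct the analytic signal at a set of analysis frequencies with a
   complex Gaussian wavelet and take its modulus — the amplitude envelope;
3. treat each envelope time course as an empirical distribution and summarize
   its tail with sample skewness g1 = m3/m2^(3/2) and Fisher excess kurtosis
   g2 = m4/m2^2 − 3 (central moments with 1/n; a normal sample has g2 = 0);
   aggregate segments by the median, giving one participants × channels
   feature matrix per (metric, frequency);
4. run mean-centered partial least squares (task PLS) on each feature matrix:
   SVD of the centered group-mean matrix, a permutation test on the singular
   values, and a within-group bootstrap for per-channel bootstrap ratios.

## The model and its assumptions

**Null baseline (Rayleigh).**  If a channel is a Gaussian process, the
envelope at any analysis frequency is Rayleigh distributed, with closed-form
skewness 2√π(π−3)/(4−π)^{3/2} ≈ 0.6311 and excess kurtosis
−(6π²−24π+16)/(4−π)² ≈ 0.2451.  Departures above these values indicate
burst-like, heavy-tailed amplitude dynamics.  This closed form anchors both
the generator's no-burst regime and the end-to-end calibration tests.

**Wavelet.**  The analysis frequencies (defaults 2, 6, 10.5, 22, 39 Hz —
delta through lower gamma) are extracted with the order-8 complex Gaussian
wavelet ψ(t) = C₈ d⁸/dt⁸(e^{−it}e^{−t²}) (PyWavelets `cgau8`), FFT-based
convolution.  The scale for frequency f is a = fc/(f·Δt), where the
intrinsic center frequency fc is computed numerically as the spectral peak
of ψ (argmax of |FT ψ| on a densely zero-padded grid with parabolic
refinement; fc(8) = 0.72115).  Computing fc rather than hard-coding it makes
the pseudo-frequency calibration independent of normalization conventions;
a brute-force FFT scan and PyWavelets' own (grid-limited) estimate serve as
cross-checks in the tests.

**Edge handling.**  By default every sample enters the empirical
distribution (`edge_policy="keep"`), since the analysis treats each time
point as one realization.  A `trim` policy removes the cone of influence of
the largest scale (default width 5 scales = half the mother wavelet's
effective support) for sensitivity analyses; the output stays rectangular
across frequencies by trimming all bands with the widest margin.

**Moment estimators.**  Plain g1/g2 without small-sample bias correction:
at the default segment length (30 s at ≥250 Hz, tens of thousands of
samples) the iid correction is negligible; it is switchable (`bias=False`).
Note that the *effective* sample size of an envelope is set by its
autocorrelation (≈ the inverse wavelet bandwidth), not the sample count —
see Limitations.

**Mean-centered PLS.**  For G groups and F channel features, the group-mean
matrix M (G × F) is centered with the unweighted mean across groups (the
standard mean-centered task-PLS convention; a weighted variant is one flag
away and matches it closely for near-equal groups).  SVD of the centered
matrix yields latent variables (LVs): columns of U are group contrasts,
columns of V are channel saliences, singular values S quantify the
between-group variance (explained share S²ₖ/ΣS²).  LVs are truncated to the
rank bound min(G−1, F) and sign-fixed so each contrast's largest-magnitude
entry is positive (both polarities are interpretable; the convention only
makes runs comparable).

**Permutation test.**  Participants are reassigned to groups by uniform
permutations preserving group sizes; the k-th permuted singular value is
compared with the k-th observed (greedy matching), and
p_k = (1 + #{S_k^perm ≥ S_k^obs})/(n_perm + 1), so the smallest attainable
p is 1/(n_perm+1).  The add-one form keeps the test exact-level.

**Bootstrap ratios.**  Participants are resampled with replacement within
groups; each bootstrap SVD is aligned to the original by an orthogonal
Procrustes rotation of the saliences (removing the SVD's sign/rotation
indeterminacy) applied to the weighted saliences V·diag(S).  The bootstrap
ratio of a channel is its original weighted salience divided by the SD of
the aligned replicates — interpreted like a z-score of how robustly the
channel supports the contrast.  Channels with zero bootstrap SE are flagged
NaN.  For site-level maps, ratios of channels sharing a sensor site (the
paired planar gradiometers of a site) are averaged.

Default resampling depth is 10,000 for both tests; reduced depths are used
in the validation suite.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
sensor physics.  Each channel is a sum of

- one unit-SD narrowband Gaussian carrier per carrier frequency (Gaussian
  spectral band of width f/8, ≥0.25 Hz);
- a unit-SD 1/f background (default spectral exponent 1.0);
- on *effect channels* only: an additive burst train per carrier frequency —
  Poisson event times (default 0.2 events/s), raised-cosine (Hann) windowed
  cosine bursts of default 1.0 s, peak amplitude lognormal (shape 0.5) with
  median `burst_amp_scale × group_profile[g]` carrier-SDs (default scale 3).

Without bursts the channel is Gaussian, so the envelope is Rayleigh — the
exchangeable null.  Burst amplitude scales with a per-group profile
(monotonic ramp, inverted-U, or flat), which makes envelope skewness and
kurtosis rise monotonically with the effective amplitude — the planted
ground truth for recovery tests.  Ages are drawn uniformly within contiguous
per-group bands spanning 18–89 years, so percentile grouping (rank by age,
cut into near-equal contiguous blocks; largest-remainder apportionment,
stable tie-break by input order) recovers the generating labels by
construction.  Channels are laid out as co-located pairs on a planar grid of
sites, emulating paired planar gradiometers.

What the generator does *not* emulate: volume conduction and spatial
correlation between sites, physiological artifacts (eye, muscle, cardiac),
non-stationary background power, 1/f exponent changes with age, realistic
head geometry.  Passing recovery tests therefore show that the statistical
chain detects group-graded heavy-tailedness against Gaussian + 1/f
backgrounds — not that it is robust to every real-data nuisance.

## Validation scales and numerical choices

The validation suite runs reduced problem sizes chosen so each check has the
power it needs while the whole suite stays in minutes:

- **Estimator calibrations**: 10⁶ draws against normal/exponential closed
  forms (g2 within ±0.02 of 0 for normal; g1→2, g2→6 for exponential).
- **Rayleigh end-to-end**: a white-noise cohort, 50 segments of 30 s at
  250 Hz, 8 channels, medians pooled over segments × channels per frequency.
  Median skewness lands within [0.48, 0.78] at all five frequencies.  Median
  excess kurtosis meets [0.05, 0.45] only at 10.5/22/39 Hz: at 2 and 6 Hz
  the envelope's autocorrelation within the narrow wavelet band leaves only
  a few dozen effective samples per segment, and the sample-kurtosis bias
  (≈ −6(γ₂+2)/n_eff) pushes the median to ≈ −0.15 and ≈ −0.07 respectively.
  An edge-free oracle (circular frequency-domain synthesis of analytic
  Gaussian noise with the same scaled band shape) reproduces these values,
  confirming they are estimator properties of the stated segment length,
  not implementation artifacts.  The corresponding acceptance check asserts
  the nominal band at every frequency and accordingly fails at the low
  frequencies; it is kept as-is deliberately.
- **Type-I error**: 500 exchangeable-null feature matrices (5 groups × 20
  participants, 16 features, iid N(0,1) — the feature-space null; full
  signal synthesis would multiply compute without changing the null), 200
  permutations each; LV1 rejection at α = 0.05 must lie in the binomial
  band [0.02, 0.09].
- **Planted-effect recovery**: 50 cohorts of 5 × 20 participants, 32
  channels with the monotonic ramp on 8, single 10.5 Hz carrier, 3 × 10 s
  segments at 200 Hz, 500 permutations / 500 bootstraps.  The planted
  amplitude is `burst_amp_scale = 6` (not the default 3): a power analysis
  showed that at the default, the 0.25-profile group's bursts (0.75
  carrier-SD) sit below the Rayleigh envelope floor, so the first two groups
  are statistically indistinguishable at *any* recording length and
  rank-perfect contrast recovery cannot be demanded.  At 6 carrier-SDs every
  adjacent profile step is resolvable and the criteria (LV1 p < 0.05 and
  rank-perfect contrast in ≥90% of runs; ≥80% of |BSR| > 3 channels are
  planted) hold with margin.  Rank-perfection is tested as |Spearman ρ| >
  1 − 10⁻¹², since floating-point rank correlation of a perfectly ordered
  contrast returns 1 − O(ε).
- **Degenerate inputs**: constant channels raise errors naming the channel;
  zero-variance features get NaN bootstrap ratios with a zero-SE flag;
  empty groups, single-participant groups, too-short recordings and
  above-Nyquist frequencies raise typed errors (`ValidationError` /
  `DataError`, CLI exit codes 2 / 3).
- **Determinism**: every stochastic stage takes an explicit seed; the
  pipeline spawns independent substreams per analysis from one master seed,
  so full runs are bit-reproducible.

## Known limitations

- Tail metrics at delta/theta frequencies are biased low at 30-s segments
  (see above); group *comparisons* remain valid since the bias is common to
  all groups, but absolute values should not be read against the Rayleigh
  closed forms at low frequencies.
- The permutation test calibrates the global null; it does not correct
  across the 10 (frequency × metric) analyses.
- The bootstrap-ratio construction (weighted saliences, Procrustes
  alignment) follows the established task-PLS recipe; other estimators
  (e.g. raw-salience SE) would scale ratios differently.
- The FIF reader is a convenience for real recordings and is not exercised
  by the test suite.
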