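# Methods

This note documents the models, estimators and numerical choices behind
`bgosc`, including the places where the design was genuinely open and the
package had to commit to a convention.

## Recording model and montage

A hemisphere is recorded monopolarly from one depth electrode with eight
circular contacts ordered ventral to dorsal, spanning GPi, GPe and
striatum. Adjacent-contact bipolar derivation (ventral minus dorsal — the
sign is irrelevant to power and coherence magnitudes but is fixed for
reproducibility) yields seven parallel channels; a channel is assigned to a
nucleus only when both member contacts lie inside it, all mixed pairs are
discarded, and when several pairs qualify for one nucleus the most ventral
is retained (a declared tie-break; the choice does not affect the synthetic
cohorts, which qualify exactly one pair per nucleus). Recordings are stored
as little-endian float64 channel-major binary or TSV, with a JSON sidecar
carrying the sampling rate, contact labels and structure map.

## Conditioning

Channels are decimated to 200 Hz (polyphase anti-aliased resampling), then
filtered forward–backward with 4th-order Butterworth designs: high-pass
1 Hz, low-pass 98 Hz, band-stop 48–52 Hz. Zero-phase filtering is mandatory
here: any phase distortion would leak into the imaginary part of coherency
and the phase-lag index. Epochs are contiguous, non-overlapping, 2 s by
default (0.5 Hz spectral bin spacing); epochs intersecting an optional
artifact mask (user-supplied or |z| > threshold on the conditioned signal,
off by default) are dropped.

## Spectral estimation

Power and cross-spectra come from convolution with L2-normalized complex
Morlet wavelets, 7 cycles at every frequency, on a 0.5 Hz grid. Two
implementation points matter:

- **The transform runs on the continuous conditioned signal**, and the
  coefficient stream is then sliced at epoch boundaries. A 7-cycle wavelet
  at 3 Hz is ~2.3 s long — longer than a 2 s epoch — so per-epoch
  convolution would make every low-frequency sample an edge sample.
  Samples within half a wavelet length of the recording edges are flagged
  per frequency and excluded from all averages; an epoch enters the
  cross-spectral average at a frequency only when fully valid.
- **Scaling**: with the L2 normalization, `2·E|c(f)|²` estimates the
  one-sided power spectral density, so Morlet band power is directly
  comparable to a Welch periodogram (the test suite holds them to 15%
  agreement on band power). At spectral features narrower than the wavelet
  bandwidth (σ_f = f/7) the two estimators legitimately differ in peak
  height while preserving the integral.

Spectra are normalized by the signal variance — equivalent to scaling the
channel to unit standard deviation — which removes electrode-impedance
scale differences; the normalized spectrum is invariant to any positive
rescaling of the input.

**Peak detection and flattening.** The aperiodic trend is a linear fit of
log10 power on log10 frequency. The fit excludes the line-noise band *and
both oscillation bands*: leaving the bumps in drags the trend upward by an
amount that varies with bump size, which biases flattened peak heights
(measured on synthetic hemispheres, the correlation between flattened peak
height and true oscillation gain rises from ~0.6 to ~0.88 with the
exclusion). Peaks are local maxima of the flattened spectrum inside a band
whose prominence exceeds 5% of the flattened in-band range (with a small
absolute floor against floating-point ripple); absence of a qualifying
peak is a valid outcome. For group display, flattened spectra are shifted
so individual peaks coincide at relative frequency zero and averaged.

## Coupling measures

All measures derive from epoch-resolved wavelet cross-spectra
`S_ab(e, f) = 2·mean_t a conj(b)`.

- **Imaginary part of coherence**: `Im(S_ab / sqrt(S_aa·S_bb))` on the
  epoch-averaged spectra. Instantaneous mixing of a common source is
  purely real, so iCOH indexes time-lagged interaction only.
- **Debiased wPLI**: pairwise products of per-epoch imaginary
  cross-spectra over distinct epoch pairs, normalized by the products of
  their magnitudes. The debiasing removes the positive sample bias; the
  null is centered at zero and the estimate may be negative. Degenerate
  inputs (all imaginary parts zero, e.g. a channel against itself) return
  0 with a warning.
- **Nonparametric Granger causality**: Wilson's iterative spectral matrix
  factorization `S(f) = ψ(f) ψ(f)^H` gives the causal transfer function
  `H = ψ A0^{-1}` and innovation covariance `Σ = A0 A0^T`; Geweke's
  formula then yields the frequency-resolved directed influence in both
  directions. Estimates on time-reversed data — obtained by conjugating
  the cross-spectrum, which is exact for stationary pairs — are
  subtracted (`corrected = raw − reversed`); genuine lagged drive
  survives, direction artifacts from lag-free asymmetries (e.g. unequal
  SNR under volume conduction) cancel. Corrected values may be negative
  and are never clipped.

### Wilson factorization numerics

The iteration starts from the upper-triangular Cholesky factor of the
lag-zero covariance and applies the causal-part ("plus") operator with the
upper-triangular half-lag-zero convention. The factorization grid is the
uniform 0-to-Nyquist extension of the measured grid: the real part is
edge-replicated, the imaginary part is linearly tapered to zero at DC and
Nyquist (Hermitian symmetry of a real process forces Im S = 0 there — a
constant complex extension would introduce a jump discontinuity that
stalls the iteration). Convergence: on analytically smooth spectra the
iteration reaches a relative step of 1e-9 in a few dozen iterations; on
estimated spectra the step size floors at ~1e-4, set by grid
discretization (covariance tails truncated at the FFT length), while the
factorization error is already at its achievable minimum and the Granger
values are stable to five decimals. The implementation therefore stops on
step < 1e-9 *or* step stagnation, and judges success by the
reconstruction residual `||ψψ^H − S||/||S||`, raising an error above
1e-2. Diagonal loading (1e-12 of the mean trace plus the magnitude of any
negative eigenvalue) guards positive definiteness.

### Surrogates

Null distributions destroy the cross-channel epoch alignment while
preserving both channels' marginal spectra. The default scheme is a
**random circular shift of one channel's epoch sequence** rather than a
full permutation: wavelet kernels at low frequencies extend across epoch
boundaries, so consecutive epochs are serially dependent, and a full
permutation removes that dependence from the null while the observed
statistic contains it — measured under a pure volume-conduction scenario,
the wPLI exceedance of the permutation null's 95th percentile is ~7%
instead of the nominal 5%, while the circular-shift null is calibrated
(~3–5%). Permutation remains available (`method="permute"`).

### Direction designation

The paper-style bin-count rule designates a hemisphere striatal-driving
when the corrected striatal drive exceeds the pallidal drive in a strict
majority of low-frequency bins (exact ties count for neither side and are
logged; an optional margin turns small differences into ties). On
continuous data the plain rule always produces a majority, so the package
adds a gated verdict (`direction_verdict`) for analyses that must be able
to return "no direction": a direction is designated only when the bin
majority agrees with the **time-reversal sign signature** — the band-mean
net influence (forward − reverse) is positive on the original data and
negative on the time-reversed data for striatal driving, and mirrored for
pallidal. Genuine lagged interactions flip this sign under time reversal;
lag-free artifacts preserve it. The rule is parameter-free. Alternatives
evaluated on synthetic data and rejected: an epoch-shuffle significance
margin (its null destroys all coupling, so under a strong zero-lag
confound the corrected-Granger noise dwarfs it and every confound is
designated) and an epoch-bootstrap confidence interval (underpowered for
genuine coupling, because the corrected-difference noise grows with
coherence). An epoch-bootstrap of the band-mean corrected difference
remains available as an uncertainty measure.

## Group statistics

Monte Carlo permutation tests (sign flips of paired differences, label
exchange otherwise; two-sided; add-one p-values, default 5000 draws);
Benjamini–Hochberg step-up FDR within each analysis family, cross-checked
in the tests against statsmodels' implementation; cluster-based
permutation across frequency bins for dependent spectrum-wise comparisons
(bin-wise paired t, cluster mass = summed |t| of contiguous same-sign
supra-threshold bins, max-mass null under sign flips); Lilliefors
normality screen (statsmodels) before Pearson correlation — a violation
is flagged, not fatal. Hemisphere estimates are averaged to one value per
subject before correlating, because the severity score is global.

**Correlation estimates.** The cohort table stores band means, but the
severity correlations use the flattened low-frequency peak height (power)
and the in-band peak |iCOH| (coupling): band means sit on a large
aperiodic/uncoupled baseline, and individual peak frequencies move within
the band, both of which dilute between-subject differences in the
quantity of interest.

## Synthetic cohort generator

Each hemisphere channel is a sum of unit-variance 1/f background (default
exponent 1), narrowband-filtered Gaussian oscillations (~2 Hz bandwidth;
band-limited processes, not sinusoids, so coherence stays below one and
surrogate statistics are non-degenerate), 50 Hz line noise, a shared
zero-lag component (volume conduction), and delayed linear mixing for
directional coupling: GPi (and, at a smaller gain, GPe) receives a copy of
the striatal low-frequency component delayed by 25 ms (~a quarter cycle at
10 Hz, keeping the imaginary part of coherency large at the peak). The
monopolar contacts inject each nucleus signal differentially within its
contact pair on top of a shared reference, so bipolar derivation recovers
the signal and rejects the common mode.

Cohorts draw one subject-level latent u per subject, stratified across
deciles (emulating recruitment across the severity spectrum); u drives the
STR–GPi coupling gain (default range 0.2–1.0). GPi low-frequency activity
is largely *inherited* from the delayed striatal drive (intrinsic GPi gain
0.45–0.75, independent of u), so stronger coupling raises both measured
GPi low-frequency power and STR–GPi coherence — mirroring their joint
clinical association, and reflecting the directional finding the analysis
is designed to recover. STR/GPe gains and STR–GPe coupling are drawn
independently of u: designed nulls. Severity is
`2 + 8·(mean GPi gain) + 20·(mean STR–GPi gain) + N(0, 0.75)`, clamped at
zero, giving BFMDRS-like scores in the teens-to-thirties. Cohort peak
frequencies are normal (8.5 ± 2.5 Hz) truncated to 4.5–11.5 Hz so the
~2 Hz bump stays inside the 3–12 Hz band. These defaults were calibrated
once, on pilot simulations, so that effects are detectable at n = 10
without being saturated, and then frozen.

What the generator does **not** emulate: non-stationarity and movement
artifacts, electrode geometry and tissue conduction physics, cross-
frequency coupling, asymmetric or frequency-dependent conduction delays,
beta-band coupling, and any biophysical (conductance-based or neural-mass)
dynamics. Passing parameter-recovery tests therefore demonstrates that the
estimators recover the statistical structure they assume — lagged linear
narrowband coupling in 1/f noise with zero-lag leakage — not that real
dystonia recordings satisfy those assumptions.

## Validation experiments and problem sizes

The acceptance experiments (shared by `tests/test_acceptance.py` and
`scripts/acceptance.py`) use these sizes, chosen to keep the full suite
around ten minutes on one CPU:

- estimator oracles: one 180 s pair at 200 Hz (iCOH vs Welch-segment
  coherency) and 100,000 samples of a bivariate AR(2) with broad ~35 Hz
  resonance (nonparametric vs parametric VAR Granger, 20–50 Hz band; a
  sharper resonance would measure wavelet smoothing, not factorization
  correctness);
- volume-conduction immunity: 20 seeds, 120 s hemispheres, common-source
  gain 2.0 over symmetric 0.5 oscillation gains, 200 surrogates;
- direction recovery: 20 + 20 datasets, 180 s; genuine drive with STR 1.0
  / GPi intrinsic 0.5 / coupling 0.8, confound with asymmetric SNR
  (STR 1.2 / GPi 0.4) under common-source gain 1.2;
- statistical calibration: 500 null simulations of 19 paired values, 1000
  permutations each; 1000 random p-vectors against the reference BH;
- peak recovery: 50 hemispheres, uniform 3–12 Hz peaks, 90 s;
- pattern recovery: 50 cohorts of 10 subjects / 19 hemispheres, 90 s
  hemispheres, 2–45 Hz analysis grid.

## Known limitations

- Bivariate Granger only; no conditional/multivariate variants, so a
  common driver of two nuclei can appear as mutual coupling.
- The time-reversal sign gate is a heuristic designation rule, not a
  calibrated hypothesis test; near-symmetric bidirectional coupling will
  usually be designated "neither".
- Absolute power levels are in arbitrary units; only scale-invariant
  structure (normalized spectra, coherence-family measures) is
  interpretable across recordings.
- Epochs cut from continuous data remain serially dependent at low
  frequencies; the circular-shift surrogate accounts for this, but the
  wPLI's effective sample size is smaller than the epoch count.
- The Lilliefors screen at n = 10 has little power; the Pearson
  correlations should be read accordingly.
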