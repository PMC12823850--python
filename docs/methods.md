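# Methods

This note records the models implemented in `bbnet`, the defaults chosen
where a design decision was genuinely open, and what the synthetic-data
validation does and does not establish.

## Signal model of the synthetic EEG

### Band-limited sources

All oscillatory components are synthesized in the frequency domain:
independent complex-Gaussian Fourier coefficients on the bins inside a band
`[lo, hi]`, zero elsewhere, scaled so the time series has unit variance in
expectation. Two consequences matter:

* the one-sided power spectral density is exactly flat at `1/(hi − lo)`
  inside the band, so auto- and cross-spectra are analytic;
* two independent draws have *identical* expected spectra, which is what
  the coherence oracle below requires.

This is equivalent to an oscillation with random amplitude/phase drift of
bandwidth `hi − lo`; it is stationary and Gaussian.

### The coherence oracle (common-source pair)

`generate_common_source_pair` produces two channels

    x_i = sqrt(snr_i) · s + m_i + w_i ,   i ∈ {a, b}

with `s` a unit-variance band-limited source centred on `f0`, `m_i`
independent noises **with the same spectrum as `s`**, and `w_i`
unit-variance white noise. Because signal and narrowband noise share one
spectral shape, the per-bin signal-to-noise ratio at the source band is
`snr_i` exactly, and the magnitude-squared coherence there is

    MSC = snr_a · snr_b / ((1 + snr_a)(1 + snr_b)) ,

independent of bandwidth. The white floor perturbs this by <1% (its density
at `f0` is ~0.8% of the narrowband density at the default 2 Hz bandwidth).
The matched-spectrum noise is essential: against *white* noise alone, a
narrowband source concentrates its variance into one analysis bin and the
per-bin SNR — hence the coherence — would be far larger than `snr_i`.

The source bandwidth defaults to 2 Hz. Much narrower bandwidths make the
process decorrelation time exceed the 2-s Welch segment step; successive
segments then stop being independent, the effective segment count
collapses, and the estimator's upward bias (≈(1−C)²/K for K independent
segments) grows by an order of magnitude. At 2 Hz, 5-minute records recover
the closed form to ~0.01–0.02 absolute. `estimate_pair_msc` averages the
interior bins of the source band (edge bins lose energy to window
smearing).

### Study recordings

Each simulated subject mixes, over a pink-noise background
(1/f density, per-channel SD 8 µV, DC removed), one band-limited source per
EEG band. Per channel `c` and band `b` the contribution is

    A_b · w_bc · ( sqrt(ρ_b) · s_b + sqrt(1 − ρ_b) · u_bc ) ,

where `s_b` is shared across channels, `u_bc` is channel-private with the
same spectrum, `A_b` is the band amplitude (µV), `w_bc` a fixed regional
weight profile (frontal-dominant θ, posterior-dominant α), and `ρ_b` the
shared-variance fraction. In the high-SNR limit the band coherence between
two channels approaches `ρ_b²`; with the finite pink floor it is
`ρ_b² / (1 + P_pink/P_src)²` per bin.

Defaults (chosen once for plausibility and testability, since no
quantitative spectra are available for the population being emulated):
`A = 7, 8, 6, 4 µV` and `ρ = 0.55, 0.55, 0.55, 0.50` for θ, α, β, γ. These
put total RMS near 14 µV (well under the 100 µV artifact threshold),
relative power ≈ 0.40/0.33/0.14/0.07 across the four bands, and baseline
band coherence ≈ 0.37 (θ) and ≈ 0.29 (α) — i.e. straddling the 0.30 graph
threshold, so thresholded graphs have non-degenerate between-subject
variance in both directions. Subject-level jitter (log-normal ±10%
amplitude, ±8% weights, ±0.04 on ρ) is keyed on the subject seed and held
fixed across states; realization noise differs per state. A planted effect
(`EffectSpec`) multiplies `A_b` by `power_delta` and shifts `ρ_b` by
`coherence_delta` in the during/post states only, for the effect group
only.

The default simulated study is 3 groups × 20 subjects × 3 states of
5-minute 14-channel recordings at 128 Hz, matching the emulated design.
Validation runs scale this down (2 states, 120-s records, 50 replicates)
to keep whole-suite runtimes in minutes; the planted effect is strong
enough (paired dz ≈ 2–2.5 on global θ clustering) that the scaled run is
not power-limited.

What the generator does **not** model: volume conduction and
reference-electrode effects (coherence between real neighboring electrodes
is inflated by both), realistic artifact morphology (only amplitude
outliers), non-stationarity, and any 1/f knee or alpha-peak asymmetries.
Passing tests therefore demonstrate correctness of the estimators and the
statistical machinery under a known stationary Gaussian model — not
fidelity of any specific biological claim about real recordings.

### Digit-span sessions

Recall in round `r` (sequence length `3 + r`, rounds 1–5) is binomial with
a per-round success probability; the session truncates at the first round
scoring below the 60% advancement threshold. Baseline probabilities
(0.95, 0.92, 0.85, 0.72, 0.55) and Gaussian per-round times (23 ± 3 s)
give pre-stimulation session scores near 80% and times near 115 s per
session. The effect group gains +0.08 recall probability and −2 s per
round post-stimulation. Trials per round default to 5 (the emulated
protocol does not state a count).

## Analysis choices

* **Filtering.** The band-pass is applied forward-backward
  (`sosfiltfilt`, effective order 10) by default so that cross-channel
  phase — and therefore coherence — is undistorted; `causal=True` gives
  the conventional single-pass filter.
* **Artifact rejection** replaces visual inspection with a deterministic
  rule: drop any non-overlapping 2-s epoch whose peak |amplitude| exceeds
  100 µV on any channel; warn above a 10% rejection rate. Both parameters
  are configurable; epoch order is preserved.
* **Band edges.** Bands are closed intervals; the θ/α boundary bin at
  8 Hz is assigned to θ only (the lower band wins a shared printed edge),
  so band masks partition the grid. The four bands deliberately leave
  1–4, 12–13 and 29–30 Hz uncovered, hence band fractions sum to < 1.
* **Band coherence** is the mean of the magnitude-squared coherence over
  the band's bins (not coherence of band-filtered signals). A single-
  segment MSC is identically 1 and is rejected as an error.
* **Graph threshold.** "30% coherence" is read as an absolute MSC cutoff
  of 0.30 with a strict inequality; a proportional (edge-density) mode is
  provided for the alternative reading.
* **Metric conventions.** CC and LE are 0 for nodes of degree < 2;
  closeness sums distances over the reachable set only (isolated nodes
  score 0); betweenness is unnormalized, counting unordered pairs on
  undirected graphs and ordered pairs on directed ones. Coherence is
  symmetric, so coherence-derived graphs are undirected and in/out
  variants coincide node-wise; the directed forms accept externally
  supplied asymmetric adjacencies.
* **Statistics.** Cohen's d for paired contrasts uses the SD of the
  within-subject differences, matching the paired-t structure. FDR
  families: node-level contrasts correct the 14 channel tests of one
  (group, contrast, metric, band) cell together; global-mean contrasts
  correct all metric × band tests of one (group, contrast) cell together.
  The two-way ANOVA treats state as a between-cell factor (as the
  emulated study's summary table does) although state is within-subject;
  the report's provenance block flags this fidelity-over-correctness
  choice. The sample-size utility inverts the noncentral-t power function
  of the two-sided paired t-test and exposes effect size, α and power
  explicitly rather than hard-coding any particular interim analysis.
* **Degenerate inputs.** Zero-variance paired differences, zero-variance
  correlation inputs, empty p-value lists and empty ANOVA cells raise
  errors at the statistics layer; inside a test family, degenerate units
  are reported as NaN rows labeled "degenerate" rather than failing the
  family. An all-identical ANOVA response returns F = 0 for every effect.
* **Pipeline.** During-stimulation EEG is analyzed as a single recording
  (concatenation of sub-sessions is the caller's choice when preparing
  files). Reported contrasts are Pre-vs-Du and Pre-vs-Post;
  Du-vs-Post is available behind a flag. Subjects with missing/unreadable
  state files are skipped with a warning; more than 50% skipped aborts
  the run. No persistent stage cache is kept: per-recording analysis is
  ~60 ms, so deterministic recomputation is cheaper and simpler than
  cache invalidation.

## Numerical notes

* Welch PSD uses density scaling; integrated white-noise power matches the
  signal variance to within leakage error.
* The all-pairs coherence computes each channel's tapered segment FFTs
  once and forms cross-spectra by outer product; it matches
  `scipy.signal.coherence` to 1e-10 and makes a whole-study analysis
  (hundreds of 14-channel recordings) run in minutes.
* The Welch MSC estimator is biased upward by ≈ 1/K under independence
  (K = segment count); tests against "zero" coherence allow exactly this
  floor rather than an arbitrary tolerance.
* BH-FDR under the global null has expected FDR exactly q for independent
  continuous p-values; empirical checks therefore allow a 3-standard-error
  Monte-Carlo margin above q.

## Known limitations

* Directed connectivity is supported in the metric layer but never arises
  from the coherence pathway (MSC is symmetric); no directed-connectivity
  estimator is provided.
* No ICA/regression ocular correction, bad-channel interpolation,
  weighted-graph metrics, small-world or modularity statistics, or
  repeated-measures/mixed-effects ANOVA.
* EDF files are read (via `mne`); fixtures are written as headered CSV and
  TSV. EDF export is not implemented.
* The amplitude quantization in CSV output is 1e-5 µV; round-tripping is
  exact to that precision only.
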