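# Methods

`lfpattr` analyzes trial-structured local field potentials (LFPs) evoked
by brief optogenetic stimulation of cortical fast-spiking interneurons:
ensembles of one hundred 2-s sweeps per animal and pharmacological
condition, digitized at 10 kHz and band-passed 0.1–130 Hz by the
acquisition chain.  The package implements the full analysis pipeline —
phase-resetting correction, dendrogram clustering with an overlap
statistic, delay-embedding reconstruction, distributional and geometric
cross-condition comparison, and low-order Fourier modeling — together
with a synthetic trial generator that reproduces the statistical
structure the pipeline assumes, so every stage is testable without the
original recordings.

## Data model and trimming

A `Trial` is one sweep (sample vector, rate, mouse/condition identity);
a `TrialSet` is the per-condition ensemble.  Condition names follow the
`<antagonist><order><mouse>` scheme (`schb14`, `sulpa18`, `bc8`, …).
The first 0.5 s of each sweep contains the stimulus transient and is
discarded (`trim_transient`); all dynamics analysis operates on the
remaining 1.5 s (15 000 samples) of steady activity.  The online
band-pass is treated as a property of the input and never re-applied.

## Phase-resetting correction

The light pulse arrives at a random phase of the ongoing rhythm, so raw
trials decorrelate even when their waveforms coincide.  `circular_align`
rotates each trial to the circular shift that maximizes its Pearson
correlation with a reference trial (default: trial 1), searching all N
shifts exactly via FFT cross-correlation.  Because the zero shift is in
the search set, alignment can never lower the correlation; ties break
toward the smallest non-negative shift.  SSD summaries are computed on
the raw aligned traces without amplitude normalization — whether the
original analysis normalized first is not documented, and the report
states the convention used.

## Clustering and the overlap statistic

Trials are points in R^N under the Euclidean metric; `linkage_euclidean`
builds the agglomerative merge tree (default: single linkage — the
nearest-neighbor rule matches the closest-pair-merges-first narrative of
the method's illustration; complete/average/ward are available and ward
is recommended when balanced partitions matter).  For a concatenated
baseline+treatment ensemble cut into k clusters, each cluster is scored
as `100 * min(n_baseline, n_treatment) / n_cluster`: 0 for a pure
cluster, at most 50 for a perfectly mixed one.  The summary is the
unweighted mean ± sd across clusters, reported at k = 6 and k = 12 by
default, with the coarse-vs-fine difference as a consistency check.
Whether distances should be computed on aligned or raw trials is exposed
as a caller choice; aligned is the default because random stimulus phase
otherwise dominates the metric.

## Lag time

Two estimators of the delay `tau = n * dt`:

* `autocorr_lag` — the first lag at which the biased (divide-by-N),
  mean-removed autocorrelation is ≤ 0.  A 1e-10 absolute tolerance
  absorbs floating-point zeros (a sampled sinusoid's quarter-period zero
  lands within 1e-16 of zero).  No interpolation: the reported lag is an
  integer sample count, matching the convention of reporting lags like
  "1953 sampling times".
* `ami_lag` — the first strict local minimum of the average mutual
  information, estimated with equiprobable (rank-based) marginal bins
  (default 16) and plug-in entropies in nats.  Rank binning makes the
  estimate invariant under monotone transforms of the signal.

Per-ensemble statistics (`lag_distribution`) screen out faulty-coupling
trials (peak-to-peak amplitude below 0.04 signal units, configurable)
before anything else.  The scalar summary is the count-weighted mean of
the empirical lag distribution — identical to the plain mean of the
per-trial lags — which keeps the summary inside the observed lag range
regardless of the display histogram's binning (50 ms bins spanning
0–0.7 s by default).

## Embedding dimension

`fnn_curve` implements the Kennel false-nearest-neighbor criterion: for
each embedding dimension d, embed at the chosen lag, find every point's
nearest neighbor outside a Theiler window (default 500 samples;
exact k-d tree search), and call the pair false when the extra
coordinate of the (d+1)-lift grows the pair distance by more than the
ratio f (default 12).  `min_embedding_dim` returns the first d with
FNN below a threshold (default 0.1%).  The loneliness (attractor-size)
second criterion is implemented as an optional flag but off by default;
the distance-ratio rule is the criterion the analysis relies on.

## Cross-condition comparison

* `percent_change` rounds `100*(treated-baseline)/baseline` half away
  from zero to the nearest integer — the rounding that reproduces
  published integer percents (6.515% prints as 7%).
* `ks_matrix` runs the two-sample Kolmogorov–Smirnov test on the raw
  per-trial lag lists (never the binned histograms): exact ECDF
  sup-difference, asymptotic p-value (adequate at ~100 trials per
  condition; flagged as approximate below 5), natural-log p reporting
  floored at −745 (exp underflow).
* `discrete_frechet` is the coupling-minimax distance computed by the
  standard O(nm) dynamic program (numba-compiled kernel, NumPy
  fallback).  `frechet_block` uniformly downsamples trajectories to 400
  points by default before the DP: the distance is a topology-level
  summary and the full 10^4-point grids cost O(nm) each for no
  interpretive gain; oracle tests run undownsampled on small inputs.
  Whether to amplitude-normalize before comparison is exposed
  (`normalize`, default off) and reported.

## Spectral modeling

`top_k_synthesize` computes the full DFT, keeps the DC term plus the k
positive-frequency harmonics of largest amplitude (ties toward the lower
index), and synthesizes by inverting the masked spectrum — so
`synthesized + residual == original` holds exactly and retaining every
harmonic reconstructs the trial to machine precision.  Residuals are
screened by `residual_tests`: ADF with constant and AIC lag selection
(reject unit root ⇒ stationary), KPSS against the level null (residuals
are mean-zero by construction), and a Ljung–Box portmanteau test at 20
lags as the whiteness check — the same null as an ARMA(0,0)
identification, fully specifiable.  `synthesis_adequacy` returns the
smallest tested harmonic budget whose residual passes both stationarity
screens.  `frequency_of_index` maps index k to `k * fundamental`; the
shipped display default of 1/3 Hz matches the published coefficient
tables, while `rate/N` gives the exact fundamental of an analyzed
window.

## The synthetic generator

Each regular trial is

    x(t) = env(t) * sum_k A_k cos(2 pi f_k s (t + t0) + phi_k) + noise(t)

* **Harmonics.**  Default `(2 Hz, A=1, phi=0)` and `(14/3 Hz, A=0.472,
  phi=2.7)`: two non-harmonically related components in the 2–8 Hz band
  whose noiseless delay trajectory folds in two dimensions and embeds in
  three.  The secondary amplitude pins the analytic autocorrelation
  first zero tau* at f2·tau* ≈ 1/2 cycle.  At that delay the fourth
  delay coordinate is (nearly) a linear combination of the first three
  — there exists a cubic with real coefficients whose roots include
  e^{±i w1 tau} and e^{i w2 tau} ≈ −1 — so the neighbor-distance growth
  factor from d=3 to d=4 is bounded well below the FNN threshold ratio
  f=12 everywhere on the attractor, while the d=2 projection keeps
  20–40% false neighbors.  This is the geometry that makes the minimal
  embedding dimension robustly 3 under noise, the regime the recorded
  sweeps exhibit.  Away from this delay relation the immersed delay
  torus develops near-self-intersections whose lift gaps defeat the
  ratio criterion for a few seeds in ten — the calibration that fixed
  these defaults swept frequency ratios 5/3–4, amplitudes 0.2–0.6 and
  envelope slopes over many seeds before freezing.
* **Stimulus phase.**  `phase_jitter="uniform_circular"` draws a random
  time shift t0 per trial (every component advances by 2 pi f t0).  A
  shared time shift — not a shared additive phase — preserves the
  relative phase of the harmonics and hence the attractor geometry
  across trials, and is exactly the transformation circular alignment
  inverts.
* **Correlation-time spread.**  A per-trial log-normal frequency scale s
  (log-sd 0.3, centred so E[1/s]=1) reproduces the broad per-trial
  lag-time distributions of the recordings (reported sd/mean ≈ 0.4–0.6)
  and keeps the mean lag on target.  `target_correlation_time` rescales
  all frequencies so the analytic autocorrelation zero lands on a
  requested lag, giving a closed-form recovery oracle.
* **Envelope.**  `linear_decay` from 1 to 0.3 over the sweep emulates
  the graded amplitude decay of the large-amplitude trial family;
  `constant` is available (and used by the exact-spectrum tests).
* **Noise.**  Additive Gaussian noise at 5% of the default waveform's
  RMS amplitude (noise_sd 0.026 signal units), low-passed at the 130 Hz
  corner of the acquisition band-pass (`noise_band`; `noise_spectrum`
  optionally shapes it 1/f).  Full-bandwidth white noise at 10 kHz is
  not a faithful emulation of band-passed recordings.
* **Faulty couplings.**  A configurable fraction of trials is replaced
  by white noise rescaled below the 0.04 peak-to-peak threshold,
  matching the screen applied before lag statistics.
* **Reproducibility.**  One root seed spawns independent per-trial
  child streams; identical configs are bit-identical, and disabling
  noise, phase jitter and frequency jitter makes all trials identical.

What the generator does **not** emulate: spiking transients, 1/f
background mixtures with state switching, inter-animal variability
beyond the correlation-time knob, gamma-band modulation, or any
biophysical network mechanism.  Tests passing on these surrogates show
the pipeline's statistics behave as designed on signals with the assumed
structure — not that the biological conclusions of any particular study
follow.

## Pipeline

`run_pipeline(PipelineConfig)` chains the stages in fixed order over two
condition ensembles (generated or loaded), validates every stage's
parameters before any stage runs, fans one root seed out per generator,
and writes each artifact (aligned sets, alignment/overlap/lag/FNN/KS/
Fréchet/spectral tables) plus a manifest with SHA-256 content hashes —
reruns with the same seed are bit-identical.

## Problem sizes in the shipped tests

Unit and property tests run on reduced geometries (0.2–1 s sweeps at
0.5–2 kHz, 8–100 trials) chosen so each oracle comparison enumerates in
milliseconds; the embedding-dimension reproduction runs one full-scale
trial (2 s at 10 kHz) through the complete FNN path, and the KS
calibration uses 200 replicates of 100-trial pairs.  These sizes are the
package's own test design: they keep every assertion exercised on the
same code paths the full-scale pipeline uses.

## Known limitations

* The asymptotic KS p-value is approximate below ~25 samples; entries
  under 5 samples are flagged invalid rather than estimated.
* The AMI estimator's plug-in bias (≈ (bins−1)²/2N nats) matters for
  short series; with 16 bins trust absolute AMI values only for
  N ≳ 3·10^4, though the *location* of the first minimum is stable far
  below that.
* FNN percentages at the 0.1% threshold involve counts of ~10 points in
  10^4; at noise levels well above the calibrated regime single
  strand-touch events can push a dimension's percentage past the
  threshold for unlucky realizations.
* `percent_change` is asymmetric by definition; only sign correctness
  and zero-at-equality are guaranteed properties.
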