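# Methods

This note documents the model, the numerical choices, and the limits of
what the test suite shows.  Notation: `s` is a nasal-airflow recording in
mL/s sampled at `f_s` Hz (250 Hz by default), positive during inspiration.

## Volume reconstruction and cycle segmentation

Cycle boundaries are unreliable on the raw flow (noise, sniffing,
vocalisation artefacts), so they are detected on the lung volume

    v_t = Σ_{u≤t} s_u / f_s − (â t + b̂),

the rectangle-rule running integral of the flow with its ordinary
least-squares line removed.  The OLS normal equations make `Σ v_t = 0` and
`Σ t·v_t = 0` hold to machine precision; the line absorbs the sensor
offset that integration would otherwise turn into a drift.  The `1/f_s`
factor keeps the trace in mL so the prominence parameter has physical
units.

Inspiration starts are local minima of `v` (lungs empty) with prominence
at least 0.03 mL, evaluated inside a 2 s sliding window; we bind the
"window length" parameter to the prominence evaluation (`wlen` of the peak
search), not to any smoothing.  Plateau minima resolve to their earliest
sample, and the expiration start is the *first* maximum between two
consecutive minima — both tie-breaks are fixed for determinism.  A cycle
whose inspiration or expiration lies outside [0.05 s, 2 s] is discarded
whole (merging neighbours would fabricate shapes); discarded spans are
retained so symbolization can mark them as unclassified time.  Boundaries
are stored as per-cycle triples `(t_in, t_out, t_end)` in 0-based sample
indices with half-open intervals, which makes phase concatenation exact.

## DTW with a slope-corrected Sakoe–Chiba band

The dissimilarity is the minimum over monotone alignment paths of the sum
of squared gaps — the squared Euclidean distance between the aligned
series, with no path-length normalization.  The band radius is specified
in seconds and converted with round-half-up, flooring at one sample
(0.01 s × 250 Hz = 2.5 → 3 samples).  For lengths m ≠ n the corridor is
centred on the resampled diagonal `j = i·(n−1)/(m−1)` and its half-width
is widened to `(slope+1)/2` when needed so consecutive row windows always
overlap: the corners are then always connected and a global uniform
dilation between the two sequences is never penalized, only local
dilations beyond the radius.  Ties in the backtracking prefer the
diagonal step, then the query step, then the reference step.

## BS-DBA barycenters

A cluster's reference shape minimizes `Σ_x DTW(y, x)` over fixed-length
`y` (an NP-hard problem); we run mini-batch stochastic subgradient
descent.  Each barycenter sample is pulled toward the data samples its
optimal path aligns it to, `g_k = Σ_x Σ_{(i,j)∈path, i=k} 2(y_k − x_j)`,
with step `η_t = η₀/(1+t)` and `η₀ = 1/(2·batch)` (so the first batch step
is exactly the jump to the batch-aligned mean).  Defaults: batch 32,
5 epochs.  Initialization is the set medoid (arg-min of the objective over
members) linearly resampled to the reference length — 0.2 s → 50 samples
at 250 Hz; when no length is configured, the rounded mean member length is
used.  The best end-of-epoch iterate is returned and the recorded
objective trace is the best-so-far value per epoch, hence monotone
non-increasing from the initialization.  A singleton set short-circuits to
its resampled member.

A known property of DTW averaging, visible in our benchmarks: under heavy
noise the optimum of the objective is slightly "noise-locked" (a wiggly
barycenter can align its wiggles to each member's noise), so the
barycenter approaches the clean template but does not converge to it.  At
the generator's operating point (SNR 20 dB, ±20 % warp) the barycenter
still beats the medoid's distance-to-template in ≈95 % of runs.

## Clustering, ordering, symbolization

Sequences are z-normalized with the population (1/n) standard deviation —
fixed for determinism — making clustering invariant to amplitude offset
and positive scaling; zero-variance sequences carry no shape and are
excluded from training and symbolized as outliers.  K-Means++ (D²
sampling under the DTW measure) seeds the references; assignment is
nearest-centroid DTW; the update is BS-DBA per cluster; the loop runs a
fixed 10 iterations with no convergence test.  Empty clusters are
reseeded with the globally farthest sequence.  Inspiration and expiration
are fitted fully independently.  After fitting, clusters are relabelled
in increasing *member* mean duration (not barycenter support): letters
for inspiration, digits for expiration.

Symbolization is 1-NN DTW against the references, applied to z-normalized
phases (normalization at both training and symbolization time, for
consistency).  The per-reference outlier threshold is the empirical
α-quantile (linear interpolation between order statistics) of the
within-cluster training distances, α = 0.95 by default; a combined cycle
symbol is an outlier if either phase is.  Duration-discarded cycles are
emitted as outlier spans so bar codes cover the full timeline.

## Statistics

The unit of observation is the per-subject percentage of *classified*
time per referent cycle (consistent with the RC maps).  Each cell is
tested with a two-sided Mann-Whitney U — exact null distribution when both
groups have fewer than 8 subjects and no ties, the tie-corrected normal
approximation otherwise — and the K₁·K₂ p-values are adjusted with
Benjamini–Hochberg; cells constant in both groups get p = 1 rather than
being dropped, preserving the map shape.  Pre/post comparisons default to
the same unpaired test, with a paired Wilcoxon available as an option.
The FDR size simulation draws both groups from one Dirichlet over the 25
cells; the power simulation uses independent Gaussian cells with a single
shifted cell, because shifting one component of a composition necessarily
perturbs the others and would confound the off-cell false-positive rate.

## Synthetic data generator

The generator emulates murine nasal airflow as a concatenation of
labelled cycle archetypes (~0.3 s cycles, peak flow 1.5 mL/s, giving a
tidal volume of ~0.15 mL): inspiration shapes are a half-sine, a biphasic
half-sine whose middle window is attenuated to 20 % of the envelope
(impaired but ongoing inflow), or a delayed inflow behind a
pre-inspiratory pause; expiration shapes are a half-sine or a
post-inspiratory pause of graded duration followed by the outflow.
Pauses are rendered as a quasi-closed airway with an 8 % residual leak —
a pause is never a perfect seal, and the leak keeps the volume strictly
monotone through it so boundaries stay well defined under noise.
Expiration amplitude is rescaled so each cycle's net volume is exactly
zero.  Distortions: per-cycle uniform warping of Ti/Te, additive white
noise (`noise_sd_for_snr` maps an SNR in dB to the matching σ), and an
optional slow sinusoidal baseline drift (0.05 Hz) that exercises the
detrending.  A half-expiration lead-in and half-inspiration lead-out make
the first and last true boundaries interior volume extrema, so noise-free
segmentation recovers the exact cycle count.  Even-in-time subsampling
ranks cycles by `t_in` and picks the cycles nearest an even time grid,
with strict-increase repair so the requested count is met exactly.

What the generator does *not* model: lung mechanics, genotype-specific
physiology, apnea/sniffing events, sensor band-pass effects, or
correlated (non-white) noise.  Passing tests therefore demonstrate the
correctness and robustness of the algorithmic pipeline under controlled
distortions, not performance on real plethysmography recordings.

## Evaluation conventions and problem sizes

Benchmarks run at desk scale, chosen to exercise every code path while
keeping the suite fast: cohorts of 4 recordings × 60 cycles with three
archetypes (K = 3 per phase), 10 seeds for clustering recovery, 5 for
end-to-end recovery, 20 for barycenter template recovery, 1000/200
replicates for the FDR size/power simulations; the bookkeeping check runs
the full 32 × 1,800-cycle subsampling.  End-to-end symbol accuracy is
scored on *classified* cycles after optimally matching predicted symbols
to ground-truth classes (Hungarian assignment on the contingency table;
predicted outliers never count as correct): the α = 0.95 gate flags
≈1−α² ≈ 10 % of cycles by construction, which is reported separately as
the outlier fraction rather than folded into the accuracy.

## Known limitations

* The number of references K is user-set; no selection heuristic is
  provided.
* BS-DBA hyperparameters (batch, epochs, step schedule) are package
  defaults; the upstream method fixes only the estimator family.
* Symbolizing recordings outside the training set is possible but not
  recommended — behaviours absent from training surface only as outliers.
* Figures are deterministic for a fixed matplotlib backend/version, but
  byte-identity of saved images across matplotlib versions is not
  guaranteed.
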