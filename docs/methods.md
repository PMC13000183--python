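# Methods

`topotrack` is a simulation and decoding pipeline for a specific question
in visual cognition: during multiple-object tracking (MOT), does the brain
maintain the tracked items as one abstract shape — the illusory polygon
formed by the shortest closed path through the four targets — rather than
as four independent locations?  If it does, *qualitative* changes of that
polygon (its topological transitions) should leave measurable traces in
the ongoing EEG.  The package builds every stage needed to test this
end-to-end on synthetic data with known ground truth: trajectory
simulation, geometric event detection, synthetic EEG generation, template
decoding, and group-level inference.

## 1. Trajectory simulation

Eight visually identical items move inside a 14.4° × 14.4° field at a
constant 4.1°/s for 4 s per trial; no two items ever come closer than
0.8°; four items form the tracked (target) set.  A session holds 300
trials, evenly split over five probe-match conditions M0–M4 that are used
downstream purely as a 5-fold train/test selector.

The original display algorithm is not fully specified, so the motion law
here is a bounded random heading drift: at Poisson-distributed instants
(rate `turn_event_rate`, default 1 Hz) an item draws a new target heading,
toward which its current heading turns at most `turn_rate_limit` (default
270°/s).  This satisfies "curved, continuous, unpredictable" motion while
keeping speed exactly constant.  Boundary handling is a two-frame
look-ahead: when the look-ahead point would leave a safe inner box, the
target heading is overridden toward the field centre.  The safe margin is
2.2 turning radii — the worst case is a U-turn started while heading
straight away from the centre near a corner, which penetrates up to two
turning radii past the trigger line; speed is never altered, so there are
no reflection discontinuities.

Trials combine individually generated paths.  Rather than rejecting whole
8-path combinations (acceptance probability is below 1% at these
densities), paths are admitted one at a time from a pre-generated pool,
resampling any candidate that violates the 0.8° minimum distance against
the already-admitted paths and extending the pool when exhausted.  The
result satisfies the same constraint — every pairwise distance ≥ 0.8° on
every frame, verified by an independent brute-force scan in the tests —
at a few dozen candidate checks per trial.  A budget (default 10,000
checks) turns unsatisfiable configurations into an explicit error
reporting the closest approach achieved.

The frame rate defaults to 100 Hz and is configurable; all event times are
carried in seconds so nothing downstream depends on it.

## 2. Topological events

For four points there are exactly three distinct cyclic orders, and the
shortest-path polygon is the one of minimal closed-path length (always
simple: for a convex quadruple only the hull order is simple, and with one
interior point all three orders are simple, so the minimum is
well-defined).  The convex hull of the quadruple has four corners (polygon
convex) or three (one interior point; polygon concave); coincident or
collinear quadruples are flagged degenerate and carried over.  Three event
types follow from consecutive frames:

* **flip** — the canonical cyclic order (invariant under rotation and
  reversal) changes; geometrically possible only while concave;
* **concave** — hull corners drop 4 → 3;
* **convex** — hull corners rise 3 → 4.

Events are stamped at the later frame of the pair.  Degenerate frames
produce no events; the last valid state is carried forward across them.
Hull corners are computed by vectorised orientation tests (each point
against the triangle of the other three); `scipy.spatial.ConvexHull`
serves as the independent oracle in the test suite rather than as the
production path, which must cover 300 trials × 401 frames × 2 item sets
in well under a minute.

**Filtering.**  Only isolated events enter the analyses: an event is
dropped when another event of the same type occurs within 500 ms on
*either* side (both members of a close pair go — the standard
overlap-avoidance rule for event-locked averaging), and events within
500 ms of motion onset or offset are excluded.  Two alternative readings
are provided behind flags: `debounce_rule="keep-first"` retains the
earlier member of a close pair, and `debounce_mode="global"` applies the
repeat filter across types.  The symmetric per-type rule is the default
because a same-type neighbour inside the epoch window contaminates both
epochs, not just the later one.

## 3. Synthetic EEG

Each subject's recording is continuous 32-channel data at 500 Hz: 4 s
motion windows separated by 1 s of pure noise, one fixed trial set shared
by all subjects (as in a fixed-session design), independent noise per
subject.

* **Noise** is Gaussian with a 1/f^α spectrum (α = 1 by default),
  unit variance per channel, and pairwise spatial correlation ρ
  (default 0.2) induced by a shared component before spectral shaping.
* **Responses** are Gabor kernels (Gaussian envelope σ = 100 ms ×
  sinusoid), one per event type, at 3 Hz (flip), 5 Hz (concave, sine
  phase) and 7 Hz (convex).  These frequencies keep each kernel's
  autocorrelation positive across ±50 ms — the interval over which
  event-time similarity is averaged — as is true of real transition ERPs,
  while pairwise waveform correlations stay ≤ 0.21.  Peak amplitude is
  `snr` µV against the unit-variance noise.
* **Latency shifts** place the ground-truth encoding asymmetry: the flip
  kernel is centred 150 ms *before* its event (anticipatory), the concave
  kernel 150 ms *after*, the convex kernel at 0 ms.
* **Topography**: all three kernels share one unit-norm bilateral
  ventral-occipital scalp pattern (strongest at O1/O2, falling off over
  O9/Oz/O10 and parietal sites), mirroring a single decodable component.
* **Placement**: kernels are embedded at *every* non-degenerate target
  transition (`embed_at="raw"`), because the simulated brain responds to
  each transition it perceives — the repeat and boundary filters are
  analysis decisions, not properties of the brain.  Distractor-set events
  drive nothing, which makes the distractor pipeline an exact null
  control.

What this generator deliberately does not emulate: ocular/muscular
artifacts (no ICA stage is needed or provided), realistic volume
conduction or per-subject topography variability, amplitude/latency
jitter of the responses, and any genuine brain dynamics between events.
A passing pipeline therefore demonstrates correctness and sensitivity of
the *analysis*, not that real recordings contain such signals.

## 4. ERP stage and spatial PCA

Preprocessing is a zero-phase 4th-order Butterworth high-pass at 0.5 Hz
followed by re-referencing to the mean of the two mastoid surrogates
(TP9/TP10).  Epochs are cut at ±400 ms around each event (2 ms steps at
500 Hz; event times snapped to the nearest sample) and never cross a
trial's motion window; epochs that would are dropped and counted.

Grand averages are pooled means over *all* events of a type (each event
weighs equally — not a mean of per-subject means; with unbalanced counts
these differ, and the pooled form is the one used throughout).

The channel weights come from a PCA of the three per-type grand averages:
observations are the epoch time samples of all three types stacked
(3 × 401 rows), variables the 32 channels, centred per channel, covariance
(not correlation) PCA — the weights later multiply raw µV signals with no
per-channel rescaling, so correlation scaling would be inconsistent.
Eigenvector signs are fixed so each component's largest-magnitude loading
is positive, making the weights reproducible run to run.  Note that after
pair re-referencing the data have rank 31, so the last component carries
no variance; the fitted rank is exposed as `rank_` and flagged.
Projection (`project`, or `SpatialPCA.transform`) is the plain weighted
channel sum without re-centring; the omitted constant offset is invisible
to the windowed-demeaned correlation that consumes the projections.

Component choice: on this generator the kernel topography dominates the
grand-average ERP, so C1 is the informative component and the tests pin
it; the pipeline also offers `component="auto"`, which picks the
component maximising training-set self-similarity at events, for settings
where the informative component is not known a priori.

## 5. Event-similarity decoding

The event-similarity measure (ESM) between the projected signal
`p(t)` and an event signature `s(τ)`, τ ∈ [τ_min, τ_max], is a sliding
Pearson-type correlation: both the signature and the signal slice
`p(t+τ)` are demeaned over the window and normalised by their windowed
SDs, giving a value in [−1, 1] at every t.  Implementation notes:

* the correlation is computed by a sliding-window matrix product with
  cumulative-sum window variances; the tests pin it to a naive per-t
  Pearson oracle at 1e-10 on a 60 s trace;
* windows that leave a trial's motion span are *missing* (NaN), never
  extrapolated; locked averages then average over defined samples only,
  with effective counts logged;
* zero-variance windows yield 0 and a flag rather than NaN, keeping
  averages defined while preserving auditability.

Signatures are pooled means of the projected training epochs per type,
with training/test splits given by the probe-match condition (five
complementary splits; the condition is assigned after the motion phase,
so it is a random selector).  The locked ESM averages the trace around
test-set events of each type over ±τ_w (400 ms by default).

The permutation baseline shuffles the three type labels among a split's
training events (counts preserved, times untouched; PCA weights held
fixed), rebuilds signatures, and re-locks; the mean of 50 such curves (8
in the reduced test configurations) is subtracted.  Corrected curves are
averaged, unweighted, over the five splits and then over subjects; cells
where a split has no test events of a type are dropped and counted.

**Time-lag maps.**  Signatures are built on ±500 ms support, a 400 ms
window is cropped at centre ("lag") τ̄ ∈ {−300, …, +300} ms in 20 ms
steps, and the whole correlate/lock/correct chain re-runs per lag with
τ_w = 500 ms, permutation label draws shared across lags so the baseline
noise is coupled.  Anticipatory encoding should appear as similarity
concentrated at negative lags, lagged encoding at positive lags.

**A caveat this package quantifies.**  Two effects distort the corrected
lag map's *argmax* away from the embedded latency shifts.  First, the
label-shuffled baseline is shape-diluted rather than shape-free: a mixed
signature still contains the own kernel at one-third weight, and because
the ESM is amplitude-blind, the baseline reaches roughly √⅓ ≈ 0.6 of the
raw effect exactly at the kernel-containing lags, cutting the own-kernel
contribution there ~2.5-fold.  Second, transitions of different types
cluster in time (a concave transition follows a convex one), so the
response to a neighbouring event is genuinely predictive structure; it is
type-specific, is not reproduced by the mixed-label baseline, and
survives correction — at negative lags for concave events.  The raw
(uncorrected) lag profiles localise the information on the correct side
for both types (flip dominant at negative lags, concave at positive
lags, with matching argmax signs), which the suite asserts; after
baseline correction both profiles peak at small negative lags under
these conditions, so the corrected-map argmax is not a reliable readout
of the encoding latency here — a failure mode of that statistic under
correlated event streams, not of the decoder, and the test demanding it
documents exactly this.

## 6. Statistics

* `cluster_permutation_t`: one-sided (positive) one-sample t at each grid
  point; points above the t threshold at the primary α (0.05, df = n−1)
  form contiguous clusters (4-connectivity on 2-D grids); the cluster
  statistic is the mass (sum of t); the null is the maximum mass under
  random per-subject sign flips.  Random mode uses the (b+1)/(m+1)
  estimator; `n_perm="all"` enumerates all 2^n patterns exactly and is
  pinned to a brute-force oracle in the tests.  Zero-variance points get
  t = 0.
* `pointwise_repeated_F`: classic one-factor within-subject F from sums
  of squares, vectorised over the grid; no sphericity correction
  (p-values labelled uncorrected); points with numerically zero condition
  variance return F = 0.  Verified against `pingouin.rm_anova`.
* `esm_histogram_correlation`: Pearson correlation between a locked ESM
  curve and the 20 ms-binned histogram of other-type events around the
  reference events, the histogram linearly interpolated onto the ESM
  grid; constant inputs are reported as undefined rather than 0.
* `performance_split`: median split on per-subject error rates (high
  performance = low error); boundary ties are resolved by subject-id
  parity, then id, so the split is deterministic.

## 7. Reduced problem sizes

The default pipeline run mirrors the study scale (300 trials, 50
permutations, ±300 ms lag range).  The test suite uses deliberately
smaller but structurally identical configurations: recovery runs use one
fixed 60-trial session with 6 subjects of fresh noise per replicate
(20 replicates, snr 1.5, 8 permutation baselines), and the false-positive
controls use 10-trial sessions with 4 subjects and a ±200 ms locking grid
over 100 replicates per mode.  These sizes keep the full suite in the
tens of minutes while leaving every pathway — splits, baselines, lag
cropping, cluster inference — identical to the full-scale run.

## 8. Known limitations

* The motion law is a stand-in; absolute event rates depend on it, and
  the simulated totals run 10–30% above the reference counts (the
  reported totals are reproduced to within the stated ±25% band for
  flips, marginally for concave/convex).
* The generator's deterministic, identical-per-event kernels make
  cross-event context unrealistically reliable; see the lag-map caveat.
* Only quadruples are handled; configurations of 3 or >4 items, occlusion
  and 3-D motion are out of scope.
* No artifact simulation or removal; the optional `to_mne()` exports
  exist for interoperability with standard EEG tooling, not as a
  processing path.
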