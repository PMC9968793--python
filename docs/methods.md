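# Methods

This note documents the models, numerical choices and limitations of
`bcitrack` the way its maintainers reason about them. Nothing here states a
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Geometry on SPD matrices

Trial covariances live on the SPD manifold with the affine-invariant metric.
All downstream metrics inherit its congruence invariance
δ(WAWᵀ, WBWᵀ) = δ(A, B), which is what makes them agnostic to linear channel
remixing (re-referencing, electrode scaling).

- **Covariance estimator.** Sample covariance with divisor N−1 after
  per-channel mean removal, symmetrized. If the smallest eigenvalue is not
  strictly positive, diagonal loading of max(`spd_jitter`, 1e-10·tr/C) is
  added (escalating ×10 until SPD). Shrinkage is deliberately *not* applied
  here: with 9 channels and 500-sample epochs the estimate is
  well-conditioned, and shrinkage would bias the Riemannian distances that
  the metrics are made of.
- **Distance.** Square root of the summed squared log generalized
  eigenvalues of the pencil (A, B), via `scipy.linalg.eigh(a, b)` — no
  explicit inverse. Batched distance-to-reference uses one whitening by the
  reference's inverse square root and a single batched eigendecomposition.
- **Fréchet mean.** Fixed-point iteration: whiten the set at the current
  estimate, average the matrix logarithms, exponentiate the mean tangent and
  transport back. Initialised at the arithmetic mean (or a caller-supplied
  warm start), tolerance 1e-8 on the tangent gradient norm, at most 50
  iterations; non-convergence logs a warning and returns the best iterate.
  The trial-wise engines warm-start each mean at the previous trial's mean,
  which keeps per-trial updates at a handful of iterations.
- **Degenerate classDistinct.** If both intra-class dispersions vanish
  (all trials identical) the ratio is 0/0; distances below 1e-12 are treated
  as exact zeros, giving classDistinct = 0 when the class means also
  coincide and an inf-with-warning otherwise, so batch evaluation continues.

## Trial-wise engines

All three engines emit (classDistinct, mean classStability) after every
trial of blocks 2..N; block 1 only warms them up because no previous-block
reference exists (the classifier baseline likewise needs a prior block for
training).

- The **running** engine is, by construction, exactly the static metrics on
  the union of all trials so far — it is the anchor oracle the other
  variants are tested against.
- The **sliding window** engine keeps one FIFO queue per class. Queue length
  defaults to 20 trials per class — exactly one block's worth, so the
  comparison horizon matches the block structure. The queue length is not
  dictated by the method; it is exposed in `EngineConfig`.
- The **weighted average** engine freezes, at each block start, the previous
  block's per-class Fréchet mean and subset dispersion Φ* (disjoint subsets).
  After each trial the post-trial mean is the geodesic point at α₁ = 0.9
  between the frozen mean and the current queue mean (the queue mean is the
  *Riemannian* mean — the only choice consistent with the geodesic update),
  and the post-trial dispersion is (1−α₂)Φ*_{prev} + α₂Φ*_{cur} with
  α₂ = 0.9, where Φ*_{cur} uses only current-block trials with the
  overlapping-tail rule. Both the classDistinct denominator and
  classStability use these Eq-style updated dispersions, for internal
  consistency. Before a class has any current-block trial its Φ*_{cur}
  defaults to the frozen previous-block value (no information yet); with
  fewer than N_t current trials, Φ* falls back to the plain dispersion of
  the available trials.
- **Subset dispersion Φ\*.** Chronological subsets of N_t = 5 trials.
  For completed blocks the subsets are disjoint and a remainder is dropped;
  for the within-block running value the final subset is the most recent
  N_t trials and may overlap its predecessor by up to N_t − 1 trials.
- **Reinforcement reference.** M_{k−1} is the static metric of the completed
  previous block (plain dispersions for running/sliding, Φ* for the
  weighted variant), not the value after the previous trial — the signal is
  meant to emphasise the trend since the block boundary, not trial-to-trial
  volatility. Reinforcement-sum normalisation to [−1, 1] as seen on figure
  axes is presentation only; every statistic here operates on raw sums
  (rank- and sign-based statistics are unaffected).

## Classifier baseline

CSP filters are the generalized eigenvectors of (S₁, S₁+S₂) where S_c is the
Euclidean mean of the class trial covariances; four filters (two per
spectrum end), log-variance features, LDA with analytic Ledoit-Wolf
shrinkage (`sklearn`, `solver="lsqr", shrinkage="auto"`). Sub-band selection
runs stratified, seeded 3-fold CV over {8-11, 9-13, 11-19, 17-30, 8-30} Hz
on the training blocks; ties break toward the widest band for robustness.
RWCA is leave-one-trial-out within a single block on the standard 8-30 Hz
pipeline, refitting CSP and LDA per fold. Spatial patterns are
A = ΣWᵀ(WΣWᵀ)⁻¹, scaled so the largest absolute entry is 1.

## Preprocessing

Zero-phase (forward-backward) 4th-order Butterworth filtering; the central
2 s of each trial are cropped *after* filtering the full trial so edge
transients stay outside the analysed window; decimation is FIR and
zero-phase (DC-exact). The potato field uses the enumerated 5 contact-loss
pair detectors (1-20 Hz band-pass) and 3 general quadruple detectors
(8-38 Hz band-stop, implemented as written and overridable via
`PotatoFieldSpec`), each calibrated in a single offline pass on the full
trial set: z = (δ_R(Γ_i, ref) − mean)/std with threshold 2.5, rejecting a
trial flagged by *any* potato. No iterative re-calibration is performed.
External artifact annotations travel as the optional `artifact_flags`
dataset of the HDF5 session container.

## Synthetic sessions: what they emulate and what they do not

The generator emulates three user-performance levels through ERD
lateralization rules acting on two band-limited SMR sources (mu 8-13 Hz plus
a 0.4-weighted beta harmonic 16-26 Hz) at the left/right motor cortices,
mixed into 9 electrodes (Fz, F4, C4, Cz, P4, Pz, P3, C3, F3) through
Gaussian spatial profiles centred at C3/C4 (σ = 0.8 grid units), with
per-source 1/f background and white sensor noise; 250 Hz, 4 s trials, blocks
of 40 trials (20 per class, interleaved), seven two-block session types.

- *low*: both tasks attenuate the right source; *moderate*: the right-hand
  task lateralizes correctly on exactly half its trials (exact-half rather
  than Bernoulli to reduce corpus variance; a flag restores Bernoulli);
  *high*: consistent contralateral ERD. ERD depth 0.5 (amplitude halved).
- **Calibration** (done once, then frozen): sensor noise 2.0 and background
  2.0 put leave-one-trial-out CSP-rLDA accuracy of high-level blocks at
  ≈ 0.94, inside the intended 0.8-0.95 band, with low ≈ 0.50 and
  moderate ≈ 0.64 — the intended monotone ordering.
- **Inter-block covariate drift**: each block draws one log-normal (σ = 0.2)
  amplitude multiplier per source plus one for the background, so trial
  distributions are more alike within than across blocks. Real SMR
  recordings show exactly this kind of session/block drift, and it is what
  gives the running and sliding classStability variants their documented
  negative bias; without it the generator's blocks would be implausibly
  exchangeable.

What the generator does *not* emulate: volume conduction from a real
leadfield, eye/movement artifacts (excluded by design), multi-session
recordings, realistic inter-subject variability, or learning *within* a
block. A green directional test therefore establishes that the metrics
respond correctly to controlled covariance-structure changes — not that
they are validated on real EEG.

## Evaluation battery

Ground truth per transition is the change in the static block-wise metric;
the predictor is a method's reinforcement sum. Spearman correlation for
simulated corpora; repeated-measures correlation (pingouin `rm_corr`,
subjects with one record dropped with a log message) for multi-subject
data. Bootstrap CIs for correlation differences resample whole sessions
(or subjects) to preserve pairing, at the Bonferroni-adjusted level
1 − 0.05/family. ROC/AUC uses sign(Δ) as label; paired AUCs are compared
with DeLong's structural-components test (midrank implementation, p = 1 for
identical scores). Sign agreement uses the natural zero threshold; zero
deltas or sums are excluded from sign analyses and counted in the report.
Exact McNemar on paired sign-correctness indicators; Holm step-down across
each family of pairwise p-values. Metric-based methods are paired with their
own metric family's deltas; classifier sums are evaluated against both
families.

## Known limitations

- The weighted engine's dispersion update makes its classStability nearly
  always a smooth blend of block-level dispersions; its per-trial
  sensitivity is intentionally damped and single-trial anomalies barely
  move it.
- Potato-field z-scores are standardized within-sample, so on perfectly
  clean data an occasional borderline trial (z slightly above 2.5) can
  still be flagged; the procedure controls gross artifacts, not a false
  positive rate.
- EDF/GDF import is not provided; sessions enter through the HDF5 container
  or in-memory `Session` objects.
- Only two-class sessions are supported throughout.
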