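# Methods

## The model

Multi-channel surface EMG envelopes are modelled as an additive mixture of
a small number of muscle synergies.  For an envelope matrix
`A (m × n)` — m muscle channels, n time samples — non-negative matrix
factorization finds

    A ≈ W H,    W ≥ 0 (m × k),  H ≥ 0 (k × n)

where each column of `W` is a fixed muscle weighting (a synergy pattern)
and each row of `H` its activation time course.  The factorization
minimizes the Euclidean cost `J = ‖A − W H‖_F` with the Lee–Seung
multiplicative updates

    H ← H ⊙ (WᵀA) ⊘ (WᵀW H),
    W ← W ⊙ (A Hᵀ) ⊘ (W H Hᵀ),

which keep both factors non-negative and never increase `J`.  After every
iteration the columns of `W` are rescaled to unit Euclidean norm and the
matching rows of `H` by the inverse factor; the product `W H` is unchanged
but patterns become comparable across subjects and segments (and the
correlation-based similarity measure becomes scale-free).  A small
constant (1e−12) in every denominator guards against division by zero.

Goodness of fit is the variability accounted for,

    VAF = 1 − ‖A − W H‖²_F / ‖A − Ā‖²_F ,

with `Ā` the grand mean of `A`.  The model order per motion is the
smallest `k` whose mean VAF over all motion segments exceeds 0.85.

### Numerical choices

- **Restarts.** A single factorization runs 20 random restarts (entries
  uniform on (0, 1], scaled to the data magnitude) plus one NNDSVD-style
  initialization (double SVD with negative parts zeroed; zeros replaced by
  `mean(A)·1e−3`), and keeps the run with the highest VAF.  Ties resolve
  to the earliest run, so results are bit-reproducible given the seed.
  The batch workflows (per-window feature extraction, per-segment VAF
  tables) use 3 random restarts plus the SVD restart: on 4 × n matrices
  with k ≤ 3 the restarts almost always converge to the same optimum, and
  the full 21-restart schedule would multiply runtime for no measurable
  change in VAF.
- **Convergence.** Relative cost decrease below 1e−6, or 1000 iterations.
- **Fixed-pattern activations** (`estimate_activation`) run only the H
  update from a uniform positive start; W is never modified.

## Preprocessing and segmentation

Raw sEMG (1 kHz) is band-passed 20–450 Hz with a 4th-order Butterworth
filter applied forward–backward (zero phase, so envelopes stay aligned
with the goniometer trace), mean-removed, and full-wave rectified.  Each
channel is normalized by its maximum over the subject's whole session (all
motions), then smoothed by a centered 100 ms moving-RMS window
(shrink-to-valid at the edges).  Envelope entries therefore lie in [0, 1].

Motion repetitions are found on the angle trace after a 100 ms moving
average.  For the bell-shaped standing/sitting tasks, repetitions are
peaks with prominence ≥ 20% of the angle range and ≥ 1 s separation;
each repetition starts at the first sample whose |angular speed| reaches
10% of the initiating phase's maximum and ends at the first sample after
the terminal-phase speed peak where |speed| drops below 10% of that
phase's maximum.  Gait cycles are delimited by the first angle minimum
after each angle maximum.  The 100 ms angle-smoothing window and the peak
parameters are package defaults (the segmentation rule itself fixes only
the 10% thresholds); they match the envelope smoothing scale and the
multi-second rests between repetitions.

Segment envelopes destined for synergy analysis are linearly resampled to
100 columns, giving 4 × 100 matrices.

## Similarity and representative synergies

Two pattern matrices are compared by the maximum correlation coefficient:
for `k1 ≤ k2`, every ordered selection of k1 columns of the larger matrix
is formed into a candidate, the Pearson correlation between column-stacked
vectorizations is computed, and the maximum taken.  Ordered selections
make the column correspondence part of the maximization; with k ≤ 4 the
enumeration is at most 24 arrangements.  Intra-group similarity is the
mean over all unordered within-group pairs, inter-group similarity the
mean over the full cross product.

A subject's representative synergy for one motion averages the
per-segment `W` matrices after removing outliers: each matrix is scored
by its mean max-CC against the others, and matrices whose score deviates
from the group mean by at least three (population) standard deviations
are dropped.  When all scores are equal (zero spread) nothing is dropped
— the strict-inequality reading would otherwise delete everything.  Note
a structural property of this rule: a lone outlier among n matrices has
z-score at most √(n−1), so groups of ten or fewer can never trigger a
removal; this is inherent to 3σ outlier rules on small samples, not a
defect of the implementation.  Survivor columns are aligned to the first
survivor by the max-CC correspondence before element-wise averaging and
renormalization; representative activations re-estimate each segment's H
under the representative W and average.

## Windowing, features, selection, classification

For classification the normalized envelope of each movement span is cut
into 256-sample windows advancing by 192 samples (64 shared samples
between neighbours); windows are restricted to the segmented movement
spans because rest periods contain no muscle activity.  Each window is
factored at k = 2 (or 3), synergies are sorted by descending activation
ratio `r_i = RMS(h_i)/Σ_j RMS(h_j)`, and features are read off:

- coarse: the 4k muscle weights of the reordered `W` (synergy-major);
- fine: coarse plus, per activation row, RMS, the four coefficients of a
  4th-order autoregressive model `h_t = −Σ a_i h_{t−i} + e_t` (Burg
  estimator, names AR2…AR5), the interquartile range (linear-interpolation
  quartiles), the waveform length `Σ|h_{t+1} − h_t|` and the mean absolute
  value — 24 features at k = 2, 36 at k = 3.  Degenerate (constant) rows
  get zero AR coefficients with a warning.

Feature selection is two-stage.  Relief-F weights each feature by
iterating over every sample (iteration count = sample count, one nearest
hit and one nearest miss per class, range-normalized Manhattan metric,
class-prior weighting of the miss terms); features with negative weight
are eliminated.  A sequential floating forward search then grows a subset
by the feature that most improves a wrapper score — the mean macro
F-measure of a 30-tree random forest under internal stratified 5-fold
cross-validation — with conditional backward elimination after each
addition, stopping after three consecutive non-improving additions.  The
internal 5-fold wrapper is deliberately distinct from the outer 10-fold
evaluation to avoid selection bias.  Forward ties break by feature name,
so selection is deterministic given the seed.

Classification uses a 30-tree random forest (Gini splits, √p candidate
features per split, unlimited depth, bootstrap sampling) under stratified
10-fold cross-validation.  Training folds are rebalanced to the rounded
geometric mean of the class counts — minority classes grown by ADASYN
(5 nearest neighbours, density-weighted interpolation toward minority
neighbours; classes with fewer than 6 samples fall back to duplication),
majority classes reduced by random sampling with replacement.  Test folds
are never resampled.  The headline number is the mean over folds of the
unweighted per-class mean F-measure, with

    P_i = n_ii/Σ_j n_ji,  R_i = n_ii/Σ_j n_ij,  FM_i = 2 P_i R_i/(P_i+R_i).

"Average F-measure" is read as macro-average over classes then mean over
folds; folds are stratified at the window level (a subject's windows may
appear in both train and test folds — the grouping follows the windowed
data set, not the subject).

## The synthetic cohort generator

The generator emulates the study conditions so the whole pipeline is
testable without the original recordings.  Each recording follows the
amplitude-modulation model of surface EMG: a planted envelope
`E = W_true H_true` multiplies a band-limited (20–450 Hz) zero-mean noise
carrier of unit RMS, per channel.  Rectify-then-smooth preprocessing
recovers `E` up to scale.  Envelope noise (default 5% of the envelope
peak, clipped at zero) and a per-subject pattern jitter (SD 0.05 before
renormalization) provide realistic variability; per-repetition effort
varies by ±20%.

- **Angle traces.**  Standing/sitting tasks: `reps` raised-cosine bells of
  6 s (2 s rise, 2 s hold, 2 s fall, 70° amplitude) separated by 3 s
  rests, the protocol timing of slow flex–hold–extend movements.  Gait: a
  sinusoid-like knee trace with one clear maximum and minimum per 1.32 s
  cycle (the mean gait-cycle duration of the cohort the pipeline is
  modelled on), four cycles per walking pass.
- **Planted patterns.**  Fixed per motion and distinct across motions:
  the standing task is flexor-led (FB/SEM), the sitting task extensor-led
  (RF/VM), gait uses three sharper single-muscle-dominant patterns.  Gait
  patterns are kept at low mutual coherence (≤ 0.34) deliberately: with
  temporally disjoint per-cycle bursts, the third singular value of the
  planted envelope — and hence the detectability of the third synergy
  after 100 ms RMS smoothing — is controlled by the pattern coherence.
- **Activations.**  Bell tasks: the agonist synergy is active through the
  whole movement (Tukey plateau, concentric–isometric–eccentric), the
  antagonist contributes onset/release co-contraction bursts at 0.8
  relative amplitude.  The bursts are kept off the plateau's flat top so
  that short windows never see two proportional activation rows — that
  would make the per-window factorization non-identifiable.  Gait: one
  raised-cosine burst per synergy per cycle, 0.18 cycle wide, evenly
  phased.
- **Group difference.**  Study-group (SG) recordings use
  `normalize(clip(W + group_shift·D, 0))` with a fixed per-motion
  direction `D` that redistributes weight *within* each pattern (e.g.
  between hamstring heads, or dominant-muscle weight onto one
  compensating muscle), mimicking compensatory recruitment while
  preserving the planted synergy count.  The default `group_shift = 0.9`
  expresses a marked pathological reorganization: it was chosen, together
  with the activation design above, so that the planted model-order
  contract holds in both groups and the binary diagnosis task is
  achievable at the F-measure scale reported for real knee-pathology
  cohorts (high 0.8s).
- **Seeding.**  One root seed; each recording derives its stream from
  (seed, subject id, group, motion) via a hash, so cohorts are
  bit-reproducible and insensitive to generation order.

### What the generator does not emulate

Motor-unit physiology, electrode crosstalk, ECG contamination, electrode
shift, fatigue drift, and heterogeneous pathologies.  Real sEMG also has
signal-dependent (multiplicative) noise and non-stationary carriers.
Passing tests therefore demonstrate that the pipeline recovers planted
structure under the amplitude-modulation model at realistic noise levels —
not that it attains any particular accuracy on clinical recordings.

## Problem sizes in tests and the acceptance script

Cohorts are scaled to desk size as the package's own test design: two
subjects per group × three motions × two repetitions for structure
recovery and motion recognition (≈ 600 windows), three subjects per group
× four repetitions of the sitting task for the diagnosis task (≈ 700
windows), and twenty seeded repetitions of the model-order recovery
check.  The real study is roughly an order of magnitude larger in every
dimension; window-level F-measures at desk scale carry correspondingly
more seed-to-seed variance (±0.03–0.05 observed).

## Known limitations

- The per-window NMF at k = 2 on 256-sample epochs is noisy where only one
  synergy is active inside the window; the second column then fits noise.
  Real pipelines share this property; it bounds window-level diagnosis
  accuracy well below segment-level analysis.
- The 3σ outlier rule cannot remove anything from groups of ≤ 10 segment
  matrices (see above); with few repetitions per recording the outlier
  count is structurally zero.
- Relief-F is O(n²p); at desk scale this is negligible but tables beyond
  ~10⁴ windows would need neighbour indexing.
- `select_synergy_number` decomposes every segment at every candidate k;
  its cost is linear in both.
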