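# Methods

This note documents the models implemented in `brainstates`, their
assumptions, the defaults that matter, and the design decisions taken where
the methodology left genuine choices open. Nothing here reports an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Observation model and inference

### Time-delay embedding

A recording is a parcels × time matrix `y` at sampling rate `fs` (250 Hz
default). Each time point is augmented with a symmetric window of `L = 15`
consecutive sample lags (−7…+7), giving `P × L` embedded channels ordered
parcel-major; edge samples with incomplete windows are dropped rather than
padded, so covariances never mix real data with zeros. For the reference
configuration of 52 parcels this yields 780 channels and
780·779/2 = 303,810 unique off-diagonal autocovariance parameters per state
— the motivation for the PCA step.

Group PCA pools the covariance over all subjects (a group HMM needs one
shared observation space), retains `2 × P` components by default, and scales
every component to pooled zero mean, unit variance. The order —
PCA first, then standardization of the pooled projections — is a choice;
standardizing per subject before PCA would reweight subjects with
atypical variance and break the shared-space interpretation.

### The hidden Markov model

Observations are modelled as `P(Y_t | x_t = k) ~ N(0, Σ(k))`: states differ
only in covariance, which in the embedded space means they differ in
autocovariance across lags, i.e. in spectral content. Means are fixed at
zero — after standardization, mean differences would capture slow drifts
rather than oscillatory structure.

Inference is Baum–Welch EM:

* scaled forward–backward recursions (per-step normalization), vectorized
  over subjects of equal length; the chain is never propagated across
  subject boundaries, and no transition is counted across them;
* M-step `Σ(k) = Σ_t γ_t(k) Y_t Y_tᵀ / Σ_t γ_t(k)`, with a ridge of
  `1e-6 × mean diagonal` added to keep every Σ(k) positive-definite on short
  runs;
* several random restarts (contiguous blocks assigned to random states seed
  the initial covariances; the transition matrix starts sticky at 0.9);
  the restart with the highest final log-likelihood wins. The log-likelihood
  is non-decreasing across iterations by construction and is checked to
  1e-6 nats in the tests.

Model selection across restarts uses the log-likelihood. A variational free
energy would add a complexity penalty; with a fixed K and fixed architecture
across restarts the data term dominates the comparison, and the surrogate is
deterministic and exactly testable. It is not claimed equivalent to a
variational criterion.

Decoding offers smoothed posteriors `γ_t(k)` (forward–backward), the
frame-wise MAP path `argmax_k γ_t(k)`, and the Viterbi path (log-space,
ties toward the smaller state index). Forward–backward and Viterbi are
verified against exhaustive path enumeration (K ≤ 3, T ≤ 8) to 1e-10, and
posteriors against an independent HMM implementation.

### Which path for which purpose

Temporal metrics default to the Viterbi path: a single globally consistent
hard assignment with exact run-length algebra. For *parameter-recovery
evaluation*, however, the frame-wise MAP path is used: frame accuracy is a
frame-wise quantity, and the Viterbi path's global smoothing systematically
absorbs visits shorter than the embedding window, lengthening mean dwell
times by ~20–25% at the benchmark SNR where the frame-wise MAP path shows
~13% error from the same fits. Both decoders are public API; the benchmark
in `brainstates.evaluate` documents this choice.

## Temporal statistics

All four per-state metrics come from one run-length decomposition of the
hard path, making `FO_k = SR_k × LT_k` an exact identity (boundary runs are
included in LT and SR for precisely this reason):

* FO — fraction of samples in state k;
* LT — mean contiguous visit length (s); NaN if never visited;
* INT — mean gap strictly between successive visits (s); NaN with < 2 visits;
* SR — visit onsets per second.

Transition probabilities default to the run-collapsed visit sequence
(`i → j` for consecutive distinct visits; diagonal structurally zero; rows
with no outgoing transitions left zero with a warning); a frame-wise variant
(`exclude_self=False`) is available. The most-likely cycle search is an
exhaustive scan over ordered cycles of distinct states scoring the sum of
log mean transition probabilities, returned in canonical rotation (smallest
state first, lexicographic tie-break).

## Spectral estimation

State spectra are computed on the **unprepared** parcel signals: the model is
trained in the embedded/PCA space, but its posteriors are carried back to
the raw data as weights. Non-overlapping 2 s windows are tapered with 4 DPSS
tapers (time–bandwidth 2.5); per state, window periodograms are averaged
with weights equal to the state's mean posterior in the window, normalized
by total weight; states below a minimum total weight get NaN (undefined),
never zeros. The 2 s / 4-taper default resolves the 1–45 Hz range with
≈ 1 Hz resolution and ±1.25 Hz spectral concentration at 250 Hz; the PSD is
one-sided density, so its full-band integral matches signal variance (checked
within 10% on white noise).

Band decomposition uses Frobenius NMF by multiplicative updates (error
non-increasing per iteration), with 5 random restarts keeping the lowest
final reconstruction error — multiplicative updates alone find local minima.
Four bands per state is the default. The band of interest per state is
assigned automatically on the state's *dynamic* spectrum: the across-state
(static) mean spectrum is subtracted, the difference rectified, projected
onto the band profiles by non-negative least squares, and the profile with
the largest coefficient × mass contribution wins; a manual override is
possible by setting `band_assignment` directly. Note that NMF factors of a
planted band mixture are only identifiable when some rows are nearly pure
single-band spectra (separability); the recovery benchmarks plant
band-dominant rows for this reason.

Band power maps integrate the group-mean PSD against a band profile
(trapezoidal, profile-weighted); "departure" mode subtracts the across-state
mean to express each state's excursion from static activity, and top-parcel
selection ranks parcels by absolute departure (ties toward the smaller
index). Network projection is a plain matrix product with a non-negative
parcels × networks overlap matrix whose rows sum to at most 1.

## Behavioral PLS

`R = Xᵀ Y / (n − 1)` on column-standardized blocks; SVD of R gives singular
values, saliences (U brain, V cognitive) and latent scores XU, YV. Component
signs are fixed by making each component's largest-|value| cognitive
salience positive. Explained covariance fractions are `S_i² / Σ S²`.

Cognitive preprocessing: (i) subjects with more than 3 missing scores among
the 8 tasks are excluded, the rest median-imputed within age deciles;
(ii) covariates (sex, volume proxy, screening proxy, retained time points)
are regressed out by OLS; (iii) each score is quantile-normalized by the
rank-based inverse-normal transform with the Blom offset,
`Φ⁻¹((r − 3/8)/(n + 1/4))`; (iv) education enters the cognitive block as a
feature (it carries salience information jointly with the task scores rather
than acting as a nuisance); (v) the two age polynomials are appended, each
rescaled to the standard deviation of age so their saliences are comparable
with the other features.

**Permutation test.** Rows of Y are permuted; the i-th *sorted* permuted
singular value is compared with the i-th observed one,
`p_i = (1 + #{S_perm,i ≥ S_i}) / (1 + n_perm)`. For the leading component
this is the classical max-vs-max comparison and is calibrated: on null data
the measured rejection rate at α = .05 stays within two binomial standard
errors of .05 and the p-values are uniform. An alternative that Procrustes-
rotates each permuted solution onto the observed saliences before comparison
is provided (`align="procrustes"`) for comparability with toolboxes that use
it, but it is strongly anti-conservative — the rotation mixes permuted
components and deflates the null — and is not the default.

**Bootstrap.** Subjects are resampled with replacement; each resample's
components are aligned to the original by a *signed permutation* (Hungarian
matching on the stacked brain+cognitive salience cross-products, sign from
the matched inner product). This resolves exactly the SVD's order and sign
indeterminacies; a soft orthogonal rotation would additionally mix resampled
components with the original noise realization and shrink the bootstrap SDs
(~1.5× in our measurements), which inflates every BSR and lets pure-noise
features cross the |BSR| ≥ 3 cut. BSR = original salience / bootstrap SD;
resamples with a zero-variance column are redrawn.

Multiple models (temporal, transition, spectral feature blocks) are
FDR-adjusted together with Benjamini–Hochberg over the pooled p-values.

## Synthetic data

The signal generator draws a hidden chain (geometric dwell times from the
self-transition probabilities; default stickiness 0.96 at 250 Hz ≈ 100 ms
mean dwell, typical of MEG state studies), then adds each active state's
sinusoids (default: one oscillator per state on a disjoint parcel block,
frequencies spread over 2–35 Hz, amplitude 1.0) to white Gaussian noise
(SD 1.0), re-randomizing phase at every visit so states are burst-like
rather than long coherent oscillations. An optional `one_over_f` exponent
spectrally shapes the background. What it does **not** emulate: sensor
physics, source leakage, artifacts, inter-subject spatial variability, or
amplitude non-stationarity within a state — so passing recovery tests
demonstrate the estimator is correct under its own assumptions, not that
real MEG meets them.

The cohort generator plants latent components `z_i` built from the two age
polynomials (defaults: component 1 monotone `a − d`, component 2 inverted-U
`a + d`, standardized), scales them by per-component strengths (1.0, 0.6),
and maps them through unit-norm saliences into the eight task scores (noise
SD 0.5) and — scaled by `effect_size` = 2.0 in units of feature SD — into
the brain block. Planted saliences default to orthonormal rows. The
orthogonality and the distinct strengths are identifiability requirements,
not conveniences: an SVD ground truth with non-orthogonal or equal-strength
components is rotationally degenerate and no estimator could recover it.
The magnitudes were chosen once so that recovery at n = 200 is reliable
(|r| ≳ 0.95) yet far from noiseless — roughly a third of each score's
variance is noise, and the permutation/bootstrap inferences remain
non-trivial. All defaults are configurable.

## Benchmark problem sizes

`brainstates.evaluate` fixes the following desk-scale conditions, chosen
once and used by both the test suite and `scripts/acceptance.py`:

* **TDE-HMM recovery** — 60 subjects × 60 s at 250 Hz, 16 parcels, 8 states,
  15 lags, PCA to 32 = 2 × 16, EM with 2 restarts and at most 25 iterations.
  Sixteen parcels give each state a two-parcel oscillator; fewer parcels
  per state leave the condition barely identifiable at amplitude 1.
  Raising the oscillator amplitude does not improve dwell recovery — the
  embedding window smears strong oscillations across visit boundaries — so
  the generator default is kept.
* **PLS calibration** — 200 null datasets of n = 200 with 6 + 6 features,
  500 permutations each; recovery and BSR benchmarks use the cohort
  defaults above with 200 bootstrap resamples (scaled down from the 10,000
  permutations / 1000 resamples defaults, which are impractical to repeat
  hundreds of times in a test run and change only the resolution of the
  p-values / SDs, not the calibration being verified).

## Numerical choices and degenerate inputs

* Forward–backward uses per-step normalization; Viterbi runs in log space;
  `log 0` transition entries are tolerated (they simply never win).
* Covariance ridge 1e-6 × mean diagonal; EM restarts that still go
  non-finite are dropped, and only if all restarts fail is an error raised.
* G-ESD is applied to log-variance of non-overlapping windows (variance
  bursts are the dominant artifact signature; the log improves normality);
  a degenerate spread (identical windows) yields no outliers by definition.
* Sign alignment maximizes agreement of lagged cross-covariance stacks with
  the group template, greedily with restarts; the objective is invariant to
  global per-subject and global per-parcel flips, so the result is
  canonicalized to majority-positive rows, then columns.
* Ties: Viterbi prefers the smaller state index; top-parcel ranking and
  cycle search break ties toward smaller indices; `quantile_normalize`
  averages tied ranks and rejects all-tied input.
* Never-visited states produce NaN metrics, which the feature builder
  mean-imputes per column with a warning rather than silently zeroing.

## Known limitations

* EM with a handful of restarts can hit local optima; the benchmark reports
  are for the selected restart. No variational posterior over parameters is
  computed.
* Dwell-time estimates from hard paths are biased upward when true dwells
  approach the embedding window length; the effect is quantified in the
  benchmark and discussed above.
* The permutation test treats subjects as exchangeable (no stratification)
  and permutes Y rows only.
* Spectral features use power only; coherence and cross-frequency coupling
  are out of scope.
* The sign-alignment procedure is a greedy surrogate with small-instance
  exhaustive verification; it is not the published large-scale algorithm.
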