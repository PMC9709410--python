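# Methods

This note documents the models implemented by `cosparse_eeg`, the choices
made where the design was genuinely open, and what the synthetic benchmark
does and does not demonstrate.

## Signal model and synthetic data

The package operates on single-channel EEG-like time series. The synthetic
generator (`signal_data.SyntheticSpec` / `generate_synthetic`) emulates a
two-class epilepsy-style problem:

* **Background** (both classes): a sum of sinusoids — defaults 10 Hz
  (alpha-band) amplitude 1.0 and 2 Hz amplitude 0.5 — plus Gaussian white
  noise of standard deviation `noise_std` (default 1.0) and an optional 1/f
  component (`pink_std`, default 0 — real EEG has a 1/f background, the
  default benchmark omits it to keep the null control exactly white).
* **Ictal class only**: spike-wave bursts at `burst_freq` = 3 Hz, Poisson
  events at `burst_rate` = 3 events/s of `burst_duration` = 0.33 s, each a
  Hann-windowed sinusoid sharpened by a clipped-harmonic term. The amplitude
  is `burst_gain × noise_std`; the default gain of 5 makes the trains
  clearly supra-threshold. Rate × duration ≈ 1 means events nearly tile the
  record — the classical picture of an ongoing 3 Hz spike-wave seizure, and
  the reason essentially every 1-second chunk of a positive record carries
  class evidence. A rare-burst configuration (e.g. rate 0.3/s) is expressible
  through the spec but leaves most positive chunks indistinguishable from
  background, capping any chunk-level classifier near 70 %.

Records default to 4097 samples at 173.61 Hz and are cut into 23
non-overlapping chunks of 178 samples (trailing remainder discarded),
matching the single-channel epilepsy ASCII dialect the reader supports
(one numeric value per line). ICA preprocessing is available for
multichannel input (fixed-point ICA via scikit-learn; single-channel input
is a documented no-op).

**What the generator does not emulate**: inter-channel structure, artifacts
(eye blinks, muscle), non-stationary background drift, or the 1/f spectrum
by default. Passing benchmarks here demonstrates that the pipeline's
machinery discriminates when class structure exists and sits at chance when
it does not — not that it reaches any particular accuracy on clinical data.

## Analysis (cosparse) dictionary learning

Signals are modelled in the analysis form: a dictionary Ω ∈ ℝ^{n×p} with
unit-norm rows multiplies the signal so that Ωz has many near-zero entries
(the count is the cosparsity). Learning minimizes

    M(X) + λ‖T − Z‖_F² + β‖ΩZ − X‖_F²   s.t.  ‖q_i‖₂ = 1,

by alternating three exact sub-updates (`sparse_model.adla_fit`):

* **Dictionary**: each row solves a unit-norm-constrained least squares
  min ‖qᵀZ − x‖² on the sphere, via the secular equation on the
  eigendecomposition of ZZᵀ (Brent root-finding; hard case handled through
  the bottom eigenspace). A cheaper variant — unconstrained least squares
  XZᵀ(ZZᵀ)⁻¹ with rows rescaled afterwards — is available as
  `method="project"` but is *not* the exact minimizer, so only the exact
  solver guarantees the monotone objective. Rank-deficient ZZᵀ is
  ridge-regularized by 1e-8·trace/p.
* **Code**: the elementwise proximal map — soft threshold at 1/(2β) for the
  l1 measure, hard threshold at √(1/β) for l0, radial shrinkage for l2, and
  for the determinant measure (−det of the row-normalized non-negative code
  Gram matrix, larger = sparser) a projected gradient descent with
  backtracking, at most 25 inner steps.
* **Signal**: the linear system (λI + βΩᵀΩ)Z = λT + βΩᵀX, solved by LU
  factorization; the solve is verified to 1e-8 relative residual.

Defaults: λ = 1, β = 0.5, stopping when the objective changes by less than
`tol` (default 1e-5) relative — with an absolute floor so near-zero
objectives terminate; initialization Ω₀ random Gaussian unit rows (seeded),
X₀ = Ω₀T, Z₀ = T.

**Degenerate attractor and atom replacement.** The plain alternating scheme
has a trivial attractor: every row independently descends the same
landscape and converges to the single direction of minimal post-threshold
sparsity, collapsing the dictionary to one repeated atom and making the
codes useless. As in synthesis dictionary learning (where unused or
duplicate atoms are re-drawn), `replace_duplicate_atoms=True` (default)
re-draws any row whose coherence with an earlier row exceeds 0.999. The
replacement step can increase the objective, so the provable sweep-to-sweep
monotonicity holds for the pure three-sub-update scheme
(`replace_duplicate_atoms=False`), which is what the monotonicity tests
exercise.

## Statistical descriptors

`features.compute_features` computes fifteen scalar descriptors per
segment. Since only the descriptor *names* are fixed by the method, the
estimators are the most widely used ones, all parameters exposed in
`FeatureConfig`:

| descriptor | estimator (defaults) |
| --- | --- |
| mean, variance | population moments |
| skewness, kurtosis | adjusted Fisher; kurtosis non-excess |
| sample / approximate entropy | m = 2, r = 0.2·std, Chebyshev distance |
| Shannon entropy | 256-bin histogram, bits |
| Hurst exponent | rescaled range, dyadic windows ≥ 8 |
| largest Lyapunov | Rosenstein, embedding 5, delay 1, mean-period Theiler window |
| fractal dimension | Higuchi, k_max = 10 |
| recurrence rate | embedding 3, radius 0.2·std, Chebyshev |
| higher-order cumulant | k₄ / variance² |
| Lempel–Ziv | LZ76 phrase count, median binarization (ties → 0) |
| Kolmogorov complexity | deflate-compression ratio of the binarized bytes |
| Hjorth | complexity parameter (mobility of derivative / mobility) |

Constant segments return the defined degenerate values (0 where the
definition forces it) with a warning, never NaN. "Hjorth exponent" is not a
standard single quantity; the complexity parameter was chosen and is
flagged here as a judgement call. Published fractal-dimension values of
0.24–0.34 for EEG waveforms are below the ≥ 1 range of every standard
waveform estimator; the Higuchi estimator is used as-is rather than
imitating an unidentifiable variant.

## Pliable HMM with Jaccard emissions

One model per class. The hidden chain is deterministic left-to-right
(state l → l+1 with probability 1, start in state 1), so the forward
probability is the product of per-state emissions; log-space accumulation
is used and exact zeros propagate.

**Observation vectors.** Each segment's sparse code (length n_atoms) is
partitioned into h = 4 contiguous terms; each term is scored by n = 6
extractors — mean, log-variance, skewness, log-energy, mean |·|, max |·| —
and the observation vector is the column mean of the resulting h × n
term-feature matrix. The log-scale spread/energy summaries are there
because code magnitudes after soft thresholding are heavy-tailed and the
classes separate multiplicatively. The bank is configurable; the number of
hidden states always equals the number of extractors.

**Emissions.** With tolerance δ_l, a training value w′ is associated with a
value a when |w′ − a| ≤ δ_l. For observation component w_l and state value
V_l the emission is the Jaccard overlap

    P(w_l | V_l) = H11 / (H11 + H10 + H01),

where H11 counts training values associated with both w_l and V_l, H01 with
w_l only, H10 with V_l only. The emission is recomputed per observation —
this is what makes the classifier discriminate: a value deep inside the
class cloud shares most of its δ-neighbourhood with V_l, an out-of-class
value shares none. `fit_model` additionally freezes a count table against
the family-mean reference observation, which is what `emission_prob`
reports.

**Initialization.** V_l = class training mean of w_l; δ_l = 1.5 × class
training std. The tolerance must cover most of the class cloud: with
δ = 0.5 std, any state with |w_l − V_l| > 2δ contributes an exactly-zero
emission and the product vanishes for roughly two-thirds of in-class
observations, collapsing classification onto the fallback label. 1.5 std
keeps ~87 % of a Gaussian cloud associated while still rejecting far-out
values; the swarm search then tunes each δ_l within [0, 2 std].

**Classification** is argmax of the forward probability over class models,
lexicographic tie-break, configurable fallback when every model yields zero.

## Swarm-tuned parameters

The per-class parameter block (δ_1..δ_n, V_1..V_n) is fitted by one of four
population metaheuristics maximizing the validation F1 of the positive
class (`fitness_f1`): the block's parameters are installed, count tables
refitted on the training pool, the validation pool classified. Blocks are
optimized one class at a time with the others frozen (`blockwise_search`);
inside the search the frozen models' validation log-probabilities and the
active block's train–validation distance matrices are cached (single
precision — count tables, which only matter for reporting, are refit once
for the winning candidate). Each block's search is warm-started by injecting the
incumbent moment-initialized candidate into the initial population — the F1
fitness has a strong degenerate attractor (predict everything positive,
F1 = 2/3 on balanced pools) that small random populations otherwise fall
into.

Optimizer defaults (all in `SwarmConfig`): population 30, 200 iterations;
PSO inertia 0.5, both acceleration constants 4, velocity clipped to 20 % of
the box per dimension; DE strategy rand/1, scale 0.5, crossover rate 0.9,
binomial crossover with a forced dimension, greedy selection; WOA spiral
constant 1, control scalar decreasing linearly 2 → 0, spiral branch when
k ≥ 0.5; BSA mutation scale 5 with the classic partial crossover
(⌈mixrate·rand·D⌉ mutant dimensions per individual, at least one) and
uniform regeneration of out-of-bounds entries. PSO/DE/WOA clip to the box.
Search bounds per block: δ_l ∈ [0, 2·std(w_l)], V_l ∈ [min, max] of the
training values. Inside the cross-validated pipeline the DE budget is
population 10 × 12 iterations per block — the fitness landscape is
piecewise constant in 12 dimensions and a larger budget mostly re-finds the
warm start.

BSA's large constant mutation scale makes it the slowest refiner of the
four; on the 4-D sphere benchmark it needs ~300 iterations to reach the
same region the others reach in 200.

## Entropy feedback loop

`active_feedback.feedback_loop` simulates querying: per round, per-class
models are refit on the labelled pool D (fresh-start; optionally tuned by a
metaheuristic), every sample in the unlabelled pool N is scored by the
Shannon entropy of its normalized per-class forward probabilities
(natural log, 0·log 0 := 0; all-zero probabilities map to the uniform
posterior with a warning), and the B_s most uncertain samples move to D
with their held-back true labels revealed — the standard active-learning
simulation. |D| + |N| is conserved; the loop stops after a configured
number of rounds (default 5) or when N empties.

## 1D convolutional network

Implemented in NumPy with hand-written backpropagation (no deep-learning
framework is part of the dependency set): im2col convolution (true
convolution, kernel reversed relative to cross-correlation, so the
layer matches the direct-summation reference `conv1d_reference`), batch
normalization, ReLU, inverted dropout, max-pool 2/2, dense layers, softmax
cross-entropy, Adam. Parameters and activations are float32 (the network is
matmul-bound; Adam moments are kept in float64). Gradients were verified
against central differences layer by layer.

Architecture: four blocks conv→BN→ReLU→dropout→maxpool with
(filters, kernel) = (20, 60), (40, 40), (60, 20), (80, 10), stride 1,
symmetric paddings (30, 10, 7, 2), then FC 64 → 32 → 2 with softmax. For a
178-sample input the conv/pool lengths are 179/89, 70/35, 30/15, 10/5
(flatten 400). The published per-layer map sizes for this architecture are
mutually inconsistent under any single padding/rounding convention; the
first block is reproduced exactly and the rest follow deterministically
from floor-mode pooling.

Two batch-norm variants exist deliberately: `batch_norm_reference`
implements the printed formula whose scale term is δ + mean squared
deviation (no square root — its output zero-means any batch regardless),
while the trainable network uses standard BN (square root, ε = 1e-5,
running statistics for inference).

Training: Adam at learning rate 1e-4, β₁ = 0.5, β₂ = 0.55, batch 200,
default 250 epochs (the benchmark uses 30). Dropout rates are not part of
the fixed design; defaults are 0.1 after conv-block ReLUs and 0.3 after FC
ReLUs — 0.5 after every ReLU prevents convergence within reduced epoch
budgets (training accuracy stalls below 50 % at 30 epochs) while
regularizing nothing that the small network needs. Inputs are standardized
per segment, so amplitude-only class differences are invisible by
construction; the synthetic ictal class differs in waveform shape, which is
what the network learns.

## Evaluation protocol

10-fold cross-validation with folds **grouped by source record** by
default: chunks of one recording never straddle the train/test boundary
(chunk-level splitting leaks near-duplicate segments and is available as
`grouped=False` for comparison with protocols that split at chunk level).
Sparse modelling runs once on all segments before the fold split — it is
unsupervised, so no label leaks. Metrics are sensitivity, specificity and
accuracy in percent plus F1; undefined metrics are reported as `None` with
a warning. The per-fold mean and the pooled confusion matrix are both
reported.

Benchmark problem sizes: 40 records per class (1840 chunks), DE-tuned HMMs
over all 10 folds per seed, CNN on one held-out fold per seed at 30 epochs.
The HMM benchmark reports the median over 20 seeds, the CNN over 5.

**Null control interval.** With burst gain 0 the labels are independent of
the signal, and expected accuracy is 50 %. Chunks of one record share a
label and receive correlated predictions, so the effective number of
independent units is the record count, not the chunk count; the control
checks |accuracy − 0.5| ≤ 1.96·0.5/√n_records.

## Known limitations

* The determinant-measure code update is a local projected-gradient scheme;
  it is guarded (only accepts descent steps) but not provably optimal.
* The Jaccard-emission classifier needs both classes' observation clouds to
  be describable by per-dimension intervals; strongly curved class
  boundaries are outside its hypothesis space.
* The NumPy CNN is single-threaded and sized for segment-scale inputs;
  it is not a general training framework.
* Blockwise optimization is coordinate-wise: families whose optimal
  parameters interact are only locally optimized.
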