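# Methods

## Model

A fitted model is the composition `y = h(g(f(x)))` over one or more
observed phenotypes.

**Additive traits (`f`).** Variant sequences are compared to the wild type
position by position (no alignment; DMS libraries are fixed-length by
construction) and one-hot encoded: an intercept column (the wild-type
term), one binary column per observed single substitution, and — when
`max_interaction_order > 1` — one column per substitution combination that
co-occurs in at least one variant, equal row-wise to the product of its
constituent single columns. Restricting interaction columns to observed
combinations keeps sparse designs (e.g. singles plus a shallow sample of
doubles) identifiable; on complete combinatorial landscapes it is
equivalent to the full set. Each trait has its own coefficient vector;
when a trait is shared by several phenotypes the coefficient set is the
union of the features of all member tables, and columns absent from a
given table are zero. For thermodynamic transformations the trait is a
dimensionless free energy in RT units; conversion to kcal/mol happens only
at reporting time (ΔG = θRT, R = 0.001987 kcal·K⁻¹·mol⁻¹, T defaults to
303 K and is accepted in °C on the command line).

**Background-averaged (ensemble) embedding.** For complete combinatorial
landscapes the alternative encoding assigns to each position a factor whose
"mean" column is 1 for every allele and whose mutant-allele-*m* column is
`δ(allele, m) − 1/a` for `a` alleles at the position; multi-position terms
are row-wise products, truncated at the requested order. The scaling is
chosen so that the exact full-order solve returns precisely the
background-averaged coefficients — alternating phenotype differences
averaged over all genetic backgrounds, with the order-0 term the landscape
mean — rather than a 2^order multiple of them (the sign convention is
mutant-positive). For biallelic positions this is a rescaled
Walsh–Hadamard basis; the multiallelic factor above is its direct
generalization, verified against brute-force background averaging in the
test suite.

**Global epistasis (`g`).** Fixed forms: two-state occupancy
`1/(1+e^{ΔG})`, three-state fraction bound
`e^{-(ΔG_f+ΔG_b)}/(1+e^{-ΔG_f}+e^{-(ΔG_f+ΔG_b)})` (states: unfolded 0,
folded ΔG_f, folded·bound ΔG_f+ΔG_b; computed via log-sum-exp for
stability), splice-site competition `log(e^φ/(k_7+e^φ))` with the
competing-exon efficiency `k_7` trained in log space (`k_7 = e^κ`)
to guarantee positivity, and the simple activations Linear, ReLU, SiLU,
Sigmoid. The learned form (`SumOfSigmoids`) is a feed-forward sub-network
— input width = number of traits, hidden layers of configurable width
(default one layer of 20 neurons), scalar output — with logistic
activations throughout; the output activation can be disabled for
unbounded phenotypes. Any standard-state concentration entering a binding
equilibrium is absorbed into ΔG_b; it is not separately identifiable from a
single assay.

Custom transformations are loaded from a user python script declaring
name, input dimensionality, trainable parameters with initial values, and
an evaluate function; analytic gradients are optional (a central
finite-difference fallback is used otherwise, adequate for the handful of
global parameters such forms typically carry).

**Calibration (`h`).** One trainable (scale, shift) pair per observed
phenotype. For bounded transformations it is initialized from the observed
fitness range (scale = range, shift = minimum), otherwise to (1, 0).

## Loss and noise model

Per-variant empirical errors σ_n (as produced by count-based preprocessing
tools) enter the loss directly. Two losses are provided:

* `GaussianNLL`: `1/(2N) Σ (y_n − ŷ_n)² σ_n⁻² + c` with
  `c = 1/(2N) Σ log(2πσ_n²)` (parameter-free), the exact negative
  log-likelihood under Gaussian noise;
* `WeightedL1` (default): `1/N Σ |y_n − ŷ_n| σ_n⁻¹`, less sensitive to
  outlying fitness estimates.

Regularization applies to the additive-trait coefficients only:
`λ₁‖θ_f‖₁ + λ₂‖θ_f‖₂²` with defaults λ₁ = 0 and λ₂ = 10⁻⁶. Wild-type
(intercept) terms are exempt from the L1 penalty — shrinking an absolute
free energy toward zero would bias the energy scale — but included in the
(very light) L2 term. Transformation and calibration parameters are not
regularized.

## Training

Mini-batch Adam (standard moment defaults; only the learning rate is
exposed), initial learning rate 0.05, at most 1000 epochs. Trait
coefficients start at zero; sum-of-sigmoids weights use seeded
Glorot-uniform initialization with biases uniform in (−1, 1) so the
sigmoid bank spans the trait range. The learning rate decays by a factor
0.98 whenever the mean validation loss over the last ten epochs is not
lower than over the preceding ten; training stops early (when enabled,
the default) once the wild-type terms of *all* traits have a standard
deviation ≤ 10⁻³ over the last ten epochs (checked from epoch 20).
Gradients flow only through training observations; validation data steers
the scheduler and early stopping, test data is never touched during
training. A non-finite loss raises an error naming the epoch; during grid
search such configurations are excluded with a warning.

Observations from all phenotypes are concatenated and batched together
(each batch may mix phenotypes; predictions are routed to the source
phenotype's transformation and calibration). The default batch size when
none is supplied is 1024; the built-in synthetic scenarios use 128 because
their libraries are small and Adam then gets enough steps per epoch to
traverse the slowly-curved trade-off between calibration amplitude and
trait scale.

**Cross-validation.** One random permutation of eligible variants is cut
into `k_folds` (default 10) equal blocks; fold *j* uses block *j* as test
and the next `validation_factor` (default 2) blocks as validation —
i.e. 10% test + 20% validation held out by default. Wild types always
train. `holdout_orders` restricts the held-out sets to chosen mutation
orders (e.g. only doubles), everything else training. Requiring a
non-empty validation set means the smallest usable configuration is 3
folds with `validation_factor = 1`.

**Training resampling.** By default each fold's training targets are
replaced by one draw from N(y_n, σ_n²) (validation/test untouched), so the
spread across fold models propagates measurement uncertainty.

**Grid search.** Over user lists of batch size, learning rate, λ₁, λ₂:
each combination is trained for 100 epochs on fold 1 and the smallest
validation loss wins (ties to the first listed). Fold 1 only: the ranking
is a model-selection heuristic and one fold keeps the budget linear in the
grid size.

## Uncertainty and gauge

Coefficient estimates are the mean across the cross-validation models;
95% intervals are mean ± 1.96·sd across models (a normal approximation —
with ~10 models percentile intervals would be degenerate). Intervals are
computed on the θ scale and converted linearly to kcal/mol.

Two gauge modes are fixed after training so coefficients are comparable
across refits:

* a phenotype with the identity transformation determines only
  `scale·θ (+ shift)`; the affine pair is folded into the coefficients and
  reset to (1, 0) when the trait feeds no other phenotype;
* for unidimensional sum-of-sigmoids fits the trait sign is arbitrary;
  models are oriented so the fitted phenotype increases with the trait
  (negating the trait and mirroring the sub-network's input weights leaves
  predictions exactly unchanged). The orientation is read off the fitted
  model only.

Mechanistic thermodynamic fits have no such exact gauge and are reported
as-is; note that amplitude-vs-trait-scale trade-offs can still be *weakly*
constrained when a library does not populate both saturation arms of the
sigmoid, which widens (honestly) the Monte-Carlo intervals of absolute
terms like the wild-type energy.

## Sparse two-stage workflow

Stage 1 embeds the library in the ensemble basis up to order 6, fits a
linear model (no global epistasis) with the L1 penalty selected from
{0.1, 0.01, 0.001} by validation loss, and ranks coefficients by
magnitude (ties: lower order first, then name — parsimony). Stage 2
refits on the top 100 columns with λ₁ = 0. Both stages fit fold 1 of the
split; the ensemble-of-folds machinery is available but a single fold
keeps the ranking deterministic and cheap.

## Synthetic data: what it does and does not emulate

The generator enumerates (or uniformly samples) complete combinatorial
libraries over biallelic and multiallelic positions, draws additive
coefficients from declared distributions, pushes them through a chosen
transformation and affine calibration, and adds homoscedastic Gaussian
noise whose sd is calibrated to a stated fraction of the noiseless fitness
range; the σ column holds the true sd, so the empirical noise model is
well-specified. Reference scenarios (fixed study conditions):

| scenario | library | coefficients | noise |
|---|---|---|---|
| linear | 40 biallelic positions, 2000 sampled | N(0, 0.5²) | 5% of range |
| two_state | 10 biallelic, complete 1024 | ΔG₀ = −2.5, ΔΔG ~ N(0.6, 0.5²) RT | 5% |
| three_state | 9 biallelic, complete 512, two assays | folding N(0.5, 0.5²), binding N(0.4, 0.6²) RT | 5% |
| splicing | 2¹⁰×3 = 3072 exon variants | N(0, 1.2²), k₇ = 1.5 | 5% |
| sum_of_sigmoids | 12 biallelic, 3000 of 4096 | N(0, 1.2²), logistic truth | 5% |
| sparse_ensemble | 13 biallelic, complete 8192 | 20 nonzero ensemble terms, &#124;β&#124; ∈ [0.8, 2], orders 1–4 | 2% |
| coverage | 200 biallelic, 3000 sampled | N(0, 0.5²), identity | 5% |

The coverage study uses the Gaussian likelihood so interval calibration
reflects the Monte-Carlo procedure rather than loss misspecification.

Deliberately not emulated: read-count sampling and sequencing error (the
upstream preprocessor's job), heteroscedasticity beyond per-variant σ,
codon structure (nucleotide and amino-acid alphabets are flat symbols),
epistatic ground truths outside the declared basis, and library biases
such as variant dropout. Passing recovery tests therefore demonstrates
correctness of encoding, optimization and uncertainty machinery under a
well-specified noise model — not robustness to the full error structure of
real sequencing data.

## Other numerical and design choices

* **Duplicate variant rows are an error**, not averaged: upstream tools
  already aggregate replicates into one fitness ± σ per variant.
* **Wild-type identification**: the unique sequence closest (summed
  Hamming distance, computed via column consensus) to all others; complete
  factorial libraries are symmetric and therefore ambiguous, so an
  explicit `wild_type` override exists everywhere and is written alongside
  generated scenarios.
* **Downsampling** of observations always retains the wild type;
  coefficient downsampling samples uniformly across all non-intercept
  columns regardless of order.
* Variants carrying substitutions never observed alone are admitted; the
  implied single-substitution columns are created (their coefficients are
  then only constrained through the carriers, an identifiability caveat
  the user inherits from the design).
* **R²** is the coefficient of determination (1 − SS_res/SS_tot about the
  observed mean), not squared Pearson correlation; on held-out data the
  two differ. Train/validation/test R² are all reported and labelled;
  headline numbers are test-set values.
* Mean-based window statistics implement the "validation loss has not
  improved" scheduler criterion; the simplest choice that makes a
  ten-epoch comparison well-defined.
* Recovery scoring excludes order-0 terms (energy *differences* are the
  gauge-free quantities) and aligns coefficients by name.

## Known limitations

* Adam on a nearly flat amplitude/scale valley converges slowly for fixed
  sigmoidal transformations when the data do not pin both saturation arms;
  absolute energies are then reported with wide intervals (see above).
* The Monte-Carlo intervals capture split and measurement-noise
  variability, not systematic model misfit; under gross misspecification
  they will undercover (the residual-bias diagnostic is the intended
  check).
* Multidimensional sum-of-sigmoids fits are left in their arbitrary gauge;
  comparing their trait coefficients across refits requires external gauge
  fixing.
* Finite-difference gradients for plug-in transformations scale linearly
  in the number of plug-in parameters; forms with many trainable
  parameters should supply analytic gradients via the `Transformation`
  subclass interface.
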