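# Methods

## Model

`oudiverge` asks, for a pair of single-copy orthologs measured in two
species across *m* shared conditions (tissues, stages, ...), whether their
expression is **conserved** or has **diverged**, and what the optimal
expression level of each ortholog is in each condition.

Expression evolution in each condition is modelled as an Ornstein-Uhlenbeck
(OU) process along the two-species phylogeny: log-expression is pulled
toward an optimum θ with selection strength α and perturbed by phenotypic
drift with variance rate σ². Species 1 is assumed to carry the ancestral
optimum θ₁; Species 2 may have shifted to a new optimum θ₂. Divergence
time is absorbed into α and σ² (unit branch length), so under stationarity
of Species 1 and relaxation of Species 2 the pair e = (e₁, e₂) of
log-expression values in one condition is bivariate normal with

    E[e₁] = θ₁
    E[e₂] = (1 − e^{−α}) θ₂ + e^{−α} θ₁
    Var[e₁] = Var[e₂] = σ² / (2α)
    Cov[e₁, e₂] = (σ² / 2α) · e^{−2α}

A gene is *conserved* when θ₁ = θ₂ in every condition and *diverged* when
θ₁ ≠ θ₂ in every condition. The asymmetry of the mean vector is why the
input convention "Species 1 = ancestral state" is enforced: swapping the
species changes the model.

Because the diverged class has four free parameters per condition, a
likelihood-ratio test on two species would be over-parameterized; instead,
predictors are trained by supervised learning on data simulated from the
model itself, with conditions treated as independent.

## Simulation design

The generator draws, independently for every condition of every simulated
pair (so 4·m parameters per pair):

| parameter | default prior | rationale |
|---|---|---|
| θ₁, θ₂ | uniform on [0, 5] (log-expression units) | range of quantile-normalized log-FPKM in the motivating fly dataset |
| α | log₁₀-uniform on [0, 3] (α ∈ [1, 1000]) | spans weak to strong selection across orders of magnitude |
| σ² | log₁₀-uniform on [−2, 3] (σ² ∈ [0.01, 1000]) | spans weak to strong drift |
| m | 6 conditions | six tissues in the motivating dataset |

Conserved pairs set θ₂ := θ₁ exactly; diverged pairs draw θ₂ independently
(ties have probability zero; no minimum separation is imposed). Features
are interleaved per condition: (e₁₁, e₂₁, …, e₁ₘ, e₂ₘ), p = 2m = 12.

The standard benchmark uses a balanced 20,000-observation training set and
an independent balanced 2,000-observation test set. Robustness variants:
a "linearized" prior (α ~ U[1, 1000], σ² ~ U[0.01, 1000] sampled on the
natural scale — our reading of "the same ranges, not on log scales");
conserved-biased designs (16,000/4,000 train or 1,600/400 test); and 15
restricted regimes crossing α ∈ {[1,10], [10,100], [100,1000]} with σ² ∈
{[0.01,0.1], …, [100,1000]}, sampled linear-uniformly, evaluated with the
models trained under the full prior.

What the generator does *not* emulate about real data: correlation of
expression across conditions, measurement error beyond the OU stationary
noise, non-normal heavy tails, missing values, and the bounded support of
real normalized data (simulated values can leave [0, 5] when drift is
strong). Passing benchmarks therefore demonstrate recovery of the model's
own signal, not robustness to these real-data features.

## Predictors

**Neural network** (implemented here in NumPy with manual
backpropagation). Dense feed-forward net; L ∈ {0..3} hidden ReLU layers of
widths 256, 128, 64 (halving per layer); softmax output with cross-entropy
loss for classification (K = 2), linear output with mean squared error
(averaged over outputs) for regression of all K = 2m optima jointly.
Training minimizes mean loss plus the elastic-net penalty
λ Σ[(1−γ)w² + γ|w|] over all inter-layer weights (biases excluded; γ = 1
is pure L1). Optimized with Adam (learning rate 10⁻³, β₁ = 0.9,
β₂ = 0.999, ε = 10⁻⁸), mini-batches of 5,000, 500 epochs, per-epoch seeded
reshuffling. Weights use seeded Glorot-uniform initialization, in float32;
biases are per-unit and start at zero. Hyperparameters (L, λ, γ) are
selected by class-balanced 5-fold cross-validation over L ∈ {0..3}, 25 λ
values log-uniform on log₁₀λ ∈ [−12, −3], γ ∈ {0, 0.1, …, 1}; the
benchmark optima are L = 2, λ = 4.327·10⁻⁴, γ = 1 (classification) and
L = 2, λ = 7.499·10⁻⁵, γ = 1 (regression).

`cross_val_loss` reports the plain validation loss (cross-entropy or MSE)
by default; `include_penalty=True` adds the fitted weights' elastic-net
penalty, which is the convention deep-learning frameworks use for their
reported validation loss. At the classification optimum the two
conventions differ by the penalty term (≈ 0.11 on the standard benchmark),
and published figures may follow either; both are exposed so the reader
can compare.

**Random forest** (scikit-learn behind the module surface). Breiman's
algorithm: 500 unpruned trees on same-size bootstrap resamples, random
feature subset per split (⌊√p⌋ for classification, ⌊p/3⌋ for regression —
the standard defaults of the reference RF implementations), Gini impurity
/ response variance, minimum node size 10 / 5 (mapped to the "do not split
smaller nodes" semantics, `min_samples_split`). Classification output is
the class with the larger mean estimated probability across trees;
regression fits one forest per output and averages trees.

**Support-vector machine** (scikit-learn SVC/SVR). RBF kernel
K(x, x′) = exp(−γₖ‖x − x′‖²); γₖ tuned over 11 values log-uniform in
[0.001, 5] and box constraint C over 5 values log-uniform in [0.01, 100]
(the C grid is a package choice; it is not prescribed). Tuning uses
class-balanced 5-fold CV on a class-balanced 3,000-observation subsample
of the training set — kernel fits scale super-quadratically, and the
CV optimum is stable under subsampling — followed by a final fit on the
full training set. Classification scores for ROC analysis are signed
decision values; regression (ε = 0.1, configurable) fits one machine per
output.

Ties (probability exactly 0.5, decision value exactly 0, distance exactly
at the cutoff) always resolve to "conserved", the null-like class.

## Distance baseline

For comparison, a cutoff classifier on the distance between the two
species' m-condition profiles: Euclidean or Manhattan metric, on absolute
log-expression vectors or on "relative" profiles. *Relative* is
implemented as per-species mean-centering across conditions (removes
overall level, keeps shape); this definition is a package choice — the
term is not standardized — and is config-exposed. The cutoff is chosen
among 100 candidates spaced uniformly over the training distance range by
class-balanced 5-fold CV accuracy, smallest candidate winning ties. On the
standard benchmark the Manhattan/absolute variant calibrates to c ≈ 7.1–7.3
and outperforms the other three variants.

## Evaluation conventions

"Diverged" is the positive class: power = diverged-class true positive
rate, false positive rate = conserved pairs called diverged. Confusion
matrices are row-normalized, rows (conserved, diverged). ROC curves sweep
all score thresholds with tied scores collapsed into one step; AUC is the
trapezoid integral (equals concordance probability with half credit for
ties, verified against brute-force pair enumeration in the tests).

## Empirical pipeline

Input tables are TSVs of log-scale, quantile-normalized expression
(`gene_id`, `sp1_<cond>`…, `sp2_<cond>`…); no re-normalization is applied.
Genes whose expression is below a floor (default 1.0, the same scale as
the data) in *every* condition of *either* species are removed — the
filter used to reduce 127 relocated fly genes to the 102 analyzed ones.
Two-tailed exact tests use the minimum-likelihood convention (sum of all
outcome probabilities no larger than the observed outcome's), matching R's
`binom.test` and `fisher.test`; both are verified against enumeration
oracles in the test suite. `synthetic_ortholog_table` provides a synthetic
stand-in for a two-species six-tissue table (strong-signal OU simulations
on the [0, 5] scale) for end-to-end testing without external data.

## Numerical and scaling choices

- Parameters α, σ² below 10⁻¹² are rejected (singular covariance); the
  bivariate density additionally refuses correlations within 10⁻⁸ of 1.
- Sampling uses an explicit Cholesky construction so fixed seeds give
  bitwise-reproducible draws; dataset generation is fully vectorized.
- Benchmark problem sizes in the test suite and acceptance script: the
  full 20,000/2,000 design for training and headline metrics (NN and RF
  figures averaged over 3 replicate seeds in the acceptance script); the
  SVM tuned on a 3,000-observation subsample; regime sweeps at 500
  observations per regime; the reduced NN model-selection grid
  (L ∈ {0, 2} × 5 λ × γ ∈ {0, 1}) run on a balanced 2,000-observation
  subset at 60 epochs — depth selection is scale-robust because the
  class boundary is intrinsically nonlinear, so L = 0 cannot compete.

## Known limitations

- Conditions are modelled as independent; correlated-condition OU
  extensions are out of scope.
- Only two-species, one-branch-shift scenarios; no multi-species trees.
- The NN is CPU-only NumPy; training the standard benchmark takes on the
  order of a minute per fit.
- Class labels are gene-level: a gene diverged in only a subset of
  conditions is not representable in the training distribution.
- The empirical lineage/arm bias tests support 2×2 contingency tables;
  larger r×c tables are not implemented.
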