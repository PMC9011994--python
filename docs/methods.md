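# Methods

## The latent-phenotype model

`latentmave` models a MAVE dataset — N pairs of a fixed-length sequence x_n
and a measurement y_n — as a two-stage process. A deterministic
genotype-phenotype (G-P) map assigns each sequence a scalar latent phenotype
φ(x; θ); a stochastic measurement process p(y | φ) then generates the
observed measurement. Both stages are inferred jointly by maximizing an
L2-regularized likelihood. The G-P map captures the biology; the measurement
process absorbs the assay's nonlinearities and noise, so that the two are not
confounded.

### G-P maps

Sequences are one-hot encoded: x_{l:c} = 1 iff character c occurs at
position l (0-based positions, alphabet order for characters; the feature
order is fixed so exported parameter files are portable). Built-in maps:

* **additive** — φ = θ₀ + Σ_{l,c} θ_{l:c} x_{l:c} (1 + LC parameters);
* **neighbor** — adds interaction terms for adjacent position pairs
  (+ (L−1)C² parameters);
* **pairwise** — adds interactions for all position pairs with l′ > l
  (+ L(L−1)C²/2 parameters);
* **black box** — a dense multilayer perceptron over the same feature
  expansions, tanh hidden layers (configurable), single linear output;
* **custom** — any callable φ(x; params); the thermodynamic models in
  `latentmave.biophysics` use this contract with analytic gradients.

Zeroing the interaction terms of a larger parametric map reproduces the
smaller one exactly (additive ⊂ neighbor ⊂ pairwise). Additive effects for
(position, character) pairs absent from the training data are stored as NaN
rather than 0; predictions for sequences that use them are NaN, never
silently computed.

### GE measurement process (continuous y)

The prediction (mode of p(y|φ)) is a monotonic sum of tanh sigmoids,
g(φ) = a + Σ_k b_k tanh(c_k φ + d_k), with b_k, c_k ≥ 0 enforced through a
softplus reparameterization of unconstrained surrogates (default K = 20
nodes). Scatter about g(φ) follows a Gaussian, Cauchy, or Jones-Faddy
skewed-t noise model whose scale s (and, for the skewed-t, shape parameters
a and b) are exponentiated polynomials in ŷ (default order 2; order 0 gives
homoscedastic noise, and the exponential form keeps them positive — we adopt
K+1 coefficients a_0..a_K for an order-K polynomial). The skewed-t's t
statistic is shifted by t* = (a−b)√(a+b)/(√(2a+1)√(2b+1)) so its mode sits
exactly at ŷ; quantiles use the regularized incomplete beta inverse. An
*empirical* noise model (Gaussian with user-supplied per-datum standard
errors, no free parameters) supports scores imported from external
enrichment pipelines.

### MPA measurement process (discrete y)

For binned readouts (e.g. sort-seq), p(y|φ) is a softmax over per-bin
weights w_y = exp[a_y + Σ_k b_yk tanh(c_yk φ + d_yk)] (default K = 10 hidden
nodes per bin). Input may be per-read (sequence, bin) pairs or a
per-sequence count matrix; both give identical likelihoods and the package
converts between them. Bins must be contiguous integers from 0 (a relabeling
helper is provided). Continuous-y MPA is out of scope.

## Training

The loss is the negative log likelihood plus λ_θ‖θ‖² + λ_η‖η‖² (defaults
10⁻³ and 10⁻¹; all measurement parameters, bias-like ones included, are
penalized — documented choice). Optimization is minibatch Adam (learning
rate 10⁻³, batch 100, up to 600 epochs) with early stopping on a validation
split (patience 30) and the best-validation parameters restored. Gradients
are computed analytically end-to-end (backpropagation through the feature
design, the nonlinearity's softplus surrogates, and each noise family's
log-density); the skewed-t's shape-parameter sensitivities use vectorized
central differences in log space (step 10⁻⁵), accurate to ~10⁻⁹ and
indistinguishable from analytic partials at optimizer precision. Data are
split train/validation/test (default 90:5:5) by seeded shuffling; all
randomness (split, initialization, batch order, simulation) flows from a
single integer seed, and refitting with the same seed reproduces the loss
trajectory bit-for-bit.

Initialization: parametric G-P maps start from a ridge regression of y (or
the mean bin) on the features; the GE nonlinearity starts near an affine
function matched to the φ–y covariance; noise scale starts at the residual
standard deviation. This removes most of the burden from the nonconvex
phase of training and is why a few hundred epochs suffice at desk scale.

### Single-mutant libraries

Measurement nonlinearities are identified by comparing how mutations combine
across backgrounds. If every non-reference sequence differs from the
inferred reference (the most frequent sequence, or user-specified) by at
most one position, that information is absent, so the library is restricted
to an additive G-P map with an affine "nonlinearity" under GE regression
(heteroscedastic noise still allowed). A few hundred double mutants lift the
restriction — the `double_mutant_deconvolution` benchmark quantifies this.

## Gauge fixing

Two non-identifiabilities are removed after training. *Diffeomorphic* modes
(affine rescalings of φ that the measurement process can undo) are fixed by
standardizing φ to mean 0 / std 1 on the training data while transforming
g(φ) → g(a + bφ) (GE) or p(y|φ) → p(y|a + bφ) (MPA), leaving p(y|x)
unchanged for every sequence. *Gauge* modes (parameter directions that leave
φ itself unchanged) are fixed in the hierarchical gauge: given a
position-factorized sequence distribution p_{l:c} (uniform, empirical, or
wildtype one-hot), parameters are shifted so additive terms have zero mean
at each position under p and every interaction block has zero marginals
under p. This makes the lower-order terms absorb the maximal share of
var(φ); the test suite verifies φ-preservation (≤10⁻⁹), idempotence, the
zero-marginal conditions, and the variance-maximality property by direct
enumeration on tiny models. The default display gauge is uniform; when a
dataset leaves some effects unobserved (NaN), the fit falls back to the
empirical distribution, whose support matches the data. Custom G-P maps are
never auto-gauge-fixed — their gauge freedoms depend on model structure and
are the author's responsibility (the bootstrap warns about this).

## Information metrics

Model performance is reported in bits on held-out data:

* I_var = H[y] − (log₂e/N)·L_like, with uncertainty combining the
  half-sample error of H[y] and the standard error of the per-datum
  surprisals;
* I_pre = I[y; φ], independent of the measurement-process parameters;
* I_int = I[x; y], bracketed by an upper bound from Poisson-propagated
  read-count noise (δy_n = log₂e·√(1/(c_in+1) + 1/(c_out+1)), Gaussian
  conditional entropy ½log₂(2πe δy²)) and lower bounds from replicate
  measurements (I[y;y′]) or any model's I_pre (data-processing inequality).

On test data I_var ≤ I_pre ≤ I_int up to estimator error; the gap
I_pre − I_var measures measurement-process misspecification.

Continuous entropies use the Kozachenko–Leonenko kNN estimator and mutual
information uses the KSG (algorithm 1) estimator, both with Chebyshev
(max-norm) balls and default k = 5; ties are broken with seeded jitter of
10⁻¹⁰ × data range. For discrete y, I_pre uses the decomposition
H[φ] − Σ_y p(y)H_y[φ] with per-bin kNN entropies. Small negative MI
estimates are floored at 0 (with a warning). Uncertainties use R = 25
random half-sample subsamples, δE = std/√2; the same scheme supplies δH[y].
A local-nonuniformity correction hook for strongly dependent (y, φ) is
exposed but not implemented by default (it is far more expensive and not
needed at the dependence levels of these benchmarks). The read-count upper
bound assumes Poisson counts; over-dispersed libraries make it unreliable
(too high), which is documented rather than corrected.

## Simulation and the parametric bootstrap

Any model doubles as a simulator: sequences come from an explicit list,
random draws over the alphabet, a mutagenized wildtype, or a
wildtype+singles+sampled-doubles library, and measurements are drawn from
the measurement process (skewed-t sampling goes through the analytic
quantile function). Parameter uncertainties use the parametric bootstrap:
the trained model simulates R datasets with the assayed sequences held
fixed, a fresh model is fit to each with the same hyperparameters, each
refit is gauge-fixed identically, and per-parameter standard deviations are
reported. Case-resampling bootstrap is deliberately not offered (resampling
sequence-measurement pairs leaves many assayed sequences without
measurements and can create artificial non-identifiability); black-box maps
are rejected because individual parameter uncertainties are meaningless for
heavily overparameterized models.

## Thermodynamic models

`latentmave.biophysics` provides Boltzmann-occupancy G-P maps over energy
matrices (kcal/mol): a three-state folding/binding model (unfolded at 0,
folded at ΔG_F(x), folded-bound at ΔG_F(x)+ΔG_B(x); φ = folded-bound
fraction) and a four-state promoter-activation model (empty, CRP-bound,
RNAP-bound, CRP+RNAP co-bound with a scalar interaction energy ΔG_I;
φ = RNAP-bound fraction). Occupancies are computed with a max-energy shift
(log-sum-exp) so extreme energies cannot overflow. β is fixed at
1/(0.593 kcal/mol) ≈ 300 K and recorded with exported parameters; since
occupancies depend on energies only through βG, the energy scale convention
must accompany any exported matrix. Concentration terms are absorbed into
the binding offsets. For display, each energy matrix is put in the uniform
hierarchical gauge independently.

## Benchmark experiment sizes

The simulation-backed benchmarks (shared by the test suite and
`scripts/acceptance.py`) use desk-scale problems chosen to make each check
statistically decisive while keeping the whole suite fast on one CPU:
estimator checks at n = 10⁴ samples; parameter recovery with an L = 10 DNA
additive map, sigmoidal nonlinearity, skewed-t noise (scale 0.15 on a y
range of ~6, matching a clean but realistic assay) and n = 5000 variants;
double-mutant deconvolution with L = 20, all 60 singles, and 500 vs 1500
doubles (recovered nonlinearities compared as quantile-matched curves over
the data-populated phi band, 1st–99th percentiles — isolated extreme-tail
sequences, often just the wildtype, cannot constrain g there); and the
information inequality over 10 random ground-truth models (alternating
GE/MPA) at n = 2000 each. In the GE draws the truth is a pairwise map but
an additive model is fitted, so each gap in
I_var ≤ I_pre ≤ I_int is genuine rather than a tie decided by estimator
bias; benchmark sequences use L = 10 so phi values stay distinct — heavy
exact duplication of phi (short sequences, small n) biases the kNN
entropies, which is an estimator limitation worth knowing about on
effectively discrete latent phenotypes.

## What the simulations do and do not show

The simulator draws measurements from the same model families the fitter
assumes, with position-independent random sequences or idealized mutant
libraries. Passing benchmarks therefore demonstrates correct and
well-conditioned inference — not robustness to misspecification found in
real data: epistasis beyond the chosen map order, over-dispersed or
non-stationary sequencing noise, library composition bias, or batch
effects. The single-mutant restriction and the intrinsic-information
caveats above are the main guardrails the package offers against
over-interpreting such data.

## Known limitations

* One-dimensional latent phenotypes and scalar (or binned) measurements only.
* Variable-length input is rejected; align or pad sequences upstream and use
  a custom alphabet with a gap character if needed.
* Training is CPU-bound numpy; it is comfortable at 10³–10⁵ variants but not
  engineered for GPU-scale datasets.
* No hyperparameter search; defaults are stated above and configurable.
* Detection of residual unconstrained parameter modes in unusual model/data
  combinations is not automated.
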