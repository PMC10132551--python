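# Methods

## The model family

All models in this package perform associative memory on a fixed set of
N real-valued patterns {x⁽ⁱ⁾} of dimension d: after a learning phase,
a partially masked or noise-corrupted cue is completed/denoised by
relaxing neural activity to a maximum of an energy function with fixed
weights.

**Explicit model.** Parameters are a mean μ and covariance Σ of a
Gaussian generative model; the energy is the log-likelihood
F = −½ log|Σ| − ½ (x−μ)ᵀΣ⁻¹(x−μ). Full-batch gradient ascent of the
pattern-summed F converges to the maximum-likelihood estimates μ → x̄,
Σ → S, where S is the **1/N** sample covariance (never 1/(N−1) — the
learned recurrent weights of the other models satisfy their convergence
identity exactly only with the MLE normalization). Retrieval follows
Δx = −βΣ⁻¹(x−μ) on the relaxing coordinates. The Σ update needs Σ⁻¹
at every step; this inverse is non-local and numerically fragile, and
that fragility is part of the model: training raises a
`SingularCovarianceError` (with the offending eigenvalue) rather than
regularizing silently. A ridge term exists nowhere in the code — data
that drives Σ singular is supposed to fail loudly.

**Implicit / dendritic models.** A zero-diagonal recurrent weight
matrix W and bias ν predict each neuron from all the others:
ε = x − W f(x) − ν, F = −½‖ε‖². Learning is Hebbian for both
parameters, ΔW = α(Σᵢ ε⁽ⁱ⁾ f(x⁽ⁱ⁾)ᵀ)_{diag=0}, Δν = α Σᵢ ε⁽ⁱ⁾, with the
diagonal of W re-zeroed after every step (projection, not
reparameterization). At convergence on full-rank data, ν = (I−W)x̄ and
off-diag[(I−W)S] = 0: W encodes the covariance *implicitly*. The two
variants share learning exactly and differ only in inference: the
implicit update is the true energy gradient
Δx = β(−ε + f′(x)⊙Wᵀε); the dendritic update Δx = −βε is the gradient
of the stop-gradient energy −½‖x − W·sg(x) − ν‖². With M = W − I the
linear dynamics are Δx ∝ −MᵀM(x−x̄) (implicit; −MᵀM is negative
semidefinite, hence unconditionally stable) versus Δx ∝ M(x−x̄)
(dendritic; stable only if every eigenvalue of M has non-positive real
part, which learning does not guarantee). Dendritic divergence is
therefore an expected observable: inference flags it (activity norm
exceeding 1e6× its initial value, configurable) and returns the trace
instead of raising.

**Clamped completion dynamics.** During pattern completion the intact
coordinates m are clamped to the cue for the entire run and only the
corrupted coordinates k relax. The analytic retrieval all three linear
models share is the conditional-mean/least-squares form
x̂_k = S_km S_mm⁻¹(x_m − x̄_m) + x̄_k, whose defining property is
ε_k = 0 at the fixed point. For the implicit variant this forces a
design choice: projecting the full-vector gradient β(−ε + Wᵀε) onto
the k coordinates converges instead to the minimizer of the *entire*
squared error over x_k, which differs from the closed form whenever the
training residual is nonzero (N > d) — we verified this numerically
before settling the design. The package therefore restricts the
backward error projection to the corrupted sub-network,
Δx_k = β(−ε_k + f′(x_k)⊙W_kkᵀε_k): the corrupted neurons act as a
covariance-learning network of their own, driven by the clamped part
through W_km x_m + ν_k. This is gradient ascent on the
corrupted-coordinate error energy −½‖ε_k‖², has Jacobian
−(I−W_kk)ᵀ(I−W_kk) (the same always-stable structure as the full
implicit dynamics), and its fixed point is exactly ε_k = 0, i.e. the
closed form. The explicit model needs no such care: the projected
update −β(Σ⁻¹(x−μ))_k already has the closed form as its fixed point
(block-inverse identity). The dendritic projected update −βε_k also
fixes ε_k = 0. Noise-corrupted cues always relax every coordinate
(denoising protocol).

**Hybrid model.** Layers 1..L−1 are a hierarchical predictive coding
network (layer 1 clamps to the sensory input during learning) and layer
L is a recurrent layer with zero-diagonal W and no bias. Predictions
are ρ(l) = Θ(l)f(x(l+1)) and ρ(L) = W x(L); energy is
F = −½Σ_l‖ε(l)‖². Inference ascends F in the activities; the top
layer's recurrent feedback Wᵀε(L) is included for an implicit top
(γ = 1) and dropped for a dendritic top (γ = 0). Each training step
runs 400 relaxation iterations on a minibatch (batch size N/8 by
default) and then applies one Hebbian weight step,
ΔΘ(l) = α ε(l)f(x(l+1))ᵀ, ΔW = α ε(L)x(L)ᵀ (diagonal re-zeroed),
batch-averaged. Retrieval additionally relaxes the corrupted sensory
coordinates by Δx_c(1) = −βε_c(1). The top-layer recurrent prediction
is linear (W x(L), no nonlinearity) even when hidden layers use tanh.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| α (learning rate) | auto | explicit: min(0.1, 0.5·λmin(S)²)/N per epoch — the Σ fixed-point iteration linearizes to ΔE = −αN S⁻¹ES⁻¹, stable only for αN < 2λmin(S)²; recurrent: 1/λmax(ZᵀZ) with Z = [f(X), 1], the row-wise least-squares stability bound; hybrid: 0.01 (0.05 used in the shipped experiments). |
| β (integration step) | auto | explicit: 1/λmax(Σ⁻¹); implicit: 1/λmax(MᵀM) (submatrix spectral norms are bounded by the full ones, so the bound covers clamped runs); dendritic: 0.9/(1+σmax(W)), a disc bound on eig(M). |
| convergence_tol | 1e-8 (train), 1e-10 (infer) | max-norm of the parameter/activity update. |
| success threshold | 5e-3 | retrieval MSE below which a retrieval counts as successful. |
| nearest-memory tolerance | 0.05·√d | Euclidean radius for classifying a probe endpoint as a stored memory. |
| divergence bound | 1e6 × initial norm | finite reporting of unstable dendritic runs. |

When `step_size` is None the *implicit* variant uses an energy-guarded
adaptive step (β halves when a step would decrease the relevant energy,
grows 5% on acceptance). This changes only the pace, not the fixed
points; trained tanh networks can carry weights with σmax(W) > 10, and
the fixed stability-bound step then crawls along ill-conditioned
valleys. The dendritic variant never adapts — its update is not a
gradient and masking its instability would hide a model property.

## Synthetic data

The generators define the experimental conditions; they are code, not
fixtures.

- `generate_gaussian_patterns`: i.i.d. N(mean, cov) rows; the default
  (standard normal) is what the random 5×5-pattern completion
  experiments use. Whether those experiments had structured covariance
  is not determinable; both are supported, standard normal is the
  default.
- `generate_toy_3d`: three uniform points in [−1,1]³ for attractor
  probing.
- `generate_correlated_patterns`: rank-r orthonormal factor mixture
  plus isotropic noise — a stand-in for natural-image pattern sets with
  a rank-dominated covariance spectrum. It reproduces the second-order
  structure those experiments rely on, and nothing else (no spatial
  locality, no pixel-intensity marginals), so tests passing on it speak
  to covariance-driven completion, not to image statistics at large.
- Corruption: `corrupt_mask` (zeroed coordinates; "bottom two rows" of
  a row-major h×w grid = the last 2w coordinates) and `corrupt_noise`
  (variance-0.1 Gaussian noise is the denoising condition).
- Seeding: one master seed expands into named child streams
  (generation / corruption / initialization) via
  `numpy.random.SeedSequence` spawning, so replicate experiments are
  reproducible from a single integer.

## Numerical choices

- Σ is symmetrized after every update (the update is symmetric in exact
  arithmetic; this contains float drift) and Σ⁻¹ is recomputed each
  step, never cached.
- Explicit Σ init = identity; recurrent W, ν init = zeros (zeros
  satisfy the diagonal constraint and make full-batch linear training a
  deterministic convex descent); hybrid Θ ~ N(0, 1/fan_in), W = 0,
  hidden activities start at zero before each relaxation.
- The closed-form oracle uses `solve` on S_mm and falls back to a
  pseudo-inverse (relative cutoff 1e-10, with a rank warning) when S_mm
  is rank deficient.
- Eigenvalue stability flags use tolerance 1e-8 on real parts.
- The condition-number guard on Σ triggers at 1e12.
- The nonlinear ΔW uses the pre-synaptic factor f(x) (the true energy
  gradient); a literal mode with pre-synaptic x is available behind
  `literal_presynaptic=True`. The two coincide for linear f. The
  zero-diagonal constraint is kept in the nonlinear model (predictions
  remain "from all other neurons").
- Retrieval-MSE scope defaults to all coordinates
  (`scope="corrupted_only"` available).

## Problem sizes used in shipped experiments

Theorem-equivalence checks run 50 random instances with d ∈ {4..20},
N = 3d. The stability analyses use N = 32, d = 64 (interpolation
regime) for the reported top eigenvalue of −MᵀM, and smaller instances
in tests. The hybrid experiment trains a [32, 16, 16] network on 16
rank-4 correlated patterns (batch size 2, 400 relaxation iterations per
step, 500 epochs) and retrieves from half-masked cues. The attractor
probe uses a 9³ grid on [−1,1]³.

## Findings and limitations

- **Exact-interpolation nonlinear networks store extra attractors.** A
  tanh network trained to (near-)zero error on 3 points in [−1,1]³
  satisfies x = W tanh(x) + ν at the memories — but that nonlinear
  system generically has *additional* solutions, all of them global
  maxima of F and hence genuine attractors of the inference flow.
  Across toy seeds, the fraction of convergent 9³-grid probes ending at
  a stored memory ranges roughly 0.3–0.95; the rest settle at spurious
  zero-error points. The qualitative dichotomy is robust — the linear
  model's probes all land on the affine set {x : (I−W)x = ν} (residual
  < 1e-9) while the nonlinear model's memories are isolated point
  attractors — but "every probe reaches a stored memory" holds only for
  favorable pattern draws. This is a property of the model class, not
  of the optimizer: it persists under fixed-small-step integration,
  both plasticity conventions, and with or without the diagonal
  constraint.
- The per-coordinate retrievals of independently trained implicit-top
  and dendritic-top hybrids differ at the few-percent level even when
  their retrieval MSEs coincide; "identical performance" is a statement
  about retrieval quality, not about activity trajectories.
- Capacity analysis (how many patterns a d-neuron network can store) is
  out of scope, as are real-image benchmarks; the correlated-pattern
  generator substitutes for the latter at the level of covariance
  structure only.
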