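# covpcn

Covariance-learning predictive coding networks for associative memory.

`covpcn` implements a family of single-layer and hierarchical predictive
coding networks that store a set of patterns and retrieve them from
partial or noisy cues, the computation attributed to the recurrent CA3
circuit of the hippocampus. It is aimed at computational neuroscientists
and machine-learning researchers who want reference implementations of
these models with their analytic retrieval theory, stability
diagnostics, and a reproducible synthetic-experiment protocol.

## The models

Given N patterns x⁽ⁱ⁾ ∈ ℝᵈ with sample mean x̄ and 1/N sample
covariance S, the package provides:

- **Explicit covPCN** — a Gaussian energy
  F = −½ log|Σ| − ½ (x−μ)ᵀΣ⁻¹(x−μ). Learning converges to the MLE
  (μ → x̄, Σ → S), so the lateral weights encode the covariance
  explicitly. The Σ learning rule needs Σ⁻¹ each step: non-local and
  numerically fragile.
- **Implicit covPCN** — zero-diagonal recurrent weights W and bias ν
  with ε = x − Wx − ν and F = −½‖ε‖². Learning is purely Hebbian
  (ΔW ∝ Σᵢ ε⁽ⁱ⁾x⁽ⁱ⁾ᵀ, diagonal re-zeroed) and at convergence satisfies
  ν = (I−W)x̄ and off-diag[(I−W)S] = 0: the covariance is encoded
  implicitly, with no inverse anywhere.
- **Dendritic covPCN** — identical learning; inference drops the
  backward error projection (a stop-gradient), Δx = −βε, as if errors
  were computed in apical dendrites. Stability is no longer guaranteed:
  with M = W − I, implicit inference follows −MᵀM (always negative
  semidefinite) while dendritic inference follows M itself.
- **Nonlinear covPCN** — ε = x − W f(x) − ν with f = tanh; stores
  memories as isolated point attractors instead of the linear models'
  affine attractor set {x : (I−W)x = ν}.
- **Hybrid PCN** — a hierarchical network (neocortex analog) whose top
  layer is a recurrent covPCN (hippocampus analog); prediction errors
  flow up, predictions flow down, and all plasticity stays local.

All three linear models retrieve the same completion in theory: the
masked coordinates converge to the conditional-mean/least-squares
estimate x̂_k = S_km S_mm⁻¹(x_m − x̄_m) + x̄_k, which
`covpcn.theorem_retrieval_oracle` computes in closed form directly from
the data as an independent reference.

## Worked example

Store 64 correlated 5×5 patterns in an implicit covPCN, mask the bottom
two rows (10 of 25 coordinates), and retrieve:

```python
import numpy as np
import covpcn as cp

patterns = cp.generate_correlated_patterns(n=64, d=25, rank=4, noise_sd=0.02, seed=0)
stats = cp.sample_stats(patterns)

model = cp.learn_recurrent(patterns, cp.TrainConfig(max_epochs=200_000,
                                                    convergence_tol=1e-11))
cues = cp.corrupt_mask(patterns, np.arange(15, 25))   # bottom 2 rows, row-major
cfg = cp.InferConfig(max_iters=200_000, convergence_tol=1e-12)
retrieved = np.array([cp.infer_recurrent(c, model, cfg).x_final for c in cues])

per_pattern, mean_mse = cp.retrieval_mse(retrieved, patterns)
print(f"mean retrieval MSE: {mean_mse:.3e}")
print(f"successful retrievals (MSE < 5e-3): {cp.success_count(per_pattern)}/{patterns.n}")

oracle = cp.theorem_retrieval_oracle(stats, cues[0])
print("closed form :", np.round(oracle[:3], 4))
print("network     :", np.round(retrieved[0][15:18], 4))

rep = cp.stability_report(model)
print(f"largest eigenvalue of -M^T M: {rep.max_negMtM:.2e}")
```

Output:

```
mean retrieval MSE: 1.773e-04
successful retrievals (MSE < 5e-3): 64/64
closed form : [ 0.5567 -0.2809  0.0054]
network     : [ 0.5567 -0.2809  0.0054]
largest eigenvalue of -M^T M: -3.45e-08
```

The network's iterative retrieval agrees with the closed form to the
printed precision; every pattern is recovered below the 5e-3 success
threshold; and the −MᵀM spectrum confirms the implicit dynamics are
stable. Masked-coordinate completion is informative here because the
patterns are correlated (rank-4 structure plus noise) — for i.i.d.
patterns with N > d the least-squares completion necessarily reverts
toward the mean.

## Command line

```sh
covpcn simulate --config experiment.yaml --out data/
covpcn train    --config experiment.yaml --data data/patterns.csv --out ckpt
covpcn retrieve --config experiment.yaml --checkpoint ckpt \
                --cues data/cues.json --data data/patterns.csv --out results.csv
covpcn analyze  --checkpoint ckpt --what stability --out stability.json
```

The YAML config selects the model (`explicit | implicit | dendritic |
nonlinear | hybrid`), the data generator, the corruption, and the
training/inference settings; every output file carries a JSON
provenance sidecar sufficient to re-run the command that produced it.

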