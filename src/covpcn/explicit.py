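"""The explicit covariance-learning predictive coding network.

A single-layer network whose parameters are the mean μ and covariance Σ
of a Gaussian generative model of the pattern set.  The (negative free)
energy of an activity vector x is the Gaussian log-likelihood

    F(x) = -1/2 log|Σ| - 1/2 (x-μ)ᵀ Σ⁻¹ (x-μ)

up to an additive constant.  Learning performs gradient ascent of F
summed over the patterns and converges to the maximum-likelihood
estimates: μ → x̄ and Σ → S (the 1/N sample covariance), so the lateral
weights *explicitly* encode the sample covariance.  Retrieval fixes the
parameters, initializes the activity at a cue, and ascends F in x; the
errors are precision-weighted, ε = Σ⁻¹(x-μ).

The Σ update requires inverting Σ at every step.  That inverse is both
non-local (the update of one synapse needs the whole matrix) and
numerically fragile; the fragility is a genuine property of the model,
so training surfaces singularity as an error instead of patching it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .patterns import (
    CueSpec,
    InferConfig,
    PatternMatrix,
    RetrievalResult,
    TrainConfig,
)

__all__ = [
    "ExplicitParams",
    "SingularCovarianceError",
    "energy_explicit",
    "weighted_error",
    "explicit_gradients",
    "learn_explicit",
    "infer_explicit",
]

_COND_MAX = 1e12


class SingularCovarianceError(RuntimeError):
    """Raised when Σ becomes numerically singular or non-finite."""


@dataclass(frozen=True)
class ExplicitParams:
    """Mean vector μ and covariance matrix Σ of the explicit model."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if mu.ndim != 1 or sigma.shape != (mu.size, mu.size):
            raise ValueError("mu must be a vector and sigma a matching square matrix")
        sigma = (sigma + sigma.T) / 2.0
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)

    @property
    def d(self) -> int:
        return self.mu.size


def _checked_inverse(sigma: np.ndarray) -> np.ndarray:
    if not np.all(np.isfinite(sigma)):
        raise SingularCovarianceError("covariance contains non-finite entries")
    eigs = np.linalg.eigvalsh(sigma)
    if eigs[0] <= 0 or eigs[-1] / eigs[0] > _COND_MAX:
        raise SingularCovarianceError(
            "covariance is numerically singular or indefinite: "
            f"smallest eigenvalue {eigs[0]:.3e}"
        )
    return np.linalg.inv(sigma)


def energy_explicit(x: np.ndarray, params: ExplicitParams) -> float:
    """F(x) = -1/2 log|Σ| - 1/2 (x-μ)ᵀΣ⁻¹(x-μ)."""
    inv = _checked_inverse(params.sigma)
    diff = np.asarray(x, dtype=float) - params.mu
    sign, logdet = np.linalg.slogdet(params.sigma)
    if sign <= 0:
        raise SingularCovarianceError("covariance has non-positive determinant")
    return float(-0.5 * logdet - 0.5 * diff @ inv @ diff)


def weighted_error(x: np.ndarray, params: ExplicitParams) -> np.ndarray:
    """Precision-weighted prediction error ε = Σ⁻¹(x - μ)."""
    inv = _checked_inverse(params.sigma)
    return inv @ (np.asarray(x, dtype=float) - params.mu)


def explicit_gradients(
    patterns: PatternMatrix, params: ExplicitParams
) -> tuple[np.ndarray, np.ndarray]:
    """Full-batch parameter updates (per unit learning rate).

    Returns (Δμ/α, ΔΣ/α) with Δμ/α = Σ_i ε(i) and
    ΔΣ/α = -NΣ⁻¹ + Σ_i ε(i)ε(i)ᵀ, where ε(i) = Σ⁻¹(x(i)-μ).
    """
    inv = _checked_inverse(params.sigma)
    diffs = patterns.values - params.mu
    eps = diffs @ inv  # rows are ε(i)ᵀ (inv symmetric)
    g_mu = eps.sum(axis=0)
    g_sigma = -patterns.n * inv + eps.T @ eps
    return g_mu, (g_sigma + g_sigma.T) / 2.0


def _default_lr(patterns: PatternMatrix, config: TrainConfig) -> float:
    # Near the optimum the Σ update linearizes to ΔE = -αN S⁻¹ E S⁻¹, so
    # the iteration is stable only for αN < 2 λmin(S)²; pick half that,
    # capped at 0.1 so early steps from Σ = I stay small, floored so
    # near-singular data stalls visibly instead of silently.
    from .patterns import sample_stats

    lam_min = float(np.linalg.eigvalsh(sample_stats(patterns).cov)[0])
    per_epoch = min(0.1, max(1e-4, 0.5 * lam_min**2))
    n = patterns.n if config.mode == "full_batch" else 1
    if config.mode == "minibatch":
        n = config.batch_size or max(1, patterns.n // 8)
    return per_epoch / max(n, 1)


def learn_explicit(
    patterns: PatternMatrix,
    config: TrainConfig,
    init: ExplicitParams | None = None,
) -> ExplicitParams:
    """Train μ and Σ by gradient ascent of the summed log-likelihood.

    In ``full_batch`` mode the updates use the pattern-summed gradients
    and stop once the largest parameter change drops below
    ``config.convergence_tol`` (or the epoch cap is hit); at convergence
    μ ≈ x̄ and Σ ≈ S.  ``online`` mode applies the single-pattern update
    once per row per epoch, in memorization order; ``minibatch`` sums
    within shuffled batches.  Σ is symmetrized after every step and its
    inverse is recomputed from scratch each step.
    """
    d = patterns.d
    if init is None:
        init = ExplicitParams(mu=np.zeros(d), sigma=np.eye(d))
    mu = init.mu.copy()
    sigma = init.sigma.copy()
    alpha = config.learning_rate if config.learning_rate is not None else _default_lr(
        patterns, config
    )
    rng = np.random.default_rng(config.seed)

    def batches():
        if config.mode == "full_batch":
            yield patterns.values
        elif config.mode == "online":
            for row in patterns.values:
                yield row[None, :]
        else:
            bs = config.batch_size or max(1, patterns.n // 8)
            order = rng.permutation(patterns.n)
            for start in range(0, patterns.n, bs):
                yield patterns.values[order[start : start + bs]]

    for _ in range(config.max_epochs):
        max_step = 0.0
        for batch in batches():
            g_mu, g_sigma = explicit_gradients(
                PatternMatrix(batch), ExplicitParams(mu, sigma)
            )
            d_mu = alpha * g_mu
            d_sigma = alpha * g_sigma
            mu = mu + d_mu
            sigma = sigma + d_sigma
            sigma = (sigma + sigma.T) / 2.0
            if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(sigma))):
                raise SingularCovarianceError(
                    "training diverged: parameters became non-finite"
                )
            max_step = max(max_step, np.abs(d_mu).max(), np.abs(d_sigma).max())
        if max_step < config.convergence_tol:
            break
    return ExplicitParams(mu=mu, sigma=sigma)


def infer_explicit(
    cue: CueSpec, params: ExplicitParams, config: InferConfig
) -> RetrievalResult:
    """Retrieve a pattern from a cue by precision-weighted relaxation.

    The activity starts at the cue and follows Δx = -β ε = -β Σ⁻¹(x-μ)
    on the relaxing coordinates.  With ``relax_set='corrupted_only'``
    the intact coordinates stay clamped at the cue for the whole run;
    noise-corrupted cues (or ``relax_set='all'``) relax everywhere.
    """
    inv = _checked_inverse(params.sigma)
    x = cue.cue.copy()
    free = _free_indices(cue, config)
    beta = config.step_size
    if beta is None:
        # stability bound: spectral radius of the free-block of Σ⁻¹ is
        # at most the full spectral radius (eigenvalue interlacing)
        beta = 1.0 / np.linalg.eigvalsh(inv)[-1]
    energies = []
    norms = []
    x0_scale = max(1.0, float(np.linalg.norm(x)))
    converged = diverged = False
    it = 0
    for it in range(1, config.max_iters + 1):
        eps = inv @ (x - params.mu)
        dx = -beta * eps[free]
        x[free] += dx
        diff = x - params.mu
        energies.append(-0.5 * float(diff @ inv @ diff))
        step = float(np.abs(dx).max()) if dx.size else 0.0
        norms.append(step)
        if not np.all(np.isfinite(x)) or np.linalg.norm(x) > config.explosion_bound * x0_scale:
            diverged = True
            break
        if step < config.convergence_tol:
            converged = True
            break
    return RetrievalResult(
        x_final=x,
        converged=converged,
        diverged=diverged,
        iterations=it,
        energy_trace=np.asarray(energies),
        update_norm_trace=np.asarray(norms),
    )


def _free_indices(cue: CueSpec, config: InferConfig) -> np.ndarray:
    if config.relax_set == "all" or cue.kind == "gaussian_noise":
        return np.arange(cue.d)
    if cue.corrupted_idx.size == 0:
        return np.arange(0)
    return cue.corrupted_idx
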