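"""Implicit, dendritic, and nonlinear covariance-learning networks.

These single-layer recurrent networks replace the explicit covariance
matrix with a zero-diagonal recurrent weight matrix W and bias ν: each
neuron is predicted by all the others, ε = x - W f(x) - ν, and the
energy is F = -1/2 ‖ε‖².  Learning is purely Hebbian,

    Δν = α Σ_i ε(i),      ΔW = α (Σ_i ε(i) f(x(i))ᵀ)_{diag=0},

identical for all variants.  At convergence on a full-rank dataset the
weights satisfy ν = (I-W)x̄ and off-diag[(I-W)S] = 0, so W encodes the
sample covariance *implicitly* — no matrix inverse ever appears.

The variants differ only in retrieval dynamics:

* ``implicit``  — Δx = β(-ε + f'(x)⊙Wᵀε), the exact energy gradient.
  With M = W - I (linear case) this is Δx = -β MᵀM (x - x̄), an
  unconditionally stable linear system.
* ``dendritic`` — Δx = -βε, the gradient of the stop-gradient energy
  F = -1/2‖x - W sg(x) - ν‖².  Its linear dynamics Δx = βM(x - x̄) share
  the implicit fixed points but are stable only when every eigenvalue
  of M has non-positive real part, which learning does not guarantee;
  divergence here is reported, never masked.

With the intact coordinates clamped during pattern completion, the
implicit update confines the backward error projection to the corrupted
sub-network: Δx_k = β(-ε_k + f'(x_k)⊙W_kkᵀε_k).  The corrupted neurons
then behave as a covariance-learning network of their own, driven by
the clamped part through W_km x_m + ν_k; the fixed point is ε_k = 0,
which is exactly the closed-form retrieval S_km S_mm⁻¹(x_m-x̄_m)+x̄_k,
and the dynamics inherit the -AᵀA stability of the full implicit model
(A = I - W_kk).  Projecting the full-vector gradient instead would drag
the retrieval toward minimizing the clamped coordinates' errors too,
which is not the completion estimate whenever the training residual is
nonzero (N > d).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .patterns import (
    CueSpec,
    InferConfig,
    PatternMatrix,
    RetrievalResult,
    TrainConfig,
)

__all__ = [
    "RecurrentParams",
    "error_recurrent",
    "energy_recurrent",
    "recurrent_gradients",
    "learn_recurrent",
    "infer_recurrent",
]


@dataclass(frozen=True)
class RecurrentParams:
    """Zero-diagonal recurrent weights W, bias ν, variant and nonlinearity."""

    W: np.ndarray
    nu: np.ndarray
    variant: str = "implicit"  # implicit | dendritic
    nonlinearity: str = "identity"  # identity | tanh

    def __post_init__(self):
        W = np.asarray(self.W, dtype=float).copy()
        nu = np.asarray(self.nu, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1] or nu.shape != (W.shape[0],):
            raise ValueError("W must be square and nu a matching vector")
        np.fill_diagonal(W, 0.0)
        if self.variant not in ("implicit", "dendritic"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.nonlinearity not in ("identity", "tanh"):
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "nu", nu)

    @property
    def d(self) -> int:
        return self.nu.size

    def f(self, x: np.ndarray) -> np.ndarray:
        return np.tanh(x) if self.nonlinearity == "tanh" else x

    def fprime(self, x: np.ndarray) -> np.ndarray:
        if self.nonlinearity == "tanh":
            return 1.0 - np.tanh(x) ** 2
        return np.ones_like(x)

    @classmethod
    def zeros(cls, d: int, variant: str = "implicit", nonlinearity: str = "identity"):
        return cls(W=np.zeros((d, d)), nu=np.zeros(d), variant=variant,
                   nonlinearity=nonlinearity)


def error_recurrent(x: np.ndarray, params: RecurrentParams) -> np.ndarray:
    """Prediction error ε = x - W f(x) - ν."""
    x = np.asarray(x, dtype=float)
    return x - params.W @ params.f(x) - params.nu


def energy_recurrent(x: np.ndarray, params: RecurrentParams) -> float:
    """F = -1/2 ‖ε‖²; identical for implicit and dendritic variants."""
    eps = error_recurrent(x, params)
    return float(-0.5 * eps @ eps)


def recurrent_gradients(
    patterns: PatternMatrix,
    params: RecurrentParams,
    literal_presynaptic: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Full-batch Hebbian updates (per unit learning rate).

    Returns (ΔW/α, Δν/α) with ΔW/α = (Σ_i ε(i) g(x(i))ᵀ)_{diag=0} and
    Δν/α = Σ_i ε(i).  The pre-synaptic factor g is f(x) by default (the
    true gradient of the nonlinear energy); ``literal_presynaptic``
    uses the raw activity x instead, matching the linear-form plasticity
    verbatim.  The two coincide for the identity nonlinearity.
    """
    X = patterns.values
    FX = params.f(X)
    E = X - FX @ params.W.T - params.nu  # rows are ε(i)ᵀ
    pre = X if literal_presynaptic else FX
    gW = E.T @ pre
    np.fill_diagonal(gW, 0.0)
    return gW, E.sum(axis=0)


def _default_lr(patterns: PatternMatrix, params: RecurrentParams,
                config: TrainConfig) -> float:
    # Hessian of each row's squared error is Σ_i z zᵀ, z = [f(x); 1];
    # 1/λmax of its full-batch version keeps gradient descent stable.
    Z = np.hstack([params.f(patterns.values), np.ones((patterns.n, 1))])
    lam = np.linalg.eigvalsh(Z.T @ Z)[-1]
    scale = 1.0
    if config.mode == "online":
        scale = patterns.n
    elif config.mode == "minibatch":
        bs = config.batch_size or max(1, patterns.n // 8)
        scale = patterns.n / bs
    return 1.0 / (lam / scale)


def learn_recurrent(
    patterns: PatternMatrix,
    config: TrainConfig,
    params: RecurrentParams | None = None,
    literal_presynaptic: bool = False,
) -> RecurrentParams:
    """Train W and ν with the Hebbian covariance-learning rule.

    W and ν start at zero unless ``params`` supplies an initialization.
    The diagonal of W is re-zeroed after every update.  Learning does
    not depend on the variant (the stop gradient only changes inference),
    so implicit and dendritic training are bit-identical under the same
    configuration.
    """
    if params is None:
        params = RecurrentParams.zeros(patterns.d)
    W = params.W.copy()
    nu = params.nu.copy()
    alpha = config.learning_rate
    if alpha is None:
        alpha = _default_lr(patterns, params, config)
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
            cur = replace(params, W=W, nu=nu)
            gW, gnu = recurrent_gradients(
                PatternMatrix(batch), cur, literal_presynaptic=literal_presynaptic
            )
            dW = alpha * gW
            dnu = alpha * gnu
            W = W + dW
            np.fill_diagonal(W, 0.0)
            nu = nu + dnu
            if not (np.all(np.isfinite(W)) and np.all(np.isfinite(nu))):
                raise FloatingPointError("training diverged: non-finite parameters")
            max_step = max(max_step, np.abs(dW).max(),
                           np.abs(dnu).max() if dnu.size else 0.0)
        if max_step < config.convergence_tol:
            break
    return replace(params, W=W, nu=nu)


def _default_beta(params: RecurrentParams, free: np.ndarray) -> float:
    if params.variant == "implicit":
        M = params.W - np.eye(params.d)
        lam = np.linalg.eigvalsh(M.T @ M)[-1]
        return 1.0 / max(lam, 1e-12)
    # dendritic: eigenvalues of M lie within σmax(W) of -1
    smax = np.linalg.svd(params.W, compute_uv=False)[0]
    return 0.9 / (1.0 + smax)


def infer_recurrent(
    cue: CueSpec, params: RecurrentParams, config: InferConfig
) -> RetrievalResult:
    """Retrieve a pattern by relaxing the recurrent network from a cue.

    Implicit variant: Δx = β(-ε + f'(x)⊙Wᵀε), restricted to the
    corrupted sub-network when the intact coordinates are clamped (see
    module docstring).  Dendritic variant: Δx = -βε on the relaxing
    coordinates.  Noise-corrupted cues always relax every coordinate.
    Divergence (non-finite activity or norm blow-up) sets the
    ``diverged`` flag and returns the trace rather than raising —
    dendritic instability is an expected, observable regime.

    When ``config.step_size`` is None the implicit variant uses an
    energy-guarded adaptive step: β starts at the linear stability bound
    1/λmax(MᵀM), is halved whenever a step would decrease the (free
    part of the) energy, and grows by 5% on accepted steps.  The fixed
    points are those of the underlying gradient dynamics; only the pace
    changes.  The dendritic variant never adapts — its update is not a
    gradient and its instability must stay observable.
    """
    x = cue.cue.copy()
    d = cue.d
    if config.relax_set == "all" or cue.kind == "gaussian_noise":
        free = np.arange(d)
    else:
        free = cue.corrupted_idx
    full_relax = free.size == d
    beta0 = config.step_size
    adaptive = beta0 is None and params.variant == "implicit"
    if beta0 is None:
        beta0 = _default_beta(params, free)
    beta = beta0
    W_kk = params.W if full_relax else params.W[np.ix_(free, free)]

    def grad(xv: np.ndarray) -> np.ndarray:
        eps = error_recurrent(xv, params)
        if params.variant == "dendritic":
            return -eps[free]
        if full_relax:
            return -eps + params.fprime(xv) * (params.W.T @ eps)
        return -eps[free] + params.fprime(xv[free]) * (W_kk.T @ eps[free])

    def free_energy(xv: np.ndarray) -> float:
        eps = error_recurrent(xv, params)
        return float(-0.5 * eps[free] @ eps[free]) if not full_relax else float(
            -0.5 * eps @ eps
        )

    energies, norms = [], []
    x0_scale = max(1.0, float(np.linalg.norm(x)))
    converged = diverged = False
    e_cur = free_energy(x)
    it = 0
    for it in range(1, config.max_iters + 1):
        g = grad(x)
        if adaptive:
            accepted = False
            for _ in range(60):
                x_try = x.copy()
                x_try[free] += beta * g
                e_try = free_energy(x_try)
                if np.isfinite(e_try) and e_try >= e_cur - 1e-15 * abs(e_cur):
                    accepted = True
                    break
                beta *= 0.5
            if not accepted:
                converged = True  # no ascent direction at floating-point resolution
                x_try, e_try = x, e_cur
            dx = x_try[free] - x[free]
            x, e_cur = x_try, e_try
            beta = min(beta * 1.05, beta0 * 1e8)
        else:
            dx = beta * g
            x[free] += dx
            e_cur = free_energy(x)
        energies.append(energy_recurrent(x, params))
        step = float(np.abs(dx).max()) if dx.size else 0.0
        norms.append(step)
        if not np.all(np.isfinite(x)) or np.linalg.norm(x) > config.explosion_bound * x0_scale:
            diverged = True
            converged = False
            break
        if step < config.convergence_tol or converged:
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


def relax_batch(
    X0: np.ndarray, params: RecurrentParams, config: InferConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Relax many fully-free initial activities at once (rows of X0).

    Vectorized counterpart of :func:`infer_recurrent` with
    ``relax_set='all'``, used by grid probes.  Implicit runs use a
    per-row energy-guarded adaptive step; dendritic runs use a fixed
    step.  Returns (endpoints, converged_mask); rows that diverge are
    frozen at their last finite value with converged=False.
    """
    X = np.array(X0, dtype=float, copy=True)
    n, d = X.shape
    beta0 = config.step_size
    adaptive = beta0 is None and params.variant == "implicit"
    if beta0 is None:
        beta0 = _default_beta(params, np.arange(d))
    betas = np.full(n, beta0)
    active = np.ones(n, dtype=bool)
    done_ok = np.zeros(n, dtype=bool)
    scale = np.maximum(1.0, np.linalg.norm(X, axis=1))

    def batch_eps(Xv):
        return Xv - params.f(Xv) @ params.W.T - params.nu

    E = batch_eps(X)
    e_cur = -0.5 * np.sum(E**2, axis=1)
    for _ in range(config.max_iters):
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        Xa = X[idx]
        Ea = batch_eps(Xa)
        if params.variant == "dendritic":
            G = -Ea
        else:
            G = -Ea + params.fprime(Xa) * (Ea @ params.W)
        if adaptive:
            b = betas[idx]
            for _ in range(60):
                X_try = Xa + b[:, None] * G
                e_try = -0.5 * np.sum(batch_eps(X_try) ** 2, axis=1)
                bad = ~(np.isfinite(e_try) & (e_try >= e_cur[idx] - 1e-15 * np.abs(e_cur[idx])))
                if not bad.any():
                    break
                b = np.where(bad, b * 0.5, b)
            dX = X_try - Xa
            X[idx] = np.where(bad[:, None], Xa, X_try)
            e_new = np.where(bad, e_cur[idx], e_try)
            e_cur[idx] = e_new
            betas[idx] = np.minimum(b * 1.05, beta0 * 1e8)
            step = np.where(bad, 0.0, np.abs(dX).max(axis=1))
            newly_done = (step < config.convergence_tol) | bad
        else:
            dX = betas[idx, None] * G
            X[idx] = Xa + dX
            step = np.abs(dX).max(axis=1)
            newly_done = step < config.convergence_tol
        finite = np.isfinite(X[idx]).all(axis=1) & (
            np.linalg.norm(X[idx], axis=1) <= config.explosion_bound * scale[idx]
        )
        done_ok[idx[newly_done & finite]] = True
        active[idx[newly_done | ~finite]] = False
    return X, done_ok
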