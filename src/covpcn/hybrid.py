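"""Hybrid hierarchical + recurrent predictive coding network.

Models the pathway from sensory cortex to hippocampus: layers 1..L-1
form a hierarchical predictive coding network (layer 1 = sensory input)
and layer L is a recurrent covariance-learning layer (the hippocampal
analog).  Descending predictions are

    ρ(l) = Θ(l) f(x(l+1))   for l < L,      ρ(L) = W x(L),

with errors ε(l) = x(l) - ρ(l) and energy F = -1/2 Σ_l ‖ε(l)‖².  The
top layer carries no bias term.  Inference relaxes the activities by
gradient ascent of F; the top layer's recurrent feedback term Wᵀε(L) is
included when the top is an implicit layer (γ = 1) and dropped for a
dendritic top (γ = 0, the stop-gradient form).  During training the
sensory layer is clamped to the input; during retrieval the corrupted
sensory coordinates also relax, by Δx_c(1) = -β ε_c(1).

Learning alternates relaxation (many inference steps) with one Hebbian
weight step ΔΘ(l) = α ε(l) f(x(l+1))ᵀ, ΔW = α ε(L) x(L)ᵀ (diagonal of W
re-zeroed), averaged within a minibatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .patterns import CueSpec, InferConfig, PatternMatrix, TrainConfig

__all__ = [
    "HybridParams",
    "HybridState",
    "init_hybrid",
    "hybrid_predictions",
    "hybrid_energy",
    "hybrid_infer",
    "hybrid_train",
    "hybrid_retrieve",
    "implicit_param_count",
    "hybrid_param_count",
    "matched_hybrid_sizes",
]


def _f(name: str, x: np.ndarray) -> np.ndarray:
    return np.tanh(x) if name == "tanh" else x


def _fprime(name: str, x: np.ndarray) -> np.ndarray:
    return 1.0 - np.tanh(x) ** 2 if name == "tanh" else np.ones_like(x)


@dataclass
class HybridParams:
    """Layered weights Θ(l), top recurrent W, and architecture flags."""

    layer_sizes: list[int]
    thetas: list[np.ndarray]      # thetas[l]: (size_l, size_{l+1}), l = 0..L-2
    W_top: np.ndarray             # (size_{L-1}, size_{L-1}), zero diagonal
    top_variant: str = "implicit"  # implicit (γ=1) | dendritic (γ=0)
    f: str = "tanh"               # hidden-layer nonlinearity

    def __post_init__(self):
        L = len(self.layer_sizes)
        if L < 2:
            raise ValueError("a hybrid network needs at least 2 layers")
        if len(self.thetas) != L - 1:
            raise ValueError(f"expected {L - 1} theta matrices, got {len(self.thetas)}")
        for l, th in enumerate(self.thetas):
            want = (self.layer_sizes[l], self.layer_sizes[l + 1])
            if th.shape != want:
                raise ValueError(f"theta[{l}] has shape {th.shape}, expected {want}")
        top = self.layer_sizes[-1]
        if self.W_top.shape != (top, top):
            raise ValueError("W_top shape inconsistent with top layer size")
        np.fill_diagonal(self.W_top, 0.0)
        if self.top_variant not in ("implicit", "dendritic"):
            raise ValueError(f"unknown top_variant {self.top_variant!r}")

    @property
    def L(self) -> int:
        return len(self.layer_sizes)

    @property
    def gamma(self) -> float:
        return 1.0 if self.top_variant == "implicit" else 0.0


@dataclass
class HybridState:
    """Per-layer activities, predictions and errors for a batch of patterns."""

    xs: list[np.ndarray]           # xs[l]: (B, size_l)
    rhos: list[np.ndarray] = field(default_factory=list)
    epses: list[np.ndarray] = field(default_factory=list)
    energy: float = 0.0


def init_hybrid(
    layer_sizes: list[int],
    top_variant: str = "implicit",
    f: str = "tanh",
    seed: int = 0,
) -> HybridParams:
    """Fresh parameters: Θ(l) ~ N(0, 1/fan_in) (fan_in = size of layer l+1),
    W zero."""
    rng = np.random.default_rng(seed)
    thetas = [
        rng.normal(scale=1.0 / np.sqrt(layer_sizes[l + 1]),
                   size=(layer_sizes[l], layer_sizes[l + 1]))
        for l in range(len(layer_sizes) - 1)
    ]
    W = np.zeros((layer_sizes[-1], layer_sizes[-1]))
    return HybridParams(layer_sizes=list(layer_sizes), thetas=thetas, W_top=W,
                        top_variant=top_variant, f=f)


def _zero_state(params: HybridParams, batch: np.ndarray) -> HybridState:
    B = batch.shape[0]
    xs = [batch.astype(float).copy()]
    xs += [np.zeros((B, s)) for s in params.layer_sizes[1:]]
    return HybridState(xs=xs)


def hybrid_predictions(state: HybridState, params: HybridParams) -> HybridState:
    """Recompute descending predictions, errors, and the energy in place."""
    L = params.L
    xs = state.xs
    if any(x.shape[1] != s for x, s in zip(xs, params.layer_sizes)):
        raise ValueError("activity shapes inconsistent with layer sizes")
    rhos = [None] * L
    rhos[L - 1] = xs[L - 1] @ params.W_top.T
    for l in range(L - 1):
        rhos[l] = _f(params.f, xs[l + 1]) @ params.thetas[l].T
    epses = [x - r for x, r in zip(xs, rhos)]
    state.rhos = rhos
    state.epses = epses
    state.energy = -0.5 * float(sum(np.sum(e ** 2) for e in epses))
    return state


def hybrid_energy(xs: list[np.ndarray], params: HybridParams) -> float:
    """F = -1/2 Σ_l ‖ε(l)‖² evaluated at the given activities."""
    state = hybrid_predictions(HybridState(xs=[np.atleast_2d(x) for x in xs]), params)
    return state.energy


def _activity_updates(state: HybridState, params: HybridParams) -> list[np.ndarray]:
    """Gradient-ascent updates (per unit β) for layers 2..L; layer 1 is 0."""
    L = params.L
    xs, eps = state.xs, state.epses
    dxs = [np.zeros_like(xs[0])]
    for l in range(1, L):
        dx = -eps[l] + _fprime(params.f, xs[l]) * (eps[l - 1] @ params.thetas[l - 1])
        if l == L - 1 and params.gamma == 1.0:
            dx = dx + eps[l] @ params.W_top
        dxs.append(dx)
    return dxs


def hybrid_infer(
    state: HybridState,
    params: HybridParams,
    config: InferConfig,
    mode: str = "training",
    cue: CueSpec | None = None,
) -> tuple[HybridState, dict]:
    """Relax the value neurons to an energy equilibrium.

    ``training`` mode clamps the sensory layer; ``retrieval`` mode also
    relaxes the corrupted sensory coordinates of the supplied cue while
    the intact ones stay clamped.  Returns the updated state and a trace
    dict with per-iteration energy and update norm.
    """
    if mode not in ("training", "retrieval"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "retrieval" and cue is None:
        raise ValueError("retrieval mode needs a cue")
    beta = config.step_size if config.step_size is not None else 0.1
    energies, norms = [], []
    converged = diverged = False
    scale = max(1.0, float(np.linalg.norm(state.xs[0])))
    it = 0
    for it in range(1, config.max_iters + 1):
        hybrid_predictions(state, params)
        dxs = _activity_updates(state, params)
        step = 0.0
        for l in range(1, params.L):
            state.xs[l] += beta * dxs[l]
            step = max(step, float(np.abs(dxs[l]).max()))
        if mode == "retrieval":
            c = cue.corrupted_idx
            if c.size:
                d0 = -state.epses[0][:, c]
                state.xs[0][:, c] += beta * d0
                step = max(step, float(np.abs(d0).max()))
        energies.append(state.energy)
        norms.append(step)
        if not all(np.all(np.isfinite(x)) for x in state.xs) or (
            np.linalg.norm(state.xs[0]) > config.explosion_bound * scale
        ):
            diverged = True
            break
        if beta * step < config.convergence_tol:
            converged = True
            break
    hybrid_predictions(state, params)
    trace = {
        "energy": np.asarray(energies),
        "update_norm": np.asarray(norms),
        "iterations": it,
        "converged": converged,
        "diverged": diverged,
    }
    return state, trace


def hybrid_train(
    patterns: PatternMatrix,
    params: HybridParams,
    train_config: TrainConfig,
    infer_config: InferConfig | None = None,
) -> HybridParams:
    """Train by alternating relaxation and one Hebbian weight step per batch.

    Batch size defaults to N/8.  Within each batch the sensory layer is
    clamped to the patterns, hidden activities start at zero, inference
    runs for ``infer_config.max_iters`` steps (400 by default), and the
    weight update applies the batch-averaged error-Hebbian rule once,
    re-zeroing the diagonal of W.  Stops when the batch-mean energy
    stops improving by more than ``convergence_tol`` or at the epoch cap.
    """
    if patterns.d != params.layer_sizes[0]:
        raise ValueError("pattern dimension does not match the sensory layer")
    if infer_config is None:
        infer_config = InferConfig(step_size=0.1, max_iters=400,
                                   convergence_tol=0.0, relax_set="corrupted_only")
    alpha = train_config.learning_rate if train_config.learning_rate is not None else 0.01
    bs = train_config.batch_size or max(1, patterns.n // 8)
    rng = np.random.default_rng(train_config.seed)
    prev_energy = -np.inf
    for _ in range(train_config.max_epochs):
        order = rng.permutation(patterns.n)
        epoch_energy = 0.0
        for start in range(0, patterns.n, bs):
            batch = patterns.values[order[start : start + bs]]
            state = _zero_state(params, batch)
            state, _ = hybrid_infer(state, params, infer_config, mode="training")
            B = batch.shape[0]
            for l in range(params.L - 1):
                params.thetas[l] += alpha * (
                    state.epses[l].T @ _f(params.f, state.xs[l + 1])
                ) / B
            dW = alpha * (state.epses[-1].T @ state.xs[-1]) / B
            params.W_top += dW
            np.fill_diagonal(params.W_top, 0.0)
            if not all(np.all(np.isfinite(t)) for t in params.thetas) or not np.all(
                np.isfinite(params.W_top)
            ):
                raise FloatingPointError("hybrid training diverged: non-finite weights")
            epoch_energy += state.energy
        if abs(epoch_energy - prev_energy) < train_config.convergence_tol:
            break
        prev_energy = epoch_energy
    return params


def hybrid_retrieve(
    cues: list[CueSpec],
    params: HybridParams,
    config: InferConfig | None = None,
) -> tuple[np.ndarray, list[dict]]:
    """Retrieve patterns from cues with a trained hybrid network.

    Each cue's intact sensory coordinates are clamped; corrupted ones and
    all hidden layers relax.  Returns the retrieved sensory activities
    (one row per cue) and the per-cue inference traces.
    """
    if config is None:
        config = InferConfig(step_size=0.1, max_iters=20_000, convergence_tol=1e-9)
    outs, traces = [], []
    for cue in cues:
        state = _zero_state(params, cue.cue[None, :])
        state, trace = hybrid_infer(state, params, config, mode="retrieval", cue=cue)
        outs.append(state.xs[0][0])
        traces.append(trace)
    return np.asarray(outs), traces


# --------------------------------------------------------------------------
# parameter accounting


def implicit_param_count(d: int) -> int:
    """Free parameters of a single-layer implicit network on d neurons
    (zero-diagonal W; the bias is ignored, matching the hybrid's top layer)."""
    return d * (d - 1)


def hybrid_param_count(params: HybridParams) -> int:
    total = sum(t.size for t in params.thetas)
    top = params.layer_sizes[-1]
    return total + top * (top - 1)


def matched_hybrid_sizes(d: int) -> list[int]:
    """Layer sizes [d, d/2, d/2] giving a hybrid with approximately the
    d(d-1) parameters of the flat implicit network on d neurons."""
    return [d, d // 2, d // 2]
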