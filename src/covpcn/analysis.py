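"""Analytic retrieval oracle, stability diagnostics, and evaluation metrics.

The centrepiece is the closed-form pattern-completion oracle: for a
pattern split into corrupted coordinates k and intact coordinates m,
every converged linear covariance-learning network retrieves

    x̂_k = S_km S_mm⁻¹ (x_m - x̄_m) + x̄_k,

the conditional-mean (equivalently, least-squares regression) estimate
under the sample statistics.  This closed form is computed directly
from the data, independently of any trained network, and serves as the
reference the iterative models are checked against.

Linear retrieval stability is governed by M = W - I: the implicit
dynamics follow Δx ∝ -MᵀM x (negative semidefinite, always stable)
while the dendritic dynamics follow Δx ∝ Mx, stable only when every
eigenvalue of M has non-positive real part.  After zero-error training
with fewer patterns than neurons, M annihilates all pattern
differences, so -MᵀM acquires a null space and its largest eigenvalue
is exactly 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .patterns import CueSpec, InferConfig, PatternMatrix, RetrievalResult, SampleStats
from .recurrent import RecurrentParams, error_recurrent, infer_recurrent, relax_batch

__all__ = [
    "RetrievalResult",
    "StabilityReport",
    "AttractorProbeResult",
    "theorem_retrieval_oracle",
    "oracle_completion",
    "stability_report",
    "retrieval_mse",
    "success_count",
    "attractor_probe",
]

_EIG_TOL = 1e-8
_PINV_RCOND = 1e-10


@dataclass(frozen=True)
class StabilityReport:
    """Spectral stability diagnosis of a linear recurrent model."""

    M: np.ndarray
    eigvals_M: np.ndarray
    eigvals_negMtM: np.ndarray
    max_real_M: float
    max_negMtM: float
    implicit_stable: bool
    dendritic_stable: bool

    def to_dict(self) -> dict:
        return {
            "eigvals_M_real": self.eigvals_M.real.tolist(),
            "eigvals_M_imag": self.eigvals_M.imag.tolist(),
            "eigvals_negMtM": self.eigvals_negMtM.tolist(),
            "max_real_M": self.max_real_M,
            "max_negMtM": self.max_negMtM,
            "implicit_stable": self.implicit_stable,
            "dendritic_stable": self.dendritic_stable,
        }


def theorem_retrieval_oracle(stats: SampleStats, cue: CueSpec) -> np.ndarray:
    """Closed-form retrieval of the corrupted coordinates.

    Returns x̂_k = S_km S_mm⁻¹(x_m - x̄_m) + x̄_k.  A pseudo-inverse
    (relative cutoff 1e-10) handles rank-deficient S_mm, with a warning.
    """
    blocks = stats.blocks(cue)
    S_mm = blocks["S_mm"]
    y_m = cue.cue[cue.intact_idx] - blocks["mean_m"]
    rank = np.linalg.matrix_rank(S_mm, tol=_PINV_RCOND * max(1.0, np.linalg.norm(S_mm, 2)))
    if rank < S_mm.shape[0]:
        warnings.warn(
            f"S_mm is rank deficient ({rank}/{S_mm.shape[0]}); using pseudo-inverse",
            RuntimeWarning,
            stacklevel=2,
        )
        sol = np.linalg.pinv(S_mm, rcond=_PINV_RCOND) @ y_m
    else:
        sol = np.linalg.solve(S_mm, y_m)
    return blocks["S_km"] @ sol + blocks["mean_k"]


def oracle_completion(stats: SampleStats, cue: CueSpec) -> np.ndarray:
    """Full-length retrieval: the cue with corrupted coordinates replaced
    by the closed-form estimate."""
    out = cue.cue.copy()
    out[cue.corrupted_idx] = theorem_retrieval_oracle(stats, cue)
    return out


def stability_report(params: RecurrentParams, tol: float = _EIG_TOL) -> StabilityReport:
    """Eigenspectra of M = W - I and -MᵀM, with per-variant stability flags."""
    if params.nonlinearity != "identity":
        raise ValueError("stability spectra are defined for the linear variants")
    M = params.W - np.eye(params.d)
    eig_M = np.linalg.eigvals(M)
    eig_neg = -np.linalg.eigvalsh(M.T @ M)[::-1]  # descending, all <= 0
    max_real = float(eig_M.real.max())
    max_neg = float(eig_neg.max())
    return StabilityReport(
        M=M,
        eigvals_M=eig_M,
        eigvals_negMtM=eig_neg,
        max_real_M=max_real,
        max_negMtM=max_neg,
        implicit_stable=max_neg <= tol,
        dendritic_stable=max_real <= tol,
    )


def retrieval_mse(
    retrieved: np.ndarray,
    originals: PatternMatrix,
    scope: str = "full",
    corrupted_idx: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Per-pattern mean squared error between retrievals and originals.

    ``scope='full'`` averages over all d coordinates; ``'corrupted_only'``
    averages over the given corrupted index set only.  Returns the
    per-pattern MSEs and their dataset mean.
    """
    retrieved = np.atleast_2d(np.asarray(retrieved, dtype=float))
    if retrieved.shape != originals.values.shape:
        raise ValueError(
            f"shape mismatch: retrieved {retrieved.shape} vs originals "
            f"{originals.values.shape}"
        )
    diff = retrieved - originals.values
    if scope == "corrupted_only":
        if corrupted_idx is None:
            raise ValueError("corrupted_only scope needs the corrupted index set")
        diff = diff[:, np.asarray(corrupted_idx, dtype=int)]
    elif scope != "full":
        raise ValueError(f"unknown scope {scope!r}")
    per = (diff ** 2).mean(axis=1)
    return per, float(per.mean())


def success_count(mses, threshold: float = 5e-3) -> int:
    """Number of retrievals with MSE strictly below the success threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return int(np.sum(np.asarray(list(mses), dtype=float) < threshold))


@dataclass
class AttractorProbeResult:
    """Endpoints and classification of a grid of retrieval probes."""

    grid: np.ndarray            # (n_probes, d) initial points
    endpoints: np.ndarray       # (n_probes, d) converged activities
    labels: np.ndarray          # 'memory' | 'hyperplane' | 'other' | 'diverged'
    nearest_memory: np.ndarray  # index of closest stored pattern, -1 if diverged
    converged: np.ndarray       # bool per probe

    @property
    def fraction_at_memories(self) -> float:
        conv = self.converged
        if not conv.any():
            return 0.0
        return float(np.mean(self.labels[conv] == "memory"))

    def summary(self) -> dict:
        return {
            "n_probes": int(self.grid.shape[0]),
            "n_converged": int(self.converged.sum()),
            "n_at_memories": int(np.sum(self.labels == "memory")),
            "n_on_hyperplane": int(np.sum(self.labels == "hyperplane")),
            "n_other": int(np.sum(self.labels == "other")),
            "n_diverged": int(np.sum(self.labels == "diverged")),
            "fraction_at_memories": self.fraction_at_memories,
        }


def attractor_probe(
    params: RecurrentParams,
    memories: PatternMatrix,
    grid_low: float = -1.0,
    grid_high: float = 1.0,
    points_per_axis: int = 9,
    infer_config: InferConfig | None = None,
    memory_tol: float | None = None,
    hyperplane_tol: float = 1e-4,
) -> AttractorProbeResult:
    """Map the attractor structure by relaxing from a grid of test points.

    Every grid point in [grid_low, grid_high]^d is used as a fully
    corrupted cue (all coordinates relax).  Converged endpoints are
    classified as a stored memory (within ``memory_tol``, default
    0.05·√d Euclidean), as lying on the affine solution set
    {x : (I-W)x = ν} of the linear model, or as other.  Divergent probes
    are recorded, not raised.  Intended for small d (grids grow as
    points_per_axis^d; d ≤ 4 is the practical range).
    """
    d = params.d
    if d > 4:
        raise ValueError("attractor probing is restricted to d <= 4 (grid blow-up)")
    if infer_config is None:
        infer_config = InferConfig(relax_set="all", max_iters=50_000,
                                   convergence_tol=1e-9)
    if memory_tol is None:
        memory_tol = 0.05 * np.sqrt(d)
    axes = [np.linspace(grid_low, grid_high, points_per_axis)] * d
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, d)
    endpoints, conv = relax_batch(grid, params, infer_config)
    labels = np.empty(grid.shape[0], dtype=object)
    nearest = np.full(grid.shape[0], -1, dtype=int)
    I = np.eye(d)
    for i, x_end in enumerate(endpoints):
        if not np.all(np.isfinite(x_end)):
            labels[i] = "diverged"
            continue
        if not conv[i]:
            labels[i] = "other"
            continue
        dists = np.linalg.norm(memories.values - x_end, axis=1)
        nearest[i] = int(np.argmin(dists))
        if dists[nearest[i]] < memory_tol:
            labels[i] = "memory"
        elif (
            params.nonlinearity == "identity"
            and np.linalg.norm((I - params.W) @ x_end - params.nu) < hyperplane_tol
        ):
            labels[i] = "hyperplane"
        else:
            labels[i] = "other"
    return AttractorProbeResult(
        grid=grid,
        endpoints=endpoints,
        labels=np.asarray(labels, dtype=object),
        nearest_memory=nearest,
        converged=conv,
    )
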