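"""Pattern sets, corruption operators, and synthetic data generators.

Associative-memory experiments in this package operate on a fixed set of
N real-valued patterns of dimension d (one pattern per matrix row).  A
*cue* is a corrupted version of a pattern handed to a trained network at
retrieval time: either some coordinates are masked to zero (pattern
completion) or the whole vector is perturbed with isotropic Gaussian
noise (denoising).  The generators below produce the synthetic pattern
families used throughout: i.i.d. Gaussian patterns, a 3-point toy set in
[-1, 1]^3 for attractor probing, and correlated low-rank-plus-noise
patterns that emulate the second-order statistics of natural images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "PatternMatrix",
    "CueSpec",
    "SampleStats",
    "TrainConfig",
    "InferConfig",
    "RetrievalResult",
    "split_seed",
    "generate_gaussian_patterns",
    "generate_toy_3d",
    "generate_correlated_patterns",
    "corrupt_mask",
    "corrupt_noise",
    "sample_stats",
    "load_patterns",
    "save_patterns",
]


# --------------------------------------------------------------------------
# core containers


@dataclass(frozen=True)
class PatternMatrix:
    """An N x d memory set; rows are patterns, row order is memorization order."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"pattern matrix must be 2-D, got shape {v.shape}")
        if v.shape[0] < 1 or v.shape[1] < 2:
            raise ValueError(f"need N >= 1 patterns of dimension d >= 2, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("pattern matrix contains non-finite entries")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class CueSpec:
    """A retrieval cue: initial activity plus the corrupted/intact partition.

    ``corrupted_idx`` lists the k coordinates free to relax during
    retrieval; its complement is the m intact coordinates which stay
    clamped (k + m = d).  For ``mask_zero`` cues the corrupted entries
    are zero; for ``gaussian_noise`` cues every coordinate is corrupted.
    """

    cue: np.ndarray
    corrupted_idx: np.ndarray
    kind: Literal["mask_zero", "gaussian_noise", "none"] = "mask_zero"
    noise_variance: float = 0.0

    def __post_init__(self):
        cue = np.asarray(self.cue, dtype=float)
        idx = np.unique(np.asarray(self.corrupted_idx, dtype=int))
        d = cue.shape[0]
        if cue.ndim != 1:
            raise ValueError("cue must be a vector")
        if idx.size and (idx.min() < 0 or idx.max() >= d):
            raise ValueError("corrupted indices out of range")
        if self.noise_variance < 0:
            raise ValueError("noise variance must be nonnegative")
        if self.kind == "mask_zero" and idx.size and np.any(cue[idx] != 0.0):
            raise ValueError("mask_zero cue must be zero on corrupted coordinates")
        object.__setattr__(self, "cue", cue)
        object.__setattr__(self, "corrupted_idx", idx)

    @property
    def d(self) -> int:
        return self.cue.shape[0]

    @property
    def intact_idx(self) -> np.ndarray:
        mask = np.ones(self.d, dtype=bool)
        mask[self.corrupted_idx] = False
        return np.nonzero(mask)[0]

    # JSON round-trip -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "cue": self.cue.tolist(),
                "corrupted_indices": self.corrupted_idx.tolist(),
                "kind": self.kind,
                "variance": self.noise_variance,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CueSpec":
        obj = json.loads(text)
        return cls(
            cue=np.asarray(obj["cue"], dtype=float),
            corrupted_idx=np.asarray(obj["corrupted_indices"], dtype=int),
            kind=obj.get("kind", "mask_zero"),
            noise_variance=float(obj.get("variance", 0.0)),
        )


@dataclass(frozen=True)
class SampleStats:
    """Sample mean x̄ and 1/N sample covariance S of a pattern set.

    The 1/N (maximum-likelihood) normalization matters: it is the
    quantity the learned weights converge to, so 1/(N-1) is never used.
    """

    mean: np.ndarray
    cov: np.ndarray

    def blocks(self, cue: CueSpec):
        """Partition S and x̄ into the k/m blocks induced by a cue.

        Returns a dict with keys S_kk, S_km, S_mk, S_mm, mean_k, mean_m.
        """
        k, m = cue.corrupted_idx, cue.intact_idx
        if k.size == 0 or m.size == 0:
            raise ValueError("block partition needs both corrupted and intact parts")
        return {
            "S_kk": self.cov[np.ix_(k, k)],
            "S_km": self.cov[np.ix_(k, m)],
            "S_mk": self.cov[np.ix_(m, k)],
            "S_mm": self.cov[np.ix_(m, m)],
            "mean_k": self.mean[k],
            "mean_m": self.mean[m],
        }


Mode = Literal["full_batch", "online", "minibatch"]


@dataclass
class TrainConfig:
    """Learning hyper-parameters shared by all model families.

    learning_rate is the gradient-ascent step α on the (negative) free
    energy; ``None`` asks the model to pick a stable rate from the data
    spectrum.  convergence_tol is on the max-norm of the parameter
    update; training stops when every parameter moves less than this.
    """

    learning_rate: float | None = None
    mode: Mode = "full_batch"
    batch_size: int | None = None
    max_epochs: int = 10_000
    convergence_tol: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate is not None and self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size is not None and self.batch_size < 1:
            raise ValueError("batch_size must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class InferConfig:
    """Inference (retrieval) hyper-parameters.

    step_size is the integration step β of the activity dynamics;
    ``None`` selects a rate below the local stability bound.
    relax_set selects which coordinates relax: only the corrupted ones
    (intact clamped to the cue) or all of them.
    """

    step_size: float | None = None
    max_iters: int = 100_000
    convergence_tol: float = 1e-10
    relax_set: Literal["corrupted_only", "all"] = "corrupted_only"
    explosion_bound: float = 1e6

    def __post_init__(self):
        if self.step_size is not None and self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")


@dataclass
class RetrievalResult:
    """Outcome of a retrieval run: final activity plus diagnostics."""

    x_final: np.ndarray
    converged: bool
    diverged: bool
    iterations: int
    energy_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    update_norm_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        if self.converged and self.diverged:
            raise ValueError("converged and diverged are mutually exclusive")


# --------------------------------------------------------------------------
# seeding


def split_seed(master_seed: int, *labels: str) -> dict[str, np.random.Generator]:
    """Expand one master seed into named, independent child generators.

    Children are derived with :class:`numpy.random.SeedSequence` spawning
    in the order the labels are given, so experiments that use separate
    streams for generation, corruption and initialization are fully
    reproducible from a single integer.
    """
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(labels))
    return {lab: np.random.default_rng(c) for lab, c in zip(labels, children)}


# --------------------------------------------------------------------------
# generators


def _check_psd(cov: np.ndarray) -> None:
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    w = np.linalg.eigvalsh(cov)
    if w.min() < -1e-10 * max(1.0, w.max()):
        raise ValueError(
            f"covariance is not positive semidefinite: smallest eigenvalue {w.min():.3e}"
        )


def generate_gaussian_patterns(
    n: int,
    d: int,
    mean: Sequence[float] | np.ndarray | None = None,
    cov: np.ndarray | None = None,
    seed: int = 0,
) -> PatternMatrix:
    """Draw n i.i.d. patterns from N(mean, cov).

    Defaults to the standard normal (zero mean, identity covariance),
    the distribution used for the random 5x5-pattern memory sets.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    mean = np.zeros(d) if mean is None else np.asarray(mean, dtype=float)
    cov = np.eye(d) if cov is None else np.asarray(cov, dtype=float)
    if mean.shape != (d,) or cov.shape != (d, d):
        raise ValueError("mean/cov shapes inconsistent with d")
    _check_psd(cov)
    rng = np.random.default_rng(seed)
    vals = rng.multivariate_normal(mean, cov, size=n, method="eigh")
    return PatternMatrix(vals)


def generate_toy_3d(seed: int = 0) -> PatternMatrix:
    """Three random points uniform in [-1, 1]^3, the attractor-probe toy set."""
    rng = np.random.default_rng(seed)
    return PatternMatrix(rng.uniform(-1.0, 1.0, size=(3, 3)))


def generate_correlated_patterns(
    n: int,
    d: int,
    rank: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    factor_scale: float = 1.0,
) -> PatternMatrix:
    """Correlated "image-like" patterns: a low-rank factor mixture plus noise.

    Each pattern is ``loadings @ factors + noise`` with ``rank``
    orthonormal factor directions scaled by ``factor_scale`` and
    isotropic N(0, noise_sd^2) residuals, giving a sample covariance with
    a rank-dominated leading spectrum — the qualitative signature of
    natural-image pattern sets.
    """
    if not (1 <= rank <= d):
        raise ValueError(f"need 1 <= rank <= d, got rank={rank}, d={d}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    basis, _ = np.linalg.qr(rng.normal(size=(d, rank)))
    loadings = rng.normal(size=(n, rank)) * factor_scale
    vals = loadings @ basis.T
    if noise_sd > 0:
        vals = vals + rng.normal(scale=noise_sd, size=(n, d))
    return PatternMatrix(vals)


# --------------------------------------------------------------------------
# corruption operators


def corrupt_mask(
    patterns: PatternMatrix, mask_index_set: Sequence[int] | np.ndarray
) -> list[CueSpec]:
    """Zero the masked coordinates of every pattern, producing one cue per row.

    The mask must leave both a corrupted and an intact part — a
    completion task needs known coordinates to condition on.  For a
    row-major-flattened h x w grid pattern, masking the bottom two rows
    means masking the last 2*w coordinates.
    """
    idx = np.unique(np.asarray(mask_index_set, dtype=int))
    d = patterns.d
    if idx.size == 0:
        raise ValueError("mask set is empty; nothing would be corrupted")
    if idx.size >= d:
        raise ValueError(
            "mask covers every coordinate; use corrupt_noise (or relax_set='all') "
            "for fully-corrupted cues"
        )
    if idx.min() < 0 or idx.max() >= d:
        raise ValueError("mask indices out of range")
    cues = []
    for row in patterns.values:
        cue = row.copy()
        cue[idx] = 0.0
        cues.append(CueSpec(cue=cue, corrupted_idx=idx, kind="mask_zero"))
    return cues


def corrupt_noise(
    patterns: PatternMatrix, variance: float, seed: int = 0
) -> list[CueSpec]:
    """Add isotropic Gaussian noise of the given variance to every pattern.

    All coordinates count as corrupted, so retrieval should relax the
    whole vector (denoising protocol).
    """
    if variance < 0:
        raise ValueError("variance must be nonnegative")
    rng = np.random.default_rng(seed)
    all_idx = np.arange(patterns.d)
    cues = []
    for row in patterns.values:
        noisy = row + rng.normal(scale=np.sqrt(variance), size=patterns.d)
        cues.append(
            CueSpec(
                cue=noisy,
                corrupted_idx=all_idx,
                kind="gaussian_noise",
                noise_variance=variance,
            )
        )
    return cues


# --------------------------------------------------------------------------
# statistics


def sample_stats(patterns: PatternMatrix) -> SampleStats:
    """Sample mean and 1/N-normalized sample covariance of the pattern set."""
    x = patterns.values
    mean = x.mean(axis=0)
    centered = x - mean
    cov = centered.T @ centered / patterns.n
    cov = (cov + cov.T) / 2.0
    return SampleStats(mean=mean, cov=cov)


# --------------------------------------------------------------------------
# file I/O


def save_patterns(patterns: PatternMatrix, path: str | Path) -> None:
    """Write a pattern matrix to .csv, .npy or .npz (keyed ``patterns``)."""
    path = Path(path)
    if path.suffix == ".csv":
        np.savetxt(path, patterns.values, delimiter=",")
    elif path.suffix == ".npy":
        np.save(path, patterns.values)
    elif path.suffix == ".npz":
        np.savez(path, patterns=patterns.values)
    else:
        raise ValueError(f"unsupported pattern file format: {path.suffix}")


def load_patterns(path: str | Path) -> PatternMatrix:
    """Read a pattern matrix from .csv (header optional), .npy or .npz."""
    path = Path(path)
    if path.suffix == ".csv":
        try:
            vals = np.loadtxt(path, delimiter=",", ndmin=2)
        except ValueError:
            vals = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    elif path.suffix == ".npy":
        vals = np.load(path)
    elif path.suffix == ".npz":
        vals = np.load(path)["patterns"]
    else:
        raise ValueError(f"unsupported pattern file format: {path.suffix}")
    return PatternMatrix(np.atleast_2d(vals))
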