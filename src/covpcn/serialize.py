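"""Model checkpoints: NPZ weight archives with JSON sidecars.

Each checkpoint is a pair of files: ``<stem>.npz`` holding the named
weight arrays and ``<stem>.json`` holding everything needed to rebuild
and re-run the model (kind, dimensions, variant flags, and whatever
provenance the caller supplies).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .explicit import ExplicitParams
from .hybrid import HybridParams
from .recurrent import RecurrentParams

__all__ = ["save_model", "load_model"]


def save_model(model, stem: str | Path, extra: dict | None = None) -> None:
    """Write a model checkpoint to ``<stem>.npz`` + ``<stem>.json``."""
    stem = Path(stem)
    meta: dict = dict(extra or {})
    if isinstance(model, ExplicitParams):
        np.savez(stem.with_suffix(".npz"), mu=model.mu, sigma=model.sigma)
        meta.update(kind="explicit", d=model.d)
    elif isinstance(model, RecurrentParams):
        np.savez(stem.with_suffix(".npz"), W=model.W, nu=model.nu)
        meta.update(kind="recurrent", d=model.d, variant=model.variant,
                    nonlinearity=model.nonlinearity)
    elif isinstance(model, HybridParams):
        arrays = {f"theta_{l}": t for l, t in enumerate(model.thetas)}
        arrays["W_top"] = model.W_top
        np.savez(stem.with_suffix(".npz"), **arrays)
        meta.update(kind="hybrid", layer_sizes=model.layer_sizes,
                    top_variant=model.top_variant, f=model.f)
    else:
        raise TypeError(f"cannot checkpoint {type(model).__name__}")
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_model(stem: str | Path):
    """Rebuild a model from its checkpoint pair; returns the params object."""
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    data = np.load(stem.with_suffix(".npz"))
    kind = meta["kind"]
    if kind == "explicit":
        return ExplicitParams(mu=data["mu"], sigma=data["sigma"])
    if kind == "recurrent":
        return RecurrentParams(W=data["W"], nu=data["nu"],
                               variant=meta.get("variant", "implicit"),
                               nonlinearity=meta.get("nonlinearity", "identity"))
    if kind == "hybrid":
        sizes = meta["layer_sizes"]
        thetas = [data[f"theta_{l}"] for l in range(len(sizes) - 1)]
        return HybridParams(layer_sizes=sizes, thetas=thetas, W_top=data["W_top"],
                            top_variant=meta.get("top_variant", "implicit"),
                            f=meta.get("f", "tanh"))
    raise ValueError(f"unknown checkpoint kind {kind!r}")
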