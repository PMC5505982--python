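"""Seed fan-out and small validation helpers shared across modules."""

from __future__ import annotations

import numpy as np

SeedLike = "int | np.random.SeedSequence | np.random.Generator | None"


def as_generator(seed) -> np.random.Generator:
    """Return a Generator from an int, SeedSequence, Generator or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    if isinstance(seed, np.random.SeedSequence):
        return np.random.default_rng(seed)
    return np.random.default_rng(seed)


def child_seed(seed, *key: int) -> np.random.SeedSequence:
    """Deterministically derive a child seed from a master seed and a fixed key.

    Stages of the pipeline draw from independent streams, so adding one
    stage never perturbs another stage's output.
    """
    if isinstance(seed, np.random.SeedSequence):
        base = list(np.atleast_1d(seed.entropy))
    else:
        base = [int(seed) if seed is not None else 0]
    return np.random.SeedSequence(base + list(key))


def check_positive(name: str, value, strict: bool = True) -> None:
    arr = np.asarray(value, dtype=float)
    bad = (arr <= 0) if strict else (arr < 0)
    if np.any(bad):
        op = ">" if strict else ">="
        raise ValueError(f"{name} must be {op} 0, got {value!r}")
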