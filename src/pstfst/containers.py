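"""Shared result containers for divergence estimates.

Both the neutral (theta) and phenotypic (P_ST) sides of the pipeline produce
symmetric pairwise matrices of point estimates with 95% confidence bounds;
``DivergenceMatrix`` is the common currency the comparison module consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class FstEstimate:
    """A single divergence estimate with its 95% interval.

    ``scope`` is ``"global"``, ``("pair", a, b)`` or ``("pop", label)`` for
    population-specific estimates.  ``theta`` may be slightly negative
    (moment-estimator property); the interval bounds are on the same scale.
    """

    scope: object
    theta: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    n_boot: int = 0
    flags: tuple = ()

    def __post_init__(self):
        if self.theta > 1 + 1e-12:
            raise ValueError(f"theta > 1: {self.theta}")


@dataclass
class DivergenceMatrix:
    """Symmetric pairwise divergence estimates with matching CI matrices."""

    labels: Sequence[str]
    values: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    kind: str = "FST"

    def __post_init__(self):
        self.labels = list(self.labels)
        k = len(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("divergence matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        for name in ("ci_low", "ci_high"):
            m = getattr(self, name)
            if m is not None:
                m = np.asarray(m, dtype=float)
                if m.shape != (k, k):
                    raise ValueError(f"{name} shape mismatch")
                setattr(self, name, m)

    @property
    def n_pools(self) -> int:
        return len(self.labels)

    def pair_index(self):
        """Upper-triangle (i, j) index pairs in row-major order."""
        k = self.n_pools
        return [(i, j) for i in range(k) for j in range(i + 1, k)]

    def condensed(self) -> np.ndarray:
        """Off-diagonal upper-triangle values as a flat vector."""
        iu = np.triu_indices(self.n_pools, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, j in self.pair_index():
            row = {
                "pair": f"{self.labels[i]} vs. {self.labels[j]}",
                "kind": self.kind,
                "estimate": self.values[i, j],
            }
            if self.ci_low is not None:
                row["ci_low"] = self.ci_low[i, j]
                row["ci_high"] = self.ci_high[i, j]
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_pairs(cls, labels, pair_values, kind="FST", pair_ci=None):
        """Build from a dict {(labelA, labelB): value} (order-insensitive)."""
        labels = list(labels)
        k = len(labels)
        idx = {lab: i for i, lab in enumerate(labels)}
        vals = np.zeros((k, k))
        lo = np.zeros((k, k))
        hi = np.zeros((k, k))
        for (a, b), v in pair_values.items():
            i, j = idx[a], idx[b]
            vals[i, j] = vals[j, i] = v
            if pair_ci is not None:
                lo[i, j] = lo[j, i] = pair_ci[(a, b)][0]
                hi[i, j] = hi[j, i] = pair_ci[(a, b)][1]
        return cls(labels, vals,
                   lo if pair_ci is not None else None,
                   hi if pair_ci is not None else None,
                   kind=kind)
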