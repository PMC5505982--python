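"""Bundled example data: pairwise divergence among six red gorgonian pools.

Reported common-garden estimates for six genetic pools of the Mediterranean
red gorgonian (three shallow Calanques populations, one deep Calanques
population, Medes and Scandola): pairwise P_ST from tissue-necrosis
trajectories and pairwise Weir-Cockerham F_ST from six microsatellite loci,
each with 95% confidence intervals, plus the matching global estimates.
Useful as a worked example for the comparison module and as a regression
anchor: the Mantel correlation between the two matrices is ~0.55 and every
pair's intervals overlap (the drift, not divergent-selection, pattern).
"""

from __future__ import annotations

import numpy as np

from .containers import DivergenceMatrix, FstEstimate

POOL_LABELS = ["C1-sh", "C2-sh", "C3-sh", "C1-d", "M", "S"]

# pair -> (pst, pst_lo, pst_hi, fst, fst_lo, fst_hi)
_PAIRS = {
    ("C1-sh", "C2-sh"): (0.000, 0.000, 0.135, 0.028, 0.010, 0.041),
    ("C1-sh", "C3-sh"): (0.065, 0.000, 0.314, 0.049, 0.026, 0.0627),
    ("C2-sh", "C3-sh"): (0.012, 0.000, 0.131, 0.041, 0.020, 0.057),
    ("C1-sh", "C1-d"): (0.000, 0.000, 0.080, 0.045, 0.026, 0.0761),
    ("C2-sh", "C1-d"): (0.000, 0.000, 0.095, 0.033, 0.011, 0.055),
    ("C3-sh", "C1-d"): (0.028, 0.000, 0.210, 0.045, 0.017, 0.074),
    ("C1-sh", "M"): (0.012, 0.000, 0.102, 0.131, 0.021, 0.277),
    ("C1-sh", "S"): (0.069, 0.000, 0.262, 0.137, 0.052, 0.230),
    ("C2-sh", "M"): (0.019, 0.000, 0.106, 0.094, 0.021, 0.193),
    ("C2-sh", "S"): (0.128, 0.027, 0.385, 0.116, 0.062, 0.161),
    ("C3-sh", "M"): (0.072, 0.000, 0.215, 0.126, 0.036, 0.254),
    ("C3-sh", "S"): (0.235, 0.000, 0.521, 0.127, 0.060, 0.207),
    ("C1-d", "M"): (0.004, 0.000, 0.090, 0.085, 0.028, 0.170),
    ("C1-d", "S"): (0.076, 0.000, 0.265, 0.095, 0.048, 0.137),
    ("M", "S"): (0.028, 0.000, 0.124, 0.053, 0.020, 0.076),
}

#: global estimates (point, ci_low, ci_high)
GLOBAL_PST = FstEstimate("global", 0.25, 0.007, 0.436)
GLOBAL_FST = FstEstimate("global", 0.075, 0.044, 0.134)


def gorgonian_divergence() -> tuple[DivergenceMatrix, DivergenceMatrix]:
    """The bundled (P_ST, F_ST) pairwise matrices with 95% CIs."""
    pst_vals = {k: v[0] for k, v in _PAIRS.items()}
    pst_ci = {k: (v[1], v[2]) for k, v in _PAIRS.items()}
    fst_vals = {k: v[3] for k, v in _PAIRS.items()}
    fst_ci = {k: (v[4], v[5]) for k, v in _PAIRS.items()}
    pst = DivergenceMatrix.from_pairs(POOL_LABELS, pst_vals, kind="PST",
                                      pair_ci=pst_ci)
    fst = DivergenceMatrix.from_pairs(POOL_LABELS, fst_vals, kind="FST",
                                      pair_ci=fst_ci)
    return pst, fst


def n_pairs() -> int:
    return len(_PAIRS)
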