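"""Synthetic genotype, necrosis and temperature generators with known truth.

The generators emulate the statistical structure the analysis assumes:

* genotypes follow the Balding-Nichols drift model -- per locus, ancestral
  allele frequencies are drawn from a symmetric Dirichlet and each pool's
  frequencies from Dirichlet((1 - F_i) / F_i * p_ancestral), then diploid
  genotypes are sampled under within-pool Hardy-Weinberg;
* microsatellite null alleles follow the standard dropout model: each allele
  copy is independently null with the per-locus rate, null homozygotes
  become missing and null heterozygotes apparent homozygotes;
* colony necrosis trajectories are cumulative non-negative day increments
  (tissue necrosis is irreversible) around a monotone baseline, plus a pool
  effect (a drift-linked slope times F_i plus between-pool noise) and a
  colony effect; Control colonies stay at zero;
* hourly temperature is a seasonal sinusoid with a site offset, a linear
  depth attenuation and Gaussian noise.

Every generator draws from its own stream derived from the master seed by a
fixed offset, so outputs are bit-reproducible and mutually independent.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import child_seed
from .popgen import MISSING, GenotypeMatrix, write_genepop

__all__ = ["TempParams", "SimConfig", "default_day_curve", "gen_genotypes",
           "inject_null_alleles", "gen_necrosis", "gen_temperature",
           "write_dataset"]


def default_day_curve(n_days: int = 30) -> tuple:
    """Monotone logistic baseline: slow onset, ~80% mean necrosis by day 30,
    the gradual course seen at a just-critical exposure temperature."""
    d = np.arange(1, n_days + 1)
    return tuple(85.0 / (1.0 + np.exp(-(d - 16.0) / 5.0)))


@dataclass(frozen=True)
class TempParams:
    annual_mean: float = 17.0       # degC at the reference (0 m) depth
    amplitude: float = 4.0          # seasonal half-range, degC
    depth_attenuation: float = 3.0  # degC lost at 40 m
    noise_sd: float = 0.4           # hourly noise, degC
    years: int = 3
    sites: tuple = ("site_A", "site_B", "site_C")
    site_offsets: tuple = (0.0, 1.0, -1.0)
    depths: tuple = (20, 40)


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters for one synthetic dataset.

    Defaults emulate the study conditions: six genetic pools of 30 diploid
    colonies genotyped at six multiallelic loci, an uneven drift
    profile (four weakly and two strongly isolated pools, global
    differentiation near 0.075), and a drift-dominated phenotype (necrosis
    shifted by ``drift_phenotype_slope`` percent per unit F_i, with small
    extra between-pool noise).
    """

    seed: int = 0
    n_pools: int = 6
    n_per_pool: int | tuple = 30
    n_loci: int = 6
    alleles_per_locus: int | tuple = 12
    fst_per_pool: tuple = (0.04, 0.05, 0.05, 0.06, 0.11, 0.16)
    null_allele_rate: float | tuple = 0.0
    necrosis_between_sd: float = 2.0
    necrosis_within_sd: float = 10.0
    necrosis_day_curve: tuple = field(default_factory=default_day_curve)
    necrosis_increment_cv: float = 0.5
    drift_phenotype_slope: float = 300.0
    temp_params: TempParams = field(default_factory=TempParams)

    def __post_init__(self):
        def as_tuple(v, n, name):
            t = (v,) * n if np.isscalar(v) else tuple(v)
            if len(t) != n:
                raise ValueError(f"{name} must have length {n}")
            return t

        object.__setattr__(self, "n_per_pool",
                           as_tuple(self.n_per_pool, self.n_pools,
                                    "n_per_pool"))
        object.__setattr__(self, "alleles_per_locus",
                           as_tuple(self.alleles_per_locus, self.n_loci,
                                    "alleles_per_locus"))
        object.__setattr__(self, "fst_per_pool",
                           as_tuple(self.fst_per_pool, self.n_pools,
                                    "fst_per_pool"))
        object.__setattr__(self, "null_allele_rate",
                           as_tuple(self.null_allele_rate, self.n_loci,
                                    "null_allele_rate"))
        object.__setattr__(self, "necrosis_day_curve",
                           tuple(self.necrosis_day_curve))
        if self.n_pools < 1 or self.n_loci < 1:
            raise ValueError("counts must be >= 1")
        if any(n < 1 for n in self.n_per_pool) or \
                any(a < 2 for a in self.alleles_per_locus):
            raise ValueError("invalid per-pool or per-locus counts")
        f = np.array(self.fst_per_pool)
        if np.any((f < 0) | (f >= 1)):
            raise ValueError("all F_i must lie in [0, 1)")
        r = np.array(self.null_allele_rate)
        if np.any((r < 0) | (r >= 1)):
            raise ValueError("null-allele rates must lie in [0, 1)")
        for name in ("necrosis_between_sd", "necrosis_within_sd",
                     "necrosis_increment_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        curve = np.array(self.necrosis_day_curve)
        if np.any(np.diff(curve) < 0):
            raise ValueError("necrosis_day_curve must be non-decreasing")
        if self.temp_params.years < 1:
            raise ValueError("temp years must be >= 1")

    @property
    def pool_labels(self) -> list:
        return [f"pool{i + 1}" for i in range(self.n_pools)]

    @property
    def n_days(self) -> int:
        return len(self.necrosis_day_curve)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def gen_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Balding-Nichols genotypes: F_i = 0 pools copy the ancestral
    frequencies exactly (no division by zero)."""
    rng = np.random.default_rng(child_seed(config.seed, 1))
    labels = config.pool_labels
    inds, pools = [], []
    for pool, n in zip(labels, config.n_per_pool):
        inds.extend(f"{pool}_{k + 1}" for k in range(n))
        pools.extend([pool] * n)
    n_tot = len(inds)
    calls = np.empty((n_tot, config.n_loci, 2), dtype=np.int32)
    for l in range(config.n_loci):
        n_all = config.alleles_per_locus[l]
        p_anc = rng.dirichlet(np.ones(n_all))
        row = 0
        for i, (pool, n) in enumerate(zip(labels, config.n_per_pool)):
            f = config.fst_per_pool[i]
            if f == 0:
                p_pool = p_anc
            else:
                theta = (1 - f) / f
                p_pool = rng.dirichlet(theta * p_anc)
            draws = rng.choice(n_all, size=(n, 2), p=p_pool) + 1
            calls[row:row + n, l, :] = draws
            row += n
    return GenotypeMatrix(inds, [f"loc{l + 1}" for l in range(config.n_loci)],
                          calls, np.array(pools, dtype=object))


def inject_null_alleles(g: GenotypeMatrix, rate_per_locus,
                        seed=0) -> GenotypeMatrix:
    """Introduce a hidden null allele per locus at the given frequency.

    Each allele copy is independently null with the locus rate; a
    null-homozygote call becomes missing, a null-heterozygote call is
    recorded as a homozygote for its visible allele.
    """
    rates = np.asarray(rate_per_locus, dtype=float)
    if rates.ndim == 0:
        rates = np.full(g.n_loci, float(rates))
    if len(rates) != g.n_loci:
        raise ValueError("one rate per locus required")
    if np.any((rates < 0) | (rates >= 1)):
        raise ValueError("rates must lie in [0, 1)")
    rng = np.random.default_rng(child_seed(seed, 2))
    calls = g.calls.copy()
    for l, rho in enumerate(rates):
        if rho == 0:
            continue
        ok = calls[:, l, 0] != MISSING
        nulls = rng.random((ok.sum(), 2)) < rho
        rows = np.flatnonzero(ok)
        both = nulls.all(axis=1)
        one = nulls.any(axis=1) & ~both
        calls[rows[both], l, :] = MISSING
        for r, mask in zip(rows[one], nulls[one]):
            visible = calls[r, l, ~mask][0]
            calls[r, l, :] = visible
    return GenotypeMatrix(list(g.individuals), list(g.loci), calls,
                          g.pools.copy(), dict(g.pool_merge))


# ---------------------------------------------------------------------------
# necrosis
# ---------------------------------------------------------------------------

def gen_necrosis(config: SimConfig, pools=None) -> pd.DataFrame:
    """Tidy colony x day necrosis panel (Treatment + zero Control sets).

    necrosis(day) = clip(baseline(day) + pool_effect + colony_effect
    + cumulative noise, 0, 100) with pool_effect = slope * F_i +
    N(0, between_sd), colony_effect ~ N(0, within_sd), and the noise built
    from non-negative gamma day increments so trajectories never decrease.
    """
    rng = np.random.default_rng(child_seed(config.seed, 3))
    labels = pools if pools is not None else config.pool_labels
    if len(labels) != config.n_pools:
        raise ValueError("pool label count mismatch")
    base = np.array(config.necrosis_day_curve)
    incr = np.diff(np.concatenate([[0.0], base]))
    cv = config.necrosis_increment_cv
    days = np.arange(1, config.n_days + 1)
    rows = []
    for i, (pool, n) in enumerate(zip(labels, config.n_per_pool)):
        locality = f"loc{i // 2 + 1}"
        depth = 20 if i % 2 == 0 else 40
        pool_eff = (config.drift_phenotype_slope * config.fst_per_pool[i]
                    + rng.normal(0, config.necrosis_between_sd))
        for k in range(n):
            colony_eff = rng.normal(0, config.necrosis_within_sd)
            if cv == 0:
                noise = base
            else:
                # gamma(1/cv^2, scale=incr*cv^2): mean incr, sd cv*incr
                shape = 1.0 / cv ** 2
                inc = np.where(
                    incr > 0,
                    rng.gamma(shape, np.maximum(incr, 1e-12) * cv ** 2,
                              size=config.n_days),
                    0.0)
                noise = np.cumsum(inc)
            level = np.clip(noise + pool_eff + colony_eff, 0.0, 100.0)
            cid = f"{pool}_T{k + 1}"
            tank = f"T{k % 3 + 1}"
            for d, v in zip(days, level):
                rows.append((cid, pool, locality, depth, "Treatment", tank,
                             int(d), float(v)))
        for k in range(n):
            cid = f"{pool}_C{k + 1}"
            tank = f"C{k % 3 + 1}"
            for d in days:
                rows.append((cid, pool, locality, depth, "Control", tank,
                             int(d), 0.0))
    return pd.DataFrame(rows, columns=["colony", "population", "locality",
                                       "depth", "set", "tank", "day",
                                       "necrosis"])


# ---------------------------------------------------------------------------
# temperature
# ---------------------------------------------------------------------------

def gen_temperature(config: SimConfig) -> pd.DataFrame:
    """Hourly multi-site, multi-depth series with a seasonal sinusoid.

    temp = annual_mean + site_offset + amplitude * sin(seasonal phase)
    - depth_attenuation * depth / 40 + N(0, noise_sd); the phase peaks in
    mid-August (day 228), the NW-Mediterranean pattern.
    """
    tp = config.temp_params
    rng = np.random.default_rng(child_seed(config.seed, 4))
    ts = pd.date_range("2004-01-01", periods=tp.years * 8760, freq="h")
    frac = ts.dayofyear + ts.hour / 24.0
    seasonal = tp.amplitude * np.sin(2 * np.pi * (frac - 137.0) / 365.25)
    frames = []
    for site, off in zip(tp.sites, tp.site_offsets):
        for depth in tp.depths:
            temp = (tp.annual_mean + off + seasonal
                    - tp.depth_attenuation * depth / 40.0
                    + rng.normal(0, tp.noise_sd, len(ts)))
            frames.append(pd.DataFrame({
                "site": site, "depth": depth, "timestamp": ts,
                "temp_c": temp}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# dataset on disk
# ---------------------------------------------------------------------------

def write_dataset(config: SimConfig, outdir) -> dict:
    """Write genotypes (Genepop), necrosis and temperature CSVs plus a
    ground-truth manifest; returns the file paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    g = gen_genotypes(config)
    if any(r > 0 for r in config.null_allele_rate):
        g = inject_null_alleles(g, config.null_allele_rate, seed=config.seed)
    paths = {"genotypes": out / "genotypes.gen",
             "necrosis": out / "necrosis.csv",
             "temperature": out / "temperature.csv",
             "manifest": out / "manifest.json"}
    write_genepop(g, paths["genotypes"])
    gen_necrosis(config).to_csv(paths["necrosis"], index=False)
    gen_temperature(config).to_csv(paths["temperature"], index=False)
    manifest = dataclasses.asdict(config)
    manifest["pool_labels"] = config.pool_labels
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)
    return {k: str(v) for k, v in paths.items()}
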