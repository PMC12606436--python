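"""Phenotypic summaries of a population state and replicate aggregation.

All moments are genic sums over the segregating allele table:

    V_A,f = Σ 2 af² x(1-x)          B = Σ 2 af am x(1-x)
    V_A,O = Σ 2 a²  x(1-x)          μ3,αβγ = Σ 2 aα aβ aγ x(1-x)(1-2x)

together with the distances of the sex-specific means from their optima and
the fixed-background distances ``F_a = O_a − F̃_a``, ``F_d = O_d − F̃_d`` that
track long-term equilibration.  The intersex correlation is
``r_fm = B / sqrt(V_A,f V_A,m)``; it is undefined (NaN) when either sex
carries no segregating variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .params import ModelParams, to_avg_diff
from .population import PopulationState

__all__ = [
    "MomentSet",
    "compute_moments",
    "within_between_variance",
    "aggregate_replicates",
    "equilibrium_fluctuation_stats",
]


@dataclass
class MomentSet:
    """All phenotypic summaries at one generation (trait in delta units)."""

    generation: int
    zbar_f: float
    zbar_m: float
    VA_f: float
    VA_m: float
    VA_O: float
    B: float
    rfm: float            # NaN when undefined
    SD: float             # |z̄f - z̄m|
    SDpm: float           # signed z̄f - z̄m
    mu3_fff: float
    mu3_ffm: float
    mu3_fmm: float
    mu3_mmm: float
    mu3_f: float
    mu3_m: float
    mu3_a: float
    mu3_d: float
    D_f: float
    D_m: float
    D_a: float
    D_d: float
    VA_a: float
    VA_d: float
    VA_w: float
    VA_b: float
    VA_t: float
    F_f: float
    F_m: float
    F_a: float            # distance O_a - F̃_a
    F_d: float            # distance O_d - F̃_d
    n_segregating: int

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def compute_moments(state: PopulationState,
                    params: ModelParams) -> MomentSet:
    """Evaluate every moment by direct summation over segregating alleles."""
    af, am, x = state.af, state.am, state.x
    q = 2.0 * x * (1.0 - x)
    VA_f = float(af * af @ q)
    VA_m = float(am * am @ q)
    B = float(af * am @ q)
    VA_O = params.gamma_f**2 * VA_f + params.gamma_m**2 * VA_m

    t3 = q * (1.0 - 2.0 * x)
    mu3_fff = float(af * af * af @ t3)
    mu3_ffm = float(af * af * am @ t3)
    mu3_fmm = float(af * am * am @ t3)
    mu3_mmm = float(am * am * am @ t3)
    mu3_f = 0.5 * (mu3_fff + mu3_fmm)
    mu3_m = 0.5 * (mu3_mmm + mu3_ffm)
    mu3_a = 0.25 * (mu3_fff + mu3_fmm + mu3_ffm + mu3_mmm)
    mu3_d = 0.25 * (mu3_fff + mu3_fmm - mu3_ffm - mu3_mmm)

    zf, zm = state.mean_phenotypes()
    SDpm = zf - zm
    D_f = params.O_f - zf
    D_m = params.O_m - zm
    D_a, D_d = to_avg_diff((D_f, D_m))
    VA_a, VA_d = to_avg_diff((VA_f, VA_m))

    if VA_f > 0 and VA_m > 0:
        rfm = B / math.sqrt(VA_f * VA_m)
    else:
        rfm = math.nan

    VA_w = VA_a
    VA_b = (SDpm / 2.0) ** 2

    return MomentSet(
        generation=state.generation, zbar_f=zf, zbar_m=zm,
        VA_f=VA_f, VA_m=VA_m, VA_O=VA_O, B=B, rfm=rfm,
        SD=abs(SDpm), SDpm=SDpm,
        mu3_fff=mu3_fff, mu3_ffm=mu3_ffm, mu3_fmm=mu3_fmm, mu3_mmm=mu3_mmm,
        mu3_f=mu3_f, mu3_m=mu3_m, mu3_a=mu3_a, mu3_d=mu3_d,
        D_f=D_f, D_m=D_m, D_a=D_a, D_d=D_d,
        VA_a=VA_a, VA_d=VA_d, VA_w=VA_w, VA_b=VA_b, VA_t=VA_w + VA_b,
        F_f=state.F_f, F_m=state.F_m,
        F_a=params.O_a - state.F_a, F_d=params.O_d - state.F_d,
        n_segregating=state.n_segregating,
    )


def within_between_variance(state: PopulationState):
    """Two-group variance decomposition across the sexes.

    The within-sex variance is the average of the sex-specific genic
    variances (``V_A,w = V_A,a``); the between-sex variance is the variance
    of the two equal-sized sex means about the grand mean, ``(SD±/2)²``; the
    total is their sum.
    """
    af, am, x = state.af, state.am, state.x
    q = 2.0 * x * (1.0 - x)
    VA_w = 0.5 * (float(af * af @ q) + float(am * am @ q))
    zf, zm = state.mean_phenotypes()
    VA_b = ((zf - zm) / 2.0) ** 2
    return VA_w, VA_b, VA_w + VA_b


def aggregate_replicates(trajectories: list[pd.DataFrame],
                         ci_factor: float = 1.96):
    """Across-replicate mean and 95% CI half-width per time point.

    All trajectories must share the same generation grid.  The CI half-width
    is ``1.96 * SEM`` with the sample (ddof=1) standard deviation.  The ``SD``
    column is the per-replicate absolute dimorphism, so its aggregate is the
    mean of absolute values (E[SD]), distinct from the aggregate of the
    signed ``SDpm``.

    Returns
    -------
    (mean, ci) : two DataFrames indexed like the inputs, with a
        ``generation`` column and one column per aggregated field.
    """
    if len(trajectories) < 2:
        raise ValueError("need at least two replicates to aggregate")
    gen0 = trajectories[0]["generation"].to_numpy()
    for tr in trajectories[1:]:
        if not np.array_equal(tr["generation"].to_numpy(), gen0):
            raise ValueError("replicate time grids are not aligned")
    stack = np.stack([tr.to_numpy(dtype=float) for tr in trajectories])
    cols = list(trajectories[0].columns)
    mean = pd.DataFrame(np.nanmean(stack, axis=0), columns=cols)
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(stack, axis=0, ddof=1)
    n_eff = np.sum(~np.isnan(stack), axis=0)
    ci = pd.DataFrame(ci_factor * sd / np.sqrt(np.maximum(n_eff, 1)),
                      columns=cols)
    mean["generation"] = gen0
    ci["generation"] = gen0
    return mean, ci


def equilibrium_fluctuation_stats(samples: pd.DataFrame,
                                  params: ModelParams,
                                  min_samples: int = 10) -> dict:
    """Stationary fluctuation moments of the mean-phenotype processes.

    ``samples`` holds post-burn-in (optionally thinned) rows with at least
    ``zbar_f`` and ``zbar_m`` columns, pooled over time and/or replicates.
    Second moments are taken about the known optima (the stationary means),
    so that e.g. ``V[z̄] = E[(z̄ - O_a)²]``; this avoids the bias a sample
    mean would introduce with strongly autocorrelated series.

    Returns a dict with V_zbar, V_zf, V_zm, Cov_zfzm, V_SDpm, E_SD and the
    consistency residual ``V_SDpm - (V_zf + V_zm - 2 Cov)`` (identically zero
    by construction, reported for completeness of the decomposition).
    """
    if len(samples) < min_samples:
        raise ValueError(f"need at least {min_samples} stationary samples")
    zf = samples["zbar_f"].to_numpy(float) - params.O_f
    zm = samples["zbar_m"].to_numpy(float) - params.O_m
    za = 0.5 * (zf + zm)
    sd = zf - zm
    V_zf = float(np.mean(zf * zf))
    V_zm = float(np.mean(zm * zm))
    Cov = float(np.mean(zf * zm))
    return dict(
        V_zbar=float(np.mean(za * za)),
        V_zf=V_zf,
        V_zm=V_zm,
        Cov_zfzm=Cov,
        V_SDpm=float(np.mean(sd * sd)),
        E_SD=float(np.mean(np.abs(sd + (params.O_f - params.O_m)))),
        consistency=float(np.mean(sd * sd)) - (V_zf + V_zm - 2 * Cov),
        n=len(samples),
    )
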