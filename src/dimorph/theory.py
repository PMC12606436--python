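"""Closed-form and semi-analytic predictions.

Equilibrium (coinciding optima, r_fm < 1): drift makes the sex-specific
means fluctuate around their optima, with stationary moments

    V[z̄] = δ²,   V[z̄f] = V[z̄m] = 2δ²,   Cov[z̄f, z̄m] = 0,
    V[SD±] = 4δ²,   E[SD] = 2·sqrt(2/π)·δ ≈ 1.6·δ,

the last step using the Gaussianity of the signed dimorphism.

Out of equilibrium, the expected per-generation change of the distances of
the sex means from their optima follows the two-sex breeder's equation with
a stabilizing-selection skew correction,

    E[Δ(Df, Dm)] = −(1/2VS) γ² G (Df, Dm)ᵀ + (1/2VS) γ² (μ3,f, μ3,m)ᵀ,

where γ² = diag(2γf², 2γm²) and G = [[V_A,f, B], [B, V_A,m]].  In the
average/half-difference coordinates and with equal selection on the sexes
this decouples (when V_A,d = 0, μ3 = 0) into two exponentials with rates
(V_A,a ± B)/(2VS) — the Lande trajectories — and the signed dimorphism
approaches its new optimum difference as
SD±(t) = 2Λd (1 − exp(−t·V_A,a(1−r_fm)/(2VS))).

Fixed backgrounds equilibrate much more slowly, over ~2N generations:
F_a(t) ≈ Λa e^{−t/2N} and (for low r_fm) F_d(t) ≈ Λd e^{−t/2N}; the latter
approximation degrades as r_fm → 1, where discordant equilibration is
further delayed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ModelParams, from_avg_diff, to_avg_diff
from .simulate import ShiftSpec

__all__ = [
    "TrajectoryPrediction",
    "drift_sd_prediction",
    "scaled_sd",
    "breeder_step",
    "lande_trajectories",
    "adaptation_timescales",
    "integrate_breeder",
    "equilibration_decay",
    "time_to_fraction_closed_form",
]


@dataclass
class TrajectoryPrediction:
    """Analytic time courses after a shift in optima (delta units)."""

    t: np.ndarray
    D_a: np.ndarray
    D_d: np.ndarray
    SDpm: np.ndarray        # change relative to the pre-shift dimorphism
    F_a: np.ndarray
    F_d: np.ndarray
    t_a: float              # rapid-phase length, concordant
    t_d: float              # rapid-phase length, discordant

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(generation=self.t, D_a=self.D_a,
                                 D_d=self.D_d, SDpm=self.SDpm,
                                 F_a=self.F_a, F_d=self.F_d))


def drift_sd_prediction(params: ModelParams) -> dict:
    """Equilibrium dimorphism generated by drift alone (Of = Om, r_fm < 1)."""
    d2 = params.delta**2
    return dict(
        V_zbar=d2,
        V_zfm=2.0 * d2,
        V_SD=4.0 * d2,
        E_SD=2.0 * math.sqrt(2.0 / math.pi) * params.delta,
    )


def scaled_sd(E_SD: float, VA: float) -> float:
    """Dimorphism scaled by the phenotypic standard deviation, E[SD]/√V_A.

    This unitless ratio measures whether drift-generated sex differences are
    significant relative to the spread of the trait itself.
    """
    if VA <= 0:
        raise ValueError("variance must be positive")
    return E_SD / math.sqrt(VA)


def _gamma2_matrix(params: ModelParams) -> np.ndarray:
    return np.diag([2 * params.gamma_f**2, 2 * params.gamma_m**2])


_T_AD = np.array([[0.5, 0.5], [0.5, -0.5]])      # (f,m) -> (a,d)
_T_FM = np.array([[1.0, 1.0], [1.0, -1.0]])      # (a,d) -> (f,m)


def breeder_step(D, moments, params: ModelParams):
    """Expected one-generation change (ΔD_a, ΔD_d).

    ``D = (D_a, D_d)`` are the distances in average/half-difference
    coordinates; ``moments = (V_A,a, V_A,d, B, μ3,a, μ3,d)`` the current
    second and third central moments.  Evaluates the general-γ master
    equation in sex coordinates and transforms back; with
    γf = γm = 1/√2 this is exactly

        ΔD = −(1/2VS) [[V_A,a+B, V_A,d], [V_A,d, V_A,a−B]] D
             + (1/2VS) (μ3,a, μ3,d).

    With μ3 = 0 and constant G it reduces to the Lande recursion.
    """
    D_a, D_d = D
    VA_a, VA_d, B, mu3_a, mu3_d = moments
    VA_f, VA_m = from_avg_diff((VA_a, VA_d))
    mu3_f, mu3_m = from_avg_diff((mu3_a, mu3_d))
    D_fm = _T_FM @ np.array([D_a, D_d])
    G = np.array([[VA_f, B], [B, VA_m]])
    g2 = _gamma2_matrix(params)
    dD_fm = (-g2 @ G @ D_fm + g2 @ np.array([mu3_f, mu3_m])) / (2 * params.VS)
    dD = _T_AD @ dD_fm
    return float(dD[0]), float(dD[1])


def lande_trajectories(params: ModelParams, G0, shift: ShiftSpec,
                       horizon: int, step: int = 1) -> TrajectoryPrediction:
    """Infinitesimal-limit trajectories after a shift in optima.

    ``G0 = (V_A,f, V_A,m, B)`` are the pre-shift (co)variances, assumed
    constant.  When the sex variances are equal (V_A,d = 0) the closed-form
    exponentials apply; otherwise the coupled linear recursion is integrated
    numerically one generation at a time.
    """
    VA_f, VA_m, B = G0
    VA_a, VA_d = to_avg_diff((VA_f, VA_m))
    La, Ld = shift.Lambda_a, shift.Lambda_d
    t = np.arange(0, horizon + 1, step, dtype=float)
    VS = params.VS

    if abs(VA_d) <= 1e-12 * max(VA_a, 1.0):
        D_a = La * np.exp(-t * (VA_a + B) / (2 * VS))
        D_d = Ld * np.exp(-t * (VA_a - B) / (2 * VS))
    else:
        D_a = np.empty_like(t)
        D_d = np.empty_like(t)
        da, dd = La, Ld
        moments = (VA_a, VA_d, B, 0.0, 0.0)
        idx = 0
        for gen in range(int(t[-1]) + 1):
            if idx < t.size and gen == int(t[idx]):
                D_a[idx], D_d[idx] = da, dd
                idx += 1
            dda, ddd = breeder_step((da, dd), moments, params)
            da, dd = da + dda, dd + ddd

    rfm = B / math.sqrt(VA_f * VA_m) if VA_f > 0 and VA_m > 0 else math.nan
    SDpm = 2 * Ld * (1.0 - np.exp(-t * VA_a * (1.0 - rfm) / (2 * VS))) \
        if np.isfinite(rfm) else np.full_like(t, np.nan)
    F_a, F_d = equilibration_decay(shift, params, t)
    t_a, t_d, _ = adaptation_timescales(params, (VA_f, VA_m, B), shift,
                                        strict=False)
    return TrajectoryPrediction(t=t, D_a=D_a, D_d=D_d, SDpm=SDpm,
                                F_a=F_a, F_d=F_d, t_a=t_a, t_d=t_d)


def adaptation_timescales(params: ModelParams, G0, shift: ShiftSpec,
                          strict: bool = False):
    """Rapid-phase lengths (t_a, t_d) and their ratio at equal shift sizes.

    t_a = 2VS/(V_A,a + B) · ln(Λa/δ) and t_d = 2VS/(V_A,a − B) · ln(Λd/δ):
    the times for D_a and D_d to decay to the typical equilibrium
    fluctuation δ.  The ratio (1 + r_fm)/(1 − r_fm) is computed at equal
    shift sizes and is infinite at r_fm = 1 (no discordant response).
    Shifts at or below δ are already inside the equilibrium fluctuation
    band, so their rapid-phase length is 0.
    """
    VA_f, VA_m, B = G0
    VA_a, _ = to_avg_diff((VA_f, VA_m))
    La, Ld = abs(shift.Lambda_a), abs(shift.Lambda_d)
    VS, d = params.VS, params.delta

    def phase(Lam, rate):
        if Lam <= d:
            return 0.0
        if rate <= 0:
            return math.inf
        return 2 * VS / rate * math.log(Lam / d)

    t_a = phase(La, VA_a + B)
    t_d = phase(Ld, VA_a - B)
    ratio = (VA_a + B) / (VA_a - B) if VA_a > B else math.inf
    return t_a, t_d, ratio


def integrate_breeder(moment_series: pd.DataFrame, D0,
                      params: ModelParams) -> pd.DataFrame:
    """Integrate the moment-driven breeder's equation along a simulated
    moment series.

    ``moment_series`` must have columns ``generation, VA_a, VA_d, B, mu3_a,
    mu3_d`` (e.g. an across-replicate mean trajectory restricted to the
    post-shift window); moments are linearly interpolated onto every
    generation.  ``D0 = (D_a, D_d)`` is the distance at the first row's
    generation.  Returns per-generation predicted ``D_a``, ``D_d``.
    """
    gens = moment_series["generation"].to_numpy(float)
    grid = np.arange(gens[0], gens[-1] + 1)
    interp = {c: np.interp(grid, gens, moment_series[c].to_numpy(float))
              for c in ("VA_a", "VA_d", "B", "mu3_a", "mu3_d")}
    da, dd = float(D0[0]), float(D0[1])
    out_a = np.empty_like(grid)
    out_d = np.empty_like(grid)
    for i in range(grid.size):
        out_a[i], out_d[i] = da, dd
        m = (interp["VA_a"][i], interp["VA_d"][i], interp["B"][i],
             interp["mu3_a"][i], interp["mu3_d"][i])
        dda, ddd = breeder_step((da, dd), m, params)
        da, dd = da + dda, dd + ddd
    return pd.DataFrame(dict(generation=grid, D_a=out_a, D_d=out_d))


def breeder_prediction_from_replicates(trajectories, shift: ShiftSpec,
                                       params: ModelParams,
                                       start_generation: int) -> pd.DataFrame:
    """Moment-driven mean-trajectory prediction from replicate runs.

    For each replicate, integrates the breeder's equation along that
    replicate's own recorded moment series from ``start_generation`` (the
    generation at which the shift is applied; the recorded row there is
    pre-shift, so the initial distances are offset by the shift), then
    averages the predicted trajectories.  Integrating per replicate keeps
    the within-replicate correlation between the moments and the distances,
    which integrating the across-replicate mean series would discard.
    """
    preds = []
    grid = None
    for tr in trajectories:
        post = tr[tr["generation"] >= start_generation]
        D0 = (post["D_a"].iloc[0] + shift.Lambda_a,
              post["D_d"].iloc[0] + shift.Lambda_d)
        md = integrate_breeder(
            post[["generation", "VA_a", "VA_d", "B", "mu3_a", "mu3_d"]],
            D0, params)
        preds.append(md[["D_a", "D_d"]].to_numpy())
        grid = md["generation"].to_numpy()
    avg = np.mean(preds, axis=0)
    return pd.DataFrame(dict(generation=grid, D_a=avg[:, 0], D_d=avg[:, 1]))


def equilibration_decay(shift: ShiftSpec, params: ModelParams, t):
    """Fixed-background distances F_a(t) ≈ Λa e^{−t/2N}, F_d(t) ≈ Λd e^{−t/2N}.

    Valid for an approximately infinitesimal architecture; the F_d form
    degrades for high intersex correlation, where discordant equilibration
    is delayed.
    """
    t = np.asarray(t, float)
    decay = np.exp(-t / (2 * params.N))
    return shift.Lambda_a * decay, shift.Lambda_d * decay


def time_to_fraction_closed_form(fraction: float, params: ModelParams,
                                 VA_a: float, rfm: float) -> float:
    """Infinitesimal-limit time for SD± to reach a fraction of its final
    change, from inverting the exponential approach:
    t = −2VS·ln(1−p) / (V_A,a (1−r_fm))."""
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must lie in [0, 1)")
    rate = VA_a * (1.0 - rfm) / (2 * params.VS)
    if rate <= 0:
        return math.inf if fraction > 0 else 0.0
    return -math.log(1.0 - fraction) / rate
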