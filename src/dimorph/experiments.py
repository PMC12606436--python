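"""Config-driven scenario runner for the standard study designs.

Five named scenarios cover the questions the model addresses:

* ``equilibrium_sd`` — equilibrium with coinciding optima; measures the
  drift-generated dimorphism E[SD], its variance, and the stationary
  fluctuations of the sex-specific means.
* ``concordant_shift`` — both optima shift equally; intersex correlation is
  expected to stay flat while the mean adapts.
* ``discordant_shift`` — optima shift apart (divergent); the rapid phase of
  dimorphism evolution and, for a multigenic architecture, the transient
  dip in intersex correlation.
* ``divergent_then_convergent`` — a divergent shift followed by a convergent
  one, probing the sign of the dimorphism/correlation association.
* ``transient_rfm`` — time-averaged V_A,a, B and r_fm over the 5N
  generations after a shift, across shift types and sizes.

Default replicate counts are scaled down from a full production run
(25 replicates with time-averaging where it applies) so a scenario finishes
on a desk machine; CI widths are always reported so the extra Monte Carlo
error is visible, and every count is overridable.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .moments import aggregate_replicates, equilibrium_fluctuation_stats
from .mutation import MutationModel, calibrate_U
from .params import ModelParams
from .simulate import RunConfig, ShiftSpec, run_replicates
from .theory import (breeder_prediction_from_replicates, drift_sd_prediction,
                     lande_trajectories)

__all__ = ["Scenario", "SCENARIOS", "build_config", "run_scenario",
           "relative_shift_in_sd_units", "time_to_fraction_sd",
           "time_averaged_moments"]

logger = logging.getLogger("dimorph")

ARCHITECTURES = {"infinitesimal": 1.0, "multigenic": 16.0}
SHIFT_COEFFS = {"small": 0.15, "medium": 0.25, "large": 0.5}


@dataclass
class Scenario:
    """A named study design with its default parameters."""

    name: str
    architecture: str = "infinitesimal"     # key into ARCHITECTURES
    r: float = 0.5
    target_VA: float = 40.0
    shift_coeff: float = 0.25               # in units of sqrt(VS)
    shift_kind: str = "discordant"          # concordant | discordant
    N: int = 1000
    replicates: int = 25
    burn_in_N: int | None = None            # multiples of N; None = convention
    post_shift_N: float = 5.0
    record_every: int = 10
    max_total_generations: float = 2e8      # resource guard

    def burn_in(self) -> int:
        if self.burn_in_N is not None:
            return int(self.burn_in_N * self.N)
        # convention: longer burn-ins for lower-variance traits, which
        # equilibrate more slowly relative to drift
        if self.target_VA >= 40:
            return 10 * self.N
        if self.target_VA >= 9:
            return 100 * self.N
        return 500 * self.N

    def mean_sq(self) -> float:
        return ARCHITECTURES[self.architecture]


SCENARIOS = {
    "equilibrium_sd": Scenario("equilibrium_sd", target_VA=9.0,
                               shift_coeff=0.0, replicates=8,
                               record_every=100, post_shift_N=0.0),
    "concordant_shift": Scenario("concordant_shift", shift_kind="concordant"),
    "discordant_shift": Scenario("discordant_shift", shift_kind="discordant"),
    "divergent_then_convergent": Scenario("divergent_then_convergent",
                                          architecture="multigenic", r=0.95),
    "transient_rfm": Scenario("transient_rfm", architecture="multigenic",
                              r=0.95),
}


def relative_shift_in_sd_units(shift_coeff: float, params: ModelParams,
                               target_VA: float) -> float:
    """Convert a shift of ``shift_coeff * sqrt(VS)`` into multiples of the
    phenotypic standard deviation sqrt(V_A)."""
    if target_VA <= 0:
        raise ValueError("target variance must be positive")
    return shift_coeff * math.sqrt(params.VS) / math.sqrt(target_VA)


def build_config(scenario: Scenario, seed: int = 0) -> RunConfig:
    """Materialize a scenario into a runnable configuration (calibrating U
    for the scenario's target variance and converting shift sizes)."""
    model = MutationModel(mean_sq_magnitude=scenario.mean_sq(),
                          shared_fraction=scenario.r)
    params = ModelParams(N=scenario.N, U=0.0)
    params = params.replace(U=calibrate_U(model, params, scenario.target_VA))

    shifts = []
    if scenario.shift_coeff > 0:
        lam = scenario.shift_coeff * math.sqrt(params.VS)
        post = int(scenario.post_shift_N * scenario.N)
        if scenario.shift_kind == "concordant":
            shifts = [ShiftSpec.from_avg_diff(lam, 0.0, duration=post,
                                              label="concordant")]
        elif scenario.name == "divergent_then_convergent":
            shifts = [ShiftSpec.from_avg_diff(0.0, lam, duration=post,
                                              label="divergent"),
                      ShiftSpec.from_avg_diff(0.0, -lam, duration=post,
                                              label="convergent")]
        else:
            shifts = [ShiftSpec.from_avg_diff(0.0, lam, duration=post,
                                              label="divergent")]

    cfg = RunConfig(params=params, mutation=model,
                    burn_in=scenario.burn_in(),
                    shifts=shifts, replicates=scenario.replicates,
                    seed=seed, record_every=scenario.record_every,
                    record_burn_in=scenario.shift_coeff == 0)

    total = scenario.replicates * (cfg.burn_in
                                   + sum(s.duration or 0 for s in shifts))
    if total > scenario.max_total_generations:
        raise RuntimeError(
            f"projected {total:.2g} allele-generations exceeds the scenario "
            f"budget {scenario.max_total_generations:.2g}; reduce replicates "
            "or burn-in, or raise max_total_generations")
    return cfg


def time_averaged_moments(traj: pd.DataFrame, start: int, stop: int) -> dict:
    """Uniform time averages of V_A,a, B and r_fm over [start, stop)."""
    win = traj[(traj["generation"] >= start) & (traj["generation"] < stop)]
    return dict(VA_a=float(win["VA_a"].mean()), B=float(win["B"].mean()),
                rfm=float(win["rfm"].mean()), n=len(win))


def time_to_fraction_sd(mean_traj: pd.DataFrame, fraction: float,
                        Lambda_d: float, shift_generation: int) -> float:
    """First generation (linear interpolation) at which the mean signed
    dimorphism covers ``fraction`` of its total change 2·Λd.

    Time is measured from ``shift_generation``; returns NaN (censored) if
    the trajectory never spans the target within its horizon.
    """
    if fraction <= 0:
        return 0.0
    post = mean_traj[mean_traj["generation"] >= shift_generation]
    t = post["generation"].to_numpy(float) - shift_generation
    sd = post["SDpm"].to_numpy(float)
    sd = sd - sd[0]
    target = fraction * 2.0 * Lambda_d
    if Lambda_d < 0:
        sd, target = -sd, -target
    above = np.nonzero(sd >= target)[0]
    if above.size == 0:
        return math.nan
    i = above[0]
    if i == 0:
        return float(t[0])
    frac = (target - sd[i - 1]) / (sd[i] - sd[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def run_scenario(name: str, out_dir, seed: int = 0, **overrides):
    """Run a named scenario end to end and write its artifacts.

    Writes per-replicate trajectories, the across-replicate aggregate with
    CIs, the matching analytic prediction on the same grid, and a manifest
    sufficient to re-run the scenario bit-identically.  Returns a dict of
    headline results.
    """
    t0 = time.time()
    scenario = replace(SCENARIOS[name], **overrides)
    cfg = build_config(scenario, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("scenario %s: %d replicates, burn-in %d", name,
                cfg.replicates, cfg.burn_in)

    trajectories = run_replicates(cfg)
    for i, tr in enumerate(trajectories):
        tr.to_csv(out / f"replicate_{i:03d}.tsv", sep="\t", index=False)
    mean, ci = aggregate_replicates(trajectories)
    mean.to_csv(out / "aggregate_mean.tsv", sep="\t", index=False)
    ci.to_csv(out / "aggregate_ci.tsv", sep="\t", index=False)

    results: dict = {"scenario": name}
    if scenario.shift_coeff == 0:
        pooled = pd.concat(
            [tr[tr["generation"] >= cfg.burn_in // 2] for tr in trajectories])
        stats = equilibrium_fluctuation_stats(pooled, cfg.params)
        results["fluctuations"] = stats
        results["prediction"] = drift_sd_prediction(cfg.params)
    else:
        shift = cfg.shifts[0]
        G0 = (scenario.target_VA, scenario.target_VA,
              scenario.r * scenario.target_VA)
        horizon = shift.duration or 0
        pred = lande_trajectories(cfg.params, G0, shift, horizon,
                                  step=cfg.record_every)
        pf = pred.to_frame()
        pf["generation"] += cfg.burn_in
        pf.to_csv(out / "prediction_infinitesimal.tsv", sep="\t", index=False)
        md = breeder_prediction_from_replicates(
            [tr[tr["generation"] <= cfg.burn_in + horizon]
             for tr in trajectories], shift, cfg.params, cfg.burn_in)
        md.to_csv(out / "prediction_moment_driven.tsv", sep="\t",
                  index=False)
        results["time_averaged_post_shift"] = time_averaged_moments(
            mean, cfg.burn_in, cfg.burn_in + 5 * scenario.N)
        results["timescales"] = dict(t_a=pred.t_a, t_d=pred.t_d)

    manifest = dict(scenario=name, seed=seed, config=cfg.to_dict(),
                    overrides={k: v for k, v in overrides.items()},
                    wall_clock_s=round(time.time() - t0, 2))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "results.json").write_text(json.dumps(results, indent=2,
                                                 default=float))
    return results
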