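"""Forward Wright–Fisher Hardy–Weinberg simulation of the allele table.

Each generation, every segregating allele's frequency is perturbed by its
expected selection response

    E[Δx] = [(af·Df·γf² + am·Dm·γm²) − (af²γf² + am²γm²)(½ − x)] · x(1−x) / VS

(directional term toward the sex-specific optima plus stabilizing term
pushing minor-allele frequencies down; the ½ from averaging selection over
the two sexes is folded into the γ² factors) and then resampled binomially
with 2N trials, which supplies the drift variance x(1−x)/(2N).  Fixed and
lost alleles are moved into the fixed backgrounds, and a Poisson(2NU) number
of new mutations enters at frequency 1/(2N).

Optimum shifts are applied by adding (Λf, Λm) to the current optima; the
population is otherwise left untouched, so the pre-shift state is the
mutation–selection–drift equilibrium reached during burn-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .moments import compute_moments
from .mutation import MutationModel, draw_mutations
from .params import ModelParams, from_avg_diff, to_avg_diff
from .population import PopulationState

__all__ = ["ShiftSpec", "RunConfig", "expected_delta_x", "step_generation",
           "run_replicate", "run_replicates", "replicate_rng"]


@dataclass(frozen=True)
class ShiftSpec:
    """A shift in the sex-specific optima, in delta units.

    ``Lambda_f`` and ``Lambda_m`` are added to the current optima when the
    shift is applied; ``duration`` generations are then simulated (if None,
    the run configuration's ``post_shift`` applies).  Purely concordant
    shifts have Λd = 0, purely discordant shifts Λa = 0; discordant shifts
    are *divergent* when they move the optima apart and *convergent* when
    they move them together.
    """

    Lambda_f: float
    Lambda_m: float
    duration: int | None = None
    label: str = ""

    @classmethod
    def from_avg_diff(cls, Lambda_a: float, Lambda_d: float,
                      duration: int | None = None, label: str = ""):
        lf, lm = from_avg_diff((Lambda_a, Lambda_d))
        return cls(lf, lm, duration, label)

    @property
    def Lambda_a(self) -> float:
        return to_avg_diff((self.Lambda_f, self.Lambda_m))[0]

    @property
    def Lambda_d(self) -> float:
        return to_avg_diff((self.Lambda_f, self.Lambda_m))[1]


@dataclass
class RunConfig:
    """Everything needed to reproduce a set of replicate runs."""

    params: ModelParams
    mutation: MutationModel
    burn_in: int
    post_shift: int = 0
    shifts: list[ShiftSpec] = field(default_factory=list)
    replicates: int = 1
    seed: int = 0
    record_every: int = 10
    record_burn_in: bool = False

    def to_dict(self) -> dict:
        return dict(
            params=self.params.to_dict(), mutation=self.mutation.to_dict(),
            burn_in=self.burn_in, post_shift=self.post_shift,
            shifts=[dict(Lambda_f=s.Lambda_f, Lambda_m=s.Lambda_m,
                         duration=s.duration, label=s.label)
                    for s in self.shifts],
            replicates=self.replicates, seed=self.seed,
            record_every=self.record_every,
            record_burn_in=self.record_burn_in)


def expected_delta_x(af, am, x, D_f: float, D_m: float,
                     params: ModelParams):
    """Expected one-generation change in derived-allele frequency.

    Vectorized over alleles.  Frequencies must lie strictly in (0, 1).
    """
    af = np.asarray(af, float)
    am = np.asarray(am, float)
    x = np.asarray(x, float)
    if np.any((x <= 0) | (x >= 1)):
        raise ValueError("frequencies must lie strictly in (0, 1)")
    gf2, gm2 = params.gamma_f**2, params.gamma_m**2
    directional = af * D_f * gf2 + am * D_m * gm2
    stabilizing = (af * af * gf2 + am * am * gm2) * (0.5 - x)
    return (directional - stabilizing) * x * (1.0 - x) / params.VS


def step_generation(state: PopulationState, params: ModelParams,
                    mutation: MutationModel,
                    rng: np.random.Generator) -> PopulationState:
    """Advance one generation in place: selection + drift, boundary
    bookkeeping, then mutation.  Returns the (mutated) state."""
    two_N = 2 * params.N
    if state.n_segregating:
        zf, zm = state.mean_phenotypes()
        dx = expected_delta_x(state.af, state.am, state.x,
                              params.O_f - zf, params.O_m - zm, params)
        p = np.clip(state.x + dx, 0.0, 1.0)
        state.x = rng.binomial(two_N, p).astype(float) / two_N
        state.absorb_boundaries()
    n_new = rng.poisson(two_N * params.U)
    if n_new:
        state.add_alleles(*draw_mutations(mutation, params, n_new, rng))
    state.generation += 1
    return state


def replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Independent child stream for one replicate of a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(replicate,)))


def run_replicate(config: RunConfig, replicate: int = 0,
                  return_state: bool = False):
    """Run one replicate: burn-in, then each optimum shift in order.

    Records a :class:`~dimorph.moments.MomentSet` row every ``record_every``
    generations (plus the generation of every shift application).  The run
    is deterministic given ``(config.seed, replicate)``.

    Returns the trajectory as a DataFrame (and the final state if
    ``return_state``).
    """
    rng = replicate_rng(config.seed, replicate)
    params = config.params
    state = PopulationState()
    rows = []

    def record():
        rows.append(compute_moments(state, params).to_dict())

    for t in range(config.burn_in):
        step_generation(state, params, config.mutation, rng)
        if config.record_burn_in and state.generation % config.record_every == 0:
            record()
    if not rows or rows[-1]["generation"] != state.generation:
        record()  # state at the end of burn-in (pre-shift equilibrium)

    shifts = config.shifts or []
    for spec in shifts:
        params = params.replace(O_f=params.O_f + spec.Lambda_f,
                                O_m=params.O_m + spec.Lambda_m)
        duration = spec.duration if spec.duration is not None \
            else config.post_shift
        for t in range(duration):
            step_generation(state, params, config.mutation, rng)
            if state.generation % config.record_every == 0:
                record()
        if not rows or rows[-1]["generation"] != state.generation:
            record()
    if not shifts and config.post_shift:
        for t in range(config.post_shift):
            step_generation(state, params, config.mutation, rng)
            if state.generation % config.record_every == 0:
                record()

    traj = pd.DataFrame(rows)
    if return_state:
        return traj, state
    return traj


def run_replicates(config: RunConfig) -> list[pd.DataFrame]:
    """Run ``config.replicates`` independent replicates sequentially."""
    return [run_replicate(config, i) for i in range(config.replicates)]
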