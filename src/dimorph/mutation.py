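"""Mutational input: magnitude and angle distributions, and U calibration.

A new mutation is described by an overall magnitude ``a`` and an angle
``phi_a``, drawn independently.  The squared magnitude ``a²`` — which in delta
units equals the scaled stabilizing-selection coefficient ``2*N*s_e`` — is
exponentially distributed with a configurable mean ``E(a²)``.  The angle sets
the fraction of stabilizing selection acting through each sex
(``cos²(phi)`` via females, ``sin²(phi)`` via males) and determines the
sex-specific effects

    af = a cos(phi_a) / gamma_f,    am = a sin(phi_a) / gamma_m.

The default angle distribution ``h_r`` places a fraction ``r`` of mutations
on the shared diagonal (af = am, phi in {π/4, 5π/4}) and splits the rest
equally between female-specific (am = 0) and male-specific (af = 0) classes,
each sign equally likely; under it the expected intersex correlation at
equilibrium is exactly ``r``.

The equilibrium overall genic variance follows the single-sex closed form

    V_A,O = 2NU · ∫ v(a) g(a) da,     v(a) = 4 a D+(a/2),

with ``D+`` the Dawson function, which this module integrates numerically
and inverts to calibrate ``U`` for a target variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import quad
from scipy.special import dawsn

from .params import ModelParams

__all__ = [
    "MutationModel",
    "draw_mutations",
    "equilibrium_overall_variance",
    "calibrate_U",
    "equilibrium_sex_moments",
]

_QUAD_KW = dict(epsabs=0.0, epsrel=1e-10, limit=200)

# Shared/female-specific/male-specific atom angles of h_r (positive branch;
# the negative branch adds pi to each, with equal weight).
_PHI_SHARED = math.pi / 4
_PHI_FEMALE = 0.0
_PHI_MALE = math.pi / 2


@dataclass
class MutationModel:
    """Distribution of incoming mutational effects.

    Parameters
    ----------
    mean_sq_magnitude : float
        E(a²), the mean of the exponential distribution of squared overall
        magnitudes, in delta² units.  E(a²) ≲ 4 gives an approximately
        infinitesimal architecture; larger values (e.g. 16) a multigenic one.
    shared_fraction : float
        r, the probability that a mutation is shared (af = am) under the h_r
        angle distribution.  Ignored when ``angle_density`` is given.
    angle_density : callable, optional
        A user-supplied density h(phi) on [0, 2π).  Must satisfy the sign
        symmetry h(phi) = h(phi + π); this is checked on a coarse grid.
    """

    mean_sq_magnitude: float = 1.0
    shared_fraction: float = 0.5
    angle_density: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self):
        if self.mean_sq_magnitude <= 0:
            raise ValueError("E(a^2) must be positive")
        if not (0.0 <= self.shared_fraction <= 1.0):
            raise ValueError("shared fraction r must lie in [0, 1]")
        if self.angle_density is not None:
            phi = np.linspace(0, math.pi, 64, endpoint=False)
            h1 = np.asarray(self.angle_density(phi), float)
            h2 = np.asarray(self.angle_density(phi + math.pi), float)
            if not np.allclose(h1, h2, rtol=1e-6, atol=1e-9):
                raise ValueError("angle density must satisfy h(phi)=h(phi+pi) "
                                 "(equally likely positive/negative effects)")

    # -- draws -------------------------------------------------------------

    def draw_angles(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.angle_density is not None:
            return _sample_density(self.angle_density, n, rng)
        r = self.shared_fraction
        u = rng.random(n)
        phi = np.where(u < r, _PHI_SHARED,
                       np.where(u < r + (1 - r) / 2, _PHI_FEMALE, _PHI_MALE))
        # sign: + keeps phi, - adds pi (decreasing the trait)
        phi = phi + math.pi * (rng.random(n) < 0.5)
        return phi

    def draw_magnitudes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.sqrt(rng.exponential(self.mean_sq_magnitude, size=n))

    def to_dict(self) -> dict:
        return dict(distribution="exponential_sq",
                    mean_sq=self.mean_sq_magnitude,
                    r=self.shared_fraction)


def draw_mutations(model: MutationModel, params: ModelParams, n: int,
                   rng: np.random.Generator):
    """Draw sex-specific effects (af, am) for ``n`` new mutations.

    Returns arrays ``(af, am, x0)`` where ``x0 = 1/(2N)`` is the initial
    frequency of a single new copy among 2N gene copies.
    """
    a = model.draw_magnitudes(n, rng)
    phi = model.draw_angles(n, rng)
    af = a * np.cos(phi) / params.gamma_f
    am = a * np.sin(phi) / params.gamma_m
    # exact zeros for the sex-specific classes of h_r (cos(pi/2) etc. are
    # only zero to floating point)
    if model.angle_density is None:
        af[np.isclose(np.cos(phi), 0.0, atol=1e-12)] = 0.0
        am[np.isclose(np.sin(phi), 0.0, atol=1e-12)] = 0.0
    x0 = np.full(n, 1.0 / (2 * params.N))
    return af, am, x0


def _sojourn_variance(a: float) -> float:
    """v(a) = 4 a D+(a/2): per-mutation contribution to equilibrium variance
    (in units of 2NU), from the single-sex diffusion result."""
    return 4.0 * a * dawsn(a / 2.0)


def _mean_v(mean_sq: float) -> float:
    """E[v(a)] under a² ~ Exponential(mean_sq), by adaptive quadrature on the
    exponential scale (substituting s = a²)."""
    # substitute u = a^2/mean_sq so the weight e^{-u} is scale-free
    def integrand(u):
        a = math.sqrt(mean_sq * u)
        return _sojourn_variance(a) * math.exp(-u)

    val, err = quad(integrand, 0.0, np.inf, **_QUAD_KW)
    if not np.isfinite(val) or (val > 0 and err / val > 1e-8):
        raise ArithmeticError("quadrature for E[v(a)] did not converge")
    return val


def equilibrium_overall_variance(model: MutationModel,
                                 params: ModelParams) -> float:
    """Expected overall genic variance V_A,O at mutation–selection–drift
    balance: ``2NU ∫ v(a) g(a) da`` with v(a) = 4 a D+(a/2)."""
    if params.U == 0:
        return 0.0
    return 2 * params.N * params.U * _mean_v(model.mean_sq_magnitude)


def calibrate_U(model: MutationModel, params: ModelParams,
                target_VA: float) -> float:
    """Mutation rate U per gamete per generation giving equilibrium overall
    variance ``target_VA`` (the integral is linear in U, so this inverts it
    exactly)."""
    if target_VA < 0:
        raise ValueError("target variance must be non-negative")
    if target_VA == 0:
        return 0.0
    return target_VA / (2 * params.N * _mean_v(model.mean_sq_magnitude))


def _angle_integrals(model: MutationModel) -> tuple[float, float, float]:
    """(∫cos², ∫sin², ∫cos·sin) against h(phi)."""
    if model.angle_density is None:
        r = model.shared_fraction
        cc = r * 0.5 + (1 - r) / 2 * 1.0        # shared: cos²(π/4)=½
        ss = r * 0.5 + (1 - r) / 2 * 1.0
        cs = r * 0.5                            # cos·sin = +½ on both branches
        return cc, ss, cs
    h = model.angle_density
    norm, _ = quad(lambda p: h(p), 0, 2 * math.pi, **_QUAD_KW)
    cc, _ = quad(lambda p: math.cos(p) ** 2 * h(p), 0, 2 * math.pi, **_QUAD_KW)
    ss, _ = quad(lambda p: math.sin(p) ** 2 * h(p), 0, 2 * math.pi, **_QUAD_KW)
    cs, _ = quad(lambda p: math.cos(p) * math.sin(p) * h(p), 0, 2 * math.pi,
                 **_QUAD_KW)
    return cc / norm, ss / norm, cs / norm


def equilibrium_sex_moments(model: MutationModel, params: ModelParams):
    """Expected equilibrium (V_A,f, V_A,m, B, r_fm).

    The sex-specific variances and covariance are angle integrals of h(phi)
    scaled by the overall variance:

        V_A,f / V_A,O = (1/γf²) ∫ cos²(phi) h(phi) dphi
        V_A,m / V_A,O = (1/γm²) ∫ sin²(phi) h(phi) dphi
        B     / V_A,O = (1/(γf γm)) ∫ cos(phi) sin(phi) h(phi) dphi

    and r_fm = B / sqrt(V_A,f · V_A,m).  With h_r and γf = γm = 1/√2 this
    gives V_A,f = V_A,m = V_A,O and r_fm = r.  If one sex carries no variance
    r_fm is undefined and returned as NaN.
    """
    VA_O = equilibrium_overall_variance(model, params)
    cc, ss, cs = _angle_integrals(model)
    VA_f = VA_O * cc / params.gamma_f**2
    VA_m = VA_O * ss / params.gamma_m**2
    B = VA_O * cs / (params.gamma_f * params.gamma_m)
    if VA_f > 0 and VA_m > 0:
        rfm = B / math.sqrt(VA_f * VA_m)
    else:
        rfm = math.nan
    return VA_f, VA_m, B, rfm


def _sample_density(h, n: int, rng: np.random.Generator,
                    grid: int = 4096) -> np.ndarray:
    """Inverse-CDF sampling of an angle density tabulated on a fine grid."""
    phi = np.linspace(0, 2 * math.pi, grid, endpoint=False)
    w = np.asarray(h(phi), float)
    if np.any(w < 0):
        raise ValueError("angle density must be non-negative")
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    u = rng.random(n)
    return phi[np.searchsorted(cdf, u)]
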