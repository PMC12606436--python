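"""Global model parameters and unit conventions.

The trait is measured in units of delta, the typical equilibrium deviation of
the population mean phenotype from its optimum under stabilizing selection:
``delta**2 = VS / (2N)``.  The default configuration sets ``VS = 2N`` so that
``delta = 1``; in these units results are invariant to the population size,
the selection width, and the mutational input separately, and an allele's
squared overall magnitude ``a**2`` coincides with its scaled selection
coefficient ``2*N*s_e``.

Sex-specific selection is parameterized by an overall width ``VS`` and two
share factors ``gamma_f, gamma_m`` with ``gamma_f**2 + gamma_m**2 = 1``; the
sex-specific widths are ``VS_f = VS / (2 gamma_f**2)`` and likewise for males.
The symmetric default ``gamma_f = gamma_m = 1/sqrt(2)`` gives equal selection
on the two sexes (``VS_f = VS_m = VS``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass


__all__ = ["ModelParams", "to_avg_diff", "from_avg_diff"]


def to_avg_diff(pair):
    """Map a (female, male) pair to (average, half-difference) coordinates.

    For any quantity with female and male counterparts ``(kf, km)``, returns
    ``(ka, kd) = ((kf + km)/2, (kf - km)/2)``.  The population mean phenotype
    is ``z_a`` and the signed sexual dimorphism is ``SD± = 2 * z_d``.
    The transform is a linear bijection inverted by :func:`from_avg_diff`
    (the same matrix up to scale, so a round trip only halves and re-sums).
    """
    kf, km = pair
    return (kf + km) / 2, (kf - km) / 2


def from_avg_diff(pair):
    """Inverse of :func:`to_avg_diff`: (ka, kd) -> (kf, km) = (ka+kd, ka-kd)."""
    ka, kd = pair
    return ka + kd, ka - kd


@dataclass
class ModelParams:
    """Population and selection parameters.

    Parameters
    ----------
    N : int
        Diploid population size.
    U : float
        Expected number of new mutations per gamete per generation (``U = L*mu``
        under infinite sites).
    VS : float
        Width of the overall Gaussian fitness function; ``1/VS`` is the overall
        strength of stabilizing selection.  Defaults to ``2N`` (delta units).
    gamma_f, gamma_m : float
        Sex-specific selection share factors, ``gamma_f**2 + gamma_m**2 = 1``.
    O_f, O_m : float
        Sex-specific trait optima, in delta units.
    """

    N: int
    U: float
    VS: float | None = None
    gamma_f: float = 1 / math.sqrt(2)
    gamma_m: float = 1 / math.sqrt(2)
    O_f: float = 0.0
    O_m: float = 0.0

    def __post_init__(self):
        if self.VS is None:
            self.VS = 2 * self.N
        if self.N <= 0:
            raise ValueError("N must be positive")
        if self.U < 0:
            raise ValueError("U must be non-negative")
        if self.VS <= 0:
            raise ValueError("VS must be positive")
        if not (self.gamma_f > 0 and self.gamma_m > 0):
            raise ValueError("gamma_f and gamma_m must be positive "
                             "(neither sex evolves neutrally)")
        if abs(self.gamma_f**2 + self.gamma_m**2 - 1.0) > 1e-9:
            raise ValueError("gamma_f**2 + gamma_m**2 must equal 1")
        if self.U > 0 and 2 * self.N * self.U <= 1:
            warnings.warn(
                "2NU <= 1: outside the high-polygenicity regime the analytic "
                "predictions assume (2NU >> 1)", stacklevel=2)

    @property
    def delta(self) -> float:
        """Typical equilibrium fluctuation of the mean, sqrt(VS/(2N))."""
        return math.sqrt(self.VS / (2 * self.N))

    @property
    def VS_f(self) -> float:
        """Width of the female fitness function, VS/(2 gamma_f^2)."""
        return self.VS / (2 * self.gamma_f**2)

    @property
    def VS_m(self) -> float:
        """Width of the male fitness function, VS/(2 gamma_m^2)."""
        return self.VS / (2 * self.gamma_m**2)

    @property
    def O_a(self) -> float:
        return to_avg_diff((self.O_f, self.O_m))[0]

    @property
    def O_d(self) -> float:
        return to_avg_diff((self.O_f, self.O_m))[1]

    def replace(self, **kw) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        d = dict(N=self.N, U=self.U, VS=self.VS, gamma_f=self.gamma_f,
                 gamma_m=self.gamma_m, O_f=self.O_f, O_m=self.O_m)
        d.update(kw)
        return ModelParams(**d)

    def to_dict(self) -> dict:
        return dict(N=self.N, U=self.U, VS=self.VS, gamma_f=self.gamma_f,
                    gamma_m=self.gamma_m, O_f=self.O_f, O_m=self.O_m)
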