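"""Allele table and population state.

Under linkage equilibrium and Hardy–Weinberg proportions the population is
fully described by its list of segregating derived alleles — each with
sex-specific per-copy effects ``(af, am)`` and a single (sex-averaged)
frequency ``x`` — plus the *fixed backgrounds*: the component of each
sex-specific mean phenotype contributed by alleles that have gone to
fixation.  Effects carry explicit signs (mutations are equally likely to
increase or decrease the trait), which matters for means and third moments.

The sex-specific mean phenotypes satisfy, at every generation,

    z̄_f = F̃_f + Σ_i 2 a_{i,f} x_i        (and likewise for males),

with fixation bookkeeping transferring ``2*af`` (``2*am``) into ``F̃_f``
(``F̃_m``) when an allele fixes, so the identity is conserved exactly across
fixation events.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams, to_avg_diff

__all__ = ["Allele", "PopulationState"]


@dataclass(frozen=True)
class Allele:
    """A single segregating derived allele.

    ``af`` and ``am`` are per-copy effects in females and males (delta units);
    ``x`` is the derived-allele frequency, strictly inside (0, 1).
    """

    af: float
    am: float
    x: float

    def __post_init__(self):
        if not (0.0 < self.x < 1.0):
            raise ValueError("allele frequency must lie strictly in (0, 1)")

    def magnitude(self, params: ModelParams) -> float:
        """Overall phenotypic magnitude a >= 0, a² = af²γf² + am²γm²."""
        return float(np.sqrt(self.af**2 * params.gamma_f**2
                             + self.am**2 * params.gamma_m**2))

    def angle(self, params: ModelParams) -> float:
        """Angle φ_a in [0, 2π) with af = a cos(φ)/γf, am = a sin(φ)/γm."""
        return float(np.arctan2(self.am * params.gamma_m,
                                self.af * params.gamma_f) % (2 * np.pi))


@dataclass
class PopulationState:
    """Segregating alleles plus fixed backgrounds at one generation.

    Effect and frequency columns are stored as parallel numpy arrays so a
    whole generation update is a handful of vectorized operations.
    """

    af: np.ndarray = field(default_factory=lambda: np.empty(0))
    am: np.ndarray = field(default_factory=lambda: np.empty(0))
    x: np.ndarray = field(default_factory=lambda: np.empty(0))
    F_f: float = 0.0
    F_m: float = 0.0
    generation: int = 0

    def __post_init__(self):
        self.af = np.asarray(self.af, dtype=float)
        self.am = np.asarray(self.am, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if not (self.af.shape == self.am.shape == self.x.shape):
            raise ValueError("af, am, x must have equal lengths")

    @property
    def n_segregating(self) -> int:
        return self.x.size

    # -- mean phenotypes ---------------------------------------------------

    def mean_phenotypes(self) -> tuple[float, float]:
        """(z̄f, z̄m): fixed background plus segregating contribution."""
        zf = self.F_f + 2.0 * float(self.af @ self.x)
        zm = self.F_m + 2.0 * float(self.am @ self.x)
        return zf, zm

    @property
    def zbar_f(self) -> float:
        return self.mean_phenotypes()[0]

    @property
    def zbar_m(self) -> float:
        return self.mean_phenotypes()[1]

    @property
    def F_a(self) -> float:
        """Average fixed background (F̃f + F̃m)/2."""
        return to_avg_diff((self.F_f, self.F_m))[0]

    @property
    def F_d(self) -> float:
        """Fixed background half-difference (F̃f − F̃m)/2."""
        return to_avg_diff((self.F_f, self.F_m))[1]

    # -- mutation / fixation bookkeeping -----------------------------------

    def add_alleles(self, af, am, x) -> None:
        self.af = np.concatenate([self.af, np.atleast_1d(np.asarray(af, float))])
        self.am = np.concatenate([self.am, np.atleast_1d(np.asarray(am, float))])
        self.x = np.concatenate([self.x, np.atleast_1d(np.asarray(x, float))])

    def absorb_boundaries(self) -> None:
        """Drop lost alleles; fold fixed alleles into the fixed backgrounds."""
        fixed = self.x >= 1.0
        if np.any(fixed):
            self.F_f += 2.0 * float(self.af[fixed].sum())
            self.F_m += 2.0 * float(self.am[fixed].sum())
        keep = (self.x > 0.0) & (self.x < 1.0)
        self.af, self.am, self.x = self.af[keep], self.am[keep], self.x[keep]

    def copy(self) -> "PopulationState":
        return PopulationState(self.af.copy(), self.am.copy(), self.x.copy(),
                               self.F_f, self.F_m, self.generation)

    # -- serialization -----------------------------------------------------

    def to_tsv(self, path, params: ModelParams | None = None) -> None:
        """Write the allele table as TSV with a JSON header comment line."""
        header = {"F_f": self.F_f, "F_m": self.F_m,
                  "generation": self.generation}
        if params is not None:
            header["params"] = params.to_dict()
        with open(path, "w") as fh:
            fh.write("#" + json.dumps(header) + "\n")
            fh.write("af\tam\tx\n")
            for a_f, a_m, xi in zip(self.af, self.am, self.x):
                fh.write(f"{a_f:.17g}\t{a_m:.17g}\t{xi:.17g}\n")

    @classmethod
    def from_tsv(cls, path) -> "PopulationState":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("#"):
                raise ValueError("missing JSON header line")
            header = json.loads(first[1:])
            body = fh.read()
        lines = body.splitlines()
        if len(lines) > 1:
            data = np.loadtxt(io.StringIO(body), skiprows=1, ndmin=2)
        else:
            data = np.empty((0, 3))
        return cls(af=data[:, 0], am=data[:, 1], x=data[:, 2],
                   F_f=header["F_f"], F_m=header["F_m"],
                   generation=header["generation"])
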