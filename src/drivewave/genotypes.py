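"""Non-spatial reaction terms of the three-genotype homing-drive system.

The population is tracked as densities of drive homozygotes (DD),
heterozygotes (DW) and wild-type homozygotes (WW).  Gene conversion happens in
the germline: a heterozygote transmits the drive allele with probability
``(1+c)/2``, where ``c`` is the probability that conversion takes place and
succeeds.  Failed conversion leaves the wild-type allele intact (no resistance
alleles).  The drive reduces fecundity: drive homozygotes reproduce at rate
``1-s``, heterozygotes at ``1-s*h``, wild-type homozygotes at ``1``.

With random mating, the mating sums factorise through the gamete pool.
Writing ``g_D = (n_DD + (1+c) n_DW / 2) / n`` for the drive-gamete fraction
(and ``g_W = 1 - g_D``), the birth fluxes into the three genotype classes are

    DD: (1-s)   B(n) n g_D^2
    DW: (1-s h) B(n) n 2 g_D g_W
    WW:          B(n) n g_W^2

and each class dies at rate ``D(n)``.  Expanding the squares reproduces the
literal mating-pair sums term by term (this equivalence is property-tested).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .demography import DemographyParams, birth_rate, death_rate

__all__ = [
    "DriveParams",
    "GenotypeDensities",
    "drive_gamete_fraction",
    "reaction_terms",
    "wellmixed_rhs",
    "allele_frequency",
    "mean_fitness",
    "DENSITY_GUARD",
]

#: densities below this are treated as extinct when normalising by n (the
#: mating brackets are quadratic over n, so their limit at n -> 0 is 0)
DENSITY_GUARD = 1e-12


@dataclass(frozen=True)
class DriveParams:
    """Genetic parameters of the drive construct.

    s : fitness cost of drive homozygotes (fecundity 1-s), in [0, 1]
    c : germline conversion rate, in [0, 1]
    h : dominance of the fitness cost (heterozygote fecundity 1-s*h), in [0, 1]
    """

    s: float
    c: float
    h: float

    def __post_init__(self) -> None:
        for name in ("s", "c", "h"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @property
    def fitnesses(self) -> tuple[float, float, float]:
        """(f_DD, f_DW, f_WW) = (1-s, 1-sh, 1)."""
        return (1.0 - self.s, 1.0 - self.s * self.h, 1.0)


@dataclass(frozen=True)
class GenotypeDensities:
    """Densities of the three genotypes at one point (or an array of points)."""

    nDD: float
    nDW: float
    nWW: float

    def __post_init__(self) -> None:
        arrs = [np.asarray(v, dtype=float) for v in (self.nDD, self.nDW, self.nWW)]
        if any(np.any(a < 0) for a in arrs):
            raise ValueError("genotype densities must be non-negative")

    @property
    def n(self):
        """Total density."""
        return self.nDD + self.nDW + self.nWW

    def as_array(self) -> np.ndarray:
        return np.asarray([self.nDD, self.nDW, self.nWW], dtype=float)


def drive_gamete_fraction(state: GenotypeDensities, c: float) -> float:
    """Fraction g_D of drive alleles in the gamete pool after germline conversion.

    Heterozygotes contribute drive gametes at rate (1+c)/2.  Undefined for an
    empty population (total density 0); the caller must guard.
    """
    n = state.n
    if np.any(np.asarray(n) <= 0):
        raise ZeroDivisionError("drive gamete fraction undefined at zero total density")
    return (state.nDD + 0.5 * (1.0 + c) * state.nDW) / n


def _reaction(nDD, nDW, nWW, drive: DriveParams, demo: DemographyParams,
              guard: float = DENSITY_GUARD):
    """Vectorised reaction terms; inputs are arrays or scalars of equal shape."""
    n = nDD + nDW + nWW
    B = birth_rate(demo, n)
    D = death_rate(demo, n)

    # gamete-pool densities (not normalised); the birth brackets are
    # (gd^2, 2 gd gw, gw^2) / n, quadratic over n -> 0 as n -> 0.
    gd = nDD + 0.5 * (1.0 + drive.c) * nDW
    gw = nWW + 0.5 * (1.0 - drive.c) * nDW
    fDD, fDW, _ = drive.fitnesses
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_n = np.where(n > guard, 1.0 / np.maximum(n, guard), 0.0)
        births_DD = fDD * B * gd * gd * inv_n
        births_DW = fDW * B * 2.0 * gd * gw * inv_n
        births_WW = B * gw * gw * inv_n

    return (births_DD - D * nDD, births_DW - D * nDW, births_WW - D * nWW)


def reaction_terms(state: GenotypeDensities, drive: DriveParams,
                   demo: DemographyParams) -> tuple:
    """Growth rates (dn_DD/dt, dn_DW/dt, dn_WW/dt) of the well-mixed system.

    Birth fluxes carry the fecundity of the *offspring* genotype class; each
    class dies at the per-capita rate D(n).  Below the density guard all birth
    terms are 0 (their analytic limit) while deaths are evaluated as written.
    """
    return _reaction(state.nDD, state.nDW, state.nWW, drive, demo)


def wellmixed_rhs(state: GenotypeDensities, drive: DriveParams,
                  demo: DemographyParams) -> tuple:
    """Alias of :func:`reaction_terms`, exposed as the ODE right-hand side."""
    return reaction_terms(state, drive, demo)


def allele_frequency(state: GenotypeDensities):
    """Drive allele frequency p_D = (n_DD + n_DW/2) / n.

    Returns NaN (not an exception) where the total density is 0, so spatial
    classifiers can handle eradicated regions.
    """
    n = np.asarray(state.n, dtype=float)
    num = np.asarray(state.nDD + 0.5 * state.nDW, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, num / np.where(n > 0, n, 1.0), np.nan)
    return p if p.ndim else float(p)


def mean_fitness(pD, drive: DriveParams):
    """Mean fecundity F(p_D) = (1-s) p^2 + 2 (1-sh) p (1-p) + (1-p)^2.

    Assumes Hardy-Weinberg genotype proportions at allele frequency p_D; this
    is the fitness that sets the wake demography via F * B(n) = D(n).
    """
    pD = np.asarray(pD, dtype=float)
    if np.any((pD < 0) | (pD > 1)):
        raise ValueError("allele frequency must lie in [0, 1]")
    s, h = drive.s, drive.h
    out = (1.0 - s) * pD**2 + 2.0 * (1.0 - s * h) * pD * (1.0 - pD) + (1.0 - pD) ** 2
    return out if out.ndim else float(out)
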