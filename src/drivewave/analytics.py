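"""Closed-form layer: invasion thresholds, equilibrium regimes, wave speeds.

Everything here is analytic; the PDE solver is only needed to *verify* these
predictions.  The key quantities:

* Fitness-cost thresholds ``s1 = c / (1 - h(1-c))`` and
  ``s2g = c / (h(1+c))``.  A drive invades unconditionally for
  ``s < min(s1, s2g)``; above ``max(s1, s2g)`` the wild type wins.  In the
  intermediate band the outcome is coexistence of both alleles when the cost
  is recessive (``h < 1/2``) and threshold-dependent (bistable in allele
  frequency) when it is dominant (``h > 1/2``).
* The internal allele-frequency equilibrium ``p_D* = (1 - (1-sh)(1+c)) /
  (s(2h-1))`` in the intermediate band.
* Wake regimes: once the final allele frequency p_D* (0, 1, or the
  coexistence root) fixes the mean fitness F = F(p_D*), the final density
  solves ``F B(n) = D(n)``.  Depending on the model and (r, a, F) this gives
  eradication, persistence at a density n+, or density bistability with a
  basin threshold n_tau.
* Pulled-wave speeds at the drive expansion edge: with
  ``lambda = (1-sh)(1+c) - 1`` the drive production rate excess at the front,
  the speed is ``2 sqrt(lambda)`` when density dependence acts on births and
  ``2 sqrt((1+r) lambda)`` when it acts on deaths.  The speed exists only for
  lambda > 0 (equivalently s < s2g) and never depends on the Allee threshold,
  because the front sits in a wild-type population at carrying capacity.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .demography import DemographyParams, Model, birth_rate, death_rate
from .genotypes import DriveParams

__all__ = [
    "Regime",
    "Outcome",
    "RegimeReport",
    "OutcomePrediction",
    "fitness_thresholds",
    "coexistence_frequency",
    "predicted_outcome",
    "regime_and_equilibria",
    "regime_boundary_r",
    "linear_wave_speed",
]


class Regime(str, enum.Enum):
    ERADICATION = "eradication"
    PERSISTENCE = "persistence"
    BISTABILITY = "bistability"


class Outcome(str, enum.Enum):
    DRIVE_INVASION = "drive_invasion"
    COEXISTENCE = "coexistence"
    WILD_TYPE_INVASION = "wild_type_invasion"
    BISTABLE_FREQUENCY = "bistable_frequency"
    GENE_DRIVE_CLEARANCE = "gene_drive_clearance"


@dataclass(frozen=True)
class RegimeReport:
    """Analytic wake regime with its equilibrium densities.

    n_plus is the persistent final density (when the population persists);
    n_tau the basin threshold separating extinction from persistence in the
    density-bistable regime.  F_star is the mean fitness at the assumed final
    allele frequency.
    """

    regime: Regime
    F_star: float
    n_plus: float | None = None
    n_tau: float | None = None


@dataclass(frozen=True)
class OutcomePrediction:
    """Qualitative outcome in allele-frequency space (the r=0 / r->inf table)."""

    outcome: Outcome
    s_band: str  # below_both | intermediate | above_both


def fitness_thresholds(drive: DriveParams) -> tuple[float, float]:
    """Thresholds (s1, s2g) of the fitness cost.

    s1 = c / (1 - h(1-c)); s2g = c / (h(1+c)).  s1 < s2g iff h < 1/2.
    Sentinels: h = 0 makes s2g infinite (a fully recessive cost never blocks
    drive production at the front); c = 1 makes s1 infinite (no wild-type
    invasion band is reachable for s <= 1).
    """
    c, h = drive.c, drive.h
    s1 = math.inf if c >= 1.0 else c / (1.0 - h * (1.0 - c))
    s2g = math.inf if h <= 0.0 else c / (h * (1.0 + c))
    return s1, s2g


def coexistence_frequency(drive: DriveParams) -> float:
    """Internal equilibrium drive frequency p_D* in the intermediate cost band.

    Solves (2h-1) s p + (1-sh)(1+c) - 1 = 0.  Only defined for h != 1/2 and
    min(s1, s2g) < s < max(s1, s2g); outside the band the root leaves (0, 1).
    """
    s, c, h = drive.s, drive.c, drive.h
    if h == 0.5:
        raise ValueError("h = 1/2: the threshold band is empty, no interior equilibrium")
    s1, s2g = fitness_thresholds(drive)
    lo, hi = min(s1, s2g), max(s1, s2g)
    if not lo < s < hi:
        raise ValueError(
            f"s={s} outside the interior-equilibrium band "
            f"(min(s1,s2g)={lo:.6g}, max(s1,s2g)={hi:.6g})"
        )
    return (1.0 - (1.0 - s * h) * (1.0 + c)) / (s * (2.0 * h - 1.0))


def predicted_outcome(drive: DriveParams, r_regime: str) -> OutcomePrediction:
    """Qualitative outcome for the two analytically tractable growth regimes.

    ``r_regime`` is ``"zero"`` (r = 0) or ``"finite_large"`` (r -> infinity).
    At high growth rate: drive invasion below both thresholds, wild-type
    invasion above both, and in between coexistence (h < 1/2) or an
    initial-condition-dependent bistable outcome (h > 1/2).  At r = 0 a costly
    drive above the low band cannot even sustain a pure-drive population, so
    the drive decays uniformly (gene drive clearance) and the wild type
    recolonises.
    """
    if r_regime not in ("zero", "finite_large"):
        raise ValueError("r_regime must be 'zero' or 'finite_large'")
    s = drive.s
    s1, s2g = fitness_thresholds(drive)
    lo, hi = min(s1, s2g), max(s1, s2g)
    if s < lo:
        band = "below_both"
    elif s > hi:
        band = "above_both"
    else:
        band = "intermediate"

    if band == "below_both":
        out = Outcome.DRIVE_INVASION
    elif r_regime == "zero":
        out = Outcome.GENE_DRIVE_CLEARANCE
    elif band == "above_both":
        out = Outcome.WILD_TYPE_INVASION
    else:
        out = Outcome.COEXISTENCE if drive.h < 0.5 else Outcome.BISTABLE_FREQUENCY
    return OutcomePrediction(outcome=out, s_band=band)


def _report(regime: Regime, F: float, n_plus=None, n_tau=None) -> RegimeReport:
    return RegimeReport(regime=regime, F_star=F, n_plus=n_plus, n_tau=n_tau)


def regime_and_equilibria(demo: DemographyParams, F_star: float) -> RegimeReport:
    """Wake regime and equilibrium densities for a given final mean fitness.

    F_star = F(p_D*) is supplied by the caller (1 for a wild-type wake, 1-s for
    a pure-drive wake, the coexistence value otherwise).  The final density
    solves F B(n) = D(n); the regime depends on the model:

    * BN / DN: eradication iff r < (1-F)/F, else persistence.
    * BA: with K = (1-F)/(rF), eradication iff K > ((1-a)/2)^2; otherwise the
      quadratic n^2 - (1+a) n + (a + K) = 0 has roots n_tau <= n+, and the
      population persists from any density iff the low-density growth is
      positive (-a r > (1-F)/F), else the outcome is density-bistable.
    * DA: same structure with K' = (r+1)(1-F)/r in place of K, eradication iff
      r(((1-a)/2)^2 - (1-F)) < 1-F, and the bistable/persistent split at
      r(-a - (1-F)) vs 1-F.

    Ties at regime boundaries break toward the less persistent regime.
    """
    if not 0.0 < F_star <= 1.0:
        raise ValueError(f"F_star must lie in (0, 1], got {F_star}")
    F = F_star
    r = demo.r
    one_mF = 1.0 - F

    if F == 1.0:
        # neutral wake: carrying capacity is globally attracting in all models
        return _report(Regime.PERSISTENCE, F, n_plus=1.0)

    if r == 0.0:
        return _report(Regime.ERADICATION, F)

    model = demo.model
    if model is Model.BN:
        if r <= one_mF / F:
            return _report(Regime.ERADICATION, F)
        return _report(Regime.PERSISTENCE, F, n_plus=1.0 - one_mF / (r * F))
    if model is Model.DN:
        if r <= one_mF / F:
            return _report(Regime.ERADICATION, F)
        return _report(Regime.PERSISTENCE, F, n_plus=1.0 - (r + 1.0) * one_mF / r)

    a = demo.a
    if model is Model.BA:
        K = one_mF / (r * F)
        # eradication iff the quadratic n^2 - (1+a) n + (a+K) has no real root,
        # i.e. (1+a)^2 - 4(a+K) = (1-a)^2 - 4K < 0  <=>  K > ((1-a)/2)^2
        disc = (1.0 + a) ** 2 - 4.0 * (a + K)
        if disc <= 0.0:
            return _report(Regime.ERADICATION, F)
        root = math.sqrt(disc)
        n_plus = (1.0 + a + root) / 2.0
        n_tau = (1.0 + a - root) / 2.0
        if -a * r > one_mF / F:
            return _report(Regime.PERSISTENCE, F, n_plus=n_plus)
        return _report(Regime.BISTABILITY, F, n_plus=n_plus, n_tau=n_tau)

    # DA
    Kp = (r + 1.0) * one_mF / r
    disc = (1.0 + a) ** 2 - 4.0 * (a + Kp)
    # eradication iff r(((1-a)/2)^2 - (1-F)) < 1-F, which is exactly disc < 0
    if r * (((1.0 - a) / 2.0) ** 2 - one_mF) <= one_mF or disc <= 0.0:
        return _report(Regime.ERADICATION, F)
    root = math.sqrt(disc)
    n_plus = (1.0 + a + root) / 2.0
    n_tau = (1.0 + a - root) / 2.0
    if r * (-a - one_mF) > one_mF:
        return _report(Regime.PERSISTENCE, F, n_plus=n_plus)
    return _report(Regime.BISTABILITY, F, n_plus=n_plus, n_tau=n_tau)


def regime_boundary_r(model: Model | str, a: float, s_grid, boundary: str) -> np.ndarray:
    """Regime-boundary curves r(s) for the Allee models, assuming a pure-drive wake.

    With F = 1-s:

    * lower boundary (eradication below / bistable above):
      BA: r = 4s / ((1-a)^2 (1-s)); DA: r = s / (((1-a)/2)^2 - s), infinite
      where ((1-a)/2)^2 <= s (the population is eradicated at every growth
      rate — a feature unique to density dependence on deaths).
    * upper boundary (bistable below / persistence above):
      BA: r = s / (-a (1-s)) for a < 0, infinite for a >= 0;
      DA: r = s / (-a - s) where -a > s, else infinite.

    A strong Allee effect (a > 0) makes the persistence regime disappear
    entirely, hence the infinite sentinels.
    """
    model = Model(model)
    if not model.has_allee:
        raise ValueError("regime boundaries are only defined for the Allee models BA and DA")
    if boundary not in ("lower", "upper"):
        raise ValueError("boundary must be 'lower' or 'upper'")
    if not -1.0 <= a <= 1.0:
        raise ValueError(f"Allee threshold a must lie in [-1, 1], got {a}")
    s = np.asarray(s_grid, dtype=float)
    if np.any((s < 0) | (s >= 1)):
        raise ValueError("s grid must lie in [0, 1)")

    out = np.full_like(s, np.inf)
    if boundary == "lower":
        if model is Model.BA:
            out = 4.0 * s / ((1.0 - a) ** 2 * (1.0 - s))
        else:
            cap = ((1.0 - a) / 2.0) ** 2
            mask = s < cap
            out = np.where(mask, s / np.where(mask, cap - s, 1.0), np.inf)
    else:
        if model is Model.BA:
            if a < 0:
                out = s / (-a * (1.0 - s))
        else:
            mask = -a > s
            out = np.where(mask, s / np.where(mask, -a - s, 1.0), np.inf)
    return out


def linear_wave_speed(family: str, demo: DemographyParams | None,
                      drive: DriveParams) -> float | None:
    """Pulled-wave speed of a drive invasion, from linearisation at the front.

    lambda = (1-sh)(1+c) - 1 is the net production rate of drive alleles by
    rare heterozygotes in a wild-type population at carrying capacity.  Returns
    None when lambda <= 0 (no pulled drive wave, equivalently s >= s2g).
    births_regulated -> 2 sqrt(lambda);
    deaths_regulated -> 2 sqrt((1+r) lambda) (faster turnover at the front).
    Independent of the Allee threshold.
    """
    if family not in ("births_regulated", "deaths_regulated"):
        raise ValueError("family must be 'births_regulated' or 'deaths_regulated'")
    lam = (1.0 - drive.s * drive.h) * (1.0 + drive.c) - 1.0
    if lam <= 0.0:
        return None
    if family == "births_regulated":
        return 2.0 * math.sqrt(lam)
    if demo is None:
        raise ValueError("deaths_regulated speed needs demographic parameters (r)")
    return 2.0 * math.sqrt((1.0 + demo.r) * lam)


def equilibrium_residual(demo: DemographyParams, F_star: float, n: float) -> float:
    """Residual F * B(n) - D(n) of the wake fixed-point equation (oracle hook)."""
    return F_star * birth_rate(demo, n) - death_rate(demo, n)
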