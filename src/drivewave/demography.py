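"""Per-capita birth and death rates of the four demographic models.

Four deterministic models of a monomorphic population are distinguished by
where density dependence acts (births vs. deaths) and whether an Allee effect
is present:

* ``BN`` — density regulation on births, no Allee effect:
  ``B(n) = max(0, r(1-n) + 1)``, ``D(n) = 1``.
* ``BA`` — density regulation on births with an Allee effect:
  ``B(n) = max(0, r(1-n)(n-a) + 1)``, ``D(n) = 1``.
* ``DN`` — density regulation on deaths, no Allee effect:
  ``B(n) = r + 1``, ``D(n) = rn + 1``.
* ``DA`` — density regulation on deaths with an Allee effect:
  ``B(n) = r + 1``, ``D(n) = r + 1 - r(1-n)(n-a)``.

Density ``n`` is scaled so the carrying capacity is 1 in every model, and time
is scaled so the baseline death rate is 1.  ``r`` is the intrinsic growth rate
and ``a`` the Allee threshold: per-capita growth at vanishing density is ``r``
without an Allee effect and ``-a*r`` with one, so ``a < 0`` is a weak Allee
effect (growth at low density stays positive) and ``a > 0`` a strong one.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = ["Model", "DemographyParams", "birth_rate", "death_rate", "net_growth"]


class Model(str, enum.Enum):
    """Demographic model selector."""

    BN = "BN"
    BA = "BA"
    DN = "DN"
    DA = "DA"

    @property
    def has_allee(self) -> bool:
        return self in (Model.BA, Model.DA)

    @property
    def births_regulated(self) -> bool:
        """True when density dependence acts on the birth term."""
        return self in (Model.BN, Model.BA)


@dataclass(frozen=True)
class DemographyParams:
    """Demographic parameters: model label, growth rate ``r``, Allee threshold ``a``.

    ``a`` is stored but inert for the models without an Allee effect (BN, DN),
    which lets parameter sweeps vary ``a`` uniformly across models.
    """

    model: Model
    r: float
    a: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "model", Model(self.model))
        if self.r < 0:
            raise ValueError(f"intrinsic growth rate r must be >= 0, got {self.r}")
        if self.model.has_allee:
            if self.a is None:
                raise ValueError(f"model {self.model.value} requires an Allee threshold a")
            if not -1.0 <= self.a <= 1.0:
                raise ValueError(f"Allee threshold a must lie in [-1, 1], got {self.a}")

    @property
    def allee_strength(self) -> str | None:
        """'weak' for a < 0, 'strong' for a > 0, None when no Allee effect."""
        if not self.model.has_allee:
            return None
        return "strong" if self.a > 0 else ("weak" if self.a < 0 else "threshold")


def _check_density(n) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("density n must be non-negative")
    return n


def birth_rate(params: DemographyParams, n):
    """Per-capita birth rate B(n).

    Accepts scalars or arrays.  The births-regulated terms are clamped at 0
    pointwise: the BA formula can go negative for a strong Allee effect at low
    density, the BN formula for transient overshoot beyond n = 1 + 1/r.
    Densities above 1 are otherwise evaluated as written.
    """
    n = _check_density(n)
    r = params.r
    if params.model is Model.BN:
        out = np.maximum(0.0, r * (1.0 - n) + 1.0)
    elif params.model is Model.BA:
        out = np.maximum(0.0, r * (1.0 - n) * (n - params.a) + 1.0)
    else:  # DN, DA share a constant birth term
        out = np.full_like(n, r + 1.0)
    return out if out.ndim else float(out)


def death_rate(params: DemographyParams, n):
    """Per-capita death rate D(n); strictly positive for all admissible inputs."""
    n = _check_density(n)
    r = params.r
    if params.model in (Model.BN, Model.BA):
        out = np.ones_like(n)
    elif params.model is Model.DN:
        out = r * n + 1.0
    else:  # DA
        out = r + 1.0 - r * (1.0 - n) * (n - params.a)
    return out if out.ndim else float(out)


def net_growth(params: DemographyParams, n):
    """Instantaneous growth (B(n) - D(n)) * n of a monomorphic wild-type population."""
    n = _check_density(n)
    out = (birth_rate(params, n) - death_rate(params, n)) * n
    return out if np.ndim(out) else float(out)
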