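"""Front tracking, speed estimation and outcome classification.

A simulation started from drive-on-the-left / wild-type-on-the-right settles
into one of a handful of spatial behaviours:

* **drive invasion** — a rightward travelling wave of the drive allele; the
  wake behind it can be at carrying capacity (*replacement*), at a reduced
  density (*suppression*) or empty (*eradication*);
* **wild-type invasion** — the front retreats leftward;
* **coexistence** — two fronts move apart leaving an interior region where
  both alleles segregate at an intermediate frequency;
* **gene drive clearance** — no travelling wave at all: the drive decays in
  place and the wild type later recolonises the freed space.

The front is the rightmost level-crossing of the drive allele frequency;
frequency is treated as undefined where the local density is below the
eradication threshold, so near-vacuum debris behind an eradication wave does
not register as a front.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .demography import DemographyParams
from .genotypes import DriveParams
from .solver import GenotypeField, Trajectory

__all__ = [
    "WaveType",
    "WakeState",
    "OutcomeReport",
    "front_position",
    "estimate_speed",
    "wake_density",
    "classify_outcome",
    "EPS_ERADICATION",
    "EPS_REPLACEMENT",
]

#: wake densities below this count as eradicated
EPS_ERADICATION = 1e-3
#: wake densities within this of carrying capacity count as replacement
EPS_REPLACEMENT = 1e-2
#: minimum |speed| regarded as a moving front (space units per time unit)
EPS_SPEED = 5e-3
#: minimum front displacement for the two-front coexistence pattern
COEX_DISPLACEMENT = 5.0


class WaveType(str, enum.Enum):
    DRIVE_INVASION = "drive_invasion"
    WILD_TYPE_INVASION = "wild_type_invasion"
    COEXISTENCE = "coexistence"
    GENE_DRIVE_CLEARANCE = "gene_drive_clearance"
    UNCLASSIFIED = "unclassified"


class WakeState(str, enum.Enum):
    REPLACEMENT = "replacement"
    SUPPRESSION = "suppression"
    ERADICATION = "eradication"
    NOT_APPLICABLE = "not_applicable"


@dataclass
class OutcomeReport:
    """Classified spatial outcome of one simulation."""

    wave_type: WaveType
    wake_state: WakeState
    speed: float | None
    wake_density: float
    front_positions: np.ndarray  # per-snapshot front (NaN where undefined)
    notes: str = ""


def _masked_p_drive(fld: GenotypeField, density_floor: float = EPS_ERADICATION):
    """Drive allele frequency with NaN wherever total density < density_floor."""
    n = fld.total
    p = fld.p_drive
    return np.where(n >= density_floor, p, np.nan)


def _rightmost_crossing(profile: np.ndarray, x: np.ndarray, level: float,
                        valid: np.ndarray) -> float | None:
    """Rightmost level-crossing of ``profile`` by linear interpolation."""
    idx = np.where(valid[:-1] & valid[1:])[0]
    if idx.size == 0:
        return None
    p0, p1 = profile[idx], profile[idx + 1]
    crossing = ((p0 - level) * (p1 - level) <= 0) & (p0 != p1)
    flat = (p0 == level) & (p1 == level)
    hits = idx[crossing | flat]
    if hits.size == 0:
        exact = np.where(valid & (profile == level))[0]
        return float(x[exact[-1]]) if exact.size else None
    i = hits[-1]
    if profile[i] == profile[i + 1]:
        return float(0.5 * (x[i] + x[i + 1]))
    frac = (level - profile[i]) / (profile[i + 1] - profile[i])
    return float(x[i] + frac * (x[i + 1] - x[i]))


def front_position(fld: GenotypeField, grid, level: float = 0.5) -> float | None:
    """Rightmost location where the drive allele frequency crosses ``level``.

    Linear interpolation between adjacent nodes; frequency is only evaluated
    where the local density is above the eradication threshold.  An
    eradication wave travels as a low-density pulse whose frequency front sits
    in near-vacuum, so when no frequency crossing exists the front falls back
    to the half-maximum crossing of the drive allele *density* profile (the
    object drawn in allele-density space).  Returns None when neither exists
    (all wild type, or the drive has decayed everywhere).
    """
    x = grid.x
    p = _masked_p_drive(fld)
    valid = np.isfinite(p)
    if valid.any():
        pos = _rightmost_crossing(p, x, level, valid)
        if pos is not None:
            return pos
    nD = fld.DD + 0.5 * fld.DW
    peak = float(nD.max())
    if peak < EPS_ERADICATION:
        return None
    return _rightmost_crossing(nD, x, 0.5 * peak, np.ones_like(nD, dtype=bool))


def front_series(traj: Trajectory, level: float = 0.5) -> np.ndarray:
    """Front position at every snapshot (NaN where undefined)."""
    out = np.full(len(traj.times), np.nan)
    for i in range(len(traj.times)):
        fp = front_position(traj.field_at(i), traj.grid, level=level)
        if fp is not None:
            out[i] = fp
    return out


def estimate_speed(traj: Trajectory, fronts: np.ndarray | None = None) -> float | None:
    """Least-squares front speed over the second half of the run.

    The first half is discarded as transient.  Returns None when the front is
    undefined in the late snapshots; raises if fewer than 10 usable snapshots
    remain (the trajectory is too short to separate transient from wave).
    """
    if fronts is None:
        fronts = front_series(traj)
    half = len(traj.times) // 2
    t = traj.times[half:]
    f = fronts[half:]
    ok = np.isfinite(f)
    if ok.sum() == 0:
        return None
    if len(t) < 10:
        raise ValueError("need at least 10 snapshots in the second half to estimate a speed")
    if ok.sum() < max(10, 0.5 * len(t)):
        return None
    slope = np.polyfit(t[ok], f[ok], 1)[0]
    return float(slope)


def wake_density(fld: GenotypeField, grid) -> float:
    """Mean total density over the leftmost 10% of the domain (far behind the front)."""
    n = fld.total
    k = max(1, int(round(0.1 * len(n))))
    return float(np.mean(n[:k]))


def classify_outcome(traj: Trajectory, drive: DriveParams,
                     demo: DemographyParams) -> OutcomeReport:
    """Classify a finished trajectory into the outcome taxonomy.

    Decision order:

    1. *clearance*: the total drive-allele mass decreases over the last
       quarter of the run while no front exists in the late snapshots (the
       drive wave has vanished rather than retreated);
    2. *coexistence*: the interface has split into two fronts displaced at
       least 5 space units in opposite directions, leaving an interior region
       at intermediate allele frequency;
    3. otherwise the signed front speed decides drive vs. wild-type invasion,
       and for a drive invasion the wake density sets the wake state
       (replacement / suppression / eradication).

    Anything not matching these patterns is reported ``unclassified`` with
    diagnostics, never silently guessed.
    """
    grid = traj.grid
    fronts = front_series(traj)
    final = traj.final
    wden = wake_density(final, grid)
    dx = grid.dx

    # drive allele mass per snapshot
    mass = np.array([
        np.sum(traj.fields[i][0] + 0.5 * traj.fields[i][1]) * dx
        for i in range(len(traj.times))
    ])

    last_q = max(2, len(traj.times) // 4)
    late_mass = mass[-last_q:]
    mass_decreasing = bool(np.all(np.diff(late_mass) <= 1e-12) and late_mass[-1] < late_mass[0] + 1e-12)
    late_fronts = fronts[-last_q:]
    front_absent_late = bool(np.mean(~np.isfinite(late_fronts)) > 0.5)

    if mass_decreasing and front_absent_late:
        return OutcomeReport(WaveType.GENE_DRIVE_CLEARANCE, WakeState.NOT_APPLICABLE,
                             None, wden, fronts,
                             notes="drive mass decays with no surviving front")

    # two-front (coexistence) pattern: edges of the intermediate-frequency zone
    delta = 0.05
    ref_i = len(traj.times) // 2
    edges = []
    for i in (ref_i, len(traj.times) - 1):
        p = _masked_p_drive(traj.field_at(i))
        interior = np.isfinite(p) & (p > delta) & (p < 1.0 - delta)
        if interior.any():
            xs = grid.x[interior]
            edges.append((xs.min(), xs.max()))
        else:
            edges.append(None)
    if edges[0] is not None and edges[1] is not None:
        left_disp = edges[1][0] - edges[0][0]
        right_disp = edges[1][1] - edges[0][1]
        if left_disp <= -COEX_DISPLACEMENT and right_disp >= COEX_DISPLACEMENT:
            p_final = _masked_p_drive(final)
            interior = np.isfinite(p_final) & (p_final > delta) & (p_final < 1.0 - delta)
            speed = None
            try:
                speed = estimate_speed(traj, fronts)
            except ValueError:
                pass
            return OutcomeReport(WaveType.COEXISTENCE, WakeState.NOT_APPLICABLE,
                                 speed, wden, fronts,
                                 notes=f"interior frequency ~{np.nanmedian(p_final[interior]):.3f}")

    try:
        speed = estimate_speed(traj, fronts)
    except ValueError:
        speed = None
    if speed is None:
        return OutcomeReport(WaveType.UNCLASSIFIED, WakeState.NOT_APPLICABLE,
                             None, wden, fronts,
                             notes="no usable front series in the late run")

    if speed > EPS_SPEED:
        if wden >= 1.0 - EPS_REPLACEMENT:
            wake = WakeState.REPLACEMENT
        elif wden < EPS_ERADICATION:
            wake = WakeState.ERADICATION
        else:
            wake = WakeState.SUPPRESSION
        return OutcomeReport(WaveType.DRIVE_INVASION, wake, speed, wden, fronts)
    if speed < -EPS_SPEED:
        return OutcomeReport(WaveType.WILD_TYPE_INVASION, WakeState.NOT_APPLICABLE,
                             speed, wden, fronts)
    return OutcomeReport(WaveType.UNCLASSIFIED, WakeState.NOT_APPLICABLE, speed,
                         wden, fronts, notes="front effectively stationary")
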