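"""Crank-Nicolson integration of the spatial three-genotype system.

Each genotype density diffuses with unit coefficient on a 1-D interval and
reacts through the well-mixed genotype dynamics.  Diffusion is advanced with
the Crank-Nicolson (trapezoidal) scheme; the nonlinear reaction is advanced
within the same step by averaging the reaction rate at the current state and
at a one-step explicit predictor (Heun-type), so the whole step is
second-order accurate in time without a nonlinear solve:

    u* = u^k + dt (A u^k + R(u^k))                       (predictor)
    (I - dt/2 A) u^{k+1} = (I + dt/2 A) u^k + dt/2 (R(u^k) + R(u*))

A is the standard second-difference Laplacian with zero-flux (reflecting)
boundaries in finite-volume form, which conserves mass exactly when the
reaction is switched off.  Small negative undershoots from the linear solve
are floored at zero after each step (densities are physical; the undershoot
is of the order of the truncation error).

The reference discretisation is dt = 1/6, dx = 1, final time T = 500; all are
configurable, and tests use shorter horizons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import solve_banded

from .analytics import linear_wave_speed
from .demography import DemographyParams
from .genotypes import DriveParams, GenotypeDensities, _reaction, allele_frequency

__all__ = [
    "Grid1D",
    "GenotypeField",
    "Trajectory",
    "default_domain_length",
    "suggested_dt",
    "build_initial_condition",
    "step",
    "simulate",
    "simulate_wellmixed",
]


@dataclass(frozen=True)
class Grid1D:
    """Uniform 1-D grid: domain [0, L], nodes x_i = i dx, time step dt, horizon T."""

    L: float
    dx: float = 1.0
    dt: float = 1.0 / 6.0
    T: float = 500.0

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dt <= 0:
            raise ValueError("dx and dt must be positive")
        if self.T < self.dt:
            raise ValueError("final time T must be at least one time step")
        if self.n_nodes < 16:
            raise ValueError("grid must have at least 16 nodes")

    @property
    def n_nodes(self) -> int:
        return int(round(self.L / self.dx)) + 1

    @property
    def x(self) -> np.ndarray:
        return np.arange(self.n_nodes) * self.dx

    @property
    def n_steps(self) -> int:
        return int(round(self.T / self.dt))


@dataclass
class GenotypeField:
    """Densities of the three genotypes over the grid nodes at one time."""

    DD: np.ndarray
    DW: np.ndarray
    WW: np.ndarray
    t: float = 0.0

    @property
    def total(self) -> np.ndarray:
        return self.DD + self.DW + self.WW

    @property
    def p_drive(self) -> np.ndarray:
        """Drive allele frequency per node (NaN where the population is extinct)."""
        return allele_frequency(GenotypeDensities(self.DD, self.DW, self.WW))

    def copy(self) -> "GenotypeField":
        return GenotypeField(self.DD.copy(), self.DW.copy(), self.WW.copy(), self.t)


@dataclass
class Trajectory:
    """Snapshots of a simulation at a fixed stride, plus summary series."""

    grid: Grid1D
    times: np.ndarray
    fields: np.ndarray  # shape (n_snapshots, 3, n_nodes)
    front_positions: np.ndarray = field(default=None)  # filled by the classifier
    wake_densities: np.ndarray = field(default=None)

    def field_at(self, i: int) -> GenotypeField:
        f = self.fields[i]
        return GenotypeField(f[0], f[1], f[2], t=float(self.times[i]))

    @property
    def final(self) -> GenotypeField:
        return self.field_at(len(self.times) - 1)


def default_domain_length(drive: DriveParams, demo: DemographyParams,
                          T: float = 500.0) -> float:
    """Domain long enough that the drive wave stays inside the window until T.

    Uses the analytic pulled speed as the travel estimate when it exists; the
    initial interface sits at L/2, so L = 2 v T keeps the front just inside.
    A 100-unit margin keeps the leading edge clear of the boundary.
    """
    family = "births_regulated" if demo.model.births_regulated else "deaths_regulated"
    v = linear_wave_speed(family, demo, drive)
    if v is None:
        return 300.0
    return float(max(300.0, math.ceil(2.0 * v * T) + 100.0))


def suggested_dt(demo: DemographyParams, cap: float = 1.0 / 6.0) -> float:
    """Time step resolving the fastest reaction rate, capped at the reference 1/6.

    Per-capita rates scale with 1+r at the leading edge (birth term B(0) for
    the deaths-regulated family, and up to r+1 for births-regulated at low
    density), so the reference step dt = 1/6 loses accuracy once (1+r) dt is
    of order 1.  dt = min(cap, 1/(3(1+r))) keeps the per-step reaction
    increment below ~1/3.
    """
    return min(cap, 1.0 / (3.0 * (1.0 + demo.r)))


def build_initial_condition(grid: Grid1D) -> GenotypeField:
    """Left half of the domain pure drive at density 1, right half pure wild type.

    The midpoint node is assigned to the wild-type side.
    """
    x = grid.x
    mid = grid.L / 2.0
    DD = np.where(x < mid, 1.0, 0.0)
    WW = np.where(x >= mid, 1.0, 0.0)
    DW = np.zeros_like(x)
    return GenotypeField(DD, DW, WW, t=0.0)


def _laplacian_banded(n: int, dx: float, dt: float):
    """Banded forms of (I - dt/2 A) and the action of (I + dt/2 A).

    A is the zero-flux finite-volume Laplacian: interior rows
    (1, -2, 1)/dx^2, boundary rows (-1, 1)/dx^2 — columns sum to zero, so the
    scheme conserves total mass exactly under pure diffusion.
    """
    k = dt / (2.0 * dx * dx)
    main = np.full(n, 1.0 + 2.0 * k)
    main[0] = main[-1] = 1.0 + k
    upper = np.full(n, -k)
    lower = np.full(n, -k)
    ab = np.zeros((3, n))
    ab[0, 1:] = upper[1:]
    ab[1] = main
    ab[2, :-1] = lower[:-1]
    return ab, k


def _apply_explicit(u: np.ndarray, k: float) -> np.ndarray:
    """(I + dt/2 A) u for the zero-flux Laplacian."""
    out = u.copy()
    out[1:-1] += k * (u[:-2] - 2.0 * u[1:-1] + u[2:])
    out[0] += k * (u[1] - u[0])
    out[-1] += k * (u[-2] - u[-1])
    return out


def _laplacian(u: np.ndarray, dx: float) -> np.ndarray:
    out = np.empty_like(u)
    inv = 1.0 / (dx * dx)
    out[1:-1] = (u[:-2] - 2.0 * u[1:-1] + u[2:]) * inv
    out[0] = (u[1] - u[0]) * inv
    out[-1] = (u[-2] - u[-1]) * inv
    return out


def step(fld: GenotypeField, grid: Grid1D, drive: DriveParams,
         demo: DemographyParams, reaction: bool = True,
         _ab=None) -> GenotypeField:
    """Advance the field by one time step dt.

    ``reaction=False`` integrates pure diffusion (used to test conservation).
    Raises FloatingPointError-style failure (ArithmeticError) with the failure
    time if non-finite values appear.
    """
    n = grid.n_nodes
    if _ab is None:
        _ab = _laplacian_banded(n, grid.dx, grid.dt)
    ab, k = _ab
    dt = grid.dt

    u = (fld.DD, fld.DW, fld.WW)
    if reaction:
        R0 = _reaction(*u, drive, demo)
        pred = tuple(
            np.maximum(0.0, ui + dt * (_laplacian(ui, grid.dx) + ri))
            for ui, ri in zip(u, R0)
        )
        R1 = _reaction(*pred, drive, demo)
        rhs = [
            _apply_explicit(ui, k) + 0.5 * dt * (r0 + r1)
            for ui, r0, r1 in zip(u, R0, R1)
        ]
    else:
        rhs = [_apply_explicit(ui, k) for ui in u]

    t_new = fld.t + dt
    try:
        new = [solve_banded((1, 1), ab, b) for b in rhs]
    except ValueError as exc:  # scipy rejects non-finite right-hand sides
        raise ArithmeticError(f"integration failure: non-finite densities at t={t_new:g}") from exc
    for arr in new:
        if not np.all(np.isfinite(arr)):
            raise ArithmeticError(f"integration failure: non-finite densities at t={t_new:g}")
    if reaction:
        new = [np.maximum(a, 0.0) for a in new]
    return GenotypeField(new[0], new[1], new[2], t=t_new)


def simulate(drive: DriveParams, demo: DemographyParams, grid: Grid1D,
             snapshot_stride: int = 10, initial: GenotypeField | None = None,
             reaction: bool = True) -> Trajectory:
    """Integrate from the half-drive/half-wild-type initial condition to T.

    Snapshots (including the initial state) are recorded every
    ``snapshot_stride`` steps and always at the final step.  Fully
    deterministic: identical inputs give bit-identical trajectories.
    """
    if snapshot_stride < 1:
        raise ValueError("snapshot_stride must be >= 1")
    fld = build_initial_condition(grid) if initial is None else initial.copy()
    ab = _laplacian_banded(grid.n_nodes, grid.dx, grid.dt)

    times = [fld.t]
    fields = [np.stack([fld.DD, fld.DW, fld.WW])]
    n_steps = grid.n_steps
    for i in range(1, n_steps + 1):
        fld = step(fld, grid, drive, demo, reaction=reaction, _ab=ab)
        if i % snapshot_stride == 0 or i == n_steps:
            times.append(fld.t)
            fields.append(np.stack([fld.DD, fld.DW, fld.WW]))
    return Trajectory(grid=grid, times=np.asarray(times), fields=np.stack(fields))


def simulate_wellmixed(drive: DriveParams, demo: DemographyParams, t_end: float,
                       initial_state: GenotypeDensities,
                       rtol: float = 1e-9, atol: float = 1e-12):
    """Integrate the well-mixed three-genotype ODE (oracle for the wake regimes).

    Returns the scipy ``OdeResult``; ``sol.y`` has rows (n_DD, n_DW, n_WW).
    """

    def rhs(_t, y):
        y = np.maximum(y, 0.0)  # the integrator may probe marginally negative states
        return np.asarray(_reaction(y[0], y[1], y[2], drive, demo))

    y0 = initial_state.as_array()
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA", rtol=rtol, atol=atol,
                    dense_output=False)
    if not sol.success:
        raise ArithmeticError(f"well-mixed integration failed: {sol.message}")
    return sol
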