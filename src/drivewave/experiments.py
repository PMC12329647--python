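"""Batch experiment driver: single runs, regime heatmaps, boundary curves.

The analytic layer (thresholds, wake regimes, pulled speeds) is cheap and is
always computed; PDE verification is opt-in per cell because it costs minutes
rather than seconds.  All outputs are plain CSV (plus optional ``.npz`` field
dumps and PNG figures) and every run is fully deterministic, so re-running a
configuration reproduces byte-identical tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .analytics import (
    Regime,
    coexistence_frequency,
    fitness_thresholds,
    linear_wave_speed,
    predicted_outcome,
    regime_and_equilibria,
    regime_boundary_r,
)
from .classify import (
    OutcomeReport,
    classify_outcome,
    estimate_speed,
    front_series,
    wake_density,
)
from .demography import DemographyParams, Model
from .genotypes import DriveParams
from .solver import Grid1D, Trajectory, default_domain_length, simulate

__all__ = ["ExperimentConfig", "run_single", "run_heatmap", "render_boundaries",
           "speed_check", "expected_wave_types"]

_PARAM_BOUNDS = {
    "s": (0.0, 1.0),
    "c": (0.0, 1.0),
    "h": (0.0, 1.0),
    "a": (-1.0, 1.0),
}


@dataclass
class ExperimentConfig:
    """Validated configuration of one experiment (single run or sweep)."""

    model: str = "BN"
    s: float | list = 0.2
    c: float = 0.85
    h: float = 0.9
    r: float | list = 2.0
    a: float | None = None
    L: float | None = None  # None: sized from the analytic speed estimate
    dx: float = 1.0
    dt: float = 1.0 / 6.0
    T: float = 500.0
    snapshot_stride: int = 10
    resolution: int = 2  # minimum points per swept axis
    out_dir: str | None = None
    save_fields: bool = False
    pde_verify: bool = False
    runtime_budget_cells: int = 400  # refuse sweeps larger than this with PDE on

    def __post_init__(self) -> None:
        errors = []
        try:
            Model(self.model)
        except ValueError:
            errors.append(f"model must be one of {[m.value for m in Model]}, got {self.model!r}")
        for name in ("s", "r"):
            vals = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if vals.size == 0:
                errors.append(f"{name} range is empty")
        for name, (lo, hi) in _PARAM_BOUNDS.items():
            v = getattr(self, name)
            if v is None:
                continue
            for vi in np.atleast_1d(np.asarray(v, dtype=float)):
                if not lo <= vi <= hi:
                    errors.append(f"{name}={vi} outside its admissible range [{lo}, {hi}]")
        for vi in np.atleast_1d(np.asarray(self.r, dtype=float)):
            if vi < 0:
                errors.append(f"r={vi} outside its admissible range [0, inf)")
        if self.model in ("BA", "DA") and self.a is None:
            errors.append(f"model {self.model} requires the Allee threshold a")
        if self.dx <= 0:
            errors.append(f"dx={self.dx} must be positive")
        if self.dt <= 0:
            errors.append(f"dt={self.dt} must be positive")
        if self.T <= 0:
            errors.append(f"T={self.T} must be positive")
        if self.snapshot_stride < 1:
            errors.append("snapshot_stride must be >= 1")
        if errors:
            raise ValueError("invalid configuration:\n  - " + "\n  - ".join(errors))

    # -- helpers -------------------------------------------------------
    def demo(self, r: float | None = None) -> DemographyParams:
        r = float(np.atleast_1d(self.r)[0]) if r is None else r
        a = self.a if Model(self.model).has_allee else None
        return DemographyParams(model=Model(self.model), r=r, a=a)

    def drive(self, s: float | None = None) -> DriveParams:
        s = float(np.atleast_1d(self.s)[0]) if s is None else s
        return DriveParams(s=s, c=self.c, h=self.h)

    def grid(self, drive: DriveParams, demo: DemographyParams) -> Grid1D:
        L = self.L if self.L is not None else default_domain_length(drive, demo, self.T)
        return Grid1D(L=L, dx=self.dx, dt=self.dt, T=self.T)


def expected_wave_types(drive: DriveParams, demo: DemographyParams) -> set:
    """Admissible wave types for a half-drive initial condition at finite r.

    Finite-growth-rate reading of the qualitative outcome table:

    * below both cost thresholds the drive invades at every growth rate;
    * at r = 0 the drive invades exactly when the pulled wave exists
      (s < s2g, as a low-density eradication pulse); otherwise it decays in
      place (clearance);
    * above both thresholds the wild type wins, but at finite r the drive
      bulk may sit in its eradication regime and collapse before the
      wild-type front can sweep it, which presents as clearance;
    * in the intermediate band the outcome is coexistence (h < 1/2) or
      initial-condition dependent (h > 1/2); when the relevant wake cannot
      persist at this r the eradication-regime outcomes are also admissible.
    """
    from .classify import WaveType

    s1, s2g = fitness_thresholds(drive)
    lo, hi = min(s1, s2g), max(s1, s2g)
    s, r = drive.s, demo.r
    if s < lo:
        return {WaveType.DRIVE_INVASION}
    if r == 0.0:
        return ({WaveType.DRIVE_INVASION} if s < s2g
                else {WaveType.GENE_DRIVE_CLEARANCE})
    if s > hi:
        return {WaveType.WILD_TYPE_INVASION, WaveType.GENE_DRIVE_CLEARANCE}
    if drive.h < 0.5:
        from .genotypes import mean_fitness

        F = mean_fitness(coexistence_frequency(drive), drive)
        if regime_and_equilibria(demo, F).regime.value == "persistence" and \
                demo.r > 1.2 * (1.0 - F) / F:
            return {WaveType.COEXISTENCE}
        return {WaveType.COEXISTENCE, WaveType.DRIVE_INVASION}
    if r > 1.2 * s / (1.0 - s):
        return {WaveType.DRIVE_INVASION, WaveType.WILD_TYPE_INVASION}
    return {WaveType.DRIVE_INVASION, WaveType.WILD_TYPE_INVASION,
            WaveType.GENE_DRIVE_CLEARANCE}


def _analytic_row(drive: DriveParams, demo: DemographyParams) -> dict:
    s1, s2g = fitness_thresholds(drive)
    family = "births_regulated" if demo.model.births_regulated else "deaths_regulated"
    v = linear_wave_speed(family, demo, drive)
    report = regime_and_equilibria(demo, F_star=1.0 - drive.s)
    return {
        "s1": s1,
        "s2g": s2g,
        "predicted_speed": v if v is not None else np.nan,
        "regime": report.regime.value,
        "n_plus": report.n_plus if report.n_plus is not None else np.nan,
        "n_tau": report.n_tau if report.n_tau is not None else np.nan,
    }


def run_single(config: ExperimentConfig) -> tuple[OutcomeReport, pd.DataFrame]:
    """One simulation plus its analytic predictions; optionally writes artifacts.

    Returns the classified outcome and the one-row summary table.  When
    ``config.out_dir`` is set, writes ``trajectory.csv`` (t, front position,
    wake density, total mass), ``summary.csv`` and, if requested, the full
    fields in ``fields.npz``.
    """
    drive = config.drive()
    demo = config.demo()
    grid = config.grid(drive, demo)
    analytic = _analytic_row(drive, demo)

    traj = simulate(drive, demo, grid, snapshot_stride=config.snapshot_stride)
    report = classify_outcome(traj, drive, demo)

    row = {
        "model": demo.model.value,
        "r": demo.r,
        "s": drive.s,
        "c": drive.c,
        "h": drive.h,
        "a": demo.a if demo.a is not None else np.nan,
        "wave_type": report.wave_type.value,
        "wake_state": report.wake_state.value,
        "speed": report.speed if report.speed is not None else np.nan,
        "wake_density": report.wake_density,
        **analytic,
    }
    summary = pd.DataFrame([row])

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fronts = report.front_positions
        mass = traj.fields.sum(axis=(1, 2)) * grid.dx
        wakes = [wake_density(traj.field_at(i), grid) for i in range(len(traj.times))]
        pd.DataFrame({
            "t": traj.times,
            "front_position": fronts,
            "wake_density": wakes,
            "total_mass": mass,
        }).to_csv(out / "trajectory.csv", index=False)
        summary.to_csv(out / "summary.csv", index=False)
        if config.save_fields:
            np.savez_compressed(out / "fields.npz", times=traj.times, fields=traj.fields,
                                x=grid.x)
    return report, summary


def run_heatmap(config: ExperimentConfig) -> pd.DataFrame:
    """Sweep an (r, s) grid; analytic layer per cell, PDE verification opt-in.

    Long-format output: one row per (r, s) cell with the analytic regime,
    final density and pulled speed, plus measured speed / wake density /
    outcome when ``pde_verify`` is set.
    """
    r_vals = np.atleast_1d(np.asarray(config.r, dtype=float))
    s_vals = np.atleast_1d(np.asarray(config.s, dtype=float))
    n_cells = r_vals.size * s_vals.size
    if config.pde_verify and n_cells > config.runtime_budget_cells:
        raise RuntimeError(
            f"PDE verification over {n_cells} cells exceeds the configured budget "
            f"({config.runtime_budget_cells}); reduce the grid or raise the budget"
        )

    rows = []
    for r, s in itertools.product(r_vals, s_vals):
        drive = config.drive(s=float(s))
        demo = config.demo(r=float(r))
        row = {"model": demo.model.value, "r": float(r), "s": float(s),
               "c": config.c, "h": config.h,
               "a": demo.a if demo.a is not None else np.nan}
        row.update(_analytic_row(drive, demo))
        if config.pde_verify:
            grid = config.grid(drive, demo)
            traj = simulate(drive, demo, grid, snapshot_stride=config.snapshot_stride)
            rep = classify_outcome(traj, drive, demo)
            row.update({
                "wave_type": rep.wave_type.value,
                "wake_state": rep.wake_state.value,
                "measured_speed": rep.speed if rep.speed is not None else np.nan,
                "measured_wake_density": rep.wake_density,
            })
        rows.append(row)
    df = pd.DataFrame(rows)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "heatmap.csv", index=False)
        _plot_heatmap(df, r_vals, s_vals, out / "heatmap.png")
    return df


def _plot_heatmap(df: pd.DataFrame, r_vals, s_vals, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_plus = df.pivot(index="r", columns="s", values="n_plus").values
    grid = np.nan_to_num(n_plus, nan=0.0)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    im = ax.pcolormesh(s_vals, r_vals, grid, shading="nearest", cmap="viridis",
                       vmin=0.0, vmax=1.0)
    fig.colorbar(im, ax=ax, label="final density $n^+$ (pure-drive wake)")
    ax.set_xlabel("fitness cost s")
    ax.set_ylabel("intrinsic growth rate r")
    ax.set_title(f"model {df['model'].iloc[0]}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_boundaries(model: str, a_list, s_grid, out_dir: str | None = None) -> pd.DataFrame:
    """Regime-boundary curves r(s) for a list of Allee thresholds.

    Asserts the monotone ordering in ``a`` (a stronger Allee effect enlarges
    the eradication region and shrinks persistence) before rendering.
    """
    model = Model(model)
    s_grid = np.asarray(s_grid, dtype=float)
    rows = []
    curves = {}
    for bnd in ("lower", "upper"):
        for a in a_list:
            curve = regime_boundary_r(model, a, s_grid, bnd)
            curves[(bnd, a)] = curve
            for s, r in zip(s_grid, curve):
                rows.append({"model": model.value, "a": a, "s": s,
                             "boundary": bnd, "r": r})
    a_sorted = sorted(a_list)
    for bnd in ("lower", "upper"):
        for a0, a1 in zip(a_sorted[:-1], a_sorted[1:]):
            c0, c1 = curves[(bnd, a0)], curves[(bnd, a1)]
            if not np.all(c1 >= c0 - 1e-12):
                raise AssertionError(
                    f"{bnd} boundary for a={a1} not pointwise above a={a0}"
                )
    df = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / f"boundaries_{model.value}.csv", index=False)
        _plot_boundaries(df, model, out / f"boundaries_{model.value}.png")
    return df


def _plot_boundaries(df: pd.DataFrame, model: Model, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    styles = {"lower": "--", "upper": "-."}
    for (bnd, a), sub in df.groupby(["boundary", "a"]):
        finite = np.isfinite(sub["r"])
        if finite.any():
            ax.plot(sub.loc[finite, "s"], sub.loc[finite, "r"], styles[bnd],
                    label=f"{bnd}, a={a}")
    ax.set_xlabel("fitness cost s")
    ax.set_ylabel("intrinsic growth rate r")
    ax.set_ylim(0, 12)
    ax.set_title(f"regime boundaries, model {model.value} (pure-drive wake)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def speed_check(config: ExperimentConfig) -> pd.DataFrame:
    """Measured vs. analytic pulled speed for the configured parameter values."""
    r_vals = np.atleast_1d(np.asarray(config.r, dtype=float))
    s_vals = np.atleast_1d(np.asarray(config.s, dtype=float))
    rows = []
    for r, s in itertools.product(r_vals, s_vals):
        drive = DriveParams(s=float(s), c=config.c, h=config.h)
        demo = config.demo(r=float(r))
        family = "births_regulated" if demo.model.births_regulated else "deaths_regulated"
        v_pred = linear_wave_speed(family, demo, drive)
        grid = config.grid(drive, demo)
        traj = simulate(drive, demo, grid, snapshot_stride=config.snapshot_stride)
        fronts = front_series(traj)
        v_meas = estimate_speed(traj, fronts)
        rows.append({
            "model": demo.model.value, "r": float(r), "s": float(s),
            "c": config.c, "h": config.h,
            "analytic_speed": v_pred if v_pred is not None else np.nan,
            "measured_speed": v_meas if v_meas is not None else np.nan,
            "relative_error": (abs(v_meas - v_pred) / v_pred
                               if v_pred and v_meas is not None else np.nan),
        })
    df = pd.DataFrame(rows)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "speedcheck.csv", index=False)
    return df
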