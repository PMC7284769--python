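"""Sweep driver: geometry series, scaled-down simulation sweeps,
aggregation of observables and figure-style reports.

The three series mirror the ways the array geometry can be varied: at
constant effective post diameter d_p (vary S_p), at constant post
separation S_p (vary d_p), and at constant passage width w_p (vary S_p
with d_p = S_p - w_p).  Defaults are desk-scale (N = 100 beads, 10^6-step
production); the full-scale protocol (N = 1000, 2e8 tau) is reachable
through the same config surface but is cluster work.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import PostArray, derive_parameters
from .io import write_csv_with_provenance, write_xyz, read_xyz
from .model import ForceFieldParams
from .observables import (
    ObservableSeries, axial_span, gyration, occupation_number,
    structure_factor, default_q_grid,
)
from .simulate import SimulationConfig, Trajectory, init_conformation, integrate

__all__ = ["SweepPlan", "build_series", "run_sweep", "render_reports"]

log = logging.getLogger("nanopost")

_MODES = ("constant_dp", "constant_Sp", "constant_wp")


@dataclass(frozen=True)
class SweepPlan:
    """One geometry series plus the chain/simulation settings to run it.

    ``fixed`` is d_p, S_p or w_p depending on ``mode``; ``varied`` lists
    the other primary parameter (S_p for constant_dp/constant_wp, d_p for
    constant_Sp).  ``bead_width`` converts effective to geometric post
    diameters (D_p = d_p - w).
    """

    mode: str
    fixed: float
    varied: tuple
    N: int = 100
    stiffness: float = 0.0
    bead_width: float = 0.9
    config: SimulationConfig = field(default_factory=lambda: SimulationConfig(
        n_equil=100_000, n_prod=1_000_000, sample_stride=1_000))
    replica_seeds: tuple = (101, 202, 303)

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if len(set(self.replica_seeds)) != len(self.replica_seeds):
            raise ValueError("replica seeds must be distinct")
        if not self.varied:
            raise ValueError("no varied values given")


def build_series(plan: SweepPlan) -> list[PostArray]:
    """Materialise the geometry series of a plan as PostArray objects."""
    w = plan.bead_width
    arrays = []
    for v in plan.varied:
        if plan.mode == "constant_dp":
            S_p, d_p = float(v), plan.fixed
        elif plan.mode == "constant_Sp":
            S_p, d_p = plan.fixed, float(v)
        else:  # constant_wp: vary S_p with d_p = S_p - w_p
            S_p = float(v)
            d_p = S_p - plan.fixed
        D_p = d_p - w
        if D_p < 0 or S_p < D_p:
            raise ValueError(
                f"impossible geometry in {plan.mode}: S_p={S_p}, d_p={d_p}")
        arrays.append(derive_parameters(S_p, D_p, w))
    return arrays


def _system_tag(plan: SweepPlan, array: PostArray, seed: int) -> str:
    key = json.dumps({
        "mode": plan.mode, "S_p": array.S_p, "D_p": array.D_p,
        "N": plan.N, "b": plan.stiffness, "seed": seed,
        "dt": plan.config.dt, "n_prod": plan.config.n_prod,
        "n_equil": plan.config.n_equil, "stride": plan.config.sample_stride,
        "thermostat": plan.config.thermostat,
    }, sort_keys=True)
    return hashlib.sha256(key.encode()).hexdigest()[:12]


def run_sweep(plan: SweepPlan, outdir: Optional[Path] = None,
              pool_orientations: bool = True):
    """Simulate every geometry x replica of the plan and aggregate.

    Returns ``(ObservableSeries, {S_p: StructureFactorCurve})``.  When
    ``outdir`` is given, trajectories are written there as extended XYZ
    and previously completed systems (matched by a provenance hash in the
    file name) are loaded instead of re-run; per-system failures are
    logged and skipped so a sweep survives individual blow-ups.
    """
    handler = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(outdir / "sweep.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(handler)
        log.setLevel(logging.INFO)
        from . import __version__

        log.info("sweep start: mode=%s fixed=%g N=%d b=%g seeds=%s version=%s",
                 plan.mode, plan.fixed, plan.N, plan.stiffness,
                 list(plan.replica_seeds), __version__)
    p = ForceFieldParams(stiffness=plan.stiffness, bead_width=plan.bead_width)
    series = ObservableSeries()
    curves: dict = {}
    orientations = ("parallel", "perpendicular") if pool_orientations else ("parallel",)

    for array in build_series(plan):
        trajs = []
        for k, seed in enumerate(plan.replica_seeds):
            orientation = orientations[k % len(orientations)]
            tag = _system_tag(plan, array, seed)
            cache = outdir / f"traj_{tag}.xyz" if outdir is not None else None
            if cache is not None and cache.exists():
                log.info("loading cached system %s", tag)
                trajs.append(read_xyz(cache))
                continue
            cfg = replace(plan.config, seed=seed, init_orientation=orientation)
            state = init_conformation(plan.N, array, orientation, p)
            try:
                traj = integrate(state, array, p, cfg)
            except Exception as exc:  # noqa: BLE001 — sweep must survive aborts
                log.error("system S_p=%.3g seed=%d aborted: %s",
                          array.S_p, seed, exc)
                continue
            trajs.append(traj)
            if cache is not None:
                write_xyz(traj, cache)
        if not trajs:
            continue
        pooled = Trajectory.concatenate(trajs)
        n_p, n_p_err = occupation_number(pooled, array)
        r_s, r_s_err = axial_span(pooled)
        gy = gyration(pooled)
        series.add(array, n_p, n_p_err, r_s, r_s_err,
                   gy.r_g, gy.axial, gy.lateral,
                   pooled.n_frames, len(trajs))
        curves[array.S_p] = structure_factor(
            pooled, default_q_grid(plan.N), max_frames=200)

    if outdir is not None:
        log.removeHandler(handler)
        handler.close()
        df = series.to_dataframe()
        write_csv_with_provenance(
            df, outdir / "observables.csv",
            {"mode": plan.mode, "N": plan.N, "stiffness": plan.stiffness,
             "replica_seeds": list(plan.replica_seeds)})
        for sp, curve in curves.items():
            write_csv_with_provenance(
                pd.DataFrame({"q": curve.q, "S": curve.S}),
                outdir / f"sq_Sp{sp:g}.csv",
                {"S_p": sp, "n_frames": curve.n_frames})
    return series, curves


def render_reports(results, outdir: Path,
                   theory_overlays: bool = True) -> list[Path]:
    """Render summary figures from one or more sweep results.

    ``results`` is a list of ``(label, ObservableSeries, curves)``
    triples.  Produces occupation and span plots against d_c/w_p and F,
    a log-log span-vs-d_c plot, and log-log S(q) panels with slope guides
    and a 2*pi/S_p marker.  Returns the written paths; an empty result
    set yields an empty report with a warning.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if not results:
        log.warning("render_reports called with no results")
        return written

    for xcol, fname in (("ratio", "occupation_vs_ratio.png"),
                        ("F", "occupation_vs_F.png")):
        fig, ax = plt.subplots()
        for label, series, _ in results:
            df = series.to_dataframe()
            if df.empty:
                continue
            df = df.sort_values(xcol)
            ax.errorbar(df[xcol], df["n_p"], yerr=df["n_p_err"],
                        marker="o", label=label)
        ax.set_xlabel("d_c/w_p" if xcol == "ratio" else "F")
        ax.set_ylabel("occupation number n_p")
        ax.set_xscale("log" if xcol == "ratio" else "linear")
        ax.legend()
        path = outdir / fname
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    fig, ax = plt.subplots()
    for label, series, _ in results:
        df = series.to_dataframe()
        if df.empty:
            continue
        df = df.sort_values("d_c")
        ax.loglog(df["d_c"], df["R_s"], marker="o", label=label)
    ax.set_xlabel("d_c")
    ax.set_ylabel("axial span R_s")
    ax.legend()
    path = outdir / "span_vs_dc.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    for label, _, curves in results:
        if not curves:
            continue
        fig, ax = plt.subplots()
        for sp, curve in sorted(curves.items()):
            ax.loglog(curve.q, curve.S, label=f"S_p={sp:g}")
            ax.axvline(2.0 * np.pi / sp, ls=":", lw=0.6, color="grey")
        if theory_overlays:
            qg = np.geomspace(curve.q[0], curve.q[-1], 50)
            for slope in (-1.0, -5.0 / 3.0, -2.0):
                ax.loglog(qg, 0.5 * (qg / qg[-1]) ** slope, lw=0.7, ls="--",
                          label=f"slope {slope:.2f}")
        ax.set_xlabel("q (sigma^-1)")
        ax.set_ylabel("S(q)")
        ax.legend(fontsize=6)
        path = outdir / f"sq_{label.replace(' ', '_')}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
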