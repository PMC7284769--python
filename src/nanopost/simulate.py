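"""Equilibrium sampling of the confined chain.

Two samplers share the Hamiltonian of :mod:`nanopost.model`:

* :func:`integrate` — NVT molecular dynamics (velocity-Verlet core with a
  Nose-Hoover thermostat by default, Langevin as an alternative, or no
  thermostat for energy-conservation checks), suitable with or without
  the post array.
* :func:`pivot_sample` — Metropolis Monte Carlo for *free* chains, mixing
  pivot, crankshaft and single-bead displacement moves.  Pivot moves
  decorrelate global size in a handful of accepted moves, which makes
  this the method of choice for long-chain equilibrium averages (R_g,
  bond correlations); displacement moves let bond lengths fluctuate so
  the stationary distribution is exp(-U/k_BT) of the full Hamiltonian.

Lengths in sigma, energies in epsilon, time in tau = sigma*sqrt(m_o/eps).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from . import _kernels as K
from .geometry import PostArray
from .model import ChainState, ForceFieldParams, OverlapError, OverstretchError, total_energy

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "init_conformation",
    "integrate",
    "pivot_sample",
]

_THERMOSTATS = {"none": 0, "nose-hoover": 1, "langevin": 2}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of an NVT run, in reduced units.

    ``dt`` and ``thermostat_tau`` default to the protocol values 0.005 tau
    and 0.1 tau; ``sample_stride`` defaults to one frame per 10,000 steps.
    """

    dt: float = 0.005
    thermostat_tau: float = 0.1
    temperature: float = 1.0
    n_equil: int = 50_000
    n_prod: int = 500_000
    sample_stride: int = 10_000
    seed: int = 0
    init_orientation: str = "parallel"
    thermostat: str = "nose-hoover"
    langevin_gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.thermostat_tau <= self.dt:
            raise ValueError("thermostat_tau must exceed dt")
        if self.sample_stride < 1:
            raise ValueError("sample_stride must be >= 1")
        if self.thermostat not in _THERMOSTATS:
            raise ValueError(f"unknown thermostat {self.thermostat!r}")
        if self.init_orientation not in ("parallel", "perpendicular"):
            raise ValueError("init_orientation must be parallel|perpendicular")


@dataclass
class Trajectory:
    """Sampled conformations with timestamps and provenance.

    ``frames`` has shape (n_frames, N, 3); ``provenance`` records how the
    frames were produced (sampler, seed, force field, geometry, run
    statistics) and is echoed into every output file header.
    """

    frames: np.ndarray
    times: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (F, N, 3)")
        if self.times.shape[0] != self.frames.shape[0]:
            raise ValueError("one timestamp per frame required")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_beads(self) -> int:
        return self.frames.shape[1]

    def states(self) -> Iterator[ChainState]:
        for i in range(self.n_frames):
            yield ChainState(self.frames[i])

    @staticmethod
    def concatenate(trajs: list["Trajectory"]) -> "Trajectory":
        frames = np.concatenate([t.frames for t in trajs], axis=0)
        times = np.concatenate([t.times for t in trajs], axis=0)
        prov = {"pooled_from": [t.provenance for t in trajs]}
        return Trajectory(frames, times, prov)


def init_conformation(
    N: int,
    array: Optional[PostArray],
    orientation: str = "parallel",
    p: ForceFieldParams = ForceFieldParams(),
) -> ChainState:
    """Straight chain at bond spacing <l>, as the starting configuration.

    ``parallel`` lays the chain along x through the centre of cell (0, 0);
    ``perpendicular`` lays it along y at z = S_p/2, x = 0 (crossing many
    cells).  With no array the chain lies along x through the origin.
    """
    if N < 2:
        raise ValueError("need at least two beads")
    pos = np.zeros((N, 3))
    span = np.arange(N) * p.mean_bond
    if array is None:
        pos[:, 0] = span
    elif orientation == "parallel":
        pos[:, 0] = span
        pos[:, 1] = 0.5 * array.S_p
        pos[:, 2] = 0.5 * array.S_p
    elif orientation == "perpendicular":
        pos[:, 1] = span
        pos[:, 2] = 0.5 * array.S_p
    else:
        raise ValueError("orientation must be parallel|perpendicular")
    return ChainState(pos)


def _soft_pushoff(
    pos: np.ndarray,
    array: PostArray,
    p: ForceFieldParams,
    n_steps: int = 500,
    max_disp: float = 0.05,
) -> np.ndarray:
    """Capped-displacement steepest descent to relax bead-post overlaps.

    Replaces a long thermal pre-equilibration for starting configurations
    that graze the posts: each step moves beads along the force direction
    with per-bead displacement capped at ``max_disp``.
    """
    from .model import total_forces

    pos = pos.copy()
    for _ in range(n_steps):
        f = total_forces(ChainState(pos), array, p)
        norm = np.linalg.norm(f, axis=1, keepdims=True)
        step = np.where(norm > 0, np.minimum(norm, max_disp / 1.0) / np.maximum(norm, 1e-300), 0.0)
        pos = pos + 0.01 * f * step  # displacement <= 0.01*max per step
        big = np.linalg.norm(f, axis=1).max()
        if big < 50.0:
            break
    return pos


def integrate(
    state: ChainState,
    array: Optional[PostArray],
    p: ForceFieldParams,
    cfg: SimulationConfig,
) -> Trajectory:
    """Run NVT dynamics from ``state`` and return the sampled trajectory.

    Deterministic for a given seed and configuration.  Raises
    :class:`OverstretchError`/:class:`OverlapError` with the failing step
    index if the integration blows up.
    """
    rng = np.random.default_rng(cfg.seed)
    pos = state.positions.copy()
    n = pos.shape[0]

    if array is not None:
        # relax configurations that start too close to a post
        yz = pos[:, 1:] - np.floor(pos[:, 1:] / array.S_p + 0.5) * array.S_p
        # distance to nearest post axis (nearest lattice node)
        d = np.linalg.norm(yz, axis=1)
        if np.any(d - array.D_p / 2.0 < 0.9 * p.sigma):
            pos = _soft_pushoff(pos, array, p)

    # Maxwell-Boltzmann velocities at T with zero total momentum
    vel = rng.normal(0.0, np.sqrt(cfg.temperature), size=(n, 3))
    vel -= vel.mean(axis=0)

    n_frames = cfg.n_prod // cfg.sample_stride
    frames = np.empty((n_frames, n, 3))
    times = np.empty(n_frames)
    temps = np.empty(n_frames)
    epots = np.empty(n_frames)

    use_posts = array is not None
    status, fail_step, written = K.run_nvt(
        pos, vel,
        p.kappa, p.r_max**2, p.stiffness * p.kBT,
        use_posts,
        array.S_p if use_posts else 1.0,
        array.D_p / 2.0 if use_posts else 0.0,
        cfg.dt, cfg.n_equil, cfg.n_prod, cfg.sample_stride,
        _THERMOSTATS[cfg.thermostat], cfg.thermostat_tau, cfg.temperature,
        cfg.langevin_gamma, cfg.seed % (2**31),
        frames, times, temps, epots,
    )
    if status == K.STATUS_OVERSTRETCH:
        raise OverstretchError(
            f"bond reached R_o at step {fail_step} ({written} frames saved)")
    if status == K.STATUS_OVERLAP:
        raise OverlapError(
            f"bead entered a post at step {fail_step} ({written} frames saved)")

    prov = {
        "sampler": "md",
        "thermostat": cfg.thermostat,
        "seed": cfg.seed,
        "dt": cfg.dt,
        "n_equil": cfg.n_equil,
        "n_prod": cfg.n_prod,
        "sample_stride": cfg.sample_stride,
        "stiffness": p.stiffness,
        "mean_kinetic_T": float(temps[:written].mean()) if written else float("nan"),
        "mean_potential": float(epots[:written].mean()) if written else float("nan"),
        # per-frame series (arrays are kept out of text headers by the writer)
        "kinetic_T_series": temps[:written],
        "potential_series": epots[:written],
    }
    if array is not None:
        prov.update({"S_p": array.S_p, "D_p": array.D_p})
    return Trajectory(frames[:written], times[:written], prov)


# -- Monte Carlo sampler for free chains -------------------------------------

def _random_rotation(rng: np.random.Generator, max_angle: float = np.pi) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(-max_angle, max_angle)
    return _axis_angle_matrix(axis, angle)


def _axis_angle_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


def _joint_bend_energy(pos: np.ndarray, joints, bkt: float) -> float:
    """Bending energy restricted to the given interior joints."""
    if bkt == 0.0:
        return 0.0
    e = 0.0
    n = pos.shape[0]
    for m in joints:
        if m < 1 or m > n - 2:
            continue
        b1 = pos[m] - pos[m - 1]
        b2 = pos[m + 1] - pos[m]
        c = np.dot(b1, b2) / (np.linalg.norm(b1) * np.linalg.norm(b2))
        e += bkt * (1.0 - min(1.0, max(-1.0, c)))
    return e


def _fene_pair_energy(pos: np.ndarray, bonds, kappa: float, r_max2: float) -> float:
    e = 0.0
    n = pos.shape[0]
    for i in bonds:
        if i < 0 or i > n - 2:
            continue
        l2 = float(np.sum((pos[i + 1] - pos[i]) ** 2))
        if l2 >= r_max2:
            return np.inf
        e += -0.5 * kappa * r_max2 * np.log1p(-l2 / r_max2)
    return e


def pivot_sample(
    N: int,
    p: ForceFieldParams = ForceFieldParams(),
    n_samples: int = 200,
    seed: int = 0,
    stride: int = 40,
    n_equil_moves: Optional[int] = None,
    move_mix: tuple = (0.6, 0.2, 0.2),
    local_delta: float = 0.18,
    crank_max_span: Optional[int] = None,
) -> Trajectory:
    """Equilibrium Metropolis sampling of a *free* chain.

    One frame is stored every ``stride`` attempted moves after
    ``n_equil_moves`` equilibration moves (default 25*N).  ``move_mix``
    gives the pivot/crankshaft/displacement proposal probabilities.
    Reports move acceptance rates and the lag-1 autocorrelation of R_g^2
    between stored frames in the provenance.
    """
    rng = np.random.default_rng(seed)
    bkt = p.stiffness * p.kBT
    r_max2 = p.r_max**2
    if n_equil_moves is None:
        n_equil_moves = 25 * N
    if crank_max_span is None:
        crank_max_span = max(4, N // 4)

    pos = init_conformation(N, None, p=p).positions.copy()
    # a gentle initial bend so the straight start is not a bending-energy
    # stationary point for stiff chains
    frames = np.empty((n_samples, N, 3))
    times = np.empty(n_samples)
    p_pivot, p_crank, _ = move_mix
    att = np.zeros(3, dtype=int)
    acc = np.zeros(3, dtype=int)

    total_moves = n_equil_moves + n_samples * stride
    written = 0
    for move in range(total_moves):
        u = rng.uniform()
        if u < p_pivot:
            kind = 0
            k = int(rng.integers(1, N - 1))
            rot = _random_rotation(rng)
            head = k < N - 1 - k  # rotate the shorter arm
            if head:
                moved_idx = slice(0, k)
                fixed_idx = slice(k, N)
            else:
                moved_idx = slice(k + 1, N)
                fixed_idx = slice(0, k + 1)
            old_moved = pos[moved_idx]
            new_moved = (old_moved - pos[k]) @ rot.T + pos[k]
            fixed = pos[fixed_idx]
            e_old = K.wca_cross_energy(old_moved, fixed, np.inf)
            e_old += _joint_bend_energy(pos, (k,), bkt)
            cap = e_old + 45.0
            e_new = K.wca_cross_energy(new_moved, fixed, cap)
            if e_new < cap:
                trial = pos.copy()
                trial[moved_idx] = new_moved
                e_new += _joint_bend_energy(trial, (k,), bkt)
            else:
                trial = None
        elif u < p_pivot + p_crank:
            kind = 1
            i = int(rng.integers(0, N - 3))
            j = int(rng.integers(i + 2, min(N, i + 2 + crank_max_span)))
            axis = pos[j] - pos[i]
            nrm = np.linalg.norm(axis)
            if nrm < 1e-12:
                continue
            rot = _axis_angle_matrix(axis / nrm, rng.uniform(-np.pi, np.pi))
            moved_idx = slice(i + 1, j)
            old_moved = pos[moved_idx]
            new_moved = (old_moved - pos[i]) @ rot.T + pos[i]
            fixed = np.concatenate([pos[: i + 1], pos[j:]], axis=0)
            e_old = K.wca_cross_energy(old_moved, fixed, np.inf)
            e_old += _joint_bend_energy(pos, (i, j), bkt)
            cap = e_old + 45.0
            e_new = K.wca_cross_energy(new_moved, fixed, cap)
            if e_new < cap:
                trial = pos.copy()
                trial[moved_idx] = new_moved
                e_new += _joint_bend_energy(trial, (i, j), bkt)
            else:
                trial = None
        else:
            kind = 2
            m = int(rng.integers(0, N))
            disp = rng.uniform(-local_delta, local_delta, size=3)
            new_point = pos[m] + disp
            bonds = (m - 1, m)
            joints = (m - 1, m, m + 1)
            e_old = K.wca_one_vs_rest(pos, m, pos[m], np.inf)
            e_old += _fene_pair_energy(pos, bonds, p.kappa, r_max2)
            e_old += _joint_bend_energy(pos, joints, bkt)
            cap = e_old + 45.0
            e_new = K.wca_one_vs_rest(pos, m, new_point, cap)
            if e_new < cap:
                trial = pos.copy()
                trial[m] = new_point
                ef = _fene_pair_energy(trial, bonds, p.kappa, r_max2)
                e_new += ef + _joint_bend_energy(trial, joints, bkt)
            else:
                trial = None

        att[kind] += 1
        if trial is not None and np.isfinite(e_new):
            de = e_new - e_old
            if de <= 0.0 or rng.uniform() < np.exp(-de / p.kBT):
                pos = trial
                acc[kind] += 1

        done_equil = move - n_equil_moves + 1
        if done_equil > 0 and done_equil % stride == 0 and written < n_samples:
            frames[written] = pos
            times[written] = float(move + 1)
            written += 1

    rg2 = np.array([_rg2(frames[i]) for i in range(written)])
    ac1 = float("nan")
    if written > 3 and rg2.std() > 0:
        x = rg2 - rg2.mean()
        ac1 = float(np.dot(x[:-1], x[1:]) / np.dot(x, x))
    prov = {
        "sampler": "pivot-mc",
        "seed": seed,
        "stride": stride,
        "n_equil_moves": n_equil_moves,
        "stiffness": p.stiffness,
        "acceptance": {
            "pivot": _rate(acc[0], att[0]),
            "crankshaft": _rate(acc[1], att[1]),
            "displacement": _rate(acc[2], att[2]),
        },
        "rg2_lag1_autocorr": ac1,
    }
    return Trajectory(frames[:written], times[:written], prov)


def _rate(a: int, n: int) -> float:
    return float(a) / n if n else float("nan")


def _rg2(pos: np.ndarray) -> float:
    d = pos - pos.mean(axis=0)
    return float(np.mean(np.sum(d * d, axis=1)))
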