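"""Deterministic toy conformations and synthetic S(q) curves.

These generators produce configurations whose observables are known
exactly by construction (span of a rod, occupation of a U-turn, hump
position of a synthetic structure factor), so the analysis code is
testable without running any simulation.  They emulate geometric motifs
of confined chains — stretched fragments, hairpins around a post — not
equilibrium Boltzmann statistics; that is the samplers' job.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .geometry import PostArray
from .model import ChainState
from .observables import StructureFactorCurve
from .simulate import Trajectory

__all__ = [
    "make_rod",
    "make_u_turn",
    "make_helix",
    "make_lattice_random",
    "make_synthetic_sq",
    "as_trajectory",
]

_AXES = {"x": 0, "y": 1, "z": 2}


def as_trajectory(*states: ChainState, kind: str = "fixture") -> Trajectory:
    """Stack fixture states into a single-replica trajectory."""
    frames = np.stack([s.positions for s in states])
    return Trajectory(frames, np.arange(len(states), dtype=float),
                      {"sampler": kind})


def make_rod(N: int, l: float = 0.97, axis: str = "x",
             origin=(0.0, 0.0, 0.0)) -> ChainState:
    """Straight chain of N beads at spacing l along a coordinate axis.

    Its span along that axis is exactly (N-1)*l and its structure factor
    shows the rod slope -1 between the chain and the bond scale.
    """
    if N < 2:
        raise ValueError("need at least two beads")
    if not 0 < l < 1.5:
        raise ValueError("bond length must lie in (0, R_o)")
    pos = np.tile(np.asarray(origin, dtype=float), (N, 1))
    pos[:, _AXES[axis]] += np.arange(N) * l
    return ChainState(pos)


def make_u_turn(array: PostArray, cells: tuple[tuple[int, int], tuple[int, int]],
                N: int, l: float = 0.97) -> ChainState:
    """Hairpin spanning two adjacent interstitial cells.

    Two antiparallel x-aligned strands, one through each cell centre,
    joined by a turn that threads the shared passage aperture.  The
    occupation number is exactly 2 and the strand separation exactly
    S_p, the motif behind the inter-strand hump of S(q) at q ~ 2*pi/S_p.
    """
    (i1, j1), (i2, j2) = cells
    if abs(i1 - i2) + abs(j1 - j2) != 1:
        raise ValueError("cells must be lattice-adjacent")
    if N % 2 or N < 6:
        raise ValueError("N must be even and >= 6")
    sp = array.S_p
    c1 = np.array([(i1 + 0.5) * sp, (j1 + 0.5) * sp])
    c2 = np.array([(i2 + 0.5) * sp, (j2 + 0.5) * sp])
    # turn beads bridge the gap between the strand ends at spacing <= l
    n_turn = int(np.ceil(sp / l)) + 1
    n_strand = (N - n_turn) // 2
    if n_strand < 2:
        raise ValueError("N too small for this post separation")
    n_turn = N - 2 * n_strand
    pos = np.empty((N, 3))
    # strand 1 along +x in cell 1
    pos[:n_strand, 0] = np.arange(n_strand) * l
    pos[:n_strand, 1] = c1[0]
    pos[:n_strand, 2] = c1[1]
    # turn: from end of strand 1 to start of strand 2 through the aperture
    x_end = (n_strand - 1) * l
    frac = np.linspace(0.0, 1.0, n_turn + 2)[1:-1]
    pos[n_strand:n_strand + n_turn, 0] = x_end
    pos[n_strand:n_strand + n_turn, 1] = c1[0] + frac * (c2[0] - c1[0])
    pos[n_strand:n_strand + n_turn, 2] = c1[1] + frac * (c2[1] - c1[1])
    # strand 2 along -x in cell 2
    pos[n_strand + n_turn:, 0] = x_end - np.arange(n_strand) * l
    pos[n_strand + n_turn:, 1] = c2[0]
    pos[n_strand + n_turn:, 2] = c2[1]
    return ChainState(pos)


def make_helix(N: int, l: float = 0.97, radius: float = 1.5,
               pitch_angle: float = 0.4, axis: str = "x") -> ChainState:
    """Regular helix with bond length exactly l; a smooth non-planar
    test conformation with tunable axial extension."""
    if N < 2:
        raise ValueError("need at least two beads")
    dz = l * np.sin(pitch_angle)
    chord = l * np.cos(pitch_angle)
    dphi = 2.0 * np.arcsin(chord / (2.0 * radius))
    t = np.arange(N)
    pos = np.empty((N, 3))
    k = _AXES[axis]
    pos[:, k] = t * dz
    pos[:, (k + 1) % 3] = radius * np.cos(t * dphi)
    pos[:, (k + 2) % 3] = radius * np.sin(t * dphi)
    return ChainState(pos)


def make_lattice_random(array: PostArray, cells: list[tuple[int, int]],
                        N: int, seed: int = 0,
                        x_extent: float = 10.0) -> ChainState:
    """Beads scattered uniformly over the given interstitial cells.

    Not a bonded chain (bond invariants are not honoured): ground truth
    for occupation counting — the visited cell set is exactly ``cells``
    when N >= len(cells) (each cell is guaranteed one bead).
    """
    if N < len(cells):
        raise ValueError("need at least one bead per requested cell")
    rng = np.random.default_rng(seed)
    sp = array.S_p
    assign = np.concatenate([np.arange(len(cells)),
                             rng.integers(0, len(cells), N - len(cells))])
    pos = np.empty((N, 3))
    pos[:, 0] = rng.uniform(0.0, x_extent, N)
    # keep beads in the open middle of each cell, clear of posts
    frac = rng.uniform(0.3, 0.7, size=(N, 2))
    for b, ci in enumerate(assign):
        i, j = cells[ci]
        pos[b, 1] = (i + frac[b, 0]) * sp
        pos[b, 2] = (j + frac[b, 1]) * sp
    state = ChainState.__new__(ChainState)
    state.positions = pos  # bypass bonded-chain validation deliberately
    return state


def make_synthetic_sq(bump_q: float, bump_width: float = 0.05,
                      amplitude: float = 0.3,
                      grid: Optional[np.ndarray] = None) -> StructureFactorCurve:
    """Synthetic S(q): q^-1 background times a Gaussian bump at bump_q.

    Ground truth for hump detection; with amplitude 0 the curve is a
    pure power law and no hump exists.
    """
    if grid is None:
        grid = np.geomspace(0.02, 2.0 * np.pi, 400)
    grid = np.asarray(grid, dtype=float)
    if not grid[0] < bump_q < grid[-1]:
        raise ValueError("bump_q must lie inside the grid")
    bump = 1.0 + amplitude * np.exp(-0.5 * ((grid - bump_q) / bump_width) ** 2)
    S = (grid[0] / grid) * bump
    S = S / S.max()  # keep S within (0, 1]
    return StructureFactorCurve(q=grid, S=S, n_frames=1)
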