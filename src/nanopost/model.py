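"""Reduced-unit force field for the confined bead-spring chain.

The chain is a touching-bead worm-like chain: beads of size ``sigma``
joined by FENE springs, with a purely repulsive WCA potential acting
between *all* bead pairs (bonded neighbours included) and between beads
and the cylindrical posts of the array.  A discrete bending potential
``b*k_BT*(1 + cos(theta))`` controls stiffness; ``b = 0`` is the fully
flexible chain and ``b = 20`` maps double-stranded DNA at high ionic
strength (P ~ 50 nm, backbone width ~ 2.5 nm).

Energies are in units of epsilon (= k_BT, since T = epsilon/k_B) and
lengths in units of sigma.  All functions are vectorised over numpy
arrays where that is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ForceFieldParams",
    "ChainState",
    "EnergyBreakdown",
    "WCA_CUTOFF",
    "wca_pair_energy",
    "post_monomer_energy",
    "fene_energy",
    "bending_energy",
    "total_energy",
    "total_forces",
]

#: WCA cutoff distance, 2^(1/6) sigma: the minimum of the LJ potential,
#: beyond which the shifted potential is exactly zero.
WCA_CUTOFF: float = 2.0 ** (1.0 / 6.0)


class OverlapError(ValueError):
    """A bead sits inside a post (divergent monomer-post energy)."""


class OverstretchError(ValueError):
    """A FENE bond reached or exceeded its maximal length R_o."""


@dataclass(frozen=True)
class ForceFieldParams:
    """Interaction constants of the chain/post model, in reduced units.

    Parameters
    ----------
    epsilon : float
        Lennard-Jones energy unit (and k_BT, since T = epsilon/k_B).
    sigma : float
        Lennard-Jones length unit = bead diameter.
    kappa : float
        FENE spring constant, units epsilon/sigma^2.
    r_max : float
        FENE maximal bond length R_o, units sigma.
    stiffness : float
        Dimensionless bending parameter b = B/(l k_BT); 0 for a flexible
        chain, 20 for the DNA-like semiflexible chain.
    bead_width : float
        Effective bead size w (enters the effective post diameter and
        the confinement theory); a model constant, ~0.9 sigma.
    mean_bond : float
        Mean effective bond length <l> produced by FENE+WCA at T=1;
        a model constant, ~0.97 sigma.
    """

    epsilon: float = 1.0
    sigma: float = 1.0
    kappa: float = 30.0
    r_max: float = 1.5
    stiffness: float = 0.0
    bead_width: float = 0.9
    mean_bond: float = 0.97

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.r_max <= self.sigma:
            raise ValueError("r_max must exceed sigma")
        if self.stiffness < 0:
            raise ValueError("stiffness must be non-negative")
        if not 0 < self.bead_width < self.sigma * WCA_CUTOFF:
            raise ValueError("bead_width outside (0, 2^(1/6) sigma)")
        if not self.bead_width < self.mean_bond < self.r_max:
            raise ValueError("mean_bond outside (bead_width, r_max)")

    @property
    def kBT(self) -> float:
        """Thermal energy; the model fixes T = epsilon/k_B."""
        return self.epsilon


@dataclass
class ChainState:
    """Bead coordinates of a single chain, x collinear with the post axes."""

    positions: np.ndarray  # (N, 3) float64, sigma units

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] < 2:
            raise ValueError("positions must be an (N>=2, 3) array")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        self.positions = pos

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def bond_vectors(self) -> np.ndarray:
        return np.diff(self.positions, axis=0)

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.bond_vectors(), axis=1)

    def validate_bonds(self, p: ForceFieldParams) -> None:
        lmax = float(self.bond_lengths().max())
        if lmax >= p.r_max:
            raise OverstretchError(f"bond length {lmax:.4f} >= R_o = {p.r_max}")


@dataclass
class EnergyBreakdown:
    """Per-term potential energy of a configuration, epsilon units."""

    wca: float = 0.0
    fene: float = 0.0
    bending: float = 0.0
    post: float = 0.0

    @property
    def total(self) -> float:
        return self.wca + self.fene + self.bending + self.post


def wca_pair_energy(r, p: ForceFieldParams = ForceFieldParams()):
    """Weeks-Chandler-Andersen energy of a bead pair at distance ``r``.

    4*eps*[(sigma/r)^12 - (sigma/r)^6] + eps for r < 2^(1/6) sigma,
    exactly zero beyond; continuous at the cutoff.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    s6 = (p.sigma / r) ** 6
    u = np.where(r < WCA_CUTOFF * p.sigma, 4.0 * p.epsilon * (s6 * s6 - s6) + p.epsilon, 0.0)
    return u if u.ndim else float(u)


def post_monomer_energy(r_axis, D_p: float, p: ForceFieldParams = ForceFieldParams()):
    """WCA repulsion between a bead and a post of geometric diameter D_p.

    The pair distance is shifted by the post radius: the potential acts on
    r_axis - D_p/2, the distance from the bead centre to the post surface.
    """
    r_axis = np.asarray(r_axis, dtype=float)
    shifted = r_axis - D_p / 2.0
    if np.any(shifted <= 0):
        raise OverlapError("bead at or inside the post surface")
    return wca_pair_energy(shifted, p)


def fene_energy(l, p: ForceFieldParams = ForceFieldParams()):
    """FENE bond energy -(kappa/2) R_o^2 ln[1 - (l/R_o)^2]; diverges at R_o."""
    l = np.asarray(l, dtype=float)
    if np.any(l < 0):
        raise ValueError("bond length must be non-negative")
    if np.any(l >= p.r_max):
        raise OverstretchError("bond length >= R_o")
    x = (l / p.r_max) ** 2
    u = -0.5 * p.kappa * p.r_max**2 * np.log1p(-x)
    return u if u.ndim else float(u)


def bending_energy(theta, p: ForceFieldParams = ForceFieldParams()):
    """Bending energy b*k_BT*(1 + cos(theta)) of a valence angle.

    ``theta`` is the angle between the two bonds meeting at a bead, so a
    straight chain has theta = pi and zero energy (cos(theta) equals
    minus the dot product of consecutive bond unit vectors).
    """
    c = np.clip(np.cos(np.asarray(theta, dtype=float)), -1.0, 1.0)
    u = p.stiffness * p.kBT * (1.0 + c)
    return u if u.ndim else float(u)


# -- whole-configuration energy and forces -----------------------------------

def _pair_wca_energy_sum(pos: np.ndarray, p: ForceFieldParams) -> float:
    from scipy.spatial.distance import pdist

    d = pdist(pos)
    d = d[d < WCA_CUTOFF * p.sigma]
    if d.size == 0:
        return 0.0
    s6 = (p.sigma / d) ** 6
    return float(np.sum(4.0 * p.epsilon * (s6 * s6 - s6) + p.epsilon))


def _post_energy_sum(pos: np.ndarray, array, p: ForceFieldParams) -> float:
    # lazy import to avoid a cycle: geometry imports nothing from here
    yz = pos[:, 1:]
    base = np.floor(yz / array.S_p)
    e = 0.0
    # the four lattice posts bounding each bead's cell; posts farther away
    # cannot be within the WCA cutoff because S_p > cutoff in any valid array
    for dy in (0.0, 1.0):
        for dz in (0.0, 1.0):
            axes = (base + np.array([dy, dz])) * array.S_p
            r_axis = np.linalg.norm(yz - axes, axis=1)
            shifted = r_axis - array.D_p / 2.0
            if np.any(shifted <= 0):
                raise OverlapError("bead inside a post")
            mask = shifted < WCA_CUTOFF * p.sigma
            if mask.any():
                e += float(np.sum(wca_pair_energy(shifted[mask], p)))
    return e


def total_energy(state: ChainState, array=None, p: ForceFieldParams = ForceFieldParams()) -> EnergyBreakdown:
    """Full potential energy of a chain configuration, split by term.

    WCA acts between every bead pair, bonded neighbours included; FENE on
    consecutive pairs; bending on consecutive bond pairs; monomer-post WCA
    against the (infinite) square lattice of posts when ``array`` is given.
    """
    pos = state.positions
    out = EnergyBreakdown()
    out.wca = _pair_wca_energy_sum(pos, p)
    out.fene = float(np.sum(fene_energy(state.bond_lengths(), p)))
    if p.stiffness > 0 and pos.shape[0] >= 3:
        u = state.bond_vectors()
        u = u / np.linalg.norm(u, axis=1, keepdims=True)
        dots = np.clip(np.sum(u[:-1] * u[1:], axis=1), -1.0, 1.0)
        out.bending = float(np.sum(p.stiffness * p.kBT * (1.0 - dots)))
    if array is not None:
        out.post = _post_energy_sum(pos, array, p)
    return out


def total_forces(state: ChainState, array=None, p: ForceFieldParams = ForceFieldParams()) -> np.ndarray:
    """Analytic forces (negative energy gradient) on every bead.

    Reference numpy implementation; the MD integrator uses an equivalent
    jitted kernel that is tested against this one.
    """
    pos = state.positions
    n = pos.shape[0]
    f = np.zeros_like(pos)

    # WCA: all pairs within cutoff
    diff = pos[:, None, :] - pos[None, :, :]  # r_i - r_j
    d2 = np.sum(diff * diff, axis=-1)
    np.fill_diagonal(d2, np.inf)
    cut2 = (WCA_CUTOFF * p.sigma) ** 2
    iu, ju = np.where(np.triu(d2 < cut2, k=1))
    if iu.size:
        rij = diff[iu, ju]
        r2 = d2[iu, ju]
        s6 = (p.sigma**2 / r2) ** 3
        # dU/dr * (1/r) = -24 eps (2 s12 - s6) / r^2
        coef = 24.0 * p.epsilon * (2.0 * s6 * s6 - s6) / r2
        fij = coef[:, None] * rij  # force on i from j
        np.add.at(f, iu, fij)
        np.add.at(f, ju, -fij)

    # FENE bonds
    b = np.diff(pos, axis=0)
    l2 = np.sum(b * b, axis=1)
    if np.any(l2 >= p.r_max**2):
        raise OverstretchError("bond length >= R_o")
    coef = p.kappa / (1.0 - l2 / p.r_max**2)
    fb = coef[:, None] * b  # pulls bead i toward bead i+1
    f[:-1] += fb
    f[1:] -= fb

    # bending: U = b_kT * (1 - u_i . u_{i+1}) summed over joints
    if p.stiffness > 0 and n >= 3:
        bk = p.stiffness * p.kBT
        l = np.sqrt(l2)
        u = b / l[:, None]
        for i in range(n - 2):
            u1, u2 = u[i], u[i + 1]
            l1, l2i = l[i], l[i + 1]
            c = float(np.dot(u1, u2))
            dcdr1 = (u2 - c * u1) / l1
            dcdr2 = (u1 - c * u2) / l2i
            # U = bk (1 - c); F = bk * dc/dx
            f[i] += -bk * dcdr1
            f[i + 1] += bk * (dcdr1 - dcdr2)
            f[i + 2] += bk * dcdr2

    # posts
    if array is not None:
        yz = pos[:, 1:]
        base = np.floor(yz / array.S_p)
        for dy in (0.0, 1.0):
            for dz in (0.0, 1.0):
                axes = (base + np.array([dy, dz])) * array.S_p
                rv = yz - axes
                r_axis = np.linalg.norm(rv, axis=1)
                shifted = r_axis - array.D_p / 2.0
                if np.any(shifted <= 0):
                    raise OverlapError("bead inside a post")
                mask = shifted < WCA_CUTOFF * p.sigma
                if mask.any():
                    s6 = (p.sigma / shifted[mask]) ** 6
                    dudr = -24.0 * p.epsilon * (2.0 * s6 * s6 - s6) / shifted[mask]
                    # force along the outward radial direction in the yz plane
                    fr = (-dudr / r_axis[mask])[:, None] * rv[mask]
                    f[mask, 1:] += fr
    return f
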