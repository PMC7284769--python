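"""Square-lattice nanopost array geometry and derived confinement descriptors.

The array is an infinite square lattice (spacing ``S_p``) of parallel
cylindrical posts with axes along x.  A chain lives in the interstitial
space; each interstitial volume is gauged by a quasi-channel of diameter
``d_c = sqrt(2)*S_p - d_p`` and each passage between two adjacent posts by
a quasi-slit of height ``w_p = S_p - d_p``, where ``d_p = D_p + w`` is the
effective post diameter (geometric diameter plus bead width).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import ForceFieldParams, WCA_CUTOFF, post_monomer_energy

__all__ = [
    "PostArray",
    "derive_parameters",
    "nearest_posts",
    "cell_index",
    "passage_barrier",
    "min_translocation_separation",
]


@dataclass(frozen=True)
class PostArray:
    """Geometry of a square-lattice post array with its derived descriptors.

    Attributes
    ----------
    S_p : float
        Separation of adjacent post axes (sigma).
    D_p : float
        Geometric post diameter (sigma).
    d_p : float
        Effective post diameter D_p + w (sigma).
    w_p : float
        Passage width S_p - d_p: closest wall-to-wall distance (sigma).
    d_c : float
        Quasi-channel diameter sqrt(2)*S_p - d_p, the gauge of the
        interstitial volume bounded by four posts (sigma).
    F : float
        Post volume fraction pi*d_p^2/(4*S_p^2).
    """

    S_p: float
    D_p: float
    d_p: float
    w_p: float
    d_c: float
    F: float

    @property
    def ratio(self) -> float:
        """Confinement ratio d_c/w_p."""
        return self.d_c / self.w_p


def derive_parameters(S_p: float, D_p: float, w: float = 0.9) -> PostArray:
    """Build a :class:`PostArray` from the primary geometric parameters.

    Parameters
    ----------
    S_p, D_p : float
        Post-axis separation and geometric post diameter (sigma).
    w : float
        Effective bead width, default 0.9 sigma.
    """
    if w <= 0:
        raise ValueError("bead width must be positive")
    if D_p < 0 or S_p < D_p:
        raise ValueError("overlapping posts: need S_p >= D_p >= 0")
    d_p = D_p + w
    return PostArray(
        S_p=float(S_p),
        D_p=float(D_p),
        d_p=d_p,
        w_p=S_p - d_p,
        d_c=math.sqrt(2.0) * S_p - d_p,
        F=math.pi * d_p**2 / (4.0 * S_p**2),
    )


def cell_index(y, z, array: PostArray):
    """Interstitial-cell label (i, j) = (floor(y/S_p), floor(z/S_p)).

    Cells tile the yz plane with the half-open convention
    [i*S_p, (i+1)*S_p); a point exactly on a lattice line belongs to the
    higher-index cell.
    """
    i = np.floor(np.asarray(y, dtype=float) / array.S_p).astype(int)
    j = np.floor(np.asarray(z, dtype=float) / array.S_p).astype(int)
    if i.ndim == 0:
        return int(i), int(j)
    return i, j


def nearest_posts(y: float, z: float, array: PostArray) -> np.ndarray:
    """(y, z) axis coordinates of the four posts bounding the point's cell."""
    i, j = cell_index(y, z, array)
    corners = np.array(
        [[i, j], [i + 1, j], [i, j + 1], [i + 1, j + 1]], dtype=float
    )
    return corners * array.S_p


def passage_barrier(array: PostArray, p: ForceFieldParams = ForceFieldParams()) -> float:
    """Energy (k_BT) of one bead at the midpoint of a passage aperture.

    The bead sits halfway between two adjacent post surfaces, i.e. at axis
    distance S_p/2 from each flanking post; every lattice post within the
    WCA cutoff contributes.  This is the barrier a monomer must overcome
    to translocate into the neighbouring interstitial volume.
    """
    # midpoint of the aperture between posts (0,0) and (S_p,0)
    point = np.array([array.S_p / 2.0, 0.0])
    cut = array.D_p / 2.0 + WCA_CUTOFF * p.sigma
    # scan a small patch of lattice posts around the midpoint
    e = 0.0
    for iy in range(-2, 3):
        for iz in range(-2, 3):
            axis = np.array([iy * array.S_p, iz * array.S_p])
            r = float(np.linalg.norm(point - axis))
            if r < cut:
                e += post_monomer_energy(r, array.D_p, p)
    return e / p.kBT


def min_translocation_separation(D_p: float, w: float = 0.9) -> float:
    """Smallest post separation S_p at which a bead fits through a passage.

    The passage width w_p = S_p - d_p must reach the bead width w, giving
    S_p = d_p + w = D_p + 2w.
    """
    if D_p < 0 or w <= 0:
        raise ValueError("need D_p >= 0 and w > 0")
    return D_p + 2.0 * w
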