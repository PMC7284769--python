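"""Confinement free energies, partition ratios, extension laws and
structure-factor slope predictions for a chain in a nanopost array.

The interstitial volume bounded by four posts is approximated as a
square channel of side d_c and the passage aperture between two adjacent
posts as a slit of height w_p; a slit costs half the free energy of the
square channel of equal size.  Equating the free energy *per unit
contour length* of chain fragments in the quasi-channel and quasi-slit
yields the partition ratio L_qc/L_qs of contour stored in interstitial
volumes versus apertures, which rationalises the occupation-number
trends.  The numerical prefactors below come from exact/asymptotic
channel results for ideal geometries and are order-of-magnitude guides
for the quasi-geometries of the array, not sharp constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "DEGENNES_CHANNEL_PREFACTOR",
    "ODIJK_CHANNEL_PREFACTOR",
    "ODIJK_EXTENSION_A",
    "RegimePrediction",
    "degennes_channel_dA",
    "odijk_channel_dA",
    "slit_dA",
    "partition_ratio",
    "odijk_extension",
    "degennes_extension",
    "classify_regime",
    "blob_count_extended",
    "slope_windows",
    "predict",
]

#: de Gennes free energy prefactor for a square channel:
#: dA/kBT = 4.0 * L * (P*w)^(1/3) * D^(-5/3)
DEGENNES_CHANNEL_PREFACTOR = 4.0
#: Odijk free energy prefactor for a square channel:
#: dA/kBT = 2.2072 * L * P^(-1/3) * D^(-2/3)
ODIJK_CHANNEL_PREFACTOR = 2.2072
#: Odijk extension constants A in R = L[1 - A*(D/P)^(2/3)]
ODIJK_EXTENSION_A = {"circular": 0.1701, "square": 0.18274}


def _check_positive(**kwargs) -> None:
    for name, v in kwargs.items():
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")


def degennes_channel_dA(L: float, P: float, w: float, D: float) -> float:
    """Free-energy excess (k_BT) of a chain in a square channel, de Gennes
    (blob) regime: 4.0*L*(P*w)^(1/3)*D^(-5/3)."""
    _check_positive(L=L, P=P, w=w, D=D)
    return DEGENNES_CHANNEL_PREFACTOR * L * (P * w) ** (1.0 / 3.0) * D ** (-5.0 / 3.0)


def odijk_channel_dA(L: float, P: float, D: float) -> float:
    """Free-energy excess (k_BT) of a semiflexible chain in a square
    channel, Odijk (deflection) regime: 2.2072*L*P^(-1/3)*D^(-2/3).
    Intended validity D < P."""
    _check_positive(L=L, P=P, D=D)
    return ODIJK_CHANNEL_PREFACTOR * L * P ** (-1.0 / 3.0) * D ** (-2.0 / 3.0)


def slit_dA(channel_dA: float) -> float:
    """Slit free energy: half the square-channel value at the slit height."""
    if channel_dA < 0:
        raise ValueError("channel free energy must be non-negative")
    return 0.5 * channel_dA


def partition_ratio(
    regime_qc: str,
    regime_qs: str,
    d_c: float,
    w_p: float,
    P: Optional[float] = None,
    w: Optional[float] = None,
) -> float:
    """Equilibrium contour-length ratio L_qc/L_qs between interstitial
    volumes (quasi-channels of size d_c) and apertures (quasi-slits of
    height w_p).

    Obtained by equating the free energy per unit contour length in the
    two environments; the slit is half the channel expression.  Regimes:
    'de Gennes' or 'Odijk' for each environment.  The Odijk-channel +
    de Gennes-slit pairing is unphysical (the slit is the *narrower*
    space) and rejected.
    """
    _check_positive(d_c=d_c, w_p=w_p)
    qc = regime_qc.lower().replace(" ", "").replace("-", "")
    qs = regime_qs.lower().replace(" ", "").replace("-", "")
    dg, od = "degennes", "odijk"
    if qc not in (dg, od) or qs not in (dg, od):
        raise ValueError("regimes must be 'de Gennes' or 'Odijk'")
    # per-unit-length free energies a(D): channel a_ch(D), slit a_ch(D)/2
    if qc == dg and qs == dg:
        # 4 (Pw)^{1/3} d_c^{-5/3} * L_qc = (1/2) 4 (Pw)^{1/3} w_p^{-5/3} * L_qs
        return 0.5 * (d_c / w_p) ** (5.0 / 3.0)
    if qc == dg and qs == od:
        if P is None or w is None:
            raise ValueError("mixed de Gennes/Odijk ratio needs P and w")
        _check_positive(P=P, w=w)
        pref = slit_dA(ODIJK_CHANNEL_PREFACTOR) / DEGENNES_CHANNEL_PREFACTOR
        return (
            pref
            * (w_p / P) ** (2.0 / 3.0)
            * (w_p / w) ** (1.0 / 3.0)
            * (d_c / w_p) ** (5.0 / 3.0)
        )
    if qc == od and qs == od:
        return 0.5 * (d_c / w_p) ** (2.0 / 3.0)
    raise ValueError(
        "Odijk quasi-channel with de Gennes quasi-slit is not a physical "
        "pairing (the slit is the narrower space)")


def odijk_extension(L: float, P: float, D: float, cross_section: str = "square") -> float:
    """Odijk axial extension R = L*[1 - A*(D/P)^(2/3)] in a channel.

    A = 0.1701 (circular) or 0.18274 (square cross-section); valid for
    D < P (a warning-free soft validity: callers may evaluate outside).
    """
    _check_positive(L=L, P=P, D=D)
    try:
        A = ODIJK_EXTENSION_A[cross_section]
    except KeyError:
        raise ValueError("cross_section must be 'circular' or 'square'") from None
    return L * (1.0 - A * (D / P) ** (2.0 / 3.0))


def degennes_extension(L: float, P: float, w: float, D: float) -> float:
    """de Gennes axial extension R = L*(w*P/D^2)^(1/3) in a channel."""
    _check_positive(L=L, P=P, w=w, D=D)
    return L * (w * P / D**2) ** (1.0 / 3.0)


def classify_regime(P: float, w: float, D: float) -> str:
    """Confinement regime of a channel of size D for a chain of
    persistence length P and width w.

    Odijk for D < P; extended de Gennes for P < D < P^2/w; classic
    de Gennes for D > P^2/w.  Boundary values take the
    stronger-confinement label.
    """
    _check_positive(P=P, w=w, D=D)
    if D <= P:
        return "Odijk"
    if D <= P * P / w:
        return "extended de Gennes"
    return "classic de Gennes"


def blob_count_extended(L: float, w: float, d_c: float, P: float) -> float:
    """Expected number of asymmetric blobs in the extended de Gennes
    regime, ~ L*(w^2/(d_c^4*P))^(1/3); when this is O(1) or less the
    blob statistics (slope -2) cannot develop."""
    _check_positive(L=L, w=w, d_c=d_c, P=P)
    return L * (w**2 / (d_c**4 * P)) ** (1.0 / 3.0)


def slope_windows(
    P: float,
    w: float,
    D: float,
    R_s: float,
    l: float = 0.97,
) -> list[tuple[float, float, float]]:
    """Predicted log-log slope windows of S(q) for a chain in a channel
    of size D, as ``(q_lo, q_hi, slope)`` tuples, high q first.

    Odijk (D < P): a single -1 window for all q > 2*pi/R_s.  Classic
    de Gennes: -1 at the persistence scale (q > 2*pi/P), -5/3 on
    (2*pi/D, 2*pi/P), -1 for the linear blob array on (2*pi/R_s, 2*pi/D).
    Extended de Gennes: the -2 blob window spans
    (2*pi/(D^2*P^2/w)^(1/3), 2*pi/P).  For a flexible chain (P ~ w ~ l)
    the high-q rod window starts at 2*pi/l instead.  Saturation (slope 0
    here) below 2*pi/R_s.  Empty windows are omitted.
    """
    _check_positive(P=P, w=w, D=D, R_s=R_s, l=l)
    q_sat = 2.0 * np.pi / R_s
    q_top = 2.0 * np.pi / l  # monomer scale: upper end of any prediction
    regime = classify_regime(P, w, D)
    candidates: list[tuple[float, float, float]] = []
    if regime == "Odijk":
        candidates.append((q_sat, q_top, -1.0))
    else:
        q_p = 2.0 * np.pi / max(P, l)
        candidates.append((q_p, q_top, -1.0))
        if regime == "classic de Gennes":
            q_blob = 2.0 * np.pi / D
            slope = -5.0 / 3.0
        else:
            # extended de Gennes: anisometric blobs give slope -2
            q_blob = 2.0 * np.pi / (D**2 * P**2 / w) ** (1.0 / 3.0)
            slope = -2.0
        candidates.append((min(q_blob, q_p), q_p, slope))
        candidates.append((q_sat, min(q_blob, q_p), -1.0))
    # saturation overrides everything below 2*pi/R_s; empty windows
    # (including all degenerate input combinations) are dropped
    windows = []
    for lo, hi, slope in candidates:
        lo = max(lo, q_sat)
        if lo < hi:
            windows.append((lo, hi, slope))
    windows.append((0.0, min(q_sat, q_top), 0.0))
    return windows


@dataclass(frozen=True)
class RegimePrediction:
    """Theory-side summary for one array geometry and one chain."""

    regime_qc: str
    regime_qs: str
    dA_qc: float
    dA_qs: float
    extension: float
    partition: Optional[float]
    blob_count: Optional[float]


def predict(
    L: float,
    P: float,
    w: float,
    d_c: float,
    w_p: float,
) -> list[RegimePrediction]:
    """Regime assignment, free energies, extension and partition ratio
    for a chain (contour L, persistence P, width w) in an array with
    quasi-channel d_c and quasi-slit w_p.

    Returns one prediction per admissible regime pairing: when the
    channel is de Gennes and the slit Odijk-like, both the pure and the
    mixed pairings are physically arguable, so all admissible pairings
    consistent with the individual regime assignments are reported.
    """
    _check_positive(L=L, P=P, w=w, d_c=d_c, w_p=w_p)
    reg_c = classify_regime(P, w, d_c)
    reg_s = classify_regime(P, w, w_p)
    c_label = "Odijk" if reg_c == "Odijk" else "de Gennes"
    s_label = "Odijk" if reg_s == "Odijk" else "de Gennes"

    pairings = {(c_label, s_label)}
    if (c_label, s_label) == ("de Gennes", "Odijk"):
        # the boundary is soft: report the mixed and both pure pairings
        pairings.add(("de Gennes", "de Gennes"))
        pairings.add(("Odijk", "Odijk"))

    out = []
    for qc, qs in sorted(pairings):
        dA_c = (odijk_channel_dA(L, P, d_c) if qc == "Odijk"
                else degennes_channel_dA(L, P, w, d_c))
        dA_s = slit_dA(odijk_channel_dA(L, P, w_p) if qs == "Odijk"
                       else degennes_channel_dA(L, P, w, w_p))
        ext = (odijk_extension(L, P, d_c) if qc == "Odijk"
               else degennes_extension(L, P, w, d_c))
        try:
            part = partition_ratio(qc, qs, d_c, w_p, P, w)
        except ValueError:
            part = None
        blobs = (blob_count_extended(L, w, d_c, P)
                 if reg_c == "extended de Gennes" else None)
        out.append(RegimePrediction(
            regime_qc=qc, regime_qs=qs, dA_qc=dA_c, dA_qs=dA_s,
            extension=min(ext, L), partition=part, blob_count=blobs))
    return out
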