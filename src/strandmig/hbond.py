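"""Hydrogen-bond geometry, the continuous bond-probability statistic, binary
cutoffs, and helix-level averaged fractions.

Two complementary monitors are provided for every Watson-Crick bond in the
construct registry:

* a binary presence criterion — hydrogen-to-acceptor distance below 3.5 A
  and donor-hydrogen-acceptor angle above 145 degrees;
* a continuous hydrogen-bond probability (HBP) in [0, 1] that decays
  exponentially as the bond geometry leaves an ideal reference state,

      HBP = clip( exp(-(d + lambda * (cos theta - cos theta_ref) - d_ref)
                      / lambda), 0, 1 )

  where ``d`` is the hydrogen-acceptor distance and ``theta`` the angle at
  the hydrogen.  The statistic equals 1 at the reference state (and for any
  tighter geometry, via the clamp), is non-increasing as ``d`` grows beyond
  ``d_ref`` or ``theta`` bends away from ``theta_ref``, and tends to 0 as the
  bond opens.  The reference-state parameters are configuration values
  (:class:`HBPParams`), never hard-coded in the operations.

Helix-level fractions average the per-bond statistic over a helix's master
bond list; they are the generalized coordinates of the reduced-landscape
module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registry import ConstructRegistry, HBond
from .trajectory_io import Frame, Trajectory

__all__ = [
    "HBondGeometry",
    "HBPParams",
    "MissingAtomError",
    "hbond_geometry",
    "hbp",
    "binary_hbond",
    "helix_hbp_fraction",
    "hbp_matrix",
    "BINARY_DISTANCE_CUTOFF",
    "BINARY_ANGLE_CUTOFF_DEG",
]

BINARY_DISTANCE_CUTOFF = 3.5  # A
BINARY_ANGLE_CUTOFF_DEG = 145.0


class MissingAtomError(KeyError):
    """An atom required by a hydrogen-bond triple is absent from the frame."""


@dataclass(frozen=True)
class HBondGeometry:
    """Hydrogen-to-acceptor distance (A) and donor-H-acceptor angle (rad)."""

    d: float
    theta: float

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValueError(f"distance must be positive, got {self.d}")
        if not 0 <= self.theta <= math.pi + 1e-9:
            raise ValueError(f"angle {self.theta} outside [0, pi]")


@dataclass(frozen=True)
class HBPParams:
    """Reference-state parameters of the continuous bond statistic.

    d_ref:
        Hydrogen-acceptor distance of the reference state, Angstrom.  The
        default 2.1 A lies at the loose end of ideal WC bond geometries, so
        an ideally formed template bond scores exactly 1.
    theta_ref:
        Reference donor-H-acceptor angle, radians (pi = collinear).
    lambda_scale:
        Exponential decay length, Angstrom.
    """

    d_ref: float = 2.1
    theta_ref: float = math.pi
    lambda_scale: float = 0.5

    def __post_init__(self) -> None:
        if min(self.d_ref, self.theta_ref, self.lambda_scale) <= 0:
            raise ValueError("HBP parameters must be positive")
        if self.theta_ref > math.pi + 1e-9:
            raise ValueError("theta_ref must be <= pi")


DEFAULT_HBP = HBPParams()


def _atom(frame: Frame, resid: int, name: str) -> np.ndarray:
    p = frame.get((resid, name))
    if p is None:
        raise MissingAtomError(f"residue {resid} atom {name} missing from frame")
    return p


def hbond_geometry(frame: Frame, bond: HBond,
                   registry: ConstructRegistry | None = None) -> HBondGeometry:
    """Measure one bond's (distance, angle) geometry in a frame.

    ``bond`` is a registry :class:`~strandmig.registry.HBond` record (or any
    object with donor/h/acceptor residue-and-atom fields).  ``registry`` is
    accepted for interface symmetry; the bond record already carries residue
    identities.
    """
    d_pos = _atom(frame, bond.donor_res, bond.donor_atom)
    h_pos = _atom(frame, bond.donor_res, bond.h_atom)
    a_pos = _atom(frame, bond.acceptor_res, bond.acceptor_atom)
    v1 = d_pos - h_pos
    v2 = a_pos - h_pos
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise ValueError(
            f"degenerate geometry: coincident atoms in bond {bond.bond_id}")
    cos_t = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    return HBondGeometry(float(n2), math.acos(cos_t))


def hbp(geom: HBondGeometry, params: HBPParams = DEFAULT_HBP) -> float:
    """Continuous hydrogen-bond probability of a measured geometry, in [0, 1].

    Equals 1 at the reference state; decays exponentially (length scale
    ``lambda_scale``) as the hydrogen-acceptor distance stretches beyond
    ``d_ref`` or the angle bends away from ``theta_ref``; clamped to [0, 1]
    because the raw exponential exceeds 1 for compressed geometries.
    """
    d_eff = geom.d + params.lambda_scale * (math.cos(geom.theta)
                                            - math.cos(params.theta_ref))
    raw = math.exp(-(d_eff - params.d_ref) / params.lambda_scale)
    return min(max(raw, 0.0), 1.0)


def binary_hbond(geom: HBondGeometry,
                 distance_cutoff: float = BINARY_DISTANCE_CUTOFF,
                 angle_cutoff_deg: float = BINARY_ANGLE_CUTOFF_DEG) -> bool:
    """Binary presence: H-acceptor distance < 3.5 A and angle > 145 degrees."""
    return geom.d < distance_cutoff and math.degrees(geom.theta) > angle_cutoff_deg


def helix_hbp_fraction(frame: Frame, registry: ConstructRegistry, helix: str,
                       params: HBPParams = DEFAULT_HBP,
                       binary: bool = False) -> float:
    """Mean bond statistic over a helix's master bond list for one frame.

    With ``binary=True`` the mean is over the 0/1 presence criterion (the
    fraction of formed bonds); otherwise over the continuous statistic.  The
    result is invariant under any permutation of the bond list.
    """
    bonds = registry.bonds(helix)
    if not bonds:
        raise ValueError(f"helix {helix!r} has an empty bond list")
    vals = []
    for b in bonds:
        g = hbond_geometry(frame, b)
        vals.append(float(binary_hbond(g)) if binary else hbp(g, params))
    return float(np.mean(vals))


def hbp_matrix(traj: Trajectory, registry: ConstructRegistry,
               params: HBPParams = DEFAULT_HBP, helix: str | None = None,
               binary: bool = False) -> pd.DataFrame:
    """Per-frame, per-bond statistic for a whole trajectory (vectorized).

    Returns a DataFrame with one row per frame and one column per bond id
    (the ids of the registry's exported bond list), suitable for direct CSV
    export.
    """
    bonds = [b for b in registry.hbonds if helix is None or b.helix == helix]
    if not bonds:
        raise ValueError("no bonds selected")
    out = np.empty((traj.n_frames, len(bonds)))
    for j, b in enumerate(bonds):
        for key in ((b.donor_res, b.donor_atom), (b.donor_res, b.h_atom),
                    (b.acceptor_res, b.acceptor_atom)):
            if not traj.has_atom(key):
                raise MissingAtomError(f"atom {key} missing from trajectory")
        dpos = traj.atom_series((b.donor_res, b.donor_atom))
        hpos = traj.atom_series((b.donor_res, b.h_atom))
        apos = traj.atom_series((b.acceptor_res, b.acceptor_atom))
        v1 = dpos - hpos
        v2 = apos - hpos
        n1 = np.linalg.norm(v1, axis=1)
        n2 = np.linalg.norm(v2, axis=1)
        cos_t = np.clip((v1 * v2).sum(axis=1) / (n1 * n2), -1.0, 1.0)
        if binary:
            theta = np.degrees(np.arccos(cos_t))
            out[:, j] = (n2 < BINARY_DISTANCE_CUTOFF) & (theta > BINARY_ANGLE_CUTOFF_DEG)
        else:
            d_eff = n2 + params.lambda_scale * (cos_t - math.cos(params.theta_ref))
            out[:, j] = np.clip(
                np.exp(-(d_eff - params.d_ref) / params.lambda_scale), 0.0, 1.0)
    return pd.DataFrame(out, columns=[b.bond_id for b in bonds])
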