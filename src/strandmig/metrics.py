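"""Superposition and RMSD monitors, pseudo-dihedrals, pairwise energies,
contact distances, and clash counting.

Energies here are monitoring proxies, not force-field evaluations: a minimal
Lennard-Jones table over heavy-atom element classes (Lorentz-Berthelot
combining) for stacking monitors, and a screened Debye-Hueckel Coulomb term
(default screening constant 0.19 A^-1) for electrostatic scoring.  Only
relative values and ranks are meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .registry import ConstructRegistry, PairPosition
from .templates import base_heavy_atoms
from .trajectory_io import AtomKey, Frame, Trajectory

__all__ = [
    "LJParams",
    "superpose",
    "base_pair_rmsd",
    "backbone_rmsd",
    "pseudo_dihedral",
    "pseudo_dihedral_series",
    "pseudo_dihedral_histogram",
    "lj_pair_energy",
    "screened_coulomb_energy",
    "contact_distance_series",
    "ContactSeries",
    "steric_clash_count",
    "exclusions_from_bonds",
    "ideal_pair_reference",
    "COULOMB_KCAL",
    "DEBYE_HUCKEL_KAPPA",
]

COULOMB_KCAL = 332.0636  # kcal*A/mol/e^2
DEBYE_HUCKEL_KAPPA = 0.19  # A^-1, inverse screening length

BACKBONE_SELECTION = ("P", "O5'", "C5'", "C4'", "C3'", "O3'")


# ---------------------------------------------------------------------------
# Superposition / RMSD
# ---------------------------------------------------------------------------

def superpose(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of X onto Y (Kabsch).

    Returns ``(R, t, rmsd)`` with ``R`` a proper rotation so that
    ``X @ R.T + t`` best fits ``Y``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(f"point sets must share shape (n, 3); got {X.shape}, {Y.shape}")
    if len(X) < 3:
        raise ValueError("superposition needs at least 3 points")
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    A = (X - xc).T @ (Y - yc)
    U, _, Vt = np.linalg.svd(A)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    diff = (X @ R.T + t) - Y
    rmsd = float(np.sqrt((diff ** 2).sum() / len(X)))
    return R, t, rmsd


def _paired_coords(frame_like, reference: Mapping[AtomKey, np.ndarray],
                   keys: Sequence[AtomKey], strict: bool = True
                   ) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for key in keys:
        ref = reference.get(tuple(key))
        cur = frame_like.get(tuple(key)) if hasattr(frame_like, "get") else None
        if ref is None or cur is None:
            if strict:
                raise KeyError(f"atom {key} missing from frame or reference")
            continue
        xs.append(cur)
        ys.append(ref)
    return np.array(xs), np.array(ys)


def base_pair_rmsd(frame: Frame, position: PairPosition,
                   reference: Mapping[AtomKey, np.ndarray]) -> float:
    """RMSD of a pair's nucleobase heavy atoms after optimal superposition.

    The reference carries ideal template coordinates for the pair (for P1
    positions, the bundled crystal-style P1 pair template; for AT positions,
    the ideal A-form template); see :func:`ideal_pair_reference`.
    """
    keys: list[AtomKey] = []
    for res in (position.res5, position.res3):
        keys.extend((res.hybrid_id, a) for a in base_heavy_atoms(res.base))
    X, Y = _paired_coords(frame, reference, keys, strict=True)
    _, _, rmsd = superpose(X, Y)
    return rmsd


def backbone_rmsd(frame: Frame, selection: Iterable[int],
                  reference: Mapping[AtomKey, np.ndarray]) -> float:
    """Backbone-atom RMSD (P, O5', C5', C4', C3', O3') over a residue set.

    Atoms absent from either the frame or the reference (e.g. a missing 5'
    phosphate) are excluded from the fit; at least three common atoms are
    required.
    """
    keys = [(rid, a) for rid in selection for a in BACKBONE_SELECTION]
    X, Y = _paired_coords(frame, reference, keys, strict=False)
    if len(X) < 3:
        raise ValueError("fewer than 3 backbone atoms shared with reference")
    _, _, rmsd = superpose(X, Y)
    return rmsd


def ideal_pair_reference(registry: ConstructRegistry, position: PairPosition
                         ) -> dict[AtomKey, np.ndarray]:
    """Ideal template coordinates of one pair, in the pair reference frame."""
    from .templates import flip_role, residue_template

    ref: dict[AtomKey, np.ndarray] = {}
    for res, role in ((position.res5, 2 if position.helix == "P1" else 1),
                      (position.res3, 1 if position.helix == "P1" else 2)):
        t = residue_template(res.base)
        if role == 2:
            t = flip_role(t)
        for name, p in t.items():
            ref[(res.hybrid_id, name)] = p
    return ref


# ---------------------------------------------------------------------------
# Pseudo-dihedrals
# ---------------------------------------------------------------------------

def pseudo_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral of four points, degrees in (-180, 180].

    IUPAC sign convention (cis-planar 0, trans-planar 180; reversing the
    point order negates the angle).  Raises on a collinear inner triple.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-9:
        raise ValueError("degenerate quartet: coincident inner points")
    b1u = b1 / nb1
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    if np.linalg.norm(v) < 1e-9 or np.linalg.norm(w) < 1e-9:
        raise ValueError("degenerate quartet: collinear triple")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang == -180.0 else ang


#: default pseudo-atom quartet spanning a dinucleotide step i -> i+1:
#: (C4' of i, P of i+1, C4' of i+1, P of i+2); configurable.
DEFAULT_QUARTET = (("C4'", 0), ("P", 1), ("C4'", 1), ("P", 2))


def pseudo_dihedral_series(traj: Trajectory, resid: int,
                           quartet=DEFAULT_QUARTET) -> np.ndarray:
    """Per-frame pseudo-dihedral of the dinucleotide step starting at resid."""
    keys = [(resid + off, name) for name, off in quartet]
    pts = [traj.atom_series(k) for k in keys]
    return np.array([pseudo_dihedral(*(p[f] for p in pts))
                     for f in range(traj.n_frames)])


def pseudo_dihedral_histogram(samples: Sequence[float], bin_width: float = 10.0,
                              domain: str = "signed"
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of angles over (-180, 180] (signed) or [0, 360) (unsigned).

    Returns ``(counts, bin_edges)``; the counts always sum to the sample
    count.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("no samples")
    if domain == "signed":
        lo, hi = -180.0, 180.0
    elif domain == "unsigned":
        lo, hi = 0.0, 360.0
        samples = np.mod(samples, 360.0)
    else:
        raise ValueError(f"unknown domain {domain!r}")
    n_bins = max(int(round((hi - lo) / bin_width)), 1)
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(np.clip(samples, lo, np.nextafter(hi, lo)), bins=edges)
    return counts, edges


# ---------------------------------------------------------------------------
# Pairwise energies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LJParams:
    """Minimal per-element 12-6 Lennard-Jones table (sigma A, epsilon
    kcal/mol), Lorentz-Berthelot combining, hard distance cutoff.

    Hydrogens are not scored: the stacking monitors act on heavy atoms only.
    """

    table: Mapping[str, tuple[float, float]] = field(default_factory=lambda: {
        "C": (3.40, 0.086),
        "N": (3.25, 0.170),
        "O": (2.96, 0.210),
        "P": (3.74, 0.200),
    })
    cutoff: float = 10.0

    def __post_init__(self) -> None:
        for el, (s, e) in self.table.items():
            if s <= 0 or e <= 0:
                raise ValueError(f"LJ parameters for {el} must be positive")


DEFAULT_LJ = LJParams()


def _element(name: str) -> str:
    stripped = name.strip("0123456789'\"*")
    return stripped[:1].upper() if stripped else name


def lj_pair_energy(res_i: Mapping[str, np.ndarray],
                   res_j: Mapping[str, np.ndarray],
                   params: LJParams = DEFAULT_LJ) -> float:
    """Sum of 12-6 LJ terms over inter-residue heavy-atom pairs within cutoff.

    Symmetric in its arguments and additive over disjoint atom subsets.  An
    atom whose element is not in the parameter table raises ``KeyError``.
    """
    total = 0.0
    items_i = [(n, p) for n, p in res_i.items() if not _element(n).startswith("H")]
    items_j = [(n, p) for n, p in res_j.items() if not _element(n).startswith("H")]
    for ni, pi in items_i:
        ei = _element(ni)
        if ei not in params.table:
            raise KeyError(f"no LJ parameters for atom {ni!r} (element {ei})")
        si, epi = params.table[ei]
        for nj, pj in items_j:
            ej = _element(nj)
            if ej not in params.table:
                raise KeyError(f"no LJ parameters for atom {nj!r} (element {ej})")
            r = float(np.linalg.norm(np.asarray(pi) - np.asarray(pj)))
            if r > params.cutoff:
                continue
            sj, epj = params.table[ej]
            sig = 0.5 * (si + sj)
            eps = math.sqrt(epi * epj)
            sr6 = (sig / r) ** 6
            total += 4.0 * eps * (sr6 * sr6 - sr6)
    return total


def screened_coulomb_energy(charges: Sequence[tuple[np.ndarray, float]],
                            kappa: float = DEBYE_HUCKEL_KAPPA,
                            cutoff: float | None = None,
                            k_e: float = COULOMB_KCAL) -> float:
    """Debye-Hueckel screened Coulomb energy over all pairs (kcal/mol).

    ``E = sum k_e q_i q_j exp(-kappa r_ij) / r_ij``; ``kappa = 0`` recovers
    the unscreened Coulomb sum.
    """
    pts = np.array([np.asarray(p, dtype=float) for p, _ in charges])
    qs = np.array([q for _, q in charges], dtype=float)
    total = 0.0
    for i in range(len(qs)):
        for j in range(i + 1, len(qs)):
            r = float(np.linalg.norm(pts[i] - pts[j]))
            if cutoff is not None and r > cutoff:
                continue
            total += k_e * qs[i] * qs[j] * math.exp(-kappa * r) / r
    return total


def phosphate_charges(coords: Mapping[AtomKey, np.ndarray], q: float = -1.0
                      ) -> list[tuple[np.ndarray, float]]:
    """Default charge model: one point charge per phosphate P, zero elsewhere."""
    return [(p, q) for (rid, name), p in coords.items() if name == "P"]


# ---------------------------------------------------------------------------
# Contacts and clashes
# ---------------------------------------------------------------------------

@dataclass
class ContactSeries:
    """Per-frame distance of one atom pair plus summary statistics."""

    distances: np.ndarray
    atom_a: AtomKey
    atom_b: AtomKey

    @property
    def mean(self) -> float:
        return float(self.distances.mean())

    def fraction_below(self, cutoff: float) -> float:
        return float((self.distances < cutoff).mean())


def contact_distance_series(traj: Trajectory, atom_a: AtomKey,
                            atom_b: AtomKey) -> ContactSeries:
    """Euclidean distance of an atom pair in every frame."""
    for key in (atom_a, atom_b):
        if not traj.has_atom(key):
            raise KeyError(f"atom {key} missing from all {traj.n_frames} frames")
    d = np.linalg.norm(traj.atom_series(atom_a) - traj.atom_series(atom_b), axis=1)
    return ContactSeries(d, tuple(atom_a), tuple(atom_b))


def exclusions_from_bonds(bonds: Iterable[tuple[AtomKey, AtomKey]]
                          ) -> set[frozenset]:
    """1-2 and 1-3 exclusion pairs implied by a covalent bond list."""
    adj: dict[AtomKey, set[AtomKey]] = {}
    for a, b in bonds:
        adj.setdefault(tuple(a), set()).add(tuple(b))
        adj.setdefault(tuple(b), set()).add(tuple(a))
    excl: set[frozenset] = set()
    for a, nbrs in adj.items():
        for b in nbrs:
            excl.add(frozenset((a, b)))
            for c in adj[b]:
                if c != a:
                    excl.add(frozenset((a, c)))
    return excl


def steric_clash_count(coords: Mapping[AtomKey, np.ndarray],
                       cutoff: float = 2.0,
                       exclusions: set[frozenset] | None = None) -> int:
    """Number of non-excluded heavy-atom pairs closer than ``cutoff``."""
    exclusions = exclusions or set()
    keys = [k for k in coords if not _element(k[1]).startswith("H")]
    pts = np.array([coords[k] for k in keys])
    if not np.isfinite(pts).all():
        raise ValueError("coordinates must be finite")
    if len(keys) < 2:
        return 0
    tree = cKDTree(pts)
    count = 0
    for i, j in tree.query_pairs(cutoff):
        if frozenset((keys[i], keys[j])) not in exclusions:
            count += 1
    return count
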