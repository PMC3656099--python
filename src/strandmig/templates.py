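"""Idealized nucleotide templates for the synthetic helix builder.

Base heavy-atom coordinates are expressed in the standard base-pair reference
frame (x toward the major groove, y along the pseudo-dyad, base plane at z=0);
the paired base of a Watson-Crick pair is obtained by the 180-degree rotation
about x (y -> -y, z -> -z).  Polar hydrogens that participate in WC hydrogen
bonds are generated at import time by placing each hydrogen 1.01 A from its
donor along the line to the idealized partner acceptor, so the ideal pair is
exactly collinear (theta = pi) at every scheduled bond.

The backbone is a deliberately simplified six-atom chain (P, O5', C5', C4',
C3', O3') laid out on a helical arc chosen so that O3'(i) lands ~1.5 A from
P(i+1) under the default A-form twist/rise.  It is a scaffold for monitors
(backbone RMSD, pseudo-dihedrals, clash counting), not a chemically accurate
sugar-phosphate geometry.
"""

from __future__ import annotations

import math

import numpy as np

# ---------------------------------------------------------------------------
# Base heavy atoms in the standard pair reference frame (Angstrom).
# ---------------------------------------------------------------------------

# One canonical glycosidic-carbon position shared by all four bases, so that
# helically placed strands have exactly constant C1'-C1' step distances.
_C1P = (-2.479, 5.375, 0.000)

BASE_HEAVY: dict[str, dict[str, tuple[float, float, float]]] = {
    "A": {
        "C1'": _C1P,
        "N9": (-1.291, 4.498, 0.000),
        "C8": (0.024, 4.897, 0.000),
        "N7": (0.877, 3.902, 0.000),
        "C5": (0.071, 2.771, 0.000),
        "C6": (0.369, 1.398, 0.000),
        "N6": (1.611, 0.909, 0.000),
        "N1": (-0.668, 0.532, 0.000),
        "C2": (-1.912, 1.023, 0.000),
        "N3": (-2.320, 2.290, 0.000),
        "C4": (-1.267, 3.124, 0.000),
    },
    "U": {
        "C1'": _C1P,
        "N1": (-1.284, 4.500, 0.000),
        "C2": (-1.462, 3.131, 0.000),
        "O2": (-2.563, 2.608, 0.000),
        "N3": (-0.302, 2.397, 0.000),
        "C4": (0.989, 2.884, 0.000),
        "O4": (1.935, 2.094, 0.000),
        "C5": (1.089, 4.311, 0.000),
        "C6": (-0.024, 5.053, 0.000),
    },
    "G": {
        "C1'": _C1P,
        "N9": (-1.289, 4.551, 0.000),
        "C8": (0.023, 4.962, 0.000),
        "N7": (0.870, 3.969, 0.000),
        "C5": (0.071, 2.833, 0.000),
        "C6": (0.424, 1.460, 0.000),
        "O6": (1.554, 0.955, 0.000),
        "N1": (-0.700, 0.641, 0.000),
        "C2": (-1.999, 1.087, 0.000),
        "N2": (-2.949, 0.139, -0.001),
        "N3": (-2.342, 2.364, 0.001),
        "C4": (-1.265, 3.177, 0.000),
    },
    "C": {
        "C1'": _C1P,
        "N1": (-1.285, 4.542, 0.000),
        "C2": (-1.472, 3.158, 0.000),
        "O2": (-2.628, 2.709, 0.001),
        "N3": (-0.391, 2.344, 0.000),
        "C4": (0.837, 2.868, 0.000),
        "N4": (1.875, 2.027, 0.001),
        "C5": (1.056, 4.275, 0.000),
        "C6": (-0.023, 5.068, 0.000),
    },
}

WC_PARTNER = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: Watson-Crick donor/hydrogen/acceptor layout per pair class.  Each entry is
#: (donor_side, donor_atom, hydrogen_atom, acceptor_side, acceptor_atom) where
#: side "5" is the first base of the class label and "3" the second.
WC_BOND_LAYOUT: dict[str, tuple[tuple[str, str, str, str, str], ...]] = {
    "AU": (("5", "N6", "H61", "3", "O4"), ("3", "N3", "H3", "5", "N1")),
    "UA": (("3", "N6", "H61", "5", "O4"), ("5", "N3", "H3", "3", "N1")),
    "GC": (
        ("3", "N4", "H41", "5", "O6"),
        ("5", "N1", "H1", "3", "N3"),
        ("5", "N2", "H21", "3", "O2"),
    ),
    "CG": (
        ("5", "N4", "H41", "3", "O6"),
        ("3", "N1", "H1", "5", "N3"),
        ("3", "N2", "H21", "5", "O2"),
    ),
}

_NH_BOND_LENGTH = 1.01  # A, donor-hydrogen distance


def _pair_flip(p: np.ndarray) -> np.ndarray:
    """180-degree rotation about x: maps a base onto its WC partner's frame."""
    return np.array([p[0], -p[1], -p[2]])


def _wc_hydrogens(base: str) -> dict[str, np.ndarray]:
    """Place WC-donor hydrogens of ``base`` toward the idealized partner."""
    partner = WC_PARTNER[base]
    cls = base + partner
    out: dict[str, np.ndarray] = {}
    for donor_side, donor, hyd, _acc_side, acceptor in WC_BOND_LAYOUT[cls]:
        if donor_side != "5":
            continue  # donor on the partner base
        d = np.array(BASE_HEAVY[base][donor])
        a = _pair_flip(np.array(BASE_HEAVY[partner][acceptor]))
        u = a - d
        out[hyd] = d + _NH_BOND_LENGTH * u / np.linalg.norm(u)
    return out


# ---------------------------------------------------------------------------
# Backbone scaffold (cylindrical layout in the pair frame).
# ---------------------------------------------------------------------------

BACKBONE_ATOMS = ("P", "O5'", "C5'", "C5'", "C3'", "O3'")  # placeholder, fixed below
BACKBONE_ATOMS = ("P", "O5'", "C5'", "C4'", "C3'", "O3'")

_BB_RADIUS = 8.6  # A
_BB_THETA0 = 100.0  # deg, phosphorus azimuth in the pair frame
_BB_DTHETA = 4.6  # deg per backbone bond
_BB_Z0 = -1.30  # A
_BB_DZ = 0.48  # A per backbone bond


def _backbone_local() -> dict[str, np.ndarray]:
    out = {}
    for k, name in enumerate(BACKBONE_ATOMS):
        th = math.radians(_BB_THETA0 + k * _BB_DTHETA)
        out[name] = np.array(
            [_BB_RADIUS * math.cos(th), _BB_RADIUS * math.sin(th), _BB_Z0 + k * _BB_DZ]
        )
    return out


_BACKBONE = _backbone_local()


def residue_template(base: str) -> dict[str, np.ndarray]:
    """Full atom template (base heavies + WC hydrogens + backbone) for ``base``.

    Coordinates are in the pair reference frame for the strand-1 role; the
    strand-2 role is obtained with :func:`flip_role`.
    """
    if base not in BASE_HEAVY:
        raise ValueError(f"unknown base {base!r}")
    atoms = {name: np.array(xyz) for name, xyz in BASE_HEAVY[base].items()}
    atoms.update(_wc_hydrogens(base))
    atoms.update({k: v.copy() for k, v in _BACKBONE.items()})
    return atoms


def flip_role(atoms: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Map a strand-1 template onto the strand-2 role (y -> -y, z -> -z)."""
    return {name: _pair_flip(p) for name, p in atoms.items()}


def helical_transform(atoms: dict[str, np.ndarray], step: int | float,
                      twist_deg: float, rise: float) -> dict[str, np.ndarray]:
    """Place a pair-frame template at helical step ``step`` about the z axis."""
    phi = math.radians(twist_deg) * step
    c, s = math.cos(phi), math.sin(phi)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    dz = np.array([0.0, 0.0, rise * step])
    return {name: rot @ p + dz for name, p in atoms.items()}


def flip_out(atoms: dict[str, np.ndarray], angle_deg: float = 90.0) -> dict[str, np.ndarray]:
    """Swing the base (all non-backbone atoms) out of the pair plane.

    The base rotates by ``angle_deg`` about the axis through C1' that is
    tangential to the helix (z cross radial direction of C1'), which breaks
    both the distance and the angle criterion of every WC bond the residue
    participates in.  Backbone atoms stay on the helical scaffold.  The path
    is a documented construction, not a physical base-flipping trajectory.
    """
    pivot = atoms["C1'"]
    radial = np.array([pivot[0], pivot[1], 0.0])
    nr = np.linalg.norm(radial)
    if nr < 1e-9:  # C1' on the axis: fall back to x
        radial = np.array([1.0, 0.0, 0.0])
        nr = 1.0
    radial = radial / nr
    axis = np.cross(np.array([0.0, 0.0, 1.0]), radial)
    axis /= np.linalg.norm(axis)
    ang = math.radians(angle_deg)
    c, s = math.cos(ang), math.sin(ang)
    out = {}
    for name, p in atoms.items():
        if name in _BACKBONE:
            out[name] = p.copy()
            continue
        v = p - pivot
        rotated = (v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c))
        out[name] = pivot + rotated
    return out


# ---------------------------------------------------------------------------
# Connectivity (for 1-2/1-3 steric exclusions).
# ---------------------------------------------------------------------------

_BASE_BONDS: dict[str, tuple[tuple[str, str], ...]] = {
    "A": (
        ("N9", "C8"), ("C8", "N7"), ("N7", "C5"), ("C5", "C6"), ("C6", "N6"),
        ("C6", "N1"), ("N1", "C2"), ("C2", "N3"), ("N3", "C4"), ("C4", "C5"),
        ("C4", "N9"), ("N9", "C1'"), ("N6", "H61"),
    ),
    "G": (
        ("N9", "C8"), ("C8", "N7"), ("N7", "C5"), ("C5", "C6"), ("C6", "O6"),
        ("C6", "N1"), ("N1", "C2"), ("C2", "N2"), ("C2", "N3"), ("N3", "C4"),
        ("C4", "C5"), ("C4", "N9"), ("N9", "C1'"), ("N1", "H1"), ("N2", "H21"),
    ),
    "U": (
        ("N1", "C2"), ("C2", "O2"), ("C2", "N3"), ("N3", "C4"), ("C4", "O4"),
        ("C4", "C5"), ("C5", "C6"), ("C6", "N1"), ("N1", "C1'"), ("N3", "H3"),
    ),
    "C": (
        ("N1", "C2"), ("C2", "O2"), ("C2", "N3"), ("N3", "C4"), ("C4", "N4"),
        ("C4", "C5"), ("C5", "C6"), ("C6", "N1"), ("N1", "C1'"), ("N4", "H41"),
    ),
}

# C4'-C1' is a pseudo-bond standing in for the sugar ring that the simplified
# backbone omits.
_BACKBONE_BONDS = (
    ("P", "O5'"), ("O5'", "C5'"), ("C5'", "C4'"), ("C4'", "C3'"),
    ("C3'", "O3'"), ("C4'", "C1'"),
)


def residue_bonds(base: str) -> tuple[tuple[str, str], ...]:
    """Intra-residue bond list (base + simplified backbone) for ``base``."""
    return _BASE_BONDS[base] + _BACKBONE_BONDS


def base_heavy_atoms(base: str) -> tuple[str, ...]:
    """Nucleobase heavy atoms (ring + exocyclic; excludes sugar/backbone)."""
    return tuple(n for n in BASE_HEAVY[base] if n != "C1'")


def glycosidic_atom(base: str) -> str:
    """The base nitrogen attached to C1' (N9 purines, N1 pyrimidines)."""
    return "N9" if base in ("A", "G") else "N1"
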