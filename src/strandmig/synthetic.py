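"""Synthetic trajectory generator: ideal A-form helices and scripted strand
migration with ground truth.

This module stands in for long-timescale MD output.  It builds the competing
P1/AT helices of the hybrid construct as ideal A-form duplexes sharing one
coaxial axis, scripts a per-frame pairing schedule (which competing position
is paired in which helix), renders coordinates from the idealized templates,
and adds seeded Gaussian noise.  Because the schedule is the ground truth,
every downstream monitor (hydrogen-bond fractions, event detection,
occupancies, contact series) can be checked frame-by-frame against it.

The default scripted scenario is a desk-scale analogue of the migration event
the analysis stack is built to detect: the trajectory starts with two P1
pairs formed, three competing positions paired in the AT helix, and the
boundary residue unpaired; at the event frame all six P1 pairs form; the
closing pair then frays after 92 frames (18.2 ns at 200 ps/frame) and pair 5
is disrupted for part of the remaining trajectory.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .registry import (AT, P1, UNPAIRED, ConstructRegistry, PairingMap,
                       build_default_registry, wc_hbond_triples)
from .templates import (WC_BOND_LAYOUT, WC_PARTNER, flip_out, flip_role,
                        helical_transform, residue_bonds, residue_template)
from .trajectory_io import AtomKey, Trajectory

__all__ = [
    "HelixParams",
    "DuplexModel",
    "PairingSchedule",
    "MarkerSet",
    "MarkerScriptError",
    "build_aform_duplex",
    "script_migration_event",
    "default_schedule",
    "default_marker_scripts",
    "generate_switch_trajectory",
    "place_site_markers",
    "MG_KEY",
    "SD_KEY",
]

STATE_CODES = {UNPAIRED: 0, P1: 1, AT: 2}
CODE_STATES = {v: k for k, v in STATE_CODES.items()}

#: Competing positions in column order of PairingSchedule.states
COMPETING_IDS = (108, 109, 110, 111)

MG_KEY: AtomKey = (200, "MG")
SD_KEY: AtomKey = (201, "SD")

_MARKER_ORIGIN = np.array([12.0, 0.0, 14.5])  # core pocket site, off the helix
_MARKER_DIRECTIONS: dict[AtomKey, tuple[float, float, float]] = {
    (8, "P"): (0.2, 0.9, 0.4),
    (9, "O6"): (-0.5, 0.8, 0.1),
    (81, "P"): (0.9, -0.3, 0.2),
    (82, "P"): (0.6, 0.6, -0.5),
    (83, "P"): (0.1, -0.7, -0.7),
}
_MARKER_RESNAMES = {200: "MG", 201: "SAM", 8: "A", 9: "G", 81: "U", 82: "C", 83: "U"}


class MarkerScriptError(ValueError):
    """Raised for infeasible or invalid marker distance scripts."""


@dataclass(frozen=True)
class HelixParams:
    """A-form helix construction parameters (standard fiber values)."""

    twist_deg: float = 32.7
    rise: float = 2.81

    def __post_init__(self) -> None:
        if not 0 < self.twist_deg < 360:
            raise ValueError(f"twist {self.twist_deg} out of (0, 360)")
        if self.rise <= 0:
            raise ValueError(f"rise {self.rise} must be positive")


DEFAULT_HELIX = HelixParams()


def _place_residue(base: str, role: int, step: float,
                   hp: HelixParams) -> dict[str, np.ndarray]:
    t = residue_template(base)
    if role == 2:
        t = flip_role(t)
    return helical_transform(t, step, hp.twist_deg, hp.rise)


# ---------------------------------------------------------------------------
# Stand-alone ideal duplex
# ---------------------------------------------------------------------------

@dataclass
class DuplexModel:
    """An ideal A-form duplex: coordinates, covalent bonds, scheduled WC bonds."""

    sequence: str
    complement: str
    coords: dict[AtomKey, np.ndarray]
    resnames: dict[int, str]
    strand1: tuple[int, ...]
    strand2: tuple[int, ...]
    pairs: tuple[tuple[int, int, str], ...]  # (res5, res3, wc_class)
    params: HelixParams

    @property
    def n_residues(self) -> int:
        return len(self.strand1) + len(self.strand2)

    def covalent_bonds(self) -> list[tuple[AtomKey, AtomKey]]:
        bonds: list[tuple[AtomKey, AtomKey]] = []
        for rid in (*self.strand1, *self.strand2):
            base = self.resnames[rid]
            for a, b in residue_bonds(base):
                bonds.append(((rid, a), (rid, b)))
        for strand in (self.strand1, self.strand2):
            for r1, r2 in zip(strand, strand[1:]):
                bonds.append(((r1, "O3'"), (r2, "P")))
        return bonds

    def hbonds(self) -> list[tuple[AtomKey, AtomKey, AtomKey]]:
        """Scheduled WC bonds as (donor, hydrogen, acceptor) atom keys."""
        out = []
        for r5, r3, cls_ in self.pairs:
            for side_d, d, h, side_a, a in WC_BOND_LAYOUT[cls_]:
                dres = r5 if side_d == "5" else r3
                ares = r5 if side_a == "5" else r3
                out.append(((dres, d), (dres, h), (ares, a)))
        return out


def build_aform_duplex(sequence: str, params: HelixParams | None = None,
                       complement: str | None = None) -> DuplexModel:
    """Build an ideal A-form duplex of ``sequence`` and its complement.

    Strand 1 is residues ``1..N`` (5'->3', ascending helical steps); strand 2
    is ``N+1..2N`` (5'->3') with residue ``N+1+k`` pairing residue ``N-k``.
    If ``complement`` is given it must be the exact WC complement, otherwise
    it is derived.
    """
    hp = params or DEFAULT_HELIX
    sequence = sequence.upper()
    if not sequence:
        raise ValueError("sequence must be non-empty")
    for b in sequence:
        if b not in WC_PARTNER:
            raise ValueError(f"non-WC base {b!r} in sequence")
    n = len(sequence)
    expected = "".join(WC_PARTNER[b] for b in reversed(sequence))
    if complement is None:
        complement = expected
    elif complement.upper() != expected:
        raise ValueError(
            f"complement {complement!r} does not WC-pair sequence {sequence!r}")

    coords: dict[AtomKey, np.ndarray] = {}
    resnames: dict[int, str] = {}
    for i, base in enumerate(sequence):  # strand 1 at steps 0..n-1
        rid = i + 1
        resnames[rid] = base
        for name, p in _place_residue(base, 1, i, hp).items():
            coords[(rid, name)] = p
    for k, base in enumerate(complement):  # strand 2, residue n+1+k pairs n-k
        rid = n + 1 + k
        resnames[rid] = base
        step = n - 1 - k
        for name, p in _place_residue(base, 2, step, hp).items():
            coords[(rid, name)] = p

    pairs = tuple((n - k, n + 1 + k, sequence[n - 1 - k] + complement[k])
                  for k in range(n))
    return DuplexModel(sequence, complement, coords, resnames,
                       tuple(range(1, n + 1)), tuple(range(n + 1, 2 * n + 1)),
                       pairs, hp)


# ---------------------------------------------------------------------------
# Pairing schedules
# ---------------------------------------------------------------------------

@dataclass
class PairingSchedule:
    """Ground-truth per-frame pairing states of the competing positions.

    ``states`` has shape ``(n_frames, 4)`` with columns ordered by switching
    residue id (108, 109, 110, 111) and codes 0 = unpaired, 1 = P1, 2 = AT.
    """

    states: np.ndarray
    event_frame: int | None = None
    fray_windows: tuple[tuple[int, int, int], ...] = ()  # (P1 ordinal, start, end)
    marker_scripts: dict[tuple[AtomKey, AtomKey], np.ndarray] = field(default_factory=dict)
    sam_present: bool = True
    competing_ids: tuple[int, ...] = COMPETING_IDS

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 2 or self.states.shape[1] != len(self.competing_ids):
            raise ValueError("states must be (n_frames, n_competing)")
        for pair, d in self.marker_scripts.items():
            d = np.asarray(d, dtype=float)
            if d.shape != (self.n_frames,):
                raise MarkerScriptError(f"script {pair}: wrong length")
            if not (d > 0).all():
                raise MarkerScriptError(f"script {pair}: distances must be positive")
            self.marker_scripts[pair] = d

    @property
    def n_frames(self) -> int:
        return self.states.shape[0]

    def _col(self, switching_id: int) -> int:
        return self.competing_ids.index(switching_id)

    def state(self, frame: int, switching_id: int) -> str:
        return CODE_STATES[int(self.states[frame, self._col(switching_id)])]

    def map_at(self, frame: int) -> PairingMap:
        return PairingMap.from_dict(
            {sid: CODE_STATES[int(self.states[frame, i])]
             for i, sid in enumerate(self.competing_ids)})

    # -- schedule-implied ground truth ---------------------------------------

    def position_formed(self, registry: ConstructRegistry, helix: str,
                        ordinal: int) -> np.ndarray:
        """Boolean per frame: is this pair position scheduled as formed?"""
        pos = registry.position(helix, ordinal)
        sid = registry.switching_id(pos)
        if sid not in self.competing_ids:
            return np.ones(self.n_frames, dtype=bool)
        want = STATE_CODES[helix]
        return self.states[:, self._col(sid)] == want

    def bond_fraction(self, registry: ConstructRegistry, helix: str) -> np.ndarray:
        """Scheduled fraction of formed hydrogen bonds in ``helix`` per frame."""
        bonds = registry.bonds(helix)
        formed = np.zeros(self.n_frames)
        for pos in registry.positions(helix):
            nb = len(registry.bonds(helix, pos.ordinal))
            formed += nb * self.position_formed(registry, helix, pos.ordinal)
        return formed / len(bonds)

    def full_p1_frames(self) -> np.ndarray:
        return (self.states == STATE_CODES[P1]).all(axis=1)

    # -- serialization ---------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["frame", "position", "state"])
            for f in range(self.n_frames):
                for i, sid in enumerate(self.competing_ids):
                    w.writerow([f, sid, CODE_STATES[int(self.states[f, i])]])

    def markers_to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["frame", "res_a", "atom_a", "res_b", "atom_b", "distance"])
            for (a, b), d in sorted(self.marker_scripts.items()):
                for f in range(self.n_frames):
                    w.writerow([f, a[0], a[1], b[0], b[1], f"{d[f]:.4f}"])


_START_ROW = np.array([STATE_CODES[AT], STATE_CODES[AT],
                       STATE_CODES[UNPAIRED], STATE_CODES[AT]], dtype=np.int8)

#: switching residue id of a competing P1 ordinal (ordinal p pairs 114 - p)
_ORDINAL_TO_SID = {3: 111, 4: 110, 5: 109, 6: 108}


def script_migration_event(n_frames: int, event_frame: int | None,
                           fray: Sequence[tuple[int, int, int]] | None = None,
                           sam_present: bool = True) -> PairingSchedule:
    """Script a strand-migration trajectory schedule.

    Before ``event_frame`` the competing positions are in the start state
    (three AT pairs, boundary residue unpaired); at and after it all four are
    P1.  ``fray`` lists ``(P1 ordinal, start, end)`` windows (half-open) in
    which that position reverts to unpaired; windows must lie at or after the
    event.  ``event_frame=None`` scripts a trajectory with no migration.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    states = np.tile(_START_ROW, (n_frames, 1))
    if event_frame is not None:
        if not 0 <= event_frame < n_frames:
            raise ValueError(f"event_frame {event_frame} outside [0, {n_frames})")
        states[event_frame:, :] = STATE_CODES[P1]
    windows = []
    for ordinal, start, end in (fray or ()):
        if ordinal not in _ORDINAL_TO_SID:
            raise ValueError(f"fray ordinal {ordinal} is not a competing P1 position")
        if event_frame is None or start < event_frame or end > n_frames or start >= end:
            raise ValueError(
                f"fray window ({start}, {end}) outside [{event_frame}, {n_frames})")
        col = COMPETING_IDS.index(_ORDINAL_TO_SID[ordinal])
        states[start:end, col] = STATE_CODES[UNPAIRED]
        windows.append((ordinal, start, end))
    return PairingSchedule(states, event_frame, tuple(windows),
                           sam_present=sam_present)


def default_schedule(n_frames: int = 1000, event_frame: int | None = 400,
                     sam_present: bool = True,
                     fray: Sequence[tuple[int, int, int]] | None = None,
                     markers: bool = True,
                     helix_params: HelixParams | None = None) -> PairingSchedule:
    """The bundled migration scenario.

    After the event the closing pair (ordinal 6) frays once the full helix has
    lived for 92 frames (18.2 ns at 200 ps/frame), and pair 5 is disrupted
    over a window sized so that its occupancy over the post-event span matches
    the observed ~0.247 fraction.
    """
    if fray is None and event_frame is not None:
        fray = []
        f6 = event_frame + 92
        if f6 < n_frames:
            fray.append((6, f6, n_frames))
        f5a, f5b = event_frame + 120, min(event_frame + 572, n_frames)
        if f5a < f5b:
            fray.append((5, f5a, f5b))
    sched = script_migration_event(n_frames, event_frame, fray, sam_present)
    if markers:
        sched.marker_scripts = default_marker_scripts(
            n_frames, sam_present, helix_params)
    return sched


# ---------------------------------------------------------------------------
# Site markers (pseudo-ligand sulfur and core Mg2+)
# ---------------------------------------------------------------------------

def _u5_o2_home(hp: HelixParams) -> np.ndarray:
    """Position of the U5 carbonyl O2 when P1 pair 5 is formed."""
    return _place_residue("U", 2, 2, hp)["O2"]  # residue 5: role 2, step 7-5


def default_marker_scripts(n_frames: int, sam_present: bool = True,
                           helix_params: HelixParams | None = None,
                           ) -> dict[tuple[AtomKey, AtomKey], np.ndarray]:
    """Scripted marker distances emulating the core-site contact behaviour:

    contacts between the Mg2+ and the two J1/2 groups (A8 phosphate, G9 O6)
    stay short when the ligand is present and drift apart without it, while
    the three J3/4 phosphate contacts stay short in both conditions.  With the
    ligand present, the pseudo-ligand sulfur is held at a fixed offset from
    the Mg2+ chosen so that it sits ~3.2 A from the U5 carbonyl once P1 pair 5
    is formed.
    """
    hp = helix_params or DEFAULT_HELIX
    const = lambda d: np.full(n_frames, d)
    drift = lambda d0, d1: np.linspace(d0, d1, n_frames)
    scripts: dict[tuple[AtomKey, AtomKey], np.ndarray] = {
        (MG_KEY, (81, "P")): const(2.1),
        (MG_KEY, (82, "P")): const(2.2),
        (MG_KEY, (83, "P")): const(2.3),
    }
    if sam_present:
        scripts[(MG_KEY, (8, "P"))] = const(2.1)
        scripts[(MG_KEY, (9, "O6"))] = const(2.2)
        reach = float(np.linalg.norm(_u5_o2_home(hp) - _MARKER_ORIGIN))
        scripts[(MG_KEY, SD_KEY)] = const(max(reach - 3.2, 1.0))
    else:
        scripts[(MG_KEY, (8, "P"))] = drift(2.1, 6.0)
        scripts[(MG_KEY, (9, "O6"))] = drift(2.2, 6.0)
    return scripts


@dataclass
class MarkerSet:
    atoms: list[AtomKey]
    xyz: np.ndarray  # (n_frames, n_markers, 3)
    resnames: dict[int, str]


def _golden_directions(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = math.pi * (1 + 5 ** 0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def place_site_markers(schedule: PairingSchedule, noise_sigma: float = 0.0,
                       seed: int = 0,
                       helix_params: HelixParams | None = None) -> MarkerSet:
    """Place marker atoms so every scripted pairwise distance is met exactly
    (at ``noise_sigma = 0``).

    The Mg2+ sits at a fixed pocket position; singly-constrained atoms are
    placed along fixed per-atom directions at the scripted distance; an atom
    scripted against both the Mg2+ and the sulfur is solved by sphere
    intersection, raising :class:`MarkerScriptError` when the triangle
    inequality is violated.  In ligand-absent mode no sulfur is placed.
    """
    if not schedule.marker_scripts:
        raise MarkerScriptError("schedule has no marker distance scripts")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    hp = helix_params or DEFAULT_HELIX
    n_frames = schedule.n_frames

    # normalize scripts: centers (MG/SD) first
    scripts: dict[tuple[AtomKey, AtomKey], np.ndarray] = {}
    for (a, b), d in schedule.marker_scripts.items():
        if a in (MG_KEY, SD_KEY):
            scripts[(a, b)] = d
        elif b in (MG_KEY, SD_KEY):
            scripts[(b, a)] = d
        else:
            raise MarkerScriptError(f"script {(a, b)} references no marker center")

    positions: dict[AtomKey, np.ndarray] = {
        MG_KEY: np.tile(_MARKER_ORIGIN, (n_frames, 1))}

    sd_scripts = {k: v for k, v in scripts.items() if SD_KEY in k}
    if (MG_KEY, SD_KEY) in scripts or (SD_KEY, MG_KEY) in scripts:
        d = scripts.get((MG_KEY, SD_KEY), scripts.get((SD_KEY, MG_KEY)))
        u = _u5_o2_home(hp) - _MARKER_ORIGIN
        u = u / np.linalg.norm(u)
        positions[SD_KEY] = positions[MG_KEY] + d[:, None] * u
    elif any(SD_KEY == c for c, _ in sd_scripts):
        raise MarkerScriptError("sulfur used as a center but not scripted to Mg")

    anchors = sorted({t for c, t in scripts if t not in (MG_KEY, SD_KEY)})
    unknown = [a for a in anchors if a not in _MARKER_DIRECTIONS]
    extra_dirs = dict(zip(unknown, _golden_directions(max(len(unknown), 1))))
    for atom in anchors:
        cons = {c: scripts[(c, atom)] for c in (MG_KEY, SD_KEY)
                if (c, atom) in scripts}
        if len(cons) == 1:
            (center, d), = cons.items()
            u = np.asarray(_MARKER_DIRECTIONS.get(atom, extra_dirs.get(atom)),
                           dtype=float)
            u = u / np.linalg.norm(u)
            positions[atom] = positions[center] + d[:, None] * u
        else:
            positions[atom] = _sphere_intersection(
                positions[MG_KEY], positions[SD_KEY],
                cons[MG_KEY], cons[SD_KEY], atom)

    atoms = sorted(positions, key=lambda k: (k != MG_KEY, k != SD_KEY, k))
    xyz = np.stack([positions[a] for a in atoms], axis=1)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        xyz = xyz + rng.normal(0.0, noise_sigma, xyz.shape)
    resnames = {rid: _MARKER_RESNAMES.get(rid, "UNK") for rid, _ in atoms}
    return MarkerSet(atoms, xyz, resnames)


def _sphere_intersection(p1: np.ndarray, p2: np.ndarray, d1: np.ndarray,
                         d2: np.ndarray, atom: AtomKey) -> np.ndarray:
    c = np.linalg.norm(p2 - p1, axis=1)
    if ((d1 + d2 < c - 1e-9) | (np.abs(d1 - d2) > c + 1e-9)).any():
        raise MarkerScriptError(
            f"script for {atom}: triangle inequality violated against centers")
    u = (p2 - p1) / c[:, None]
    a = (d1 ** 2 - d2 ** 2 + c ** 2) / (2 * c)
    h = np.sqrt(np.maximum(d1 ** 2 - a ** 2, 0.0))
    # deterministic perpendicular: component of +z orthogonal to the axis
    z = np.tile(np.array([0.0, 0.0, 1.0]), (len(c), 1))
    w = z - (z * u).sum(axis=1, keepdims=True) * u
    wn = np.linalg.norm(w, axis=1, keepdims=True)
    fallback = np.tile(np.array([0.0, 1.0, 0.0]), (len(c), 1))
    w = np.where(wn > 1e-9, w / np.where(wn > 1e-9, wn, 1.0), fallback)
    return p1 + a[:, None] * u + h[:, None] * w


# ---------------------------------------------------------------------------
# Scripted trajectory
# ---------------------------------------------------------------------------

def _construct_variants(registry: ConstructRegistry, hp: HelixParams
                        ) -> dict[int, dict[str, dict[str, np.ndarray]]]:
    """Per-residue coordinate variants keyed by pairing-state label.

    Helical steps: P1 ordinal p occupies step 7 - p (so the closing pair sits
    one step above the AT helix), AT ordinal a occupies step 1 - a; the
    switching strand is the unflipped role in both helices, so it ascends the
    shared axis continuously.
    """
    variants: dict[int, dict[str, dict[str, np.ndarray]]] = {}
    for rid in range(1, 7):  # P1 5' strand, role 2 at step 7 - p
        base = registry.residues[rid].base
        home = _place_residue(base, 2, 7 - rid, hp)
        if 114 - rid in COMPETING_IDS:  # partner competes: may be displaced
            variants[rid] = {P1: home, "out": flip_out(home)}
        else:
            variants[rid] = {"fixed": home}
    for sid in range(101, 114):  # switching strand, role 1
        base = registry.residues[sid].base
        if sid in COMPETING_IDS:
            p1_home = _place_residue(base, 1, sid - 107, hp)
            at_home = _place_residue(base, 1, sid - 111, hp)
            mid = _place_residue(base, 1, sid - 109, hp)
            variants[sid] = {P1: p1_home, AT: at_home, UNPAIRED: flip_out(mid)}
        elif sid >= 112:
            variants[sid] = {"fixed": _place_residue(base, 1, sid - 107, hp)}
        else:
            variants[sid] = {"fixed": _place_residue(base, 1, sid - 111, hp)}
    for rid in range(135, 146):  # AT 3' strand, role 2 at step 135 - r
        base = registry.residues[rid].base
        home = _place_residue(base, 2, 135 - rid, hp)
        if 246 - rid in COMPETING_IDS:
            variants[rid] = {AT: home, "out": flip_out(home)}
        else:
            variants[rid] = {"fixed": home}
    return variants


def _variant_for(rid: int, registry: ConstructRegistry,
                 pairing: Mapping[int, str]) -> str:
    res = registry.residues[rid]
    if res.role == "P1_5prime":
        sid = 114 - rid
        if sid not in pairing:
            return "fixed"
        return P1 if pairing[sid] == P1 else "out"
    if res.role == "switching_strand":
        return pairing.get(rid, "fixed")
    if res.role == "AT_3prime":
        sid = 246 - rid
        if sid not in pairing:
            return "fixed"
        return AT if pairing[sid] == AT else "out"
    raise ValueError(f"residue {rid} is not placed by the helix builder")


def generate_switch_trajectory(registry: ConstructRegistry,
                               schedule: PairingSchedule,
                               noise_sigma: float = 0.0, seed: int = 0,
                               helix_params: HelixParams | None = None,
                               noise_mode: str = "residue",
                               ) -> tuple[Trajectory, PairingSchedule]:
    """Render the scripted schedule into coordinates, with ground truth.

    Paired residues sit at their helix template geometry; a residue whose
    position is paired in the other helix, or unpaired, has its base swung
    90 degrees out of the pair plane (the boundary residue additionally sits
    midway between its two potential homes), which breaks both the distance
    and angle criterion of its scheduled bonds.  Noise is a seeded isotropic
    Gaussian displacement, by default rigid per residue per frame
    (``noise_mode="residue"``); ``"atom"`` jitters every atom independently.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if noise_mode not in ("residue", "atom"):
        raise ValueError(f"unknown noise mode {noise_mode!r}")
    hp = helix_params or DEFAULT_HELIX
    variants = _construct_variants(registry, hp)

    atoms: list[AtomKey] = []
    res_of_col: list[int] = []
    for rid in sorted(variants):
        for name in variants[rid][next(iter(variants[rid]))]:
            atoms.append((rid, name))
            res_of_col.append(rid)

    n_frames = schedule.n_frames
    xyz = np.empty((n_frames, len(atoms), 3))
    rows, inverse = np.unique(schedule.states, axis=0, return_inverse=True)
    for r_i, row in enumerate(rows):
        pairing = {sid: CODE_STATES[int(code)]
                   for sid, code in zip(schedule.competing_ids, row)}
        flat = np.empty((len(atoms), 3))
        col = 0
        for rid in sorted(variants):
            v = variants[rid][_variant_for(rid, registry, pairing)]
            for name in v:
                flat[col] = v[name]
                col += 1
        xyz[inverse == r_i] = flat

    resnames = {rid: registry.residues[rid].base for rid in sorted(variants)}
    if schedule.marker_scripts:
        markers = place_site_markers(schedule, 0.0, seed, hp)
        atoms = atoms + markers.atoms
        res_of_col += [rid for rid, _ in markers.atoms]
        xyz = np.concatenate([xyz, markers.xyz], axis=1)
        resnames.update(markers.resnames)

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        if noise_mode == "residue":
            resids = sorted(set(res_of_col))
            rmap = {r: i for i, r in enumerate(resids)}
            offsets = rng.normal(0.0, noise_sigma, (n_frames, len(resids), 3))
            cols = np.array([rmap[r] for r in res_of_col])
            xyz = xyz + offsets[:, cols, :]
        else:
            xyz = xyz + rng.normal(0.0, noise_sigma, xyz.shape)

    traj = Trajectory(atoms, xyz, resnames,
                      ligand_present=schedule.sam_present,
                      label=f"synthetic(seed={seed},sigma={noise_sigma})")
    return traj, schedule
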