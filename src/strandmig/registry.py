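"""Construct registry for the hybrid riboswitch segment with competing helices.

The default registry encodes a hybrid construct (called ``6P1_11AT``) that can
form up to 6 base pairs of the P1 helix and up to 11 base pairs of the
antiterminator (AT) helix.  The two helices compete for a shared switching
strand; a 4-nucleotide competition region (switching residues 108-111) can
pair either way, with boundary residue U110 able to partner A4 (P1) or A136
(AT).

Numbering
---------
Hybrid 1-based numbering is canonical.  Core (aptamer) residues additionally
carry the aptamer numbering, offset by a constant +2 (hybrid A7 = aptamer A9).
P1 ordinals run 1 (ligand-proximal) to 6 (closing pair at the P1/AT boundary);
AT ordinals run 1 at the boundary outward.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .templates import WC_BOND_LAYOUT, residue_template

__all__ = [
    "Residue",
    "PairPosition",
    "HBond",
    "PairingMap",
    "PairingChange",
    "ConstructRegistry",
    "RegistryError",
    "build_default_registry",
    "wc_hbond_triples",
    "diff_pairing",
    "P1",
    "AT",
    "UNPAIRED",
]

P1 = "P1"
AT = "AT"
UNPAIRED = "unpaired"

_ROLES = ("P1_5prime", "switching_strand", "AT_3prime", "core")


class RegistryError(ValueError):
    """Raised for invalid registry construction or pairing-map operations."""


@dataclass(frozen=True)
class Residue:
    hybrid_id: int
    base: str
    role: str
    aptamer_id: int | None = None

    def __post_init__(self) -> None:
        if self.base not in "AUGC":
            raise RegistryError(f"residue {self.hybrid_id}: base {self.base!r}")
        if self.role not in _ROLES:
            raise RegistryError(f"residue {self.hybrid_id}: role {self.role!r}")

    @property
    def name(self) -> str:
        return f"{self.base}{self.hybrid_id}"


@dataclass(frozen=True)
class HBond:
    """One donor-H...acceptor interaction of a Watson-Crick pair."""

    bond_id: int
    helix: str
    ordinal: int
    donor_res: int
    donor_atom: str
    h_atom: str
    acceptor_res: int
    acceptor_atom: str

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.donor_atom, self.h_atom, self.acceptor_atom)


@dataclass(frozen=True)
class PairPosition:
    helix: str
    ordinal: int
    res5: Residue
    res3: Residue
    wc_class: str
    hbond_triples: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        expected = 3 if self.wc_class in ("GC", "CG") else 2
        if len(self.hbond_triples) != expected:
            raise RegistryError(
                f"{self.helix} pair {self.ordinal}: {self.wc_class} needs "
                f"{expected} hydrogen-bond triples"
            )


def wc_hbond_triples(wc_class: str) -> list[tuple[str, str, str]]:
    """Standard WC (donor, hydrogen, acceptor) atom-name triples for a class.

    A-U type pairs contribute two bonds, G-C type pairs three.  Wobble or
    non-canonical classes are not part of the registry contract.
    """
    try:
        layout = WC_BOND_LAYOUT[wc_class]
    except KeyError:
        raise RegistryError(f"unsupported Watson-Crick class {wc_class!r}") from None
    return [(d, h, a) for _, d, h, _, a in layout]


@dataclass(frozen=True)
class PairingMap:
    """State of each competing position, keyed by switching-strand residue id.

    Positions not listed are implicitly paired in their fixed helix.
    """

    states: tuple[tuple[int, str], ...]
    registry_tag: str = "6P1_11AT"

    @classmethod
    def from_dict(cls, states: Mapping[int, str], registry_tag: str = "6P1_11AT") -> "PairingMap":
        for sid, st in states.items():
            if st not in (P1, AT, UNPAIRED):
                raise RegistryError(f"position {sid}: unknown state {st!r}")
        return cls(tuple(sorted(states.items())), registry_tag)

    def as_dict(self) -> dict[int, str]:
        return dict(self.states)

    def state(self, switching_id: int) -> str:
        return dict(self.states)[switching_id]


@dataclass(frozen=True)
class PairingChange:
    position: int
    before: str
    after: str

    @property
    def label(self) -> str:
        if self.before == UNPAIRED:
            return "unpaired->paired"
        if self.after == UNPAIRED:
            return "paired->unpaired"
        return f"{self.before}->{self.after}"


# --- default construct tables ------------------------------------------------

_P1_5PRIME = {1: "G", 2: "U", 3: "U", 4: "A", 5: "U", 6: "G"}
_SWITCHING = {
    101: "G", 102: "C", 103: "A", 104: "U", 105: "G", 106: "C", 107: "A",
    108: "C", 109: "A", 110: "U", 111: "A", 112: "A", 113: "C",
}
_AT_3PRIME = {
    135: "U", 136: "A", 137: "U", 138: "G", 139: "U", 140: "G",
    141: "C", 142: "A", 143: "U", 144: "G", 145: "C",
}
# Aptamer-core residues named in the source structure; aptamer numbering is
# hybrid + 2 for every core residue.
_CORE = {
    7: "A", 8: "A", 9: "G", 10: "C", 11: "G", 12: "U", 44: "A", 46: "C",
    76: "G", 77: "G", 80: "A", 81: "U", 82: "C", 83: "U", 84: "A",
}

_COMPETING = (108, 109, 110, 111)
_BOUNDARY = 110
#: Start state: three of the four competing positions paired as AT, the
#: boundary residue unpaired between its two potential partners.
_START_STATES = {108: AT, 109: AT, 110: UNPAIRED, 111: AT}


@dataclass(frozen=True)
class ConstructRegistry:
    residues: Mapping[int, Residue]
    pair_positions: tuple[PairPosition, ...]
    competing_position_ids: tuple[int, ...]
    boundary_residue: int
    hbonds: tuple[HBond, ...]
    tag: str = "6P1_11AT"

    # -- lookup helpers -------------------------------------------------------

    def positions(self, helix: str) -> tuple[PairPosition, ...]:
        return tuple(p for p in self.pair_positions if p.helix == helix)

    def position(self, helix: str, ordinal: int) -> PairPosition:
        for p in self.pair_positions:
            if p.helix == helix and p.ordinal == ordinal:
                return p
        raise RegistryError(f"no {helix} position with ordinal {ordinal}")

    def position_for_switching(self, helix: str, switching_id: int) -> PairPosition:
        """The pair position of ``helix`` whose switching residue is given."""
        for p in self.positions(helix):
            sid = p.res3.hybrid_id if helix == P1 else p.res5.hybrid_id
            if sid == switching_id:
                return p
        raise RegistryError(f"switching residue {switching_id} not in {helix}")

    def switching_id(self, pos: PairPosition) -> int:
        return pos.res3.hybrid_id if pos.helix == P1 else pos.res5.hybrid_id

    def bonds(self, helix: str, ordinal: int | None = None) -> tuple[HBond, ...]:
        return tuple(
            b for b in self.hbonds
            if b.helix == helix and (ordinal is None or b.ordinal == ordinal)
        )

    def fixed_state(self, pos: PairPosition) -> bool:
        return self.switching_id(pos) not in self.competing_position_ids

    # -- canonical pairing maps ----------------------------------------------

    def start_map(self) -> PairingMap:
        return PairingMap.from_dict(dict(_START_STATES), self.tag)

    def full_p1_map(self) -> PairingMap:
        return PairingMap.from_dict(
            {sid: P1 for sid in self.competing_position_ids}, self.tag
        )

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "tag": self.tag,
            "boundary_residue": self.boundary_residue,
            "competing_position_ids": list(self.competing_position_ids),
            "residues": [
                {"hybrid_id": r.hybrid_id, "base": r.base, "role": r.role,
                 "aptamer_id": r.aptamer_id}
                for r in self.residues.values()
            ],
            "pair_positions": [
                {"helix": p.helix, "ordinal": p.ordinal,
                 "res5": p.res5.hybrid_id, "res3": p.res3.hybrid_id,
                 "wc_class": p.wc_class}
                for p in self.pair_positions
            ],
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, data: Mapping) -> "ConstructRegistry":
        residues = {
            int(r["hybrid_id"]): Residue(int(r["hybrid_id"]), r["base"], r["role"],
                                         r.get("aptamer_id"))
            for r in data["residues"]
        }
        positions = []
        for p in data["pair_positions"]:
            cls_ = p["wc_class"]
            positions.append(PairPosition(
                p["helix"], int(p["ordinal"]), residues[int(p["res5"])],
                residues[int(p["res3"])], cls_, tuple(wc_hbond_triples(cls_)),
            ))
        hbonds = _build_hbonds(tuple(positions))
        return cls(residues, tuple(positions), tuple(data["competing_position_ids"]),
                   int(data["boundary_residue"]), hbonds, data.get("tag", "6P1_11AT"))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ConstructRegistry":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def export_bond_list(self, path: str | Path) -> None:
        """Write the master hydrogen-bond list as CSV (one row per bond)."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["bond_id", "helix", "ordinal", "donor_res", "donor_atom",
                        "h_atom", "acceptor_res", "acceptor_atom"])
            for b in self.hbonds:
                w.writerow([b.bond_id, b.helix, b.ordinal, b.donor_res,
                            b.donor_atom, b.h_atom, b.acceptor_res, b.acceptor_atom])


def _build_hbonds(positions: Iterable[PairPosition]) -> tuple[HBond, ...]:
    bonds: list[HBond] = []
    bid = 0
    for pos in positions:
        for donor_side, donor, hyd, acc_side, acceptor in WC_BOND_LAYOUT[pos.wc_class]:
            dres = pos.res5 if donor_side == "5" else pos.res3
            ares = pos.res5 if acc_side == "5" else pos.res3
            bonds.append(HBond(bid, pos.helix, pos.ordinal, dres.hybrid_id, donor,
                               hyd, ares.hybrid_id, acceptor))
            bid += 1
    return tuple(bonds)


def build_default_registry() -> ConstructRegistry:
    """The hybrid construct with 6 potential P1 and 11 potential AT pairs.

    Deterministic and idempotent: every call returns an equal registry.
    Residues that the source names explicitly (A4, U110, A136, A109, A111,
    U2, A112, U5, G11, ...) carry those identities; remaining positions are
    filled with alternating A-U / G-C placeholders.
    """
    residues: dict[int, Residue] = {}
    for rid, base in _P1_5PRIME.items():
        residues[rid] = Residue(rid, base, "P1_5prime")
    for rid, base in _SWITCHING.items():
        residues[rid] = Residue(rid, base, "switching_strand")
    for rid, base in _AT_3PRIME.items():
        residues[rid] = Residue(rid, base, "AT_3prime")
    for rid, base in _CORE.items():
        residues[rid] = Residue(rid, base, "core", aptamer_id=rid + 2)

    positions: list[PairPosition] = []
    # P1 ordinal p pairs 5'-strand residue p with switching residue 114 - p.
    for p in range(1, 7):
        r5, r3 = residues[p], residues[114 - p]
        cls_ = r5.base + r3.base
        positions.append(PairPosition(P1, p, r5, r3, cls_,
                                      tuple(wc_hbond_triples(cls_))))
    # AT ordinal a pairs switching residue 112 - a with 3'-strand 134 + a.
    for a in range(1, 12):
        r5, r3 = residues[112 - a], residues[134 + a]
        cls_ = r5.base + r3.base
        positions.append(PairPosition(AT, a, r5, r3, cls_,
                                      tuple(wc_hbond_triples(cls_))))

    hbonds = _build_hbonds(positions)
    reg = ConstructRegistry(residues, tuple(positions), _COMPETING, _BOUNDARY, hbonds)
    _validate(reg)
    return reg


def _validate(reg: ConstructRegistry) -> None:
    if len(reg.positions(P1)) != 6 or len(reg.positions(AT)) != 11:
        raise RegistryError("construct must offer 6 P1 and 11 AT positions")
    if len(reg.competing_position_ids) != 4:
        raise RegistryError("competition region must span 4 positions")
    offsets = {r.aptamer_id - r.hybrid_id for r in reg.residues.values()
               if r.aptamer_id is not None}
    if len(offsets) > 1:
        raise RegistryError("aptamer numbering offset must be constant")
    hits = [p for p in reg.pair_positions
            if reg.boundary_residue in (p.res5.hybrid_id, p.res3.hybrid_id)]
    if {p.helix for p in hits} != {P1, AT} or len(hits) != 2:
        raise RegistryError("boundary residue must sit in exactly one P1 and one AT position")
    # WC complementarity and template atom coverage of the master bond list.
    for pos in reg.pair_positions:
        if pos.res3.base != WC_PARTNER_OF[pos.res5.base]:
            raise RegistryError(f"{pos.helix}{pos.ordinal}: non-WC pair "
                                f"{pos.res5.name}-{pos.res3.name}")
    for b in reg.hbonds:
        for rid, atom in ((b.donor_res, b.donor_atom), (b.donor_res, b.h_atom),
                          (b.acceptor_res, b.acceptor_atom)):
            if atom not in residue_template(reg.residues[rid].base):
                raise RegistryError(f"bond {b.bond_id}: atom {atom} missing from "
                                    f"{reg.residues[rid].name} template")


WC_PARTNER_OF = {"A": "U", "U": "A", "G": "C", "C": "G"}


def diff_pairing(map_a: PairingMap, map_b: PairingMap) -> list[PairingChange]:
    """Positions whose state differs between two pairing maps.

    Changes are labelled AT->P1, P1->AT, unpaired->paired or paired->unpaired.
    ``diff_pairing(a, b)`` and ``diff_pairing(b, a)`` carry exactly inverse
    labels.
    """
    if map_a.registry_tag != map_b.registry_tag:
        raise RegistryError("pairing maps refer to different registries")
    a, b = map_a.as_dict(), map_b.as_dict()
    if set(a) != set(b):
        raise RegistryError("pairing maps cover different competing positions")
    return [PairingChange(pos, a[pos], b[pos])
            for pos in sorted(a) if a[pos] != b[pos]]


def count_transitions(changes: Iterable[PairingChange]) -> dict[str, int]:
    """Tally of transition labels in a change list."""
    out: dict[str, int] = {}
    for c in changes:
        out[c.label] = out.get(c.label, 0) + 1
    return out
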