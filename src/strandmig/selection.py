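"""Conformational state clustering and intermediate-model selection.

Two uses of k-means live here: grouping per-frame base-pair geometries into
discrete conformational states (default k = 5, on nucleobase RMSD features),
and classifying candidate intermediate models by their two boundary stacking
energies (default k = 4 classes, the class with the lowest mean energy sum
being the coaxially stacked, favorable one).

Model selection applies three hard criteria — no steric clashes, an
accessible ligand pocket, and membership in the favorable stacking class —
and then ranks survivors by a pluggable energy score (Lennard-Jones plus
screened Coulomb).  Ranks, not absolute energies, are the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .metrics import (DEBYE_HUCKEL_KAPPA, DEFAULT_LJ, LJParams,
                      exclusions_from_bonds, lj_pair_energy, phosphate_charges,
                      screened_coulomb_energy, steric_clash_count)
from .registry import ConstructRegistry
from .trajectory_io import AtomKey

__all__ = [
    "StateAssignment",
    "ModelCandidate",
    "PocketSpec",
    "kmeans_states",
    "boundary_vdw",
    "stacking_class",
    "pocket_accessible",
    "score_candidate",
    "rank_models",
]

#: hinge dinucleotide steps monitored for boundary coaxial stacking
HINGE_PAIRS = ((109, 110), (110, 111))


@dataclass
class StateAssignment:
    """k-means state labels (1..k) with centroids and representatives."""

    labels: np.ndarray
    centroids: np.ndarray
    populations: dict[int, int]
    representatives: dict[int, int]  # state -> frame index nearest centroid

    @property
    def k(self) -> int:
        return len(self.centroids)

    def to_csv(self, path) -> None:
        pd.DataFrame({"frame": np.arange(len(self.labels)),
                      "state": self.labels}).to_csv(path, index=False)


def kmeans_states(features: np.ndarray, k: int, seed: int = 0,
                  n_init: int = 10) -> StateAssignment:
    """Cluster per-frame feature vectors into ``k`` states.

    Seeded multi-start k-means (squared Euclidean); deterministic for a fixed
    seed.  Each state's representative frame is the frame nearest its
    centroid, lowest index on ties.  Populations sum to the frame count.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(X)
    if k < 1 or k > n:
        raise ValueError(f"k={k} outside [1, {n}]")
    if len(np.unique(X, axis=0)) < k:
        raise ValueError(f"need at least {k} distinct feature vectors")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(X)
    labels = raw + 1
    populations = {s: int((labels == s).sum()) for s in range(1, k + 1)}
    reps = {}
    for s in range(1, k + 1):
        d = np.linalg.norm(X - km.cluster_centers_[s - 1], axis=1)
        d[labels != s] = np.inf
        reps[s] = int(np.argmin(d))  # argmin takes the lowest index on ties
    return StateAssignment(labels, km.cluster_centers_.copy(), populations, reps)


# ---------------------------------------------------------------------------
# Candidate models
# ---------------------------------------------------------------------------

@dataclass
class PocketSpec:
    """Geometric ligand-pocket accessibility test.

    The pocket is open when no heavy atom outside its native residue set lies
    within ``cutoff`` of its centroid (strict inequality: an atom exactly at
    the cutoff does not block).
    """

    native_resids: frozenset[int]
    centroid: np.ndarray
    cutoff: float = 4.0


@dataclass
class ModelCandidate:
    """One candidate intermediate structure with its audit scores."""

    model_id: str
    coords: dict[AtomKey, np.ndarray]
    vdw_hinge_a: float | None = None  # boundary stack 5' side
    vdw_hinge_b: float | None = None  # boundary stack 3' side
    clash_count: int | None = None
    energy_score: float | None = None
    pocket_open: bool | None = None
    stacking_label: int | None = None

    def residue_atoms(self, resid: int) -> dict[str, np.ndarray]:
        return {name: p for (rid, name), p in self.coords.items() if rid == resid}


def boundary_vdw(model: ModelCandidate, registry: ConstructRegistry,
                 params: LJParams = DEFAULT_LJ) -> tuple[float, float]:
    """LJ stacking energies of the two hinge dinucleotide steps.

    These are the adjacent steps flanking the boundary residue on the
    switching strand (A109-U110 and U110-A111 in the default construct); a
    coaxially stacked boundary gives two favorable (negative) values.
    """
    energies = []
    for r1, r2 in HINGE_PAIRS:
        a1, a2 = model.residue_atoms(r1), model.residue_atoms(r2)
        if not a1 or not a2:
            raise KeyError(f"model {model.model_id}: hinge residue "
                           f"{r1 if not a1 else r2} missing")
        energies.append(lj_pair_energy(a1, a2, params))
    return energies[0], energies[1]


def stacking_class(points: np.ndarray, k: int = 4, seed: int = 0,
                   n_init: int = 10) -> tuple[np.ndarray, int]:
    """Cluster boundary-energy scatter points into ``k`` classes.

    Returns ``(labels in 1..k, favorable class id)`` where the favorable
    class has the lowest mean energy sum; it necessarily contains the point
    with the minimal sum among its members.
    """
    pts = np.asarray(points, dtype=float)
    assignment = kmeans_states(pts, k, seed=seed, n_init=n_init)
    sums = assignment.centroids.sum(axis=1)
    favorable = int(np.argmin(sums)) + 1
    return assignment.labels, favorable


def pocket_accessible(model: ModelCandidate, pocket: PocketSpec) -> bool:
    """True iff no foreign heavy atom intrudes within the pocket cutoff."""
    if pocket is None or len(pocket.native_resids) == 0:
        raise ValueError("pocket specification is undefined")
    c = np.asarray(pocket.centroid, dtype=float)
    for (rid, name), p in model.coords.items():
        if rid in pocket.native_resids or name.startswith("H"):
            continue
        if float(np.linalg.norm(np.asarray(p) - c)) < pocket.cutoff:
            return False
    return True


def model_exclusions(coords: Mapping[AtomKey, np.ndarray],
                     registry: ConstructRegistry) -> set[frozenset]:
    """1-2/1-3 clash exclusions implied by residue connectivity.

    Uses the registry's base identities for intra-residue bonds plus the
    O3'-P link between consecutive residue ids; atoms of residues unknown to
    the registry carry no exclusions.
    """
    from .templates import residue_bonds

    bonds: list[tuple[AtomKey, AtomKey]] = []
    resids = sorted({rid for rid, _ in coords})
    for rid in resids:
        res = registry.residues.get(rid)
        if res is None:
            continue
        for a, b in residue_bonds(res.base):
            if (rid, a) in coords and (rid, b) in coords:
                bonds.append(((rid, a), (rid, b)))
    for r1, r2 in zip(resids, resids[1:]):
        if r2 == r1 + 1 and (r1, "O3'") in coords and (r2, "P") in coords:
            bonds.append(((r1, "O3'"), (r2, "P")))
    return exclusions_from_bonds(bonds)


def score_candidate(model: ModelCandidate, registry: ConstructRegistry,
                    pocket: PocketSpec, lj: LJParams = DEFAULT_LJ,
                    kappa: float = DEBYE_HUCKEL_KAPPA,
                    clash_cutoff: float = 2.0,
                    exclusions: set | None = None) -> ModelCandidate:
    """Fill in every per-candidate score used by :func:`rank_models`."""
    model.vdw_hinge_a, model.vdw_hinge_b = boundary_vdw(model, registry, lj)
    if exclusions is None:
        exclusions = model_exclusions(model.coords, registry)
    model.clash_count = steric_clash_count(model.coords, clash_cutoff,
                                           exclusions)
    model.pocket_open = pocket_accessible(model, pocket)
    lj_total = model.vdw_hinge_a + model.vdw_hinge_b
    coulomb = screened_coulomb_energy(phosphate_charges(model.coords), kappa)
    model.energy_score = lj_total + coulomb
    return model


def rank_models(candidates: Sequence[ModelCandidate],
                stacking_k: int = 4, seed: int = 0
                ) -> tuple[list[ModelCandidate], pd.DataFrame]:
    """Filter and rank scored candidates.

    Hard filters first — zero steric clashes, open ligand pocket, membership
    in the favorable stacking class — then ascending energy score.  Returns
    the ordered passing subset and a full per-criterion audit table.  The
    filters are order-independent and the output is a permutation of the
    passing subset.
    """
    if not candidates:
        raise ValueError("no candidate models supplied")
    for m in candidates:
        if None in (m.vdw_hinge_a, m.clash_count, m.energy_score, m.pocket_open):
            raise ValueError(f"candidate {m.model_id} not fully scored")
    pts = np.array([[m.vdw_hinge_a, m.vdw_hinge_b] for m in candidates])
    k = min(stacking_k, len(np.unique(pts, axis=0)))
    labels, favorable = stacking_class(pts, k=k, seed=seed)
    for m, lab in zip(candidates, labels):
        m.stacking_label = int(lab)

    rows = []
    passing = []
    for m in candidates:
        ok_clash = m.clash_count == 0
        ok_stack = m.stacking_label == favorable
        ok = ok_clash and m.pocket_open and ok_stack
        rows.append({"model_id": m.model_id, "clash_count": m.clash_count,
                     "clash_pass": ok_clash, "pocket_pass": m.pocket_open,
                     "stacking_class": m.stacking_label,
                     "stacking_pass": ok_stack,
                     "vdw_hinge_a": m.vdw_hinge_a, "vdw_hinge_b": m.vdw_hinge_b,
                     "energy_score": m.energy_score, "pass_all": ok})
        if ok:
            passing.append(m)
    passing.sort(key=lambda m: (m.energy_score, m.model_id))
    audit = pd.DataFrame(rows)
    rank_of = {m.model_id: i + 1 for i, m in enumerate(passing)}
    audit["rank"] = [rank_of.get(mid, pd.NA) for mid in audit["model_id"]]
    return passing, audit
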