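"""Ligand-contact probability profiles and ionic-bond occupancy.

A ligand is "in contact" with a residue in a frame when the minimal
distance between any ligand atom and any atom of the residue is strictly
below the cutoff.  Two cutoffs are in common use for this system — 2.5 A
and 2.0 A — so the cutoff is always an explicit parameter and is recorded
in the output.  Contacts use all atoms, hydrogens included when present.

The D159-K83 interdomain ionic bond of cTnC is scored the same way on the
Asp side-chain carboxylate oxygens (OD1/OD2) versus the Lys side-chain
nitrogen (NZ), with a 4.0 A default cutoff (standard salt-bridge
criterion); occupancy is the fraction of frames with the bond formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import (
    ROLE_TNC,
    ROLE_TNI,
    ROLE_TNT,
    Selection,
    Trajectory,
    ligand_atoms,
    resolve_selection,
    tn_resid,
)

__all__ = [
    "ContactProfile",
    "BondOccupancy",
    "residue_min_distance",
    "contact_profile",
    "bond_occupancy",
    "occupancy_from_distances",
    "TROPONIN_CORE_RESIDUES",
]

#: Residue grid of the troponin core: TnC 1-161, TnI 1-169, TnT 202-288.
TROPONIN_CORE_RESIDUES: tuple[tuple[str, int], ...] = tuple(
    [(ROLE_TNC, r) for r in range(1, 162)]
    + [(ROLE_TNI, r) for r in range(1, 170)]
    + [(ROLE_TNT, r) for r in range(202, 289)]
)


def residue_min_distance(
    frame: np.ndarray, ligand_atom_indices: np.ndarray, residue_atom_indices: np.ndarray
) -> float:
    """Minimum Euclidean distance (A) over all ligand-atom x residue-atom pairs."""
    li = np.asarray(ligand_atom_indices, dtype=int)
    ri = np.asarray(residue_atom_indices, dtype=int)
    if li.size == 0 or ri.size == 0:
        raise ValueError("residue_min_distance needs non-empty atom lists")
    return float(cdist(frame[li], frame[ri]).min())


@dataclass
class ContactProfile:
    """Per-residue ligand-contact counts/probabilities under one cutoff.

    Residues of the reference grid that are absent from the topology carry
    count -1 (missing), not 0; their probability is NaN.
    """

    table: pd.DataFrame  # columns: chain, residue_index, residue_name, count, probability
    cutoff: float
    n_frames: int

    def probability(self, role: str, residue_index: int) -> float:
        row = self.table[
            (self.table["chain"] == role) & (self.table["residue_index"] == residue_index)
        ]
        if row.empty:
            raise KeyError(f"residue ({role}, {residue_index}) not in profile")
        return float(row["probability"].iloc[0])

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["cutoff"] = self.cutoff
        out["n_frames"] = self.n_frames
        out.to_csv(path, index=False, float_format="%.6g")


def contact_profile(
    trajectory: Trajectory,
    ligand_selection: Selection | None = None,
    residue_set: tuple[tuple[str, int], ...] = TROPONIN_CORE_RESIDUES,
    cutoff: float = 2.5,
) -> ContactProfile:
    """Count, per residue, the frames in which any ligand atom lies strictly
    within ``cutoff`` of any residue atom."""
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    topo = trajectory.topology
    lig = resolve_selection(topo, ligand_selection or ligand_atoms())

    # group residue atoms contiguously for a reduceat-based per-frame min
    atom_by_residue: dict[tuple[str, int], list[int]] = {}
    resname_by_residue: dict[tuple[str, int], str] = {}
    for i, atom in enumerate(topo.atoms):
        key = (topo.role_of(atom), atom.residue_index)
        atom_by_residue.setdefault(key, []).append(i)
        resname_by_residue.setdefault(key, atom.residue_name)

    present = [key for key in residue_set if key in atom_by_residue]
    flat = np.concatenate([atom_by_residue[k] for k in present]) if present else np.empty(0, int)
    seg_starts = np.cumsum([0] + [len(atom_by_residue[k]) for k in present])[:-1]

    counts = np.zeros(len(present), dtype=int)
    if present and cutoff > 0:
        for f in range(trajectory.n_frames):
            frame = trajectory.coordinates[f]
            d = cdist(frame[lig], frame[flat]).min(axis=0)
            seg_min = np.minimum.reduceat(d, seg_starts)
            counts += seg_min < cutoff

    count_by_key = dict(zip(present, counts))
    rows = []
    for role, resid in residue_set:
        key = (role, resid)
        if key in count_by_key:
            c = int(count_by_key[key])
            p = c / trajectory.n_frames
            name = resname_by_residue[key]
        else:
            c, p, name = -1, float("nan"), ""
        rows.append(
            {"chain": role, "residue_index": resid, "residue_name": name, "count": c, "probability": p}
        )
    return ContactProfile(table=pd.DataFrame(rows), cutoff=cutoff, n_frames=trajectory.n_frames)


@dataclass
class BondOccupancy:
    """Per-frame minimum distance between two atom selections and the
    fraction of frames below the cutoff."""

    selection_a: str
    selection_b: str
    cutoff: float
    distances: np.ndarray
    occupancy: float


def occupancy_from_distances(distances: np.ndarray, cutoff: float) -> float:
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance series")
    return float(np.count_nonzero(d < cutoff) / d.size)


def bond_occupancy(
    trajectory: Trajectory,
    selection_a: Selection,
    selection_b: Selection,
    cutoff: float = 4.0,
) -> BondOccupancy:
    """Score a distance-defined bond: per-frame min distance between the two
    selections, occupancy = fraction of frames with distance < cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    topo = trajectory.topology
    ia = resolve_selection(topo, selection_a)
    ib = resolve_selection(topo, selection_b)
    a = trajectory.coordinates[:, ia, :]
    b = trajectory.coordinates[:, ib, :]
    # pairwise distances per frame, vectorized over frames
    diff = a[:, :, None, :] - b[:, None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1)).reshape(trajectory.n_frames, -1).min(axis=1)
    return BondOccupancy(
        selection_a=selection_a.name,
        selection_b=selection_b.name,
        cutoff=cutoff,
        distances=d,
        occupancy=occupancy_from_distances(d, cutoff),
    )


def d159_k83_selections() -> tuple[Selection, Selection]:
    """Default selections for the TnC D159-K83 ionic bond: Asp159 OD1/OD2
    versus Lys83 NZ."""
    return (
        tn_resid(ROLE_TNC, 159, 159, atom_names=("OD1", "OD2")),
        tn_resid(ROLE_TNC, 83, 83, atom_names=("NZ",)),
    )
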