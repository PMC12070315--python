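"""Ligand-pose cluster analysis.

Frames are first superposed on a common reference over the protein
C-alpha atoms, so ligand positions are expressed relative to one protein
conformer; the ligand center of mass per frame is then clustered with
DBSCAN (neighbour radius eps, default 10 A; minimum cluster size 1% of
the frame count).  Cluster occupancies estimate the probability of each
binding site; the representative pose of a cluster is the member frame
whose center of mass is nearest the cluster mean.

The DBSCAN here is written for exact reproducibility: min_points counts
the point itself, points are processed in ascending frame order, border
points belong to the first cluster that claims them, and final labels
0,1,2,... are ordered by descending occupancy (noise = -1).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import Selection, Trajectory, ligand_atoms, resolve_selection
from .core import protein_calpha as _protein_calpha
from .geometry import kabsch_fit

__all__ = [
    "PoseSet",
    "ClusterResult",
    "align_trajectory",
    "medoid_frame",
    "ligand_centers",
    "dbscan_cluster",
    "cluster_summary",
]


@dataclass
class PoseSet:
    """Aligned ligand center-of-mass points, one per frame."""

    points: np.ndarray  # (n_frames, 3)
    reference_frame: int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("PoseSet points must have shape (n_frames, 3)")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class ClusterResult:
    labels: np.ndarray               # per-frame; -1 = noise
    eps: float
    min_points: int
    occupancy: dict[int, float]      # cluster -> fraction of all frames
    noise_fraction: float
    representative_frame: dict[int, int]

    def occupancy_of_clustered(self) -> dict[int, float]:
        """Occupancies renormalised over clustered (non-noise) frames."""
        clustered = 1.0 - self.noise_fraction
        if clustered <= 0:
            return {}
        return {c: f / clustered for c, f in self.occupancy.items()}


def align_trajectory(
    trajectory: Trajectory,
    reference_frame: int = 0,
    fit_selection: Selection | None = None,
) -> Trajectory:
    """Superpose every frame onto ``reference_frame`` by a least-squares fit
    over ``fit_selection`` (default: protein C-alpha); all atoms, ligand
    included, are carried along by the per-frame rigid transform."""
    n = trajectory.n_frames
    if not (-n <= reference_frame < n):
        raise IndexError(f"reference frame {reference_frame} out of range")
    sel = fit_selection or _protein_calpha()
    idx = resolve_selection(trajectory.topology, sel)
    ref = trajectory.coordinates[reference_frame][idx]
    out = np.empty_like(trajectory.coordinates)
    for f in range(n):
        tr = kabsch_fit(trajectory.coordinates[f][idx], ref)
        out[f] = tr.apply(trajectory.coordinates[f])
    return Trajectory(
        topology=trajectory.topology,
        coordinates=out,
        frame_labels=list(trajectory.frame_labels) if trajectory.frame_labels else None,
    )


def medoid_frame(
    trajectory: Trajectory,
    fit_selection: Selection | None = None,
    candidates: np.ndarray | None = None,
) -> int:
    """Frame minimising the summed C-alpha RMSD to all (candidate) frames —
    the operational "representative structure" for superposition.

    Exhaustive over all frame pairs (O(n^2) superpositions); pass
    ``candidates`` to restrict the comparison set for long trajectories.
    """
    sel = fit_selection or _protein_calpha()
    idx = resolve_selection(trajectory.topology, sel)
    frames = np.arange(trajectory.n_frames) if candidates is None else np.asarray(candidates, int)
    coords = trajectory.coordinates[:, idx, :]
    total = np.zeros(len(frames))
    for a, fa in enumerate(frames):
        for b in range(a + 1, len(frames)):
            r = kabsch_fit(coords[frames[b]], coords[fa]).rmsd
            total[a] += r
            total[b] += r
    return int(frames[int(np.argmin(total))])


def ligand_centers(
    aligned_trajectory: Trajectory, ligand_selection: Selection | None = None,
    reference_frame: int = 0,
) -> PoseSet:
    """Mass-weighted ligand center of mass per frame of an aligned trajectory."""
    idx = resolve_selection(aligned_trajectory.topology, ligand_selection or ligand_atoms())
    masses = aligned_trajectory.topology.masses[idx]
    w = masses / masses.sum()
    pts = (aligned_trajectory.coordinates[:, idx, :] * w[None, :, None]).sum(axis=1)
    return PoseSet(points=pts, reference_frame=reference_frame)


def dbscan_cluster(
    pose_set: PoseSet | np.ndarray,
    eps: float = 10.0,
    min_points: int | None = None,
) -> ClusterResult:
    """Density-based clustering of pose centers.

    A core point has >= min_points neighbours within eps (itself included);
    clusters are connected components of core points plus their border
    points.  ``min_points`` defaults to ceil(0.01 * n_frames).
    """
    points = pose_set.points if isinstance(pose_set, PoseSet) else np.asarray(pose_set, float)
    n = points.shape[0]
    if n == 0:
        raise ValueError("empty pose set")
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_points is None:
        min_points = max(1, ceil(0.01 * n))
    if min_points < 1:
        raise ValueError("min_points must be >= 1")

    tree = cKDTree(points)
    neighbors = tree.query_ball_point(points, r=eps)
    core = np.array([len(nb) >= min_points for nb in neighbors])

    labels = np.full(n, -1, dtype=int)
    cid = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        labels[i] = cid
        stack = [i]
        while stack:
            j = stack.pop()
            for k in sorted(neighbors[j]):
                if labels[k] == -1:
                    labels[k] = cid
                    if core[k]:
                        stack.append(k)
        cid += 1

    # relabel by descending occupancy; ties broken by earliest member frame
    sizes = np.bincount(labels[labels >= 0], minlength=cid)
    first_member = [int(np.argmax(labels == c)) for c in range(cid)]
    order = sorted(range(cid), key=lambda c: (-sizes[c], first_member[c]))
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[l] if l >= 0 else -1 for l in labels], dtype=int)

    occupancy = {remap[c]: sizes[c] / n for c in range(cid)}
    noise_fraction = float(np.count_nonzero(labels == -1) / n)

    representative: dict[int, int] = {}
    for c in sorted(occupancy):
        members = np.flatnonzero(labels == c)
        center = points[members].mean(axis=0)
        dist = np.linalg.norm(points[members] - center, axis=1)
        representative[c] = int(members[int(np.argmin(dist))])  # argmin ties -> lowest index

    return ClusterResult(
        labels=labels,
        eps=float(eps),
        min_points=int(min_points),
        occupancy={c: float(f) for c, f in sorted(occupancy.items())},
        noise_fraction=noise_fraction,
        representative_frame=representative,
    )


def cluster_summary(result: ClusterResult, trajectory: Trajectory | None = None) -> pd.DataFrame:
    """Per-cluster table: frame count, occupancy as percent of all frames and
    of clustered frames, and the representative (medoid-like) frame index."""
    n = result.labels.size
    if trajectory is not None and trajectory.n_frames != n:
        raise ValueError("cluster labels inconsistent with trajectory length")
    clustered = result.occupancy_of_clustered()
    rows = [
        {
            "cluster_id": c,
            "n_frames": int(round(f * n)),
            "occupancy_pct": 100.0 * f,
            "occupancy_pct_clustered": 100.0 * clustered.get(c, float("nan")),
            "representative_frame": result.representative_frame[c],
        }
        for c, f in sorted(result.occupancy.items())
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "n_frames",
            "occupancy_pct",
            "occupancy_pct_clustered",
            "representative_frame",
        ],
    )


def write_representative_poses(
    result: ClusterResult, trajectory: Trajectory, outdir, prefix: str = "cluster"
) -> list[str]:
    """Write each cluster's representative pose as a single-model PDB file."""
    from pathlib import Path

    from .core import write_pdb_models

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for c, frame in sorted(result.representative_frame.items()):
        path = outdir / f"{prefix}_{c}_frame{frame}.pdb"
        path.write_text(write_pdb_models(trajectory, [frame]))
        paths.append(str(path))
    return paths
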