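"""Rigid-body superposition and the two angle metrics tracked per frame.

Two scalar observables summarise troponin's large-scale dynamics here:

* the **interdomain hinge angle** — the angle at the hinge linker between
  the N-lobe of cTnC (NcTnC) and the quasi-rigid ITC core, computed as the
  centroid-linker-centroid angle over C-alpha atoms;
* the **A/B interhelical angle** — the crossing angle between cTnC helices
  A and B, whose opening/closing reports the regulatory-lobe state.

Helix axes are the first principal component of the helix C-alpha cloud,
sign-fixed N-terminus -> C-terminus so the crossing angle distinguishes open
(>90 deg) from closed conformers.  Both observables are invariant under a
global rigid motion of every frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .core import SelectionError, Trajectory, calpha, resolve_selection
from .distributions import AngleSeries

__all__ = [
    "RigidTransform",
    "HelixDefinition",
    "DomainDefinition",
    "HingeDefinition",
    "DegenerateGeometryError",
    "kabsch_fit",
    "helix_axis",
    "vector_angle",
    "ab_angle_series",
    "hinge_angle_series",
]


class DegenerateGeometryError(ValueError):
    """Too few or collinear points for a well-defined geometric fit."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> rotation @ x + translation`` with the RMSD
    achieved over the fitted selection.  det(rotation) = +1 always."""

    rotation: np.ndarray     # (3, 3) orthonormal, det +1
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class HelixDefinition:
    """A helix named by its role and inclusive residue range (>= 4 residues:
    the principal axis is ill-defined below one turn)."""

    label: str
    role: str
    first: int
    last: int

    def __post_init__(self) -> None:
        if self.last - self.first + 1 < 4:
            raise ValueError(f"helix {self.label!r}: range must span >= 4 residues")

    def selection(self):
        return calpha(self.role, (self.first, self.last))


@dataclass(frozen=True)
class DomainDefinition:
    """A quasi-rigid domain as a union of (role, residue-range) parts."""

    label: str
    parts: tuple[tuple[str, tuple[int, int]], ...]

    def selection(self):
        sel = calpha(*_part(self.parts[0]))
        for part in self.parts[1:]:
            sel = sel | calpha(*_part(part))
        return sel


def _part(part):
    role, (lo, hi) = part
    return role, (lo, hi)


@dataclass(frozen=True)
class HingeDefinition:
    """Two domains plus the hinge linker between them.  Domain residue sets
    must be disjoint; the linker must be non-empty."""

    domain1: DomainDefinition
    domain2: DomainDefinition
    linker: tuple[str, tuple[int, int]]

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for dom in (self.domain1, self.domain2):
            for role, (lo, hi) in dom.parts:
                for r in range(lo, hi + 1):
                    key = (role, r)
                    if key in seen:
                        raise ValueError(
                            f"domains {self.domain1.label!r}/{self.domain2.label!r} overlap at {key}"
                        )
                    seen.add(key)


def kabsch_fit(
    mobile_coords: np.ndarray,
    reference_coords: np.ndarray,
    weights: np.ndarray | None = None,
) -> RigidTransform:
    """Weighted least-squares superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation + translation minimising the weighted RMSD;
    reflections are excluded.  Requires >= 3 non-collinear points.
    """
    mob = np.asarray(mobile_coords, dtype=float)
    ref = np.asarray(reference_coords, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("mobile and reference must both have shape (n, 3)")
    n = mob.shape[0]
    if n < 3:
        raise DegenerateGeometryError("superposition needs at least 3 points")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()

    mob_c = (w[:, None] * mob).sum(axis=0)
    ref_c = (w[:, None] * ref).sum(axis=0)
    ref0 = ref - ref_c
    sv = np.linalg.svd(ref0 * np.sqrt(w)[:, None], compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise DegenerateGeometryError("reference points are collinear")

    rot, _ = Rotation.align_vectors(ref0, mob - mob_c, weights=w)
    R = rot.as_matrix()
    t = ref_c - R @ mob_c
    moved = mob @ R.T + t
    rmsd = float(np.sqrt((w * ((moved - ref) ** 2).sum(axis=1)).sum()))
    return RigidTransform(rotation=R, translation=t, rmsd=rmsd)


def helix_axis(calpha_coords: np.ndarray, method: str = "geometric") -> np.ndarray:
    """Unit vector along a helix axis, pointing N-terminus -> C-terminus.

    ``"geometric"`` (default): the second differences of consecutive
    C-alpha positions of a helix point radially inward, so consecutive
    cross products of them lie along the axis; their sum recovers the axis
    of an ideal helix exactly for any length >= 4 residues.  ``"pca"``: the
    first principal axis of the centered cloud — simpler, but biased by up
    to a few degrees when the span is not a whole number of turns.
    """
    coords = np.asarray(calpha_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 4:
        raise DegenerateGeometryError("helix axis needs at least 4 C-alpha positions")
    axis = None
    if method == "geometric":
        second = np.diff(coords, n=2, axis=0)       # radial vectors
        crosses = np.cross(second[:-1], second[1:])  # each along the axis
        total = crosses.sum(axis=0)
        norm = np.linalg.norm(total)
        if norm > 1e-10:
            axis = total / norm
        # near-degenerate (e.g. collinear input): fall through to PCA
    elif method != "pca":
        raise ValueError(f"unknown helix-axis method {method!r}")
    if axis is None:
        centered = coords - coords.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
    if axis @ (coords[-1] - coords[0]) < 0:
        axis = -axis
    return axis


def vector_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("vector_angle is undefined for a zero vector")
    cosang = np.clip((u @ v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def ab_angle_series(
    trajectory: Trajectory,
    helix_a: HelixDefinition,
    helix_b: HelixDefinition,
    condition=None,
) -> AngleSeries:
    """Per-frame crossing angle between two helix axes (degrees)."""
    ia = resolve_selection(trajectory.topology, helix_a.selection())
    ib = resolve_selection(trajectory.topology, helix_b.selection())
    values = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        frame = trajectory.coordinates[f]
        values[f] = vector_angle(helix_axis(frame[ia]), helix_axis(frame[ib]))
    return AngleSeries(values=values, metric="ab_angle", condition=condition)


def hinge_angle_series(
    trajectory: Trajectory,
    hinge: HingeDefinition,
    condition=None,
) -> AngleSeries:
    """Per-frame centroid-linker-centroid angle between the two domains.

    For each frame, H is the C-alpha centroid of the hinge linker and c1/c2
    the C-alpha centroids of the two domains; the reported angle is the angle
    at H between H->c1 and H->c2, in degrees.
    """
    topo = trajectory.topology
    i1 = resolve_selection(topo, hinge.domain1.selection())
    i2 = resolve_selection(topo, hinge.domain2.selection())
    role, (lo, hi) = hinge.linker
    il = resolve_selection(topo, calpha(role, (lo, hi)))
    # vectorized: centroids per frame
    c1 = trajectory.coordinates[:, i1, :].mean(axis=1)
    c2 = trajectory.coordinates[:, i2, :].mean(axis=1)
    h = trajectory.coordinates[:, il, :].mean(axis=1)
    v1 = c1 - h
    v2 = c2 - h
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    if np.any(n1 == 0) or np.any(n2 == 0):
        raise DegenerateGeometryError("domain centroid coincides with hinge point")
    cosang = np.clip((v1 * v2).sum(axis=1) / (n1 * n2), -1.0, 1.0)
    values = np.degrees(np.arccos(cosang))
    return AngleSeries(values=values, metric="hinge_angle", condition=condition)
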