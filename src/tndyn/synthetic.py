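"""Synthetic troponin-like fixtures with stored ground truth.

Every analysis stage in this package is validated by parameter recovery on
data generated here: a reduced, C-alpha-scale troponin model whose hinge
angle is drawn per frame from a prescribed Gaussian, whose cTnC A/B helix
crossing follows a prescribed schedule, whose D159-K83 marker distance
realises an exact target occupancy, whose ligand center of mass is drawn
from a mixture of spatial clusters plus optional shell noise, and whose
motility curves follow a Hill model with additive Gaussian noise.

The generators are fully deterministic: the seed is mandatory, each
source of randomness uses its own derived stream, and every generator
returns its ground truth alongside the data (tests never re-derive truth
from the data itself).  Toggling the per-frame global rigid motion does
not change any drawn angle, label or distance.

The toy model is statistical scaffolding only — no force field, no
thermodynamics; see the methods note for what it does and does not
emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .core import (
    ROLE_LIGAND,
    ROLE_TNC,
    ROLE_TNI,
    ROLE_TNT,
    Atom,
    Topology,
    Trajectory,
    mass_of,
)
from .dose_response import DoseResponseDataset, hill_curve
from .geometry import helix_axis

__all__ = [
    "GeneratorSpec",
    "DoseTruth",
    "ToyModel",
    "HingeTruth",
    "PoseTruth",
    "make_toy_topology",
    "simulate_hinge_trajectory",
    "simulate_ligand_poses",
    "simulate_bond_series",
    "simulate_dose_response",
    "make_condition_fixture",
]

# default ligand-pose mixture: three sites >= 50 A apart, far outside the
# protein envelope, tight enough (sigma 2 A) to be unambiguous at eps 10 A
DEFAULT_CLUSTERS = (
    ((45.0, 0.0, 0.0), 0.90, 2.0),
    ((-45.0, 0.0, 0.0), 0.07, 2.0),
    ((0.0, 45.0, 0.0), 0.03, 2.0),
)
NOISE_SHELL = (70.0, 110.0)  # uniform-in-shell noise radii, clear of every site


@dataclass
class DoseTruth:
    """Ground-truth Hill parameters for motility generation."""

    floor: float = 0.0       # % motile at zero [Ca2+]
    ceiling: float = 80.0    # % motile at saturating [Ca2+]
    ec50: float = 0.075      # uM, Ca axis
    slope: float = 2.0
    noise_sigma: float = 3.0  # percentage points
    coupling: float = 25.0    # wild-type single-point statistic (uP - P)
    compound_ec50: float = 67.0  # uM, compound axis (reverse-recoupling sweep)
    compound_slope: float = 2.0
    replicates: int = 3


@dataclass
class GeneratorSpec:
    """All knobs of the fixture generators, with one mandatory seed."""

    seed: int
    n_frames: int = 5000
    hinge_mean: float = 120.0   # degrees
    hinge_sigma: float = 8.0    # degrees
    ab_angle: float | tuple | np.ndarray = 105.0  # fixed, ("ramp", a, b), or per-frame
    ligand_clusters: tuple = DEFAULT_CLUSTERS     # ((center, weight, sigma), ...)
    noise_weight: float = 0.0
    bond_occupancy_target: float = 0.35
    bond_cutoff: float = 4.0
    contact_residue: tuple[str, int] | None = None
    contact_fraction: float = 0.0
    contact_cutoff: float = 2.5
    global_motion: bool = True
    dose: DoseTruth = field(default_factory=DoseTruth)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("GeneratorSpec requires an explicit seed")
        if self.hinge_sigma <= 0:
            raise ValueError("hinge_sigma must be positive")
        total = sum(w for _, w, _ in self.ligand_clusters) + self.noise_weight
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"ligand cluster weights + noise must sum to 1, got {total}")
        if not 0.0 <= self.bond_occupancy_target <= 1.0:
            raise ValueError("bond_occupancy_target must be in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


# distinct RNG streams per randomness source (determinism contract)
_STREAM_HINGE = 1
_STREAM_BOND = 2
_STREAM_GLOBAL = 3
_STREAM_POSE = 4
_STREAM_DOSE = 5
_STREAM_AB = 6


# ---------------------------------------------------------------------------
# Toy topology
# ---------------------------------------------------------------------------

HELIX_RISE = 1.5     # A per residue
HELIX_RADIUS = 2.3   # A
HELIX_TWIST = 100.0  # deg per residue

HELIX_A_RANGE = (14, 28)
HELIX_B_RANGE = (41, 48)
DOMAIN1_RANGE = (1, 85)     # NcTnC
LINKER_RANGE = (86, 92)
DOMAIN2_C_RANGE = (93, 161)
ITC_TNI_RANGES = ((43, 79), (90, 135))
DOMAIN_ARM = 15.0  # A, distance hinge -> each domain centroid


def _ideal_helix(n: int, phase_deg: float = 0.0) -> np.ndarray:
    k = np.arange(n)
    ang = np.radians(phase_deg + HELIX_TWIST * k)
    return np.stack(
        [HELIX_RADIUS * np.cos(ang), HELIX_RADIUS * np.sin(ang), HELIX_RISE * k], axis=1
    )


def _coil(n: int, center: np.ndarray, pitch: float = 0.9, radius: float = 5.0) -> np.ndarray:
    """Deterministic non-collinear backbone path for filler residues."""
    k = np.arange(n)
    pts = np.stack(
        [radius * np.cos(0.35 * k), radius * np.sin(0.35 * k), pitch * (k - (n - 1) / 2.0)],
        axis=1,
    )
    return pts - pts.mean(axis=0) + np.asarray(center, float)


@dataclass
class ToyModel:
    """Reduced troponin model: topology, reference (body-frame) coordinates
    and the index bookkeeping the frame generators need."""

    topology: Topology
    ref_coords: np.ndarray
    rows_domain2: np.ndarray     # rigid block rotated about the hinge
    rows_helix_b: np.ndarray     # helix B C-alphas (A/B schedule)
    helix_b_pivot: np.ndarray    # rotation pivot for the A/B schedule
    axis_u: np.ndarray           # measured helix A axis
    axis_n: np.ndarray           # rotation axis for the A/B schedule
    ab_ref_angle: float          # crossing angle realised in ref_coords
    row_nz: int
    row_od1: int
    row_od2: int
    rows_ligand: np.ndarray
    ligand_template: np.ndarray  # body coordinates relative to ligand COM
    ligand_masses: np.ndarray


def make_toy_topology(spec: GeneratorSpec) -> ToyModel:
    """Build the reference structure.

    Chain C: 161 C-alpha residues with ideal helices at the A (14-28) and
    B (41-48) positions plus side-chain markers K83 NZ and D159 OD1/OD2;
    chain I: 169 residues; chain T: residues 202-288; a rigid 24-atom
    ligand.  The NcTnC and ITC C-alpha centroids sit exactly 15 A from the
    hinge-linker centroid, and helix B is oriented so that the *measured*
    helix-axis A/B crossing equals the requested reference angle.
    """
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []

    def add(name, element, resid, resname, chain, pos):
        atoms.append(
            Atom(
                index=len(atoms) + 1,
                name=name,
                element=element,
                residue_index=resid,
                residue_name=resname,
                chain_id=chain,
                mass=mass_of(element),
            )
        )
        coords.append(np.asarray(pos, float))

    ab_ref = float(spec.ab_angle if np.isscalar(spec.ab_angle) else 105.0)

    # --- chain C ---------------------------------------------------------
    ca_c = np.zeros((161, 3))
    d1_lo, d1_hi = DOMAIN1_RANGE
    ca_c[d1_lo - 1 : d1_hi] = _coil(d1_hi - d1_lo + 1, center=(0.0, 0.0, 0.0))
    a_lo, a_hi = HELIX_A_RANGE
    helix_a = _ideal_helix(a_hi - a_lo + 1)
    ca_c[a_lo - 1 : a_hi] = helix_a - helix_a.mean(axis=0) + np.array([-4.0, -9.0, 0.0])
    axis_u = helix_axis(ca_c[a_lo - 1 : a_hi])

    # helix B oriented so the measured principal-axis crossing is exact
    b_lo, b_hi = HELIX_B_RANGE
    helix_b_local = _ideal_helix(b_hi - b_lo + 1)
    b_axis0 = helix_axis(helix_b_local)
    w = np.array([1.0, 0.0, 0.0]) - (np.array([1.0, 0.0, 0.0]) @ axis_u) * axis_u
    w /= np.linalg.norm(w)
    target = np.cos(np.radians(ab_ref)) * axis_u + np.sin(np.radians(ab_ref)) * w
    rot_b, _ = Rotation.align_vectors(target[None, :], b_axis0[None, :])
    helix_b = helix_b_local @ rot_b.as_matrix().T
    ca_c[b_lo - 1 : b_hi] = helix_b - helix_b.mean(axis=0) + np.array([4.0, -9.0, 0.0])

    # recenter domain 1 so its C-alpha centroid is exactly (-arm, 0, 0)
    shift1 = np.array([-DOMAIN_ARM, 0.0, 0.0]) - ca_c[d1_lo - 1 : d1_hi].mean(axis=0)
    ca_c[d1_lo - 1 : d1_hi] += shift1

    # hinge linker: symmetric ring, centroid at the origin
    l_lo, l_hi = LINKER_RANGE
    ang = 2.0 * np.pi * np.arange(l_hi - l_lo + 1) / (l_hi - l_lo + 1)
    ca_c[l_lo - 1 : l_hi] = np.stack([np.cos(ang), np.sin(ang), np.zeros_like(ang)], axis=1)
    ca_c[l_lo - 1 : l_hi] -= ca_c[l_lo - 1 : l_hi].mean(axis=0)

    d2_lo, d2_hi = DOMAIN2_C_RANGE
    ca_c[d2_lo - 1 : d2_hi] = _coil(d2_hi - d2_lo + 1, center=(12.0, 0.0, 3.0))

    ca_i = _coil(169, center=(16.0, 6.0, -2.0))
    ca_t = _coil(87, center=(18.0, -6.0, 2.0))

    # shift the whole ITC block so its selection centroid is exactly (+arm, 0, 0)
    itc_parts = [ca_c[d2_lo - 1 : d2_hi]] + [ca_i[lo - 1 : hi] for lo, hi in ITC_TNI_RANGES]
    itc_centroid = np.concatenate(itc_parts).mean(axis=0)
    shift2 = np.array([DOMAIN_ARM, 0.0, 0.0]) - itc_centroid
    ca_c[d2_lo - 1 : d2_hi] += shift2
    ca_i += shift2
    ca_t += shift2

    for r in range(1, 162):
        resname = {83: "LYS", 159: "ASP"}.get(r, "ALA")
        add("CA", "C", r, resname, "C", ca_c[r - 1])
        if r == 83:
            add("NZ", "N", r, "LYS", "C", ca_c[r - 1] + [1.5, 1.5, 0.0])
        elif r == 159:
            add("OD1", "O", r, "ASP", "C", ca_c[r - 1] + [1.2, 0.8, 0.0])
            add("OD2", "O", r, "ASP", "C", ca_c[r - 1] + [1.2, -0.8, 0.0])

    for r in range(1, 170):
        add("CA", "C", r, "ALA", "I", ca_i[r - 1])
    for j, r in enumerate(range(202, 289)):
        add("CA", "C", r, "ALA", "T", ca_t[j])

    # --- rigid 24-atom ligand -------------------------------------------
    grid = np.array([[i, j, k] for i in range(4) for j in range(3) for k in range(2)], float)
    lig_elements = ["C"] * 20 + ["N", "N", "O", "O"]
    lig_masses = np.array([mass_of(e) for e in lig_elements])
    template = grid * 1.4
    template -= (template * lig_masses[:, None]).sum(axis=0) / lig_masses.sum()  # COM at origin
    lig_start = len(atoms)
    for k, (el, pos) in enumerate(zip(lig_elements, template + [40.0, 40.0, 40.0])):
        add(f"{el}{k + 1}", el, 1, "LG7", "L", pos)

    topo = Topology(
        atoms=tuple(atoms),
        chain_roles={"C": ROLE_TNC, "I": ROLE_TNI, "T": ROLE_TNT, "L": ROLE_LIGAND},
    )
    ref = np.array(coords)

    def rows_where(pred):
        return np.array([i for i, a in enumerate(topo.atoms) if pred(a)], dtype=int)

    rows_domain2 = rows_where(
        lambda a: (a.chain_id == "C" and a.residue_index >= d2_lo) or a.chain_id in ("I", "T")
    )
    rows_helix_b = rows_where(
        lambda a: a.chain_id == "C" and a.name == "CA" and b_lo <= a.residue_index <= b_hi
    )
    (row_nz,) = rows_where(lambda a: a.name == "NZ")
    (row_od1,) = rows_where(lambda a: a.name == "OD1")
    (row_od2,) = rows_where(lambda a: a.name == "OD2")
    rows_ligand = np.arange(lig_start, lig_start + 24)

    return ToyModel(
        topology=topo,
        ref_coords=ref,
        rows_domain2=rows_domain2,
        rows_helix_b=rows_helix_b,
        helix_b_pivot=ref[rows_helix_b].mean(axis=0),
        axis_u=axis_u,
        axis_n=np.cross(axis_u, w),
        ab_ref_angle=ab_ref,
        row_nz=int(row_nz),
        row_od1=int(row_od1),
        row_od2=int(row_od2),
        rows_ligand=rows_ligand,
        ligand_template=template,
        ligand_masses=lig_masses,
    )


# ---------------------------------------------------------------------------
# Frame generators
# ---------------------------------------------------------------------------

@dataclass
class HingeTruth:
    theta: np.ndarray            # drawn hinge angles (deg)
    ab_angles: np.ndarray        # scheduled A/B crossing angles (deg)
    global_rotations: np.ndarray  # (n, 3, 3)
    global_translations: np.ndarray  # (n, 3)
    bond_distances: np.ndarray   # realised D159-K83 marker min distances (A)
    bond_mask: np.ndarray        # frames assigned sub-cutoff
    bond_occupancy: float        # exact achieved fraction


def _ab_schedule(spec: GeneratorSpec, n: int) -> np.ndarray:
    """A/B crossing schedule: a fixed scalar, ("ramp", start, stop),
    ("normal", mean, sigma) per-frame draws, or an explicit per-frame array."""
    ab = spec.ab_angle
    if np.isscalar(ab):
        return np.full(n, float(ab))
    if isinstance(ab, (tuple, list)) and len(ab) == 3 and ab[0] == "ramp":
        return np.linspace(float(ab[1]), float(ab[2]), n)
    if isinstance(ab, (tuple, list)) and len(ab) == 3 and ab[0] == "normal":
        draws = spec.rng(_STREAM_AB).normal(float(ab[1]), float(ab[2]), size=n)
        return np.clip(draws, 0.5, 179.5)
    arr = np.asarray(ab, dtype=float)
    if arr.shape != (n,):
        raise ValueError("per-frame ab_angle schedule must have length n_frames")
    return arr


def _random_rotations(rng: np.random.Generator, n: int) -> np.ndarray:
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return Rotation.from_quat(q).as_matrix()


def simulate_hinge_trajectory(
    spec: GeneratorSpec, model: ToyModel | None = None
) -> tuple[Trajectory, HingeTruth, ToyModel]:
    """Per frame: draw the hinge angle from Normal(mean, sigma), rotate the
    ITC block about the hinge so the centroid-linker-centroid angle equals
    the draw exactly; set the A/B crossing per its schedule; realise the
    D159-K83 marker distance per the occupancy schedule; then apply an
    (optional) random global rigid motion.  The truth record stores every
    draw and every transform."""
    model = model or make_toy_topology(spec)
    n = spec.n_frames

    theta = spec.rng(_STREAM_HINGE).normal(spec.hinge_mean, spec.hinge_sigma, size=n)
    theta = np.clip(theta, 0.5, 179.5)
    ab = _ab_schedule(spec, n)

    n_sub = int(np.floor(spec.bond_occupancy_target * n))
    order = spec.rng(_STREAM_BOND).permutation(n)
    bond_mask = np.zeros(n, dtype=bool)
    bond_mask[order[:n_sub]] = True
    d_sub, d_supra = 0.7 * spec.bond_cutoff, 2.0 * spec.bond_cutoff

    if spec.global_motion:
        rng_g = spec.rng(_STREAM_GLOBAL)
        rots = _random_rotations(rng_g, n)
        trans = rng_g.uniform(-30.0, 30.0, size=(n, 3))
    else:
        rots = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
        trans = np.zeros((n, 3))

    ref = model.ref_coords
    coords = np.empty((n, ref.shape[0], 3))
    bond_distances = np.empty(n)
    od = ref[[model.row_od1, model.row_od2]]
    zhat = np.array([0.0, 0.0, 1.0])

    for f in range(n):
        body = ref.copy()
        # A/B schedule: rotate helix B about its own centroid in the u-w plane
        delta_ab = np.radians(ab[f] - model.ab_ref_angle)
        if delta_ab != 0.0:
            R_b = Rotation.from_rotvec(delta_ab * model.axis_n).as_matrix()
            body[model.rows_helix_b] = (
                (body[model.rows_helix_b] - model.helix_b_pivot) @ R_b.T + model.helix_b_pivot
            )
        # hinge: rotate the ITC block about z through the origin
        delta = np.radians(180.0 - theta[f])
        c, s = np.cos(delta), np.sin(delta)
        R_z = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        body[model.rows_domain2] = body[model.rows_domain2] @ R_z.T
        # bond marker: NZ placed relative to the rotated OD1
        d = d_sub if bond_mask[f] else d_supra
        od1 = body[model.row_od1]
        od2 = body[model.row_od2]
        body[model.row_nz] = od1 + d * zhat
        bond_distances[f] = min(d, float(np.linalg.norm(od1 + d * zhat - od2)))
        coords[f] = body @ rots[f].T + trans[f]

    traj = Trajectory(topology=model.topology, coordinates=coords)
    truth = HingeTruth(
        theta=theta,
        ab_angles=ab,
        global_rotations=rots,
        global_translations=trans,
        bond_distances=bond_distances,
        bond_mask=bond_mask,
        bond_occupancy=n_sub / n,
    )
    return traj, truth, model


@dataclass
class PoseTruth:
    labels: np.ndarray        # true component per frame (-1 = noise)
    body_coms: np.ndarray     # ligand COM in the protein body frame
    forced_contact: np.ndarray  # frames with placement overridden for contact
    weights: np.ndarray


def simulate_ligand_poses(
    spec: GeneratorSpec, trajectory: Trajectory, truth: HingeTruth, model: ToyModel
) -> tuple[Trajectory, PoseTruth]:
    """Place the rigid ligand per frame: choose a mixture component by
    weight (noise = uniform in a spherical shell), draw the COM in the
    protein body frame, give the ligand a random orientation, then carry it
    by that frame's global motion.  Optionally force contact with a target
    residue in a prescribed fraction of frames."""
    n = trajectory.n_frames
    rng = spec.rng(_STREAM_POSE)
    centers = np.array([c for c, _, _ in spec.ligand_clusters], float)
    sigmas = np.array([s for _, _, s in spec.ligand_clusters], float)
    weights = np.array([w for _, w, _ in spec.ligand_clusters], float)

    probs = np.concatenate([weights, [spec.noise_weight]])
    comp = rng.choice(len(probs), size=n, p=probs)
    labels = np.where(comp == len(weights), -1, comp)

    coms = np.empty((n, 3))
    for f in range(n):
        if labels[f] >= 0:
            k = labels[f]
            coms[f] = centers[k] + sigmas[k] * rng.standard_normal(3)
        else:
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            coms[f] = direction * rng.uniform(*NOISE_SHELL)
    orients = _random_rotations(rng, n)

    forced = np.zeros(n, dtype=bool)
    if spec.contact_fraction > 0:
        if spec.contact_residue is None:
            raise ValueError("contact_fraction > 0 requires contact_residue")
        k = int(round(spec.contact_fraction * n))
        forced[rng.choice(n, size=k, replace=False)] = True
        role, resid = spec.contact_residue
        target_row = next(
            i
            for i, a in enumerate(model.topology.atoms)
            if model.topology.role_of(a) == role and a.residue_index == resid and a.name == "CA"
        )

    coords = trajectory.coordinates.copy()
    rows = model.rows_ligand
    for f in range(n):
        R_g, t_g = truth.global_rotations[f], truth.global_translations[f]
        lig_body = model.ligand_template @ orients[f].T
        if forced[f]:
            # anchor atom 0 just inside the contact cutoff of the target CA
            ca_body = (coords[f, target_row] - t_g) @ R_g
            anchor = ca_body + 0.5 * spec.contact_cutoff * np.array([0.0, 0.0, 1.0])
            lig_body = lig_body - lig_body[0] + anchor
            coms[f] = (lig_body * model.ligand_masses[:, None]).sum(axis=0) / model.ligand_masses.sum()
        else:
            lig_body = lig_body + coms[f]
        coords[f, rows] = lig_body @ R_g.T + t_g

    out = Trajectory(topology=trajectory.topology, coordinates=coords)
    return out, PoseTruth(labels=labels, body_coms=coms, forced_contact=forced, weights=weights)


def simulate_bond_series(spec: GeneratorSpec) -> tuple[np.ndarray, float]:
    """Standalone D159-K83 marker distance series: exactly
    floor(target * n) frames below the cutoff, the rest above, shuffled by
    the seed.  Returns (distances, exact achieved occupancy)."""
    n = spec.n_frames
    n_sub = int(np.floor(spec.bond_occupancy_target * n))
    d = np.full(n, 2.0 * spec.bond_cutoff)
    order = spec.rng(_STREAM_BOND).permutation(n)
    d[order[:n_sub]] = 0.7 * spec.bond_cutoff
    return d, n_sub / n


# ---------------------------------------------------------------------------
# Motility curves
# ---------------------------------------------------------------------------

#: [Ca2+] grid (uM) spanning the activation transition, incl. the 0.075 uM
#: single-point concentration.
CA_GRID_UM = (0.0075, 0.015, 0.03, 0.075, 0.15, 0.3, 0.6, 1.2)
#: compound sweep (uM) for single-point assays, including zero compound.
COMPOUND_GRID_UM = (0.0, 5.0, 15.0, 40.0, 67.0, 100.0, 200.0)


def _ec50_shifted_for_coupling(dose: DoseTruth, ca_point: float) -> float:
    """EC50 of the phosphorylated curve such that uP - P at ``ca_point``
    equals the wild-type coupling value exactly (noiselessly)."""
    resp_u = hill_curve(np.array([ca_point]), dose.floor, dose.ceiling, dose.ec50, dose.slope)[0]
    target = resp_u - dose.coupling
    f = (target - dose.floor) / (dose.ceiling - dose.floor)
    if not 0.0 < f < 1.0:
        raise ValueError("coupling target outside the dynamic range")
    return ca_point * ((1.0 - f) / f) ** (1.0 / dose.slope)


def simulate_dose_response(
    spec: GeneratorSpec,
    scenario: str = "wild-type",
    ca_single_point: float = 0.075,
) -> tuple[DoseResponseDataset, dict]:
    """Generate motility data plus ground truth for one scenario.

    * ``"wild-type"`` — full Ca-activation curves for both phospho states;
      the P curve is right-shifted so the single-point coupling statistic is
      exactly +``dose.coupling`` at zero noise.
    * ``"uncoupled"`` — identical P and uP curves (coupling 0).
    * ``"reverse"`` — a single-point compound sweep at the fixed [Ca2+]:
      with increasing compound, P motility rises and uP falls along a Hill
      curve with EC50 ``dose.compound_ec50``, so the coupling statistic runs
      from 0 to -``dose.coupling`` (the reverse-recoupling signature).
    """
    dose = spec.dose
    rng = spec.rng(_STREAM_DOSE)
    rows = []
    truth: dict = {"scenario": scenario, "noise_sigma": dose.noise_sigma}

    def noisy(value: float) -> float:
        v = value + (dose.noise_sigma * rng.standard_normal() if dose.noise_sigma > 0 else 0.0)
        return float(np.clip(v, 0.0, 100.0))

    if scenario in ("wild-type", "uncoupled"):
        ec50_p = dose.ec50 if scenario == "uncoupled" else _ec50_shifted_for_coupling(dose, ca_single_point)
        truth.update(
            ec50_uP=dose.ec50, ec50_P=float(ec50_p), slope=dose.slope,
            floor=dose.floor, ceiling=dose.ceiling,
            coupling=0.0 if scenario == "uncoupled" else dose.coupling,
            ca_single_point=ca_single_point,
        )
        for phospho, ec50 in (("uP", dose.ec50), ("P", ec50_p)):
            for ca in CA_GRID_UM:
                clean = hill_curve(np.array([ca]), dose.floor, dose.ceiling, ec50, dose.slope)[0]
                for rep in range(dose.replicates):
                    rows.append(
                        dict(compound="none", compound_conc_uM=0.0, ca_conc_uM=ca,
                             phospho=phospho, replicate=rep, pct_motile=noisy(clean))
                    )
        ds = DoseResponseDataset(points=pd.DataFrame(rows), compound="none", fixed_ca=False)
        return ds, truth

    if scenario == "reverse":
        base = hill_curve(
            np.array([ca_single_point]), dose.floor, dose.ceiling, dose.ec50, dose.slope
        )[0]
        truth.update(
            compound_ec50=dose.compound_ec50, compound_slope=dose.compound_slope,
            coupling_at_saturation=-dose.coupling, baseline=float(base),
            ca_single_point=ca_single_point,
        )
        for c in COMPOUND_GRID_UM:
            effect = hill_curve(np.array([c]), 0.0, 1.0, dose.compound_ec50, dose.compound_slope)[0]
            clean_u = base - 0.5 * dose.coupling * effect
            clean_p = base + 0.5 * dose.coupling * effect
            for phospho, clean in (("uP", clean_u), ("P", clean_p)):
                for rep in range(dose.replicates):
                    rows.append(
                        dict(compound="7", compound_conc_uM=c, ca_conc_uM=ca_single_point,
                             phospho=phospho, replicate=rep, pct_motile=noisy(clean))
                    )
        ds = DoseResponseDataset(points=pd.DataFrame(rows), compound="7", fixed_ca=True)
        return ds, truth

    raise ValueError(f"unknown scenario {scenario!r}")


def make_condition_fixture(
    spec: GeneratorSpec, model: ToyModel | None = None
) -> tuple[Trajectory, dict, ToyModel]:
    """Full per-condition fixture: hinge trajectory with scheduled A/B
    crossing and bond occupancy, plus clustered ligand poses.  Returns the
    trajectory, a dict of truth records, and the toy model."""
    traj, hinge_truth, model = simulate_hinge_trajectory(spec, model)
    traj, pose_truth = simulate_ligand_poses(spec, traj, hinge_truth, model)
    return traj, {"hinge": hinge_truth, "poses": pose_truth}, model
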