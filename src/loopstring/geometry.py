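"""Structural statistics: torsions, superposition, correlations, rigid poses.

Angles are reported in degrees on (-180, 180]; distances in angstroms.
Superposition uses the Kabsch algorithm (proper rotations only).  Rigid poses
pair a centroid with a unit quaternion (w, x, y, z), canonicalised to w >= 0,
and are interpolated by linear centers plus shortest-arc slerp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .structures import AtomSelection, Conformation, MissingAtomError, Trajectory

__all__ = [
    "UndefinedDihedralError",
    "DegenerateGeometryError",
    "AlignmentError",
    "TorsionProfile",
    "DeviationProfile",
    "RigidPose",
    "CorrelationMatrix",
    "dihedral",
    "torsion_profile",
    "torsion_deviation_profile",
    "angular_difference",
    "kabsch_superpose",
    "pose_of",
    "apply_pose",
    "align_to",
    "slerp",
    "lerp_center",
    "quat_multiply",
    "quat_conjugate",
    "quat_rotation_angle",
    "quat_to_matrix",
    "matrix_to_quat",
    "rmsd",
    "rmsd_series",
    "dynamic_cross_correlation",
    "hbond_distance_series",
    "layer_thickness",
    "per_residue_displacement",
    "deviation_table",
    "correlation_table",
]


class UndefinedDihedralError(ValueError):
    """Three consecutive dihedral points are collinear."""


class DegenerateGeometryError(ValueError):
    """Too few or collinear points for a superposition."""


class AlignmentError(ValueError):
    """Two conformations do not share the compared residues."""


# ---------------------------------------------------------------------------
# Torsions


def dihedral(p1, p2, p3, p4) -> float:
    """Dihedral angle in degrees on (-180, 180].

    IUPAC sign convention: cis = 0, trans = 180, positive for a right-handed
    (clockwise, viewed from p2 towards p3) rotation of p4 relative to p1.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 * (np.linalg.norm(b1) * b2n + 1e-300):
        raise UndefinedDihedralError("p1, p2, p3 are collinear")
    if np.linalg.norm(n2) < 1e-10 * (np.linalg.norm(b3) * b2n + 1e-300):
        raise UndefinedDihedralError("p2, p3, p4 are collinear")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / b2n))
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


@dataclass(frozen=True)
class TorsionProfile:
    """Backbone phi/psi of one residue; ``None`` marks an undefined torsion."""

    residue_index: int
    phi: float | None
    psi: float | None


def torsion_profile(conf: Conformation) -> list[TorsionProfile]:
    """Backbone phi/psi for every residue (terminal torsions undefined)."""
    res = conf.residue_indices()
    out: list[TorsionProfile] = []
    for k, r in enumerate(res):
        phi = psi = None
        try:
            n = conf.atom_coord(r, "N")
            ca = conf.atom_coord(r, "CA")
            c = conf.atom_coord(r, "C")
        except MissingAtomError:
            out.append(TorsionProfile(r, None, None))
            continue
        if k > 0:
            try:
                c_prev = conf.atom_coord(res[k - 1], "C")
                phi = dihedral(c_prev, n, ca, c)
            except (MissingAtomError, UndefinedDihedralError):
                phi = None
        if k < len(res) - 1:
            try:
                n_next = conf.atom_coord(res[k + 1], "N")
                psi = dihedral(n, ca, c, n_next)
            except (MissingAtomError, UndefinedDihedralError):
                psi = None
        out.append(TorsionProfile(r, phi, psi))
    return out


def angular_difference(a: float, b: float) -> float:
    """Smallest periodic difference |a - b| mapped into [0, 180] degrees."""
    d = abs(a - b) % 360.0
    return float(min(d, 360.0 - d))


@dataclass(frozen=True)
class DeviationProfile:
    """Per-residue torsion deviation between two conformations.

    ``combined`` is the root-sum-square sqrt(dphi^2 + dpsi^2) over the
    defined torsions; ``None`` deltas mark torsions undefined in either
    structure.
    """

    residue_index: int
    delta_phi: float | None
    delta_psi: float | None
    combined: float


def torsion_deviation_profile(
    a: Conformation, b: Conformation
) -> list[DeviationProfile]:
    """Combined backbone-torsion deviation per residue between two states."""
    res_a = {p.residue_index: p for p in torsion_profile(a)}
    res_b = {p.residue_index: p for p in torsion_profile(b)}
    shared = [r for r in res_a if r in res_b]
    if not shared:
        raise AlignmentError("no shared residues between the two conformations")
    for r in shared:
        if a.residue_name(r) != b.residue_name(r):
            raise AlignmentError(
                f"residue {r} differs: {a.residue_name(r)} vs {b.residue_name(r)}"
            )
    out: list[DeviationProfile] = []
    for r in shared:
        pa, pb = res_a[r], res_b[r]
        dphi = (
            angular_difference(pa.phi, pb.phi)
            if pa.phi is not None and pb.phi is not None
            else None
        )
        dpsi = (
            angular_difference(pa.psi, pb.psi)
            if pa.psi is not None and pb.psi is not None
            else None
        )
        combined = float(np.hypot(dphi or 0.0, dpsi or 0.0))
        out.append(DeviationProfile(r, dphi, dpsi, combined))
    return out


# ---------------------------------------------------------------------------
# Quaternions and rigid poses


def quat_multiply(q: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Hamilton product of (w, x, y, z) quaternions."""
    w1, x1, y1, z1 = q
    w2, x2, y2, z2 = p
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quat_rotation_angle(q: np.ndarray, p: np.ndarray | None = None) -> float:
    """Rotation angle (degrees, in [0, 180]) of q, or of q relative to p."""
    r = q if p is None else quat_multiply(q, quat_conjugate(np.asarray(p, float)))
    w = min(1.0, abs(float(r[0])) / np.linalg.norm(r))
    return float(np.degrees(2.0 * np.arccos(w)))


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return Rotation.from_quat([x, y, z, w]).as_matrix()


def matrix_to_quat(m: np.ndarray) -> np.ndarray:
    x, y, z, w = Rotation.from_matrix(m).as_quat()
    q = np.array([w, x, y, z])
    if q[0] < 0:
        q = -q
    return q


@dataclass
class RigidPose:
    """Centroid (angstroms) plus unit orientation quaternion, w >= 0."""

    center: np.ndarray
    orientation: np.ndarray  # (w, x, y, z)

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        q = np.asarray(self.orientation, dtype=float).reshape(4)
        n = np.linalg.norm(q)
        if n < 1e-12:
            raise ValueError("zero-norm quaternion")
        if abs(n - 1.0) > 1e-8:
            raise ValueError(f"quaternion norm {n} deviates from 1 beyond 1e-8")
        q = q / n
        if q[0] < 0:
            q = -q
        self.orientation = q

    @property
    def rotation_matrix(self) -> np.ndarray:
        return quat_to_matrix(self.orientation)

    @classmethod
    def identity(cls) -> "RigidPose":
        return cls(np.zeros(3), np.array([1.0, 0.0, 0.0, 0.0]))


def slerp(q0, q1, t: float) -> np.ndarray:
    """Shortest-arc spherical interpolation between unit quaternions.

    Antipodal representations (dot < 0) are resolved by negating ``q1``; the
    result has constant angular velocity in ``t`` and is canonicalised to
    w >= 0 only at the endpoints' own convention (no re-signing mid-arc, which
    would break continuity).
    """
    q0 = np.asarray(q0, dtype=float)
    q1 = np.asarray(q1, dtype=float)
    n0, n1 = np.linalg.norm(q0), np.linalg.norm(q1)
    if n0 < 1e-12 or n1 < 1e-12:
        raise ValueError("zero-norm quaternion")
    q0, q1 = q0 / n0, q1 / n1
    dot = float(np.dot(q0, q1))
    if dot < 0.0:
        q1 = -q1
        dot = -dot
    dot = min(1.0, dot)
    omega = np.arccos(dot)
    if omega < 1e-10:
        out = (1 - t) * q0 + t * q1
        return out / np.linalg.norm(out)
    s = np.sin(omega)
    out = (np.sin((1 - t) * omega) / s) * q0 + (np.sin(t * omega) / s) * q1
    return out / np.linalg.norm(out)


def lerp_center(c0, c1, t: float) -> np.ndarray:
    """Affine interpolation of centers."""
    c0 = np.asarray(c0, dtype=float)
    c1 = np.asarray(c1, dtype=float)
    return (1.0 - t) * c0 + t * c1


# ---------------------------------------------------------------------------
# Superposition and RMSD


def _check_superposable(x: np.ndarray) -> None:
    if x.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 points to superpose")
    c = x - x.mean(axis=0)
    # collinear iff the two smallest singular values vanish
    s = np.linalg.svd(c, compute_uv=False)
    if s[1] < 1e-9 * max(1.0, s[0]):
        raise DegenerateGeometryError("points are collinear")


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[RigidPose, float]:
    """Optimal proper rotation + translation of ``reference`` onto ``mobile``.

    Returns the pose of the mobile set — its (weighted) centroid and the
    rotation carrying the centered reference onto the centered mobile — and
    the minimised weighted RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have the same shape")
    _check_superposable(mobile)
    _check_superposable(reference)
    if weights is None:
        w = np.ones(len(mobile))
    else:
        w = np.asarray(weights, dtype=float)
    wsum = w.sum()
    cm = (w[:, None] * mobile).sum(axis=0) / wsum
    cr = (w[:, None] * reference).sum(axis=0) / wsum
    rot, rssd = Rotation.align_vectors(mobile - cm, reference - cr, weights=w)
    rmsd_val = float(rssd / np.sqrt(wsum))
    pose = RigidPose(cm, matrix_to_quat(rot.as_matrix()))
    return pose, rmsd_val


def rmsd(
    a: np.ndarray,
    b: np.ndarray,
    weights: np.ndarray | None = None,
    superpose: bool = True,
) -> float:
    """(Optionally superposed) weighted RMSD between two coordinate sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if superpose:
        return kabsch_superpose(a, b, weights)[1]
    if weights is None:
        return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
    w = np.asarray(weights, dtype=float)
    return float(np.sqrt((w * np.sum((a - b) ** 2, axis=1)).sum() / w.sum()))


def pose_of(conf: Conformation, ref: Conformation, sel: AtomSelection) -> RigidPose:
    """Pose of ``conf``'s selection relative to the same selection in ``ref``."""
    sel.validate_for(conf)
    sel.validate_for(ref)
    idx = sel.array()
    pose, _ = kabsch_superpose(conf.coords[idx], ref.coords[idx])
    return pose


def apply_pose(coords: np.ndarray, pose: RigidPose) -> np.ndarray:
    """Rigidly place ``coords``: rotate about their centroid, move it to
    ``pose.center``."""
    coords = np.asarray(coords, dtype=float)
    c = coords.mean(axis=0)
    return (coords - c) @ pose.rotation_matrix.T + pose.center


def align_to(
    mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """Return ``mobile`` rigidly superposed onto ``reference``."""
    pose, _ = kabsch_superpose(mobile, reference, weights)
    m = np.asarray(mobile, dtype=float)
    w = np.ones(len(m)) if weights is None else np.asarray(weights, float)
    cm = (w[:, None] * m).sum(axis=0) / w.sum()
    r = np.asarray(reference, dtype=float)
    cr = (w[:, None] * r).sum(axis=0) / w.sum()
    return (m - cm) @ pose.rotation_matrix + cr


def rmsd_series(
    traj: Trajectory,
    ref: Conformation,
    sel: AtomSelection,
    superpose: bool = True,
) -> list[tuple[float, float]]:
    """Per-frame RMSD of a selection to a reference structure."""
    sel.validate_for(ref)
    sel.validate_for(traj.n_atoms)
    idx = sel.array()
    ref_xyz = ref.coords[idx]
    out = []
    for t, frame in zip(traj.frame_times, traj.frames):
        out.append((float(t), rmsd(frame[idx], ref_xyz, superpose=superpose)))
    return out


# ---------------------------------------------------------------------------
# Trajectory statistics


@dataclass
class CorrelationMatrix:
    """Normalised cross-correlation C_ij between two residue sets.

    Values are dimensionless in [-1, 1]; NaN marks residues with zero
    fluctuation, for which the correlation is undefined.
    """

    rows: list[int]
    cols: list[int]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1 - 1e-10 or finite.max() > 1 + 1e-10):
            raise ValueError("correlation values outside [-1, 1]")


def _ca_positions(
    conf_atoms: Sequence, frame: np.ndarray, residues: Sequence[int]
) -> np.ndarray:
    idx = []
    for r in residues:
        found = None
        for i, a in enumerate(conf_atoms):
            if a.residue_index == r and a.atom_name == "CA":
                found = i
                break
        if found is None:
            raise MissingAtomError(f"no CA for residue {r}")
        idx.append(found)
    return frame[np.asarray(idx)]


def dynamic_cross_correlation(
    traj: Trajectory,
    atoms: Sequence,
    set_a: Sequence[int],
    set_b: Sequence[int],
) -> CorrelationMatrix:
    """Dynamic cross-correlation C_ij between CA atoms of two residue sets.

    C_ij = <dr_i . dr_j> / sqrt(<dr_i^2><dr_j^2>) with dr = r - <r>, averaged
    over frames after rigidly aligning every frame to the first frame on all
    CA atoms (removes overall drift that would otherwise inflate C).
    """
    if len(traj) < 2:
        raise ValueError("need at least 2 frames")
    ca_idx = np.array(
        [i for i, a in enumerate(atoms) if a.atom_name == "CA"], dtype=int
    )
    if len(ca_idx) < 3:
        raise DegenerateGeometryError("need at least 3 CA atoms for alignment")
    ref = traj.frames[0][ca_idx]
    aligned = []
    for frame in traj.frames:
        # same fit convention as align_to: rows @ R maps mobile onto reference
        pose, _ = kabsch_superpose(frame[ca_idx], ref)
        f_c = frame[ca_idx].mean(axis=0)
        aligned.append((frame - f_c) @ pose.rotation_matrix + ref.mean(axis=0))
    aligned = np.array(aligned)

    pos_a = np.array([_ca_positions(atoms, f, set_a) for f in aligned])
    pos_b = np.array([_ca_positions(atoms, f, set_b) for f in aligned])
    da = pos_a - pos_a.mean(axis=0)
    db = pos_b - pos_b.mean(axis=0)
    var_a = np.mean(np.sum(da**2, axis=2), axis=0)
    var_b = np.mean(np.sum(db**2, axis=2), axis=0)
    cov = np.einsum("fid,fjd->ij", da, db) / len(aligned)
    denom = np.sqrt(np.outer(var_a, var_b))
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), np.nan)
    vals = np.clip(vals, -1.0, 1.0, where=np.isfinite(vals), out=vals)
    return CorrelationMatrix(list(set_a), list(set_b), vals)


def hbond_distance_series(
    traj_or_conf,
    atoms_or_donor,
    donor: tuple[int, str] | None = None,
    acceptor: tuple[int, str] | None = None,
) -> list[float]:
    """Donor-acceptor distances (angstroms), per frame.

    Accepts either ``(Conformation, donor, acceptor)`` or
    ``(Trajectory, atoms, donor, acceptor)``.
    """
    if isinstance(traj_or_conf, Conformation):
        conf = traj_or_conf
        donor, acceptor = atoms_or_donor, donor
        frames = [conf.coords]
        atoms = conf.atoms
    else:
        traj: Trajectory = traj_or_conf
        atoms = atoms_or_donor
        frames = traj.frames
    helper = Conformation(list(atoms), frames[0])
    try:
        i = helper.index_of(*donor)
        j = helper.index_of(*acceptor)
    except MissingAtomError as exc:
        raise MissingAtomError(
            f"{exc.args[0]}; if this is an amide H, build hydrogens with "
            "place_amide_hydrogens first"
        ) from exc
    return [float(np.linalg.norm(f[i] - f[j])) for f in frames]


def layer_thickness(
    traj: Trajectory, group_upper: AtomSelection, group_lower: AtomSelection
) -> list[tuple[float, float]]:
    """Per-frame mean(z_upper) - mean(z_lower), e.g. a bilayer thickness."""
    if len(group_upper) == 0 or len(group_lower) == 0:
        raise ValueError("both groups must be non-empty")
    iu, il = group_upper.array(), group_lower.array()
    return [
        (float(t), float(f[iu, 2].mean() - f[il, 2].mean()))
        for t, f in zip(traj.frame_times, traj.frames)
    ]


def per_residue_displacement(
    final: Conformation, target: Conformation, align_sel: AtomSelection
) -> list[tuple[int, float]]:
    """|CA_final - CA_target| per residue, after superposing on align_sel."""
    align_sel.validate_for(final)
    align_sel.validate_for(target)
    idx = align_sel.array()
    pose, _ = kabsch_superpose(final.coords[idx], target.coords[idx])
    cf = final.coords[idx].mean(axis=0)
    moved = (final.coords - cf) @ pose.rotation_matrix + target.coords[idx].mean(
        axis=0
    )
    shared = [r for r in final.residue_indices() if r in set(target.residue_indices())]
    out = []
    for r in shared:
        try:
            i = final.index_of(r, "CA")
            j = target.index_of(r, "CA")
        except MissingAtomError:
            continue
        out.append((r, float(np.linalg.norm(moved[i] - target.coords[j]))))
    return out


# ---------------------------------------------------------------------------
# Tabular output


def deviation_table(profiles: Sequence[DeviationProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "residue": [p.residue_index for p in profiles],
            "delta_phi_deg": [p.delta_phi for p in profiles],
            "delta_psi_deg": [p.delta_psi for p in profiles],
            "combined_deg": [p.combined for p in profiles],
        }
    )


def correlation_table(cm: CorrelationMatrix) -> pd.DataFrame:
    return pd.DataFrame(cm.values, index=cm.rows, columns=cm.cols)
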