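"""Restrained Langevin dynamics.

Four restraint kinds drive or confine the system:

* ``cartesian_harmonic`` — sum over selected atoms of (k/2)|x_a - x_a^ref|^2,
  the per-atom image springs of the string method;
* ``rmsd`` — (k/2)[RMS(R) - r0]^2 with RMS the best-fit RMSD of the selected
  atoms to a target structure (targeted MD when r0 moves linearly to zero);
* ``center`` — (k/2)|centroid - c_ref|^2;
* ``orientation_angle`` — (k/2) theta^2 with theta the rotation angle, in
  degrees, of the best-fit rotation of the selection relative to a reference
  pose (k in kcal/mol/degree^2).

All forces are exact negative gradients; the RMSD gradient uses the envelope
theorem through the optimal superposition, and the orientation gradient is
obtained by first-order perturbation of the Kabsch quaternion eigenproblem.
Time integration is BAOAB-discretised Langevin dynamics, bitwise reproducible
for a given seed.  Units: kcal/mol, angstrom, ps, K.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .geometry import RigidPose, kabsch_superpose, rmsd
from .structures import AtomSelection, Conformation, Trajectory
from .toyloop import KB_KCAL

__all__ = [
    "Schedule",
    "Restraint",
    "LangevinParams",
    "LangevinState",
    "SimulationBlowupError",
    "restraint_energy_forces",
    "langevin_step",
    "simulate",
    "run_tmd",
    "run_restrained",
]


class SimulationBlowupError(RuntimeError):
    """Coordinates became non-finite during integration."""


@dataclass(frozen=True)
class Schedule:
    """Time-dependent reference: (time ps, reference) breakpoints.

    ``linear`` interpolates between breakpoints (scalar or array references);
    ``frames`` holds each reference piecewise-constant until the next
    breakpoint time.
    """

    breakpoints: tuple
    mode: str = "linear"  # "linear" | "frames"

    def __post_init__(self) -> None:
        times = [b[0] for b in self.breakpoints]
        if times != sorted(times):
            raise ValueError("breakpoints must be time-ordered")
        if self.mode not in ("linear", "frames"):
            raise ValueError(f"unknown schedule mode {self.mode!r}")

    def value(self, t: float):
        bps = self.breakpoints
        if t <= bps[0][0]:
            return bps[0][1]
        if t >= bps[-1][0]:
            return bps[-1][1]
        if self.mode == "frames":
            out = bps[0][1]
            for bt, ref in bps:
                if bt <= t:
                    out = ref
                else:
                    break
            return out
        for (t0, r0), (t1, r1) in zip(bps[:-1], bps[1:]):
            if t0 <= t <= t1:
                w = (t - t0) / (t1 - t0)
                return (1 - w) * np.asarray(r0) + w * np.asarray(r1) \
                    if isinstance(r0, np.ndarray) or isinstance(r1, np.ndarray) \
                    else (1 - w) * r0 + w * r1
        return bps[-1][1]  # pragma: no cover


@dataclass
class Restraint:
    """A tagged harmonic energy term acting on a selection of sites."""

    kind: str  # cartesian_harmonic | rmsd | center | orientation_angle
    selection: AtomSelection
    spring_constant: float  # kcal/mol/A^2, or kcal/mol/degree^2 for orientation
    reference: object = None  # coords | 3-vector | RigidPose reference coords
    r0: float | Schedule = 0.0  # rmsd kind only
    ref_pose: RigidPose | None = None  # orientation kind only

    def __post_init__(self) -> None:
        if self.kind not in ("cartesian_harmonic", "rmsd", "center", "orientation_angle"):
            raise ValueError(f"unknown restraint kind {self.kind!r}")
        if self.spring_constant < 0:
            raise ValueError("spring_constant must be >= 0")


# 4x4 structure matrices: K = sum_ij B_ij * _S[i][j], B = sum_a xtil_a ytil_a^T
def _build_K(B: np.ndarray) -> np.ndarray:
    b11, b12, b13 = B[0]
    b21, b22, b23 = B[1]
    b31, b32, b33 = B[2]
    return np.array(
        [
            [b11 + b22 + b33, b23 - b32, b31 - b13, b12 - b21],
            [b23 - b32, b11 - b22 - b33, b12 + b21, b13 + b31],
            [b31 - b13, b12 + b21, -b11 + b22 - b33, b23 + b32],
            [b12 - b21, b13 + b31, b23 + b32, -b11 - b22 + b33],
        ]
    )


_S = np.zeros((3, 3, 4, 4))
for _i in range(3):
    for _j in range(3):
        _E = np.zeros((3, 3))
        _E[_i, _j] = 1.0
        _S[_i, _j] = _build_K(_E)


def _kabsch_quaternion(x_cent: np.ndarray, y_cent: np.ndarray):
    """Unit quaternion (w,x,y,z) of the rotation carrying centered reference
    y onto centered mobile x, plus the eigen-data needed for perturbation."""
    B = x_cent.T @ y_cent  # note: B_ij = sum_a x_a,i y_a,j
    K = _build_K(B.T)  # transpose: convention fixed against pose_of
    evals, evecs = np.linalg.eigh(K)
    q = evecs[:, -1]
    if q[0] < 0:
        q = -q
    return q, evals, evecs


def _orientation_energy_forces(
    coords_sel: np.ndarray, ref_coords: np.ndarray, ref_quat: np.ndarray, k: float
):
    x = coords_sel - coords_sel.mean(axis=0)
    y = ref_coords - ref_coords.mean(axis=0)
    q, evals, evecs = _kabsch_quaternion(x, y)
    qr = np.asarray(ref_quat, dtype=float)
    c = float(np.dot(q, qr))
    ac = min(1.0, abs(c))
    theta_rad = 2.0 * np.arccos(ac)
    theta_deg = np.degrees(theta_rad)
    energy = 0.5 * k * theta_deg**2

    # dE/dc with the theta->0 limit handled analytically:
    # E = (k/2) theta_deg^2, theta_rad = 2 acos|c|, s = sin(theta_rad/2)
    s = np.sqrt(max(1.0 - ac * ac, 0.0))
    ratio = theta_rad / s if s > 1e-8 else 2.0
    dE_dc = -k * np.degrees(1.0) ** 2 * 2.0 * ratio * np.sign(c) if c != 0 else 0.0

    # dq/dx by first-order perturbation of the eigenproblem
    lam = evals[-1]
    gaps = lam - evals[:-1]
    v = evecs[:, :-1]
    # P = sum_mu v_mu v_mu^T / gap_mu
    P = (v / gaps[None, :]) @ v.T
    Pq_r = P @ qr  # only q_ref^T P (dK) q is needed
    # M[d, j] = q_ref^T P S[d, j] q  with dB.T ordering as in _kabsch_quaternion
    M = np.einsum("l,djlm,m->dj", Pq_r, _S.transpose(1, 0, 2, 3), q)
    # dc/dx_a = M @ y_a  (from dB_ij/dx_a,d = delta_id y_a,j)
    dc_dx = y @ M.T
    forces = -dE_dc * dc_dx
    return float(energy), forces, float(theta_deg)


def restraint_energy_forces(
    r: Restraint, coords: np.ndarray, t: float = 0.0
) -> tuple[float, np.ndarray]:
    """Energy (kcal/mol) and per-site forces of one restraint at time t."""
    coords = np.asarray(coords, dtype=float)
    n_sites = coords.shape[0]
    r.selection.validate_for(n_sites)
    idx = r.selection.array()
    x = coords[idx]
    k = r.spring_constant
    forces = np.zeros_like(coords)

    def resolve(ref):
        return ref.value(t) if isinstance(ref, Schedule) else ref

    if r.kind == "cartesian_harmonic":
        ref = np.asarray(resolve(r.reference), dtype=float)
        d = x - ref
        e = 0.5 * k * float(np.sum(d * d))
        forces[idx] = -k * d
        return e, forces

    if r.kind == "center":
        c_ref = np.asarray(resolve(r.reference), dtype=float)
        c = x.mean(axis=0)
        d = c - c_ref
        e = 0.5 * k * float(d @ d)
        forces[idx] = -k * d / len(idx)
        return e, forces

    if r.kind == "rmsd":
        if len(idx) < 3:
            raise ValueError("rmsd restraint needs at least 3 selected atoms")
        target = np.asarray(resolve(r.reference), dtype=float)
        r0 = float(resolve(r.r0))
        pose, rms = kabsch_superpose(x, target)
        e = 0.5 * k * (rms - r0) ** 2
        if rms > 1e-10:
            xc = x - x.mean(axis=0)
            yc = target - target.mean(axis=0)
            # rows @ R.T applies the fitted rotation to the centered target
            resid = xc - yc @ pose.rotation_matrix.T
            grad = (k * (rms - r0) / (len(idx) * rms)) * resid
            forces[idx] = -grad
        return float(e), forces

    if r.kind == "orientation_angle":
        if len(idx) < 3:
            raise ValueError("orientation restraint needs at least 3 atoms")
        ref_coords = np.asarray(r.reference, dtype=float)
        pose = r.ref_pose if r.ref_pose is not None else RigidPose.identity()
        e, f_sel, _ = _orientation_energy_forces(x, ref_coords, pose.orientation, k)
        forces[idx] = f_sel
        return e, forces

    raise ValueError(f"unknown restraint kind {r.kind!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# Langevin dynamics (BAOAB)


@dataclass
class LangevinParams:
    temperature: float = 300.0  # K
    friction: float = 1.0  # ps^-1
    timestep: float = 0.001  # ps
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.temperature, self.friction, self.timestep) < 0:
            raise ValueError("temperature, friction and timestep must be >= 0")


@dataclass
class LangevinState:
    coords: np.ndarray  # (n, dim)
    velocities: np.ndarray
    rng: np.random.Generator
    time: float = 0.0
    forces: np.ndarray | None = None


def _init_state(
    coords: np.ndarray, masses: np.ndarray, params: LangevinParams
) -> LangevinState:
    rng = np.random.default_rng(params.seed)
    kT = KB_KCAL * params.temperature
    sigma = np.sqrt(kT / masses)[:, None] if kT > 0 else np.zeros((len(masses), 1))
    v = sigma * rng.standard_normal(coords.shape)
    return LangevinState(np.array(coords, dtype=float), v, rng)


def langevin_step(
    state: LangevinState,
    force_fn: Callable[[np.ndarray, float], tuple[float, np.ndarray]],
    masses: np.ndarray,
    params: LangevinParams,
) -> LangevinState:
    """One BAOAB update; mutates and returns ``state``."""
    dt = params.timestep
    m = masses[:, None]
    kT = KB_KCAL * params.temperature
    if state.forces is None:
        _, state.forces = force_fn(state.coords, state.time)
    # B: half kick
    state.velocities += 0.5 * dt * state.forces / m
    # A: half drift
    state.coords += 0.5 * dt * state.velocities
    # O: Ornstein-Uhlenbeck
    c1 = np.exp(-params.friction * dt)
    c2 = np.sqrt(kT * (1.0 - c1 * c1) / masses)[:, None]
    state.velocities = c1 * state.velocities + c2 * state.rng.standard_normal(
        state.coords.shape
    )
    # A: half drift
    state.coords += 0.5 * dt * state.velocities
    state.time += dt
    # B: half kick with new forces
    _, state.forces = force_fn(state.coords, state.time)
    state.velocities += 0.5 * dt * state.forces / m
    if not np.all(np.isfinite(state.coords)):
        raise SimulationBlowupError(
            "non-finite coordinates; reduce the timestep (stiffest mode needs "
            "dt < 2/omega) or check restraint springs"
        )
    return state


def simulate(
    model,
    restraints: Sequence[Restraint],
    params: LangevinParams,
    n_steps: int,
    x0: np.ndarray,
    record_stride: int = 0,
    observer: Callable[[int, LangevinState], None] | None = None,
) -> tuple[LangevinState, list[np.ndarray], list[float]]:
    """Integrate ``model`` plus restraints; optionally record frames."""

    def force_fn(x, t):
        e, f = model.energy_forces(x)
        for r in restraints:
            er, fr = restraint_energy_forces(r, x, t)
            e += er
            f = f + fr
        return e, f

    state = _init_state(np.asarray(x0, dtype=float), model.masses, params)
    frames: list[np.ndarray] = []
    times: list[float] = []
    for step in range(1, n_steps + 1):
        langevin_step(state, force_fn, model.masses, params)
        if record_stride and step % record_stride == 0:
            frames.append(state.coords.copy())
            times.append(state.time)
        if observer is not None:
            observer(step, state)
    return state, frames, times


# ---------------------------------------------------------------------------
# Protocol runners


def run_tmd(
    model,
    start: Conformation,
    target: Conformation,
    selection: AtomSelection,
    k: float,
    duration: float,
    params: LangevinParams,
    record_stride: int = 50,
) -> tuple[Trajectory, pd.DataFrame]:
    """Targeted MD: a moving RMSD restraint drives start towards target.

    The reference value r0 decreases linearly from the initial best-fit RMSD
    to 0 over ``duration`` (ps).  Returns the trajectory and a per-recorded-
    frame log of (time, RMS, r0).
    """
    selection.validate_for(start)
    selection.validate_for(target)
    idx = selection.array()
    target_xyz = target.coords[idx]
    rms0 = rmsd(start.coords[idx], target_xyz)
    sched = Schedule(((0.0, rms0), (duration, 0.0)), mode="linear")
    restraint = Restraint("rmsd", selection, k, reference=target_xyz, r0=sched)
    n_steps = int(round(duration / params.timestep))
    log_rows = []

    def observer(step, state):
        if record_stride and step % record_stride == 0:
            cur = rmsd(state.coords[idx], target_xyz)
            log_rows.append((state.time, cur, float(sched.value(state.time))))

    state, frames, times = simulate(
        model, [restraint], params, n_steps, start.coords,
        record_stride=record_stride, observer=observer,
    )
    labels = [a.atom_name for a in start.atoms]
    traj = Trajectory(frames, np.array(times), labels)
    log = pd.DataFrame(log_rows, columns=["time_ps", "rms", "r0"])
    return traj, log


def run_restrained(
    model,
    x0: np.ndarray,
    restraints: Sequence[Restraint],
    duration: float,
    params: LangevinParams,
    collect: AtomSelection,
    equilibration_fraction: float = 0.2,
    record_stride: int = 0,
) -> tuple[Trajectory | None, np.ndarray, np.ndarray]:
    """Sample under fixed restraints; average positions and restraint force.

    Returns (trajectory or None, time-averaged positions of the collected
    atoms, time-averaged total restraint force on the collected atoms), with
    the first ``equilibration_fraction`` of the run discarded from averages.
    """
    n_steps = int(round(duration / params.timestep))
    n_equil = int(n_steps * equilibration_fraction)
    idx = collect.array()
    dim = np.asarray(x0).shape[1]
    acc_pos = np.zeros((len(idx), dim))
    acc_force = np.zeros((len(idx), dim))
    count = 0

    def observer(step, state):
        nonlocal count
        if step <= n_equil:
            return
        fr_tot = np.zeros_like(state.coords)
        for r in restraints:
            _, fr = restraint_energy_forces(r, state.coords, state.time)
            fr_tot += fr
        acc_pos[...] += state.coords[idx]
        acc_force[...] += fr_tot[idx]
        count += 1

    state, frames, times = simulate(
        model, restraints, params, n_steps, x0,
        record_stride=record_stride, observer=observer,
    )
    traj = None
    if record_stride and frames:
        traj = Trajectory(frames, np.array(times))
    if count == 0:
        raise ValueError("run too short: no post-equilibration samples")
    return traj, acc_pos / count, acc_force / count
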