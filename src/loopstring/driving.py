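"""Loop-driven simulations.

The refined internal pathway of a loop is combined with a linear
interpolation of the loop center and a quaternion slerp of the loop
orientation into a single driving pathway.  A fixed number of evenly spaced
restraint frames (default 60) is taken from this pathway; advancing the
Cartesian restraints frame by frame drives the loop from one state to the
other, while stiff harmonic restraints on the center (1000 kcal/mol/A^2) and
the orientation angle (200 kcal/mol/degree^2) of the whole system pin the
global pose, so Cartesian coordinates unambiguously represent internal
conformation.  A follower analysis then quantifies how the undriven part of
the system tracks the driven loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import LangevinParams, Restraint, Schedule, simulate
from .geometry import (
    RigidPose,
    lerp_center,
    per_residue_displacement,
    rmsd,
    slerp,
)
from .structures import AtomRecord, AtomSelection, Conformation, Trajectory
from .stringmethod import StringPath, _resample_even
from .toyloop import ToyLoopModel

__all__ = [
    "DrivingPath",
    "DrivenConfig",
    "FollowerReport",
    "CoupledChainModel",
    "build_driving_path",
    "run_loop_driven",
    "follower_response",
]


@dataclass
class DrivingPath:
    """Evenly spaced restraint frames for the driven loop atoms."""

    frames: np.ndarray  # (n_frames, n_loop, 3)
    poses: list[RigidPose]
    selection: AtomSelection  # loop representative atoms in the full model

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class DrivenConfig:
    """Springs and timing of the loop-driven protocol (production defaults:
    2 / 1000 / 200 for loop, center and orientation springs)."""

    loop_spring: float = 2.0  # kcal/mol/A^2
    center_spring: float = 1000.0  # kcal/mol/A^2
    orientation_spring: float = 200.0  # kcal/mol/degree^2
    time_per_frame: float = 1.0  # ps (2 ns per frame at production scale)
    settle_time: float = 0.0  # extra ps holding the last frame
    timestep: float = 0.001
    friction: float = 5.0
    temperature: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.loop_spring, self.center_spring, self.orientation_spring) < 0:
            raise ValueError("springs must be >= 0")


def build_driving_path(
    internal_path: StringPath,
    pose_a: RigidPose,
    pose_b: RigidPose,
    n_frames: int = 60,
    loop_a: np.ndarray | None = None,
    loop_b: np.ndarray | None = None,
) -> DrivingPath:
    """Combine internal pathway, center lerp, and orientation slerp.

    For progression t_f = f/(n_frames-1): the internal conformation is the
    even-arc-length point t_f along ``internal_path``; the center is
    lerp(a, b, t_f); the orientation is slerp(q_a, q_b, t_f); the frame is
    the internal conformation placed into the interpolated pose.  When the
    loop coordinates of the endpoint states are supplied, frames 0 and
    n_frames-1 are checked against them (0.1 A RMSD) and then set to them
    exactly.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    refs = internal_path.references()
    internal = _resample_even(refs, n_frames)
    frames = []
    poses = []
    for f in range(n_frames):
        t = f / (n_frames - 1)
        c = lerp_center(pose_a.center, pose_b.center, t)
        q = slerp(pose_a.orientation, pose_b.orientation, t)
        pose = RigidPose(c, q)
        y = internal[f]
        frames.append((y - y.mean(axis=0)) @ pose.rotation_matrix.T + c)
        poses.append(pose)
    frames = np.array(frames)
    for end, loop in ((0, loop_a), (-1, loop_b)):
        if loop is not None:
            loop = np.asarray(loop, dtype=float)
            err = rmsd(frames[end], loop, superpose=False)
            if err > 0.1:
                raise ValueError(
                    f"driving-path endpoint {end} deviates {err:.3f} A RMSD "
                    "from the supplied loop state; pose/path inconsistency"
                )
            frames[end] = loop.copy()
    return DrivingPath(frames, poses, internal_path.selection)


def run_loop_driven(
    model,
    start: Conformation,
    dpath: DrivingPath,
    config: DrivenConfig,
    global_ref: Conformation | None = None,
    record_stride: int = 100,
) -> tuple[Trajectory, pd.DataFrame]:
    """Drive the loop along the restraint frames under a pinned global pose.

    Only the loop selection feels driving forces; the rest of the system
    follows through its own couplings.  Returns the trajectory and a log of
    (time, active frame, loop RMSD to current reference, center drift,
    orientation drift).
    """
    n_frames = dpath.n_frames
    duration = n_frames * config.time_per_frame + config.settle_time
    # frame f active on [f*tpf, (f+1)*tpf); last frame holds to the end
    sched = Schedule(
        tuple((f * config.time_per_frame, dpath.frames[f]) for f in range(n_frames)),
        mode="frames",
    )
    loop_restraint = Restraint(
        "cartesian_harmonic", dpath.selection, config.loop_spring, reference=sched
    )
    ref_conf = global_ref if global_ref is not None else start
    all_sel = AtomSelection(tuple(range(len(ref_conf))))
    center_restraint = Restraint(
        "center",
        all_sel,
        config.center_spring,
        reference=ref_conf.coords.mean(axis=0),
    )
    orient_restraint = Restraint(
        "orientation_angle",
        all_sel,
        config.orientation_spring,
        reference=ref_conf.coords,
        ref_pose=RigidPose.identity(),
    )
    temperature = (
        config.temperature
        if config.temperature is not None
        else getattr(model, "temperature", 300.0)
    )
    params = LangevinParams(
        temperature=temperature,
        friction=config.friction,
        timestep=config.timestep,
        seed=config.seed,
    )
    n_steps = int(round(duration / config.timestep))
    idx = dpath.selection.array()
    ref_center = ref_conf.coords.mean(axis=0)
    log_rows = []

    def observer(step, state):
        if record_stride and step % record_stride == 0:
            t = state.time
            active = min(int(t // config.time_per_frame), n_frames - 1)
            cur_ref = np.asarray(sched.value(t))
            loop_rms = rmsd(state.coords[idx], cur_ref, superpose=False)
            dc = state.coords.mean(axis=0) - ref_center
            center_drift = float(np.linalg.norm(dc))
            from .dynamics import _orientation_energy_forces

            _, _, theta = _orientation_energy_forces(
                state.coords,
                ref_conf.coords,
                RigidPose.identity().orientation,
                0.0,
            )
            log_rows.append(
                (t, active, loop_rms, center_drift, theta, dc[0], dc[1], dc[2])
            )

    state, frames, times = simulate(
        model,
        [loop_restraint, center_restraint, orient_restraint],
        params,
        n_steps,
        start.coords,
        record_stride=record_stride,
        observer=observer,
    )
    labels = [a.atom_name for a in start.atoms]
    traj = Trajectory(frames, np.array(times), labels)
    log = pd.DataFrame(
        log_rows,
        columns=[
            "time_ps", "frame", "loop_rms", "center_drift",
            "orientation_drift", "dcx", "dcy", "dcz",
        ],
    )
    return traj, log


@dataclass
class FollowerReport:
    """How the undriven part of the system tracked the driven loop."""

    rmsd_to_a: pd.DataFrame
    rmsd_to_b: pd.DataFrame
    displacements: list[tuple[int, float]]
    failed_residues: list[int]
    final_rmsd_a: float
    final_rmsd_b: float


def follower_response(
    traj: Trajectory,
    target_a: Conformation,
    target_b: Conformation,
    follower_sel: AtomSelection,
    threshold: float = 1.0,
) -> FollowerReport:
    """Follower RMSD to both endpoint structures plus final per-residue
    displacement to the driven-to target (B); residues whose final CA
    displacement exceeds ``threshold`` are flagged as failed to follow."""
    idx = follower_sel.array()
    rows_a, rows_b = [], []
    for t, frame in zip(traj.frame_times, traj.frames):
        rows_a.append((float(t), rmsd(frame[idx], target_a.coords[idx])))
        rows_b.append((float(t), rmsd(frame[idx], target_b.coords[idx])))
    final = Conformation(list(target_b.atoms), traj.frames[-1])
    disp = per_residue_displacement(final, target_b, follower_sel)
    follower_res = {
        target_b.atoms[i].residue_index for i in idx
    }
    disp = [(r, d) for r, d in disp if r in follower_res]
    failed = [r for r, d in disp if d > threshold]
    return FollowerReport(
        rmsd_to_a=pd.DataFrame(rows_a, columns=["time_ps", "rmsd"]),
        rmsd_to_b=pd.DataFrame(rows_b, columns=["time_ps", "rmsd"]),
        displacements=disp,
        failed_residues=failed,
        final_rmsd_a=rows_a[-1][1],
        final_rmsd_b=rows_b[-1][1],
    )


# ---------------------------------------------------------------------------
# Coupled two-chain toy system


class CoupledChainModel:
    """A driven toy loop plus a follower copy coupled CA-to-CA.

    The follower chain is a translated copy (offset vector) of the driven
    chain; harmonic springs connect corresponding CA atoms through the offset
    so that, when the driven loop is pulled to its other state, the
    follower's energy minimum moves with it.  Setting ``coupling_k`` to zero
    gives the negative control: the follower keeps its own bistable energy
    and stays in its initial state.  Follower residues are renumbered with
    ``residue_offset`` so both chains coexist in one conformation.
    """

    def __init__(
        self,
        driven: ToyLoopModel,
        follower: ToyLoopModel,
        offset: np.ndarray | None = None,
        coupling_k: float = 3.0,
        uncoupled_residues: tuple[int, ...] = (),
        residue_offset: int = 100,
    ):
        if driven.n_residues != follower.n_residues:
            raise ValueError("chains must have the same number of residues")
        self.driven = driven
        self.follower = follower
        self.offset = (
            np.array([18.0, 0.0, 0.0]) if offset is None else np.asarray(offset, float)
        )
        self.coupling_k = float(coupling_k)
        self.uncoupled_residues = tuple(uncoupled_residues)
        self.residue_offset = residue_offset
        self.n_driven = driven.n_sites
        dummy_d = Conformation(list(driven.atoms), np.zeros((driven.n_sites, 3)))
        dummy_f = Conformation(list(follower.atoms), np.zeros((follower.n_sites, 3)))
        pairs = []
        for r in range(1, driven.n_residues + 1):
            if r in self.uncoupled_residues:
                continue
            pairs.append(
                (dummy_d.index_of(r, "CA"), self.n_driven + dummy_f.index_of(r, "CA"))
            )
        self.coupling_pairs = np.array(pairs, dtype=int)
        self.atoms: list[AtomRecord] = list(driven.atoms) + [
            AtomRecord(
                a.atom_name,
                a.residue_name,
                a.residue_index + residue_offset,
                "B",
                a.element,
            )
            for a in follower.atoms
        ]
        self.temperature = driven.temperature

    @property
    def n_sites(self) -> int:
        return self.n_driven + self.follower.n_sites

    @property
    def dim(self) -> int:
        return 3

    @property
    def masses(self) -> np.ndarray:
        return np.concatenate([self.driven.masses, self.follower.masses])

    def combine(self, driven_coords: np.ndarray, follower_coords: np.ndarray) -> Conformation:
        return Conformation(
            list(self.atoms), np.vstack([driven_coords, follower_coords])
        )

    def state_conformation(self, driven_coords: np.ndarray) -> Conformation:
        """Composite state with the follower at the offset copy of the
        driven coordinates."""
        return self.combine(driven_coords, driven_coords + self.offset)

    def follower_selection(self, atom_name: str = "CA") -> AtomSelection:
        return AtomSelection(
            tuple(
                i
                for i, a in enumerate(self.atoms)
                if i >= self.n_driven and a.atom_name == atom_name
            ),
            label="follower-" + atom_name,
        )

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        x = np.asarray(coords, dtype=float)
        xd, xf = x[: self.n_driven], x[self.n_driven :]
        ed, fd = self.driven.energy_forces(xd)
        ef, ff = self.follower.energy_forces(xf)
        f = np.vstack([fd, ff])
        e = ed + ef
        if self.coupling_k > 0 and len(self.coupling_pairs):
            d = (
                x[self.coupling_pairs[:, 1]]
                - x[self.coupling_pairs[:, 0]]
                - self.offset
            )
            e += 0.5 * self.coupling_k * float(np.sum(d * d))
            np.add.at(f, self.coupling_pairs[:, 1], -self.coupling_k * d)
            np.add.at(f, self.coupling_pairs[:, 0], self.coupling_k * d)
        return e, f

    def energy(self, coords: np.ndarray) -> float:
        return self.energy_forces(coords)[0]
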