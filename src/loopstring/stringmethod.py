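"""String-method refinement of a discretized transition pathway.

A pathway between two endpoint conformations is discretized into images
(reference coordinates of the representative atoms).  Each image is sampled
under per-atom Cartesian harmonic restraints; Hamiltonian replica exchange
swaps configurations between adjacent images with Metropolis acceptance.
After sampling, the per-image mean conformations from two independently
seeded groups are pooled, aligned to a common reference, fitted with a
smoothing spline (piecewise between metastable-state breaks, endpoints
fixed), and re-sampled at even arc length.  A free-energy profile follows by
projecting the restraint-balance mean force k(<x> - x_ref) on the path
tangent and integrating over arc length.  Running the two groups from
different initial coordinates but a common set of restraints provides a
hysteresis check: their profiles must agree within statistical error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline, interp1d
from scipy.signal import find_peaks

from .dynamics import LangevinParams, LangevinState, _init_state, langevin_step
from .geometry import align_to
from .structures import AtomSelection, Trajectory
from .toyloop import KB_KCAL

__all__ = [
    "StringImage",
    "StringPath",
    "FreeEnergyProfile",
    "RefinementConfig",
    "ImageSample",
    "RefinementResult",
    "init_path_linear",
    "init_images_from_trajectory",
    "sample_images_with_exchange",
    "update_path",
    "integrate_mean_forces",
    "detect_metastable_states",
    "resample_path",
    "profile_disagreement",
    "refine",
]


@dataclass
class StringImage:
    reference: np.ndarray  # (n_sel, dim) representative-atom coordinates
    spring_constant: float  # kcal/mol/A^2, per atom

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)


@dataclass
class StringPath:
    images: list[StringImage]
    selection: AtomSelection
    endpoints_fixed: bool = True
    alignment_reference: np.ndarray | None = None  # (n_sel, dim)

    def __post_init__(self) -> None:
        if self.alignment_reference is not None:
            self.alignment_reference = np.asarray(self.alignment_reference, float)

    @property
    def n_images(self) -> int:
        return len(self.images)

    @property
    def dim(self) -> int:
        return self.images[0].reference.shape[1]

    def references(self) -> np.ndarray:
        return np.array([im.reference for im in self.images])

    def arc_lengths(self) -> np.ndarray:
        refs = self.references().reshape(self.n_images, -1)
        seg = np.linalg.norm(np.diff(refs, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass
class FreeEnergyProfile:
    arc_length: np.ndarray  # cumulative, angstrom
    free_energy: np.ndarray  # kcal/mol, zero at the first image
    group_id: str = ""
    sem: np.ndarray | None = None  # pointwise standard error

    def __post_init__(self) -> None:
        self.arc_length = np.asarray(self.arc_length, float)
        self.free_energy = np.asarray(self.free_energy, float)
        if self.arc_length.shape != self.free_energy.shape:
            raise ValueError("arc_length and free_energy must match")
        if abs(self.free_energy[0]) > 1e-12:
            raise ValueError("free energy must be anchored to 0 at the first image")

    def barrier(self) -> float:
        return float(self.free_energy.max() - self.free_energy[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"arc_length": self.arc_length, "free_energy": self.free_energy}
        )


def profile_disagreement(
    pa: "FreeEnergyProfile", pb: "FreeEnergyProfile", floor: float = 0.02
) -> float:
    """Largest pointwise z-score between two profiles on the same path.

    The combined standard error (with a small floor guarding against zero
    estimates) scales the pointwise difference; values of a few or less mean
    the two independently seeded groups agree within statistical error.
    """
    if pa.free_energy.shape != pb.free_energy.shape:
        raise ValueError("profiles must share the discretization")
    diff = np.abs(pa.free_energy - pb.free_energy)
    sa = pa.sem if pa.sem is not None else np.zeros_like(diff)
    sb = pb.sem if pb.sem is not None else np.zeros_like(diff)
    comb = np.sqrt(sa**2 + sb**2 + floor**2)
    return float((diff / comb).max())


@dataclass
class RefinementConfig:
    """Sampling protocol for the string refinement.

    Times are in ps; the defaults mirror the production protocol (60 images
    with 2 kcal/mol/A^2 springs for refinement, 120 images with 4 for the
    final profile pass) with toy-scale sampling times.
    """

    n_images: int = 60
    spring_constant: float = 2.0
    sampling_time: float = 2.0
    n_iterations: int = 5
    exchange_interval: float = 0.1
    timestep: float = 0.001
    friction: float = 5.0
    temperature: float | None = None  # None -> model.temperature
    burn_in: float = 0.25
    seed_a: int = 1
    seed_b: int = 2
    final_n_images: int = 120
    final_spring_constant: float = 4.0
    final_sampling_time: float | None = None  # None -> 2x sampling_time

    def __post_init__(self) -> None:
        if self.n_images < 3:
            raise ValueError("need at least 3 images")


@dataclass
class ImageSample:
    mean_positions: np.ndarray  # (n_sel, dim)
    mean_force: np.ndarray  # restraint-balance estimate k(<x> - ref)
    n_samples: int
    force_sem: np.ndarray | None = None  # per-component SEM from block means
    positions: np.ndarray | None = None  # optional recorded samples


@dataclass
class RefinementResult:
    path: StringPath
    profiles: dict
    displacement_history: list[float] = field(default_factory=list)
    exchange_stats: pd.DataFrame | None = None
    samples: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Path construction


def _resample_even(dense: np.ndarray, n_out: int) -> np.ndarray:
    """Pick n_out points at even arc length along a dense polyline."""
    flat = dense.reshape(len(dense), -1)
    seg = np.linalg.norm(np.diff(flat, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        return np.repeat(dense[:1], n_out, axis=0)
    targets = np.linspace(0.0, s[-1], n_out)
    out = np.empty((n_out,) + dense.shape[1:])
    f = interp1d(s, flat, axis=0)
    out = f(targets).reshape((n_out,) + dense.shape[1:])
    return out


def init_path_linear(
    endpoint_a: np.ndarray,
    endpoint_b: np.ndarray,
    n_images: int,
    selection: AtomSelection | None = None,
    spring_constant: float = 2.0,
    align: bool = True,
) -> StringPath:
    """Straight-line initial path after mutual superposition; endpoints exact."""
    a = np.asarray(endpoint_a, dtype=float)
    b = np.asarray(endpoint_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("endpoints must share representative atoms")
    if n_images < 2:
        raise ValueError("need at least 2 images")
    if align and a.shape[1] == 3 and len(a) >= 3:
        b = align_to(b, a)
    ts = np.linspace(0.0, 1.0, n_images)
    images = [StringImage((1 - t) * a + t * b, spring_constant) for t in ts]
    images[0].reference = a.copy()
    images[-1].reference = b.copy()
    sel = selection if selection is not None else AtomSelection(tuple(range(len(a))))
    return StringPath(images, sel, endpoints_fixed=True, alignment_reference=a.copy())


def resample_path(path: StringPath, n_images: int, spring_constant: float | None = None) -> StringPath:
    """Re-discretize a path at even arc length with n_images images."""
    refs = path.references()
    dense = _resample_even(refs, max(20 * path.n_images, n_images * 4))
    new_refs = _resample_even(dense, n_images)
    k = spring_constant if spring_constant is not None else path.images[0].spring_constant
    new_refs[0] = refs[0]
    new_refs[-1] = refs[-1]
    return StringPath(
        [StringImage(r, k) for r in new_refs],
        path.selection,
        endpoints_fixed=path.endpoints_fixed,
        alignment_reference=path.alignment_reference,
    )


def init_images_from_trajectory(
    traj: Trajectory, path: StringPath
) -> tuple[np.ndarray, np.ndarray]:
    """Starting coordinates per image from a driven trajectory.

    For each image, the frame whose representative atoms have the smallest
    RMSD to the image (ties broken by the earliest frame) is selected; the
    full frame is rigidly aligned to the path's alignment reference on the
    selection.  Returns (frame indices, aligned full-coordinate starts).
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    idx = path.selection.array()
    dim = path.dim
    refs = path.references()
    do_align = dim == 3 and len(idx) >= 3 and path.alignment_reference is not None
    aligned_frames = []
    for frame in traj.frames:
        if do_align:
            sel_xyz = frame[idx]
            moved = align_to(sel_xyz, path.alignment_reference)
            # apply the same rigid move to the full frame
            cm = sel_xyz.mean(axis=0)
            from .geometry import kabsch_superpose

            pose, _ = kabsch_superpose(sel_xyz, path.alignment_reference)
            full = (frame - cm) @ pose.rotation_matrix + path.alignment_reference.mean(
                axis=0
            )
            aligned_frames.append(full)
        else:
            aligned_frames.append(frame)
    aligned = np.array(aligned_frames)
    sel_coords = aligned[:, idx, :]
    starts = []
    chosen = []
    for ref in refs:
        d = np.linalg.norm(
            sel_coords.reshape(len(aligned), -1) - ref.ravel()[None, :], axis=1
        ) / np.sqrt(len(idx))
        j = int(np.argmin(d))  # argmin returns the earliest minimiser
        chosen.append(j)
        starts.append(aligned[j].copy())
    return np.array(chosen), np.array(starts)


# ---------------------------------------------------------------------------
# Replica-exchange sampling


def _image_restraint_energy(x_sel: np.ndarray, ref: np.ndarray, k: float) -> float:
    d = x_sel - ref
    return 0.5 * k * float(np.sum(d * d))


def sample_images_with_exchange(
    model,
    path: StringPath,
    config: RefinementConfig,
    group_seed: int,
    init_coords: np.ndarray | None = None,
    return_states: bool = False,
    record_positions: int = 0,
):
    """Sample every image under its restraint, with adjacent-pair exchange.

    Every ``exchange_interval`` ps, adjacent image pairs (alternating
    odd/even sweeps) attempt a configuration swap accepted with probability
    min(1, exp(-beta*Delta)), Delta = [U_i(x_j) + U_j(x_i)] - [U_i(x_i) +
    U_j(x_j)] where U_k is image k's restraint energy.  All randomness
    derives from ``group_seed``.

    Returns (list of ImageSample, exchange-statistics DataFrame) and, when
    ``return_states`` is set, the final walker coordinates for warm restarts.
    """
    n_im = path.n_images
    idx = path.selection.array()
    refs = path.references()
    ks = np.array([im.spring_constant for im in path.images])
    temperature = config.temperature if config.temperature is not None else getattr(
        model, "temperature", 300.0
    )
    beta = 1.0 / (KB_KCAL * temperature)
    n_steps_total = max(1, int(round(config.sampling_time / config.timestep)))
    exch_steps = max(1, int(round(config.exchange_interval / config.timestep)))
    n_blocks = max(1, n_steps_total // exch_steps)
    burn_blocks = int(np.floor(config.burn_in * n_blocks))

    if init_coords is None:
        if model.n_sites != len(idx):
            raise ValueError(
                "init_coords required when the model has atoms outside the "
                "representative selection"
            )
        init_coords = refs.copy()
    init_coords = np.asarray(init_coords, dtype=float)

    ss = np.random.SeedSequence(group_seed)
    child_seeds = ss.spawn(n_im + 1)
    exch_rng = np.random.default_rng(child_seeds[-1])

    states: list[LangevinState] = []
    force_fns = []
    for i in range(n_im):
        params_i = LangevinParams(
            temperature=temperature,
            friction=config.friction,
            timestep=config.timestep,
            seed=0,
        )
        st = _init_state(init_coords[i], model.masses, params_i)
        st.rng = np.random.default_rng(child_seeds[i])
        # re-draw velocities from the walker's own stream for reproducibility
        kT = KB_KCAL * temperature
        sigma = np.sqrt(kT / model.masses)[:, None]
        st.velocities = sigma * st.rng.standard_normal(st.coords.shape)
        states.append(st)

        def make_force(i=i):
            ref = refs[i]
            k = ks[i]

            def force_fn(x, t):
                e, f = model.energy_forces(x)
                d = x[idx] - ref
                e += 0.5 * k * np.sum(d * d)
                f = f.copy()
                f[idx] -= k * d
                return e, f

            return force_fn

        force_fns.append(make_force())

    params = LangevinParams(
        temperature=temperature,
        friction=config.friction,
        timestep=config.timestep,
        seed=0,
    )
    block_means: list[list[np.ndarray]] = [[] for _ in range(n_im)]
    pos_records: list[list[np.ndarray]] = [[] for _ in range(n_im)]
    attempts = np.zeros(n_im - 1, dtype=int)
    accepts = np.zeros(n_im - 1, dtype=int)
    step_no = 0

    for block in range(n_blocks):
        for i in range(n_im):
            st = states[i]
            bacc = np.zeros((len(idx), path.dim))
            for s in range(exch_steps):
                langevin_step(st, force_fns[i], model.masses, params)
                bacc += st.coords[idx]
                if (
                    record_positions
                    and block >= burn_blocks
                    and (step_no + s) % record_positions == 0
                ):
                    pos_records[i].append(st.coords[idx].copy())
            if block >= burn_blocks:
                block_means[i].append(bacc / exch_steps)
        step_no += exch_steps
        start = block % 2  # alternate odd/even adjacent pairs
        for i in range(start, n_im - 1, 2):
            xi = states[i].coords[idx]
            xj = states[i + 1].coords[idx]
            delta = (
                _image_restraint_energy(xj, refs[i], ks[i])
                + _image_restraint_energy(xi, refs[i + 1], ks[i + 1])
                - _image_restraint_energy(xi, refs[i], ks[i])
                - _image_restraint_energy(xj, refs[i + 1], ks[i + 1])
            )
            attempts[i] += 1
            accept = True if delta <= 0 else exch_rng.uniform() < np.exp(-beta * delta)
            if accept:
                accepts[i] += 1
                ci = states[i].coords.copy()
                states[i].coords = states[i + 1].coords.copy()
                states[i + 1].coords = ci
                states[i].forces = None
                states[i + 1].forces = None

    samples = []
    for i in range(n_im):
        bm = np.array(block_means[i])  # (n_blocks_kept, n_sel, dim)
        nb = len(bm)
        mean_pos = bm.mean(axis=0)
        # SEM of the mean force from the spread of (nearly independent)
        # block means; one exchange interval is the decorrelation unit
        sem_pos = (
            bm.std(axis=0, ddof=1) / np.sqrt(nb) if nb > 1 else np.zeros_like(mean_pos)
        )
        samples.append(
            ImageSample(
                mean_positions=mean_pos,
                mean_force=ks[i] * (mean_pos - refs[i]),
                n_samples=nb * exch_steps,
                force_sem=ks[i] * sem_pos,
            )
        )
    stats = pd.DataFrame(
        {
            "pair": [f"{i}-{i + 1}" for i in range(n_im - 1)],
            "attempts": attempts,
            "accepts": accepts,
            "acceptance": np.divide(
                accepts, attempts, out=np.zeros(n_im - 1), where=attempts > 0
            ),
        }
    )
    if record_positions:
        for smp, rec in zip(samples, pos_records):
            smp.positions = np.array(rec)
    if return_states:
        return samples, stats, np.array([st.coords for st in states])
    return samples, stats


# ---------------------------------------------------------------------------
# Path update


def _estimate_noise_scale(y: np.ndarray) -> float:
    """Per-point noise variance from second differences (columns pooled)."""
    if len(y) < 3:
        return 0.0
    d2 = y[:-2] - 2 * y[1:-1] + y[2:]
    return float(np.mean(d2**2) / 6.0)


def update_path(
    samples_a: list[ImageSample],
    samples_b: list[ImageSample] | None,
    path: StringPath,
    minima_breaks: list[int] | None = None,
    smoothing: float | None = None,
) -> StringPath:
    """New pathway through the pooled mean conformations.

    Means from the two groups are pooled per image, aligned to the common
    reference, fitted (per Cartesian coordinate, against a chordal parameter)
    with a cubic smoothing spline per partial transition between breaks, and
    re-sampled at even arc length with the endpoints fixed.
    """
    n_im = path.n_images
    breaks = sorted(minima_breaks or [])
    if any(b <= 0 or b >= n_im - 1 for b in breaks):
        raise ValueError("breaks must be interior image indices")
    if breaks != sorted(set(breaks)):
        raise ValueError("breaks must be unique and ordered")
    means = np.array(
        [
            s.mean_positions if samples_b is None
            else 0.5 * (s.mean_positions + sb.mean_positions)
            for s, sb in zip(samples_a, samples_b or samples_a)
        ]
    )
    if path.dim == 3 and means.shape[1] >= 3 and path.alignment_reference is not None:
        means = np.array([align_to(m, path.alignment_reference) for m in means])
    flat = means.reshape(n_im, -1)

    nodes = [0] + breaks + [n_im - 1]
    dense_parts = []
    for seg_start, seg_end in zip(nodes[:-1], nodes[1:]):
        seg = flat[seg_start : seg_end + 1]
        m = len(seg)
        if m < 2:
            continue
        chord = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(seg, axis=0), axis=1))]
        )
        if chord[-1] <= 0:
            dense_parts.append(seg)
            continue
        u = chord / chord[-1]
        if m >= 5:
            s_val = smoothing if smoothing is not None else m * _estimate_noise_scale(seg)
            dense_u = np.linspace(0, 1, max(10 * m, 50))
            fitted = np.empty((len(dense_u), flat.shape[1]))
            for c in range(flat.shape[1]):
                spl = UnivariateSpline(u, seg[:, c], k=3, s=s_val)
                fitted[:, c] = spl(dense_u)
        else:
            f = interp1d(u, seg, axis=0)
            dense_u = np.linspace(0, 1, max(10 * m, 50))
            fitted = f(dense_u)
        dense_parts.append(fitted)
    dense = np.vstack(
        [p if i == 0 else p[1:] for i, p in enumerate(dense_parts)]
    )
    if path.endpoints_fixed:
        # pin the ends by a linear warp of the dense curve, so the even-arc
        # resampling below keeps consecutive gaps equal
        a = path.images[0].reference.ravel()
        b = path.images[-1].reference.ravel()
        u = np.linspace(0.0, 1.0, len(dense))[:, None]
        dense = dense + (1 - u) * (a - dense[0]) + u * (b - dense[-1])
    new_flat = _resample_even(dense, n_im)
    new_refs = new_flat.reshape((n_im,) + means.shape[1:])
    if path.endpoints_fixed:
        new_refs[0] = path.images[0].reference
        new_refs[-1] = path.images[-1].reference
    return StringPath(
        [
            StringImage(r, im.spring_constant)
            for r, im in zip(new_refs, path.images)
        ],
        path.selection,
        endpoints_fixed=path.endpoints_fixed,
        alignment_reference=path.alignment_reference,
    )


# ---------------------------------------------------------------------------
# Free energy


def integrate_mean_forces(
    samples: list[ImageSample], path: StringPath, group_id: str = ""
) -> FreeEnergyProfile:
    """Free energy along the path by tangent-projected mean-force integration.

    The mean system force at image i is the restraint-balance estimate
    k(<x>_i - x_i^ref); its projection on the unit tangent (central
    differences of the references) gives -dG/ds, integrated by the
    trapezoidal rule over cumulative arc length, anchored to G = 0 at the
    first image.
    """
    refs = path.references().reshape(path.n_images, -1)
    n = len(refs)
    if n != len(samples):
        raise ValueError("one sample per image required")
    tangents = np.empty_like(refs)
    tangents[0] = refs[1] - refs[0]
    tangents[-1] = refs[-1] - refs[-2]
    tangents[1:-1] = refs[2:] - refs[:-2]
    norms = np.linalg.norm(tangents, axis=1)
    norms[norms == 0] = 1.0
    tangents /= norms[:, None]
    forces = np.array([s.mean_force.ravel() for s in samples])
    dgds = -np.sum(forces * tangents, axis=1)
    s = path.arc_lengths()
    g = np.concatenate([[0.0], np.cumsum(0.5 * (dgds[1:] + dgds[:-1]) * np.diff(s))])
    sem = None
    if all(sm.force_sem is not None for sm in samples):
        sems = np.array([sm.force_sem.ravel() for sm in samples])
        var_dgds = np.sum((tangents * sems) ** 2, axis=1)
        incr_var = (0.5 * np.diff(s)) ** 2 * (var_dgds[1:] + var_dgds[:-1])
        sem = np.sqrt(np.concatenate([[0.0], np.cumsum(incr_var)]))
    return FreeEnergyProfile(s, g, group_id, sem=sem)


def detect_metastable_states(
    profile: FreeEnergyProfile, min_depth: float
) -> list[int]:
    """Interior local minima with prominence >= min_depth, sorted."""
    if len(profile.free_energy) < 3:
        raise ValueError("profile too short")
    peaks, _ = find_peaks(-profile.free_energy, prominence=min_depth)
    return sorted(int(p) for p in peaks)


# ---------------------------------------------------------------------------
# Full refinement


def refine(
    model,
    path0: StringPath,
    config: RefinementConfig,
    init_coords_a: np.ndarray | None = None,
    init_coords_b: np.ndarray | None = None,
    minima_breaks: list[int] | None = None,
) -> RefinementResult:
    """Iterative sample-and-update refinement with two independent groups.

    Both groups sample the common path each iteration (different seeds and
    initial coordinates); their pooled means define the updated path.  After
    ``n_iterations``, a longer final pass (optionally re-discretized to
    ``final_n_images`` images with ``final_spring_constant`` springs)
    produces one free-energy profile per group.
    """
    path = path0
    disp_history: list[float] = []
    states_a, states_b = init_coords_a, init_coords_b
    for it in range(config.n_iterations):
        samples_a, _, states_a = sample_images_with_exchange(
            model, path, config, config.seed_a + 1000 * it, states_a,
            return_states=True,
        )
        samples_b, _, states_b = sample_images_with_exchange(
            model, path, config, config.seed_b + 1000 * it, states_b,
            return_states=True,
        )
        new_path = update_path(samples_a, samples_b, path, minima_breaks)
        old = path.references().reshape(path.n_images, -1)
        new = new_path.references().reshape(path.n_images, -1)
        disp = float(
            np.mean(np.linalg.norm(new - old, axis=1))
            / np.sqrt(old.shape[1] / path.dim)
        )
        disp_history.append(disp)
        path = new_path
    if len(disp_history) >= 3 and not (
        disp_history[-1] <= disp_history[-3] + 1e-12
    ):
        warnings.warn(
            "string refinement may not have converged: image displacement "
            f"not decreasing over the last iterations {disp_history[-3:]}"
        )

    final_cfg = replace(
        config,
        sampling_time=config.final_sampling_time or 2 * config.sampling_time,
    )
    final_path = path
    if config.final_n_images != path.n_images or (
        config.final_spring_constant != path.images[0].spring_constant
    ):
        final_path = resample_path(
            path, config.final_n_images, config.final_spring_constant
        )
        # image count changed: seed each new walker from the nearest old one
        def remap(states):
            if states is None:
                return None
            n_old, n_new = len(states), config.final_n_images
            pick = np.rint(
                np.linspace(0, n_old - 1, n_new)
            ).astype(int)
            return np.array([states[p] for p in pick])

        states_a = remap(states_a)
        states_b = remap(states_b)
    samples_a, stats_a = sample_images_with_exchange(
        model, final_path, final_cfg, config.seed_a + 999_000, states_a
    )
    samples_b, stats_b = sample_images_with_exchange(
        model, final_path, final_cfg, config.seed_b + 999_000, states_b
    )
    profiles = {
        "a": integrate_mean_forces(samples_a, final_path, "a"),
        "b": integrate_mean_forces(samples_b, final_path, "b"),
    }
    return RefinementResult(
        final_path,
        profiles,
        disp_history,
        exchange_stats=pd.concat(
            [stats_a.assign(group="a"), stats_b.assign(group="b")],
            ignore_index=True,
        ),
        samples={"a": samples_a, "b": samples_b},
    )
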