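"""Structures, trajectories, and atom selections.

The in-memory currency of the whole package is :class:`Conformation`: an
ordered list of :class:`AtomRecord` labels plus an (N, 3) coordinate array in
angstroms.  PDB files are parsed through gemmi (one conformation per MODEL,
altlocs resolved by highest occupancy, then alphabetically); multi-frame
trajectories use a plain-text XYZ dialect whose comment line carries the frame
time in picoseconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Conformation",
    "Trajectory",
    "AtomSelection",
    "PDBParseError",
    "EmptyStructureError",
    "MissingAtomError",
    "TrajectoryFormatError",
    "read_pdb",
    "write_pdb",
    "select_representative_atoms",
    "place_amide_hydrogens",
    "read_trajectory",
    "write_trajectory",
]


class PDBParseError(ValueError):
    """A PDB record could not be parsed."""


class EmptyStructureError(ValueError):
    """A structure file contained no ATOM/HETATM records."""


class MissingAtomError(KeyError):
    """A named atom is absent from a conformation."""


class TrajectoryFormatError(ValueError):
    """A trajectory file violates the XYZ dialect."""


@dataclass(frozen=True)
class AtomRecord:
    """Identity of one atom: name, residue, chain, element."""

    atom_name: str
    residue_name: str
    residue_index: int  # 1-based, as in the source PDB; may be gapped
    chain_id: str = "A"
    element: str = ""

    def __post_init__(self) -> None:
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")
        if self.residue_index < 1:
            raise ValueError(f"residue_index must be >= 1, got {self.residue_index}")


@dataclass
class Conformation:
    """Ordered atoms plus one coordinate set (angstroms)."""

    atoms: list[AtomRecord]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.atoms)

    def copy(self) -> "Conformation":
        return Conformation(list(self.atoms), self.coords.copy())

    def residue_indices(self) -> list[int]:
        """Distinct residue indices in order of first appearance."""
        seen: dict[int, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_index, None)
        return list(seen)

    def index_of(self, residue_index: int, atom_name: str) -> int:
        """0-based position of the named atom, or MissingAtomError."""
        for i, a in enumerate(self.atoms):
            if a.residue_index == residue_index and a.atom_name == atom_name:
                return i
        raise MissingAtomError(
            f"atom {atom_name!r} of residue {residue_index} not found"
        )

    def has_atom(self, residue_index: int, atom_name: str) -> bool:
        try:
            self.index_of(residue_index, atom_name)
            return True
        except MissingAtomError:
            return False

    def atom_coord(self, residue_index: int, atom_name: str) -> np.ndarray:
        return self.coords[self.index_of(residue_index, atom_name)]

    def residue_name(self, residue_index: int) -> str:
        for a in self.atoms:
            if a.residue_index == residue_index:
                return a.residue_name
        raise MissingAtomError(f"residue {residue_index} not found")


@dataclass
class Trajectory:
    """Frames sharing one atom list; times in ps, strictly increasing."""

    frames: list[np.ndarray]
    frame_times: np.ndarray
    atom_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ValueError("a trajectory needs at least one frame")
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        n = self.frames[0].shape[0]
        for k, f in enumerate(self.frames):
            if f.shape != (n, 3):
                raise ValueError(f"frame {k} has shape {f.shape}, expected ({n}, 3)")
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frame_times.shape != (len(self.frames),):
            raise ValueError("frame_times length must equal number of frames")
        if len(self.frame_times) > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        if not self.atom_labels:
            self.atom_labels = ["X"] * n
        if len(self.atom_labels) != n:
            raise ValueError("atom_labels length must equal atom count")

    @property
    def n_atoms(self) -> int:
        return self.frames[0].shape[0]

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class AtomSelection:
    """Ordered unique 0-based indices into a conformation's atom list."""

    indices: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        if len(set(idx)) != len(idx):
            raise ValueError("selection indices must be unique")
        if any(i < 0 for i in idx):
            raise ValueError("selection indices must be non-negative")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)

    def validate_for(self, conf_or_n) -> None:
        n = conf_or_n if isinstance(conf_or_n, int) else len(conf_or_n)
        if self.indices and max(self.indices) >= n:
            raise IndexError(
                f"selection index {max(self.indices)} out of range for {n} atoms"
            )


# ---------------------------------------------------------------------------
# PDB I/O


def _prescan_pdb(path: Path) -> int:
    """Validate coordinate fields of ATOM/HETATM lines; return their count."""
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                n += 1
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    fldtxt = line[lo:hi]
                    try:
                        float(fldtxt)
                    except ValueError:
                        raise PDBParseError(
                            f"{path}: malformed coordinate field {fldtxt!r} "
                            f"on line {lineno}"
                        ) from None
    return n


def read_pdb(path, model: int | None = None) -> Conformation:
    """Read a PDB file into a :class:`Conformation`.

    Only the first MODEL is used unless ``model`` (1-based) is given.  For
    atoms with alternate locations, the altloc with the highest occupancy is
    retained (alphabetical altloc id breaks ties).  Coordinates are in
    angstroms and residue numbering follows the file.
    """
    path = Path(path)
    if _prescan_pdb(path) == 0:
        raise EmptyStructureError(f"{path}: no ATOM/HETATM records")
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise PDBParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    gm = st[0] if model is None else st[model - 1]

    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    for chain in gm:
        for res in chain:
            # group altlocs by atom name, keep highest occupancy then altloc id
            by_name: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = by_name.get(at.name)
                if prev is None:
                    by_name[at.name] = at
                else:
                    key_new = (-at.occ, at.altloc or "~")
                    key_old = (-prev.occ, prev.altloc or "~")
                    if key_new < key_old:
                        by_name[at.name] = at
            for at in by_name.values():
                atoms.append(
                    AtomRecord(
                        atom_name=at.name,
                        residue_name=res.name,
                        residue_index=res.seqid.num,
                        chain_id=chain.name,
                        element=at.element.name,
                    )
                )
                coords.append(np.array([at.pos.x, at.pos.y, at.pos.z]))
    if not atoms:
        raise EmptyStructureError(f"{path}: no atoms in selected model")
    return Conformation(atoms, np.array(coords))


def write_pdb(conf: Conformation, path) -> None:
    """Write a conformation as PDB v3.3 ATOM records (plus TER/END)."""
    lines = []
    for serial, (a, xyz) in enumerate(zip(conf.atoms, conf.coords), start=1):
        name = a.atom_name
        # PDB convention: 1-3 char names start in column 14
        name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
        lines.append(
            f"ATOM  {serial:5d} {name_field}{'':1s}{a.residue_name:<3s} "
            f"{a.chain_id[:1] or 'A'}{a.residue_index:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {a.element:>2s}"
        )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Representative-atom selection and amide hydrogens

_PROLINE_NAMES = {"PRO", "PRO-LIKE"}


def _is_proline(conf: Conformation, residue_index: int) -> bool:
    return conf.residue_name(residue_index).upper() in _PROLINE_NAMES


def select_representative_atoms(
    conf: Conformation,
    first_res: int,
    last_res: int,
    extra_atoms: Sequence[tuple[int, str]] = (),
) -> AtomSelection:
    """Representative backbone atoms of a loop.

    For each residue in ``[first_res, last_res]``: the amide hydrogen H
    (skipped for proline residues), the carbonyl oxygen O, and CA; followed by
    any requested extra atoms of that residue (e.g. a side-chain CB).  The
    Cartesian coordinates of these atoms specify the backbone conformation,
    including the position and orientation of each peptide plane.
    """
    present = set(conf.residue_indices())
    wanted = [r for r in range(first_res, last_res + 1) if r in present]
    if len(wanted) != last_res - first_res + 1:
        missing = sorted(set(range(first_res, last_res + 1)) - present)
        raise MissingAtomError(f"residues {missing} absent from conformation")
    extras_by_res: dict[int, list[str]] = {}
    for res, name in extra_atoms:
        extras_by_res.setdefault(res, []).append(name)
    indices: list[int] = []
    for r in wanted:
        if not _is_proline(conf, r):
            indices.append(conf.index_of(r, "H"))
        indices.append(conf.index_of(r, "O"))
        indices.append(conf.index_of(r, "CA"))
        for name in extras_by_res.get(r, []):
            indices.append(conf.index_of(r, name))
    return AtomSelection(tuple(indices), label=f"rep:{first_res}-{last_res}")


def place_amide_hydrogens(conf: Conformation) -> Conformation:
    """Return a copy with backbone amide hydrogens built.

    For each non-proline, non-N-terminal residue lacking an H, the hydrogen is
    placed 1.00 angstrom from N, in the C(prev)-N-CA plane, along the bisector
    of the exterior angle.  Residues with missing backbone atoms are skipped
    with a warning, as is the N-terminal residue.
    """
    res_order = conf.residue_indices()
    new_atoms: list[AtomRecord] = []
    new_coords: list[np.ndarray] = []
    # map residue -> previous residue in chain order (per chain)
    prev_in_chain: dict[int, int | None] = {}
    last_by_chain: dict[str, int] = {}
    chain_of: dict[int, str] = {}
    for a in conf.atoms:
        chain_of.setdefault(a.residue_index, a.chain_id)
    for r in res_order:
        ch = chain_of[r]
        prev_in_chain[r] = last_by_chain.get(ch)
        last_by_chain[ch] = r

    built: dict[int, np.ndarray] = {}
    for r in res_order:
        if _is_proline(conf, r) or conf.has_atom(r, "H"):
            continue
        prev = prev_in_chain[r]
        if prev is None:
            warnings.warn(f"residue {r}: N-terminal, amide H not built")
            continue
        try:
            n = conf.atom_coord(r, "N")
            ca = conf.atom_coord(r, "CA")
            c_prev = conf.atom_coord(prev, "C")
        except MissingAtomError:
            warnings.warn(f"residue {r}: backbone atom missing, amide H skipped")
            continue
        u1 = n - c_prev
        u2 = n - ca
        u1 /= np.linalg.norm(u1)
        u2 /= np.linalg.norm(u2)
        d = u1 + u2
        nrm = np.linalg.norm(d)
        if nrm < 1e-8:
            warnings.warn(f"residue {r}: degenerate geometry, amide H skipped")
            continue
        built[r] = n + d / nrm  # 1.00 angstrom along the exterior bisector

    for i, a in enumerate(conf.atoms):
        new_atoms.append(a)
        new_coords.append(conf.coords[i])
        if a.atom_name == "N" and a.residue_index in built:
            new_atoms.append(
                AtomRecord("H", a.residue_name, a.residue_index, a.chain_id, "H")
            )
            new_coords.append(built[a.residue_index])
    return Conformation(new_atoms, np.array(new_coords))


# ---------------------------------------------------------------------------
# Trajectory I/O (multi-frame XYZ dialect)


def write_trajectory(traj: Trajectory, path) -> None:
    """Write the plain-text multi-frame XYZ dialect.

    Per frame: atom-count line, comment line ``t=<ps>``, then
    ``name x y z`` rows with six decimal places.
    """
    with open(path, "w") as fh:
        for t, frame in zip(traj.frame_times, traj.frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"t={t:.6f}\n")
            for name, xyz in zip(traj.atom_labels, frame):
                fh.write(f"{name} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")


def read_trajectory(path) -> Trajectory:
    """Read the XYZ dialect written by :func:`write_trajectory`."""
    frames: list[np.ndarray] = []
    times: list[float] = []
    labels: list[str] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_no = 0
    n_expected: int | None = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise TrajectoryFormatError(
                f"frame {frame_no}: expected atom count, got {lines[i]!r}"
            ) from None
        if n_expected is None:
            n_expected = n
        elif n != n_expected:
            raise TrajectoryFormatError(
                f"frame {frame_no}: atom count {n} differs from first frame "
                f"({n_expected})"
            )
        comment = lines[i + 1].strip()
        if not comment.startswith("t="):
            raise TrajectoryFormatError(
                f"frame {frame_no}: comment line must carry 't=<ps>', got "
                f"{comment!r}"
            )
        times.append(float(comment[2:]))
        rows = lines[i + 2 : i + 2 + n]
        if len(rows) < n:
            raise TrajectoryFormatError(f"frame {frame_no}: truncated frame")
        coords = np.empty((n, 3))
        frame_labels: list[str] = []
        for k, row in enumerate(rows):
            parts = row.split()
            if len(parts) != 4:
                raise TrajectoryFormatError(
                    f"frame {frame_no}, row {k}: expected 'name x y z'"
                )
            frame_labels.append(parts[0])
            coords[k] = [float(p) for p in parts[1:]]
        if not labels:
            labels = frame_labels
        frames.append(coords)
        i += 2 + n
        frame_no += 1
    if not frames:
        raise TrajectoryFormatError(f"{path}: no frames")
    return Trajectory(frames, np.array(times), labels)
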