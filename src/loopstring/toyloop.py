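"""A coarse peptide-like chain with designed wrapped/unwrapped states.

Each residue carries five sites (N, H, CA, C, O; H omitted for proline-like
residues).  The energy is a small internal-coordinate force field — harmonic
bonds and angles, periodic torsion wells, one short-range "helical H-bond"
contact between a donor amide hydrogen and the carbonyl oxygen four residues
upstream, and a soft-core repulsion between distant heavy atoms.  Every
backbone phi and psi torsion has two wells 180 degrees apart, so endpoint
pairs emulating the wrapping/unwrapping of a helix turn can be generated by
flipping chosen torsions into their alternative well.

Energies are kcal/mol, lengths angstroms, angles degrees in user-facing
values.  All terms are functions of internal coordinates only, so the energy
is exactly invariant under rigid-body motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .structures import AtomRecord, AtomSelection, Conformation

__all__ = [
    "ToyLoopModel",
    "EndpointPair",
    "MinimizationError",
    "build_toy_loop",
    "generate_endpoint_conformations",
]

KB_KCAL = 0.0019872041  # kcal/mol/K
AMU_TO_INTERNAL = 2.390057e-3  # amu -> kcal*ps^2/(mol*A^2)

# ideal internal coordinates (angstrom / degree)
_BONDS = {"N-H": 1.00, "N-CA": 1.46, "CA-C": 1.52, "C-O": 1.23, "C-N": 1.33}
_BOND_K = {"N-H": 450.0, "N-CA": 300.0, "CA-C": 300.0, "C-O": 500.0, "C-N": 400.0}
_ANGLES = {
    "C-N-H": 119.0,
    "CA-N-H": 119.0,
    "N-CA-C": 111.0,
    "CA-C-N": 116.0,
    "C-N-CA": 122.0,
    "CA-C-O": 121.0,
}
_ANGLE_K = 80.0  # kcal/mol/rad^2

_MASS = {"N": 14.007, "H": 1.008, "CA": 12.011, "C": 12.011, "O": 15.999}

PHI_WELLS = (-57.0, 123.0)  # helical well first, flipped well 180 deg away
PSI_WELLS = (-47.0, 133.0)


class MinimizationError(RuntimeError):
    """Energy minimization failed to reach the required gradient norm."""


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _place(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: new atom bonded to c, with angle b-c-new and dihedral
    a-b-c-new (same sign convention as :func:`loopstring.geometry.dihedral`)."""
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


@dataclass
class ToyLoopModel:
    """Topology, parameters, and energy of the toy loop chain."""

    atoms: list[AtomRecord]
    masses_amu: np.ndarray
    bond_idx: np.ndarray  # (nb, 2)
    bond_r0: np.ndarray
    bond_k: np.ndarray
    angle_idx: np.ndarray  # (na, 3), angle at the middle atom
    angle_theta0: np.ndarray  # radians
    angle_k: np.ndarray
    torsion_idx: np.ndarray  # (nt, 4)
    torsion_amp: np.ndarray  # (nt, 3), zero-padded wells
    torsion_kappa: np.ndarray  # (nt, 3)
    torsion_chi0: np.ndarray  # (nt, 3) radians
    rep_idx: np.ndarray  # (np, 2)
    rep_eps: float
    rep_rc: float
    hbond_donor: int  # site index of donor H
    hbond_acceptor: int  # site index of acceptor O
    hbond_r0: float
    hbond_depth: float
    hbond_sigma: float
    hbond_enabled: bool
    temperature: float
    n_residues: int
    proline_like: tuple[int, ...]
    contact_residues: tuple[int, int]  # (acceptor residue, donor residue)
    torsion_map: dict = field(default_factory=dict)  # (res, "phi"/"psi") -> row
    designed_base: dict = field(default_factory=dict)  # (res, kind) -> deg

    # -- model protocol -----------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.atoms)

    @property
    def dim(self) -> int:
        return 3

    @property
    def masses(self) -> np.ndarray:
        return self.masses_amu * AMU_TO_INTERNAL

    def to_conformation(self, coords: np.ndarray) -> Conformation:
        return Conformation(list(self.atoms), np.asarray(coords, float).copy())

    def energy(self, coords: np.ndarray) -> float:
        return self.energy_forces(coords)[0]

    def forces(self, coords: np.ndarray) -> np.ndarray:
        return self.energy_forces(coords)[1]

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        return -self.energy_forces(coords)[1]

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        x = np.asarray(coords, dtype=float).reshape(self.n_sites, 3)
        e = 0.0
        f = np.zeros_like(x)

        # bonds
        d = x[self.bond_idx[:, 0]] - x[self.bond_idx[:, 1]]
        r = np.linalg.norm(d, axis=1)
        dr = r - self.bond_r0
        e += float(np.sum(0.5 * self.bond_k * dr**2))
        fb = (-self.bond_k * dr / r)[:, None] * d
        np.add.at(f, self.bond_idx[:, 0], fb)
        np.add.at(f, self.bond_idx[:, 1], -fb)

        # angles (at middle atom j of i-j-k)
        i, j, k = self.angle_idx.T
        rij = x[i] - x[j]
        rkj = x[k] - x[j]
        nij = np.linalg.norm(rij, axis=1)
        nkj = np.linalg.norm(rkj, axis=1)
        uij = rij / nij[:, None]
        ukj = rkj / nkj[:, None]
        cosq = np.clip(np.sum(uij * ukj, axis=1), -1.0, 1.0)
        theta = np.arccos(cosq)
        sinq = np.sqrt(np.clip(1.0 - cosq**2, 1e-12, None))
        dtheta = theta - self.angle_theta0
        e += float(np.sum(0.5 * self.angle_k * dtheta**2))
        dVdtheta = self.angle_k * dtheta
        gi = (cosq[:, None] * uij - ukj) / (nij * sinq)[:, None]
        gk = (cosq[:, None] * ukj - uij) / (nkj * sinq)[:, None]
        np.add.at(f, i, -dVdtheta[:, None] * gi)
        np.add.at(f, k, -dVdtheta[:, None] * gk)
        np.add.at(f, j, dVdtheta[:, None] * (gi + gk))

        # torsions: V = sum_w -A exp(kappa (cos(chi - chi0) - 1))
        p1, p2, p3, p4 = (x[self.torsion_idx[:, c]] for c in range(4))
        b1 = p2 - p1
        b2 = p3 - p2
        b3 = p4 - p3
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        xcomp = np.sum(n1 * n2, axis=1)
        ycomp = np.sum(np.cross(n1, n2) * (b2 / nb2[:, None]), axis=1)
        chi = np.arctan2(ycomp, xcomp)
        dchi = chi[:, None] - self.torsion_chi0
        ex = np.exp(self.torsion_kappa * (np.cos(dchi) - 1.0))
        e += float(np.sum(-self.torsion_amp * ex))
        dVdchi = np.sum(self.torsion_amp * self.torsion_kappa * np.sin(dchi) * ex, axis=1)
        n1sq = np.sum(n1 * n1, axis=1)
        n2sq = np.sum(n2 * n2, axis=1)
        g1 = -(nb2 / n1sq)[:, None] * n1
        g4 = (nb2 / n2sq)[:, None] * n2
        a12 = np.sum(b1 * b2, axis=1) / nb2**2
        a32 = np.sum(b3 * b2, axis=1) / nb2**2
        g2 = (-1.0 - a12)[:, None] * g1 + a32[:, None] * g4
        g3 = a12[:, None] * g1 + (-1.0 - a32)[:, None] * g4
        np.add.at(f, self.torsion_idx[:, 0], -dVdchi[:, None] * g1)
        np.add.at(f, self.torsion_idx[:, 1], -dVdchi[:, None] * g2)
        np.add.at(f, self.torsion_idx[:, 2], -dVdchi[:, None] * g3)
        np.add.at(f, self.torsion_idx[:, 3], -dVdchi[:, None] * g4)

        # soft-core repulsion between non-bonded heavy atoms
        if len(self.rep_idx):
            d = x[self.rep_idx[:, 0]] - x[self.rep_idx[:, 1]]
            r = np.linalg.norm(d, axis=1)
            inside = r < self.rep_rc
            if np.any(inside):
                rr = r[inside]
                e += float(np.sum(self.rep_eps * ((self.rep_rc - rr) / self.rep_rc) ** 2))
                dVdr = -2.0 * self.rep_eps * (self.rep_rc - rr) / self.rep_rc**2
                fr = (-dVdr / rr)[:, None] * d[inside]
                np.add.at(f, self.rep_idx[inside, 0], fr)
                np.add.at(f, self.rep_idx[inside, 1], -fr)

        # switchable helical H-bond contact: short-range Gaussian well
        if self.hbond_enabled:
            dvec = x[self.hbond_donor] - x[self.hbond_acceptor]
            r = float(np.linalg.norm(dvec))
            g = np.exp(-((r - self.hbond_r0) ** 2) / (2.0 * self.hbond_sigma**2))
            e += -self.hbond_depth * g
            dVdr = self.hbond_depth * g * (r - self.hbond_r0) / self.hbond_sigma**2
            fr = (-dVdr / r) * dvec
            f[self.hbond_donor] += fr
            f[self.hbond_acceptor] -= fr

        return e, f

    # -- construction helpers ----------------------------------------------
    def build_conformation(
        self,
        phi: np.ndarray | None = None,
        psi: np.ndarray | None = None,
    ) -> Conformation:
        """Cartesian coordinates from backbone torsions (ideal geometry).

        ``phi[i]``/``psi[i]`` are per-residue angles in degrees (0-based
        arrays of length n_residues; phi[0] is ignored).  Defaults are the
        designed helical wells.
        """
        n = self.n_residues
        phi = np.full(n, PHI_WELLS[0]) if phi is None else np.asarray(phi, float)
        psi = np.full(n, PSI_WELLS[0]) if psi is None else np.asarray(psi, float)
        pos: dict[tuple[int, str], np.ndarray] = {}
        pos[(1, "N")] = np.zeros(3)
        pos[(1, "CA")] = np.array([_BONDS["N-CA"], 0.0, 0.0])
        pos[(1, "C")] = _place(
            np.array([0.0, 1.0, 0.0]),
            pos[(1, "N")],
            pos[(1, "CA")],
            _BONDS["CA-C"],
            _ANGLES["N-CA-C"],
            45.0,
        )
        for r in range(2, n + 1):
            pos[(r, "N")] = _place(
                pos[(r - 1, "N")],
                pos[(r - 1, "CA")],
                pos[(r - 1, "C")],
                _BONDS["C-N"],
                _ANGLES["CA-C-N"],
                psi[r - 2],
            )
            pos[(r, "CA")] = _place(
                pos[(r - 1, "CA")],
                pos[(r - 1, "C")],
                pos[(r, "N")],
                _BONDS["N-CA"],
                _ANGLES["C-N-CA"],
                180.0,
            )
            pos[(r, "C")] = _place(
                pos[(r - 1, "C")],
                pos[(r, "N")],
                pos[(r, "CA")],
                _BONDS["CA-C"],
                _ANGLES["N-CA-C"],
                phi[r - 1],
            )
        for r in range(1, n + 1):
            pos[(r, "O")] = _place(
                pos[(r, "N")],
                pos[(r, "CA")],
                pos[(r, "C")],
                _BONDS["C-O"],
                _ANGLES["CA-C-O"],
                psi[r - 1] + 180.0,
            )
            if r in self.proline_like:
                continue
            if r == 1:
                pos[(1, "H")] = _place(
                    pos[(1, "C")],
                    pos[(1, "CA")],
                    pos[(1, "N")],
                    _BONDS["N-H"],
                    _ANGLES["CA-N-H"],
                    180.0,
                )
            else:
                pos[(r, "H")] = _place(
                    pos[(r - 1, "O")],
                    pos[(r - 1, "C")],
                    pos[(r, "N")],
                    _BONDS["N-H"],
                    _ANGLES["C-N-H"],
                    180.0,
                )
        coords = np.array([pos[(a.residue_index, a.atom_name)] for a in self.atoms])
        return self.to_conformation(coords)

    def representative_selection(self) -> AtomSelection:
        from .structures import select_representative_atoms

        dummy = Conformation(list(self.atoms), np.zeros((self.n_sites, 3)))
        return select_representative_atoms(dummy, 1, self.n_residues)

    def designed_torsion_value(self, coords: np.ndarray, res: int, kind: str) -> float:
        """Current value (degrees) of a designed phi/psi torsion."""
        from .geometry import dihedral

        row = self.torsion_map[(res, kind)]
        idx = self.torsion_idx[row]
        x = np.asarray(coords, float)
        return dihedral(x[idx[0]], x[idx[1]], x[idx[2]], x[idx[3]])


def _site_order(n_residues: int, proline_like: set[int]) -> list[AtomRecord]:
    atoms: list[AtomRecord] = []
    for r in range(1, n_residues + 1):
        resname = "PRO" if r in proline_like else "TOY"
        atoms.append(AtomRecord("N", resname, r, "A", "N"))
        if r not in proline_like:
            atoms.append(AtomRecord("H", resname, r, "A", "H"))
        atoms.append(AtomRecord("CA", resname, r, "A", "C"))
        atoms.append(AtomRecord("C", resname, r, "A", "C"))
        atoms.append(AtomRecord("O", resname, r, "A", "O"))
    return atoms


def build_toy_loop(
    n_residues: int,
    proline_like: tuple[int, ...] = (),
    seed: int = 0,
    contact_residues: tuple[int, int] | None = None,
    temperature: float = 300.0,
) -> ToyLoopModel:
    """Construct the toy loop model (deterministic for a given seed).

    The seed reproducibly jitters torsion-well depths by +-5%, emulating the
    residue-to-residue heterogeneity of a real loop without changing the
    designed well positions.  The helical contact links the donor H of
    residue ``contact_residues[1]`` to the acceptor O of residue
    ``contact_residues[0]`` (defaults to an i, i+4 pair bracketing the chain
    middle).
    """
    if n_residues < 5:
        raise ValueError("need at least 5 residues")
    pro = set(int(p) for p in proline_like)
    if contact_residues is None:
        a = max(1, n_residues // 2 - 2)
        contact_residues = (a, a + 4)
    acc_res, don_res = contact_residues
    if don_res - acc_res != 4:
        raise ValueError("contact must be an i, i+4 pair")
    if don_res > n_residues or don_res in pro:
        raise ValueError("contact donor residue must exist and carry an H")

    rng = np.random.default_rng(seed)
    atoms = _site_order(n_residues, pro)
    conf0 = Conformation(atoms, np.zeros((len(atoms), 3)))
    ix = conf0.index_of

    bonds: list[tuple[int, int, float, float]] = []
    angles: list[tuple[int, int, int, float, float]] = []
    torsions: list[tuple[tuple[int, int, int, int], list[tuple[float, float, float]]]] = []
    torsion_map: dict[tuple[int, str], int] = {}
    designed_base: dict[tuple[int, str], float] = {}

    def add_torsion(idx4, wells, key=None):
        if key is not None:
            torsion_map[key] = len(torsions)
        torsions.append((idx4, wells))

    def jitter() -> float:
        return 1.0 + 0.05 * rng.uniform(-1.0, 1.0)

    stiff = [(20.0, 2.0, 180.0)]  # single planar well

    for r in range(1, n_residues + 1):
        n_, ca, c, o = ix(r, "N"), ix(r, "CA"), ix(r, "C"), ix(r, "O")
        bonds.append((n_, ca, _BONDS["N-CA"], _BOND_K["N-CA"]))
        bonds.append((ca, c, _BONDS["CA-C"], _BOND_K["CA-C"]))
        bonds.append((c, o, _BONDS["C-O"], _BOND_K["C-O"]))
        angles.append((n_, ca, c, _ANGLES["N-CA-C"], _ANGLE_K))
        angles.append((ca, c, o, _ANGLES["CA-C-O"], _ANGLE_K))
        if r not in pro:
            h = ix(r, "H")
            bonds.append((n_, h, _BONDS["N-H"], _BOND_K["N-H"]))
            if r == 1:
                angles.append((ca, n_, h, _ANGLES["CA-N-H"], _ANGLE_K))
                add_torsion((c, ca, n_, h), stiff)
            else:
                cp = ix(r - 1, "C")
                angles.append((cp, n_, h, _ANGLES["C-N-H"], _ANGLE_K))
                add_torsion((ix(r - 1, "O"), cp, n_, h), stiff)
        if r < n_residues:
            nn = ix(r + 1, "N")
            bonds.append((c, nn, _BONDS["C-N"], _BOND_K["C-N"]))
            angles.append((ca, c, nn, _ANGLES["CA-C-N"], _ANGLE_K))
            angles.append((c, nn, ix(r + 1, "CA"), _ANGLES["C-N-CA"], _ANGLE_K))
            # omega: trans peptide plane
            add_torsion((ca, c, nn, ix(r + 1, "CA")), [(15.0, 2.0, 180.0)])
            # O planarity: anti to the next N about the CA-C axis
            add_torsion((nn, ca, c, o), stiff)
            # designed psi with two wells 180 degrees apart
            a_amp = 8.0 * jitter()
            add_torsion(
                (n_, ca, c, nn),
                [(a_amp, 2.0, PSI_WELLS[0]), (a_amp, 2.0, PSI_WELLS[1])],
                key=(r, "psi"),
            )
            designed_base[(r, "psi")] = PSI_WELLS[0]
        else:
            # last residue: psi-like torsion carried by the carbonyl O
            a_amp = 8.0 * jitter()
            add_torsion(
                (n_, ca, c, o),
                [
                    (a_amp, 2.0, PSI_WELLS[0] + 180.0),
                    (a_amp, 2.0, PSI_WELLS[1] + 180.0),
                ],
                key=(r, "psi"),
            )
            designed_base[(r, "psi")] = PSI_WELLS[0]
        if r > 1:
            # designed phi with two wells 180 degrees apart
            a_amp = 8.0 * jitter()
            add_torsion(
                (ix(r - 1, "C"), n_, ca, c),
                [(a_amp, 2.0, PHI_WELLS[0]), (a_amp, 2.0, PHI_WELLS[1])],
                key=(r, "phi"),
            )
            designed_base[(r, "phi")] = PHI_WELLS[0]

    # repulsion pairs: heavy atoms separated by >2 bonds in the graph
    heavy = [i for i, a in enumerate(atoms) if a.atom_name != "H"]
    adj: dict[int, set[int]] = {i: set() for i in range(len(atoms))}
    for i, j, _, _ in bonds:
        adj[i].add(j)
        adj[j].add(i)

    def graph_dist_le(i: int, j: int, cutoff: int) -> bool:
        frontier = {i}
        seen = {i}
        for _ in range(cutoff):
            nxt = set()
            for u in frontier:
                nxt |= adj[u]
            if j in nxt:
                return True
            nxt -= seen
            seen |= nxt
            frontier = nxt
        return False

    rep_pairs = [
        (i, j)
        for ii, i in enumerate(heavy)
        for j in heavy[ii + 1 :]
        if not graph_dist_le(i, j, 2)
    ]

    nt = len(torsions)
    t_idx = np.array([t[0] for t in torsions], dtype=int)
    t_amp = np.zeros((nt, 3))
    t_kap = np.zeros((nt, 3))
    t_chi = np.zeros((nt, 3))
    for row, (_, wells) in enumerate(torsions):
        for w, (amp, kap, chi0) in enumerate(wells):
            t_amp[row, w] = amp
            t_kap[row, w] = kap
            t_chi[row, w] = np.radians(chi0)

    model = ToyLoopModel(
        atoms=atoms,
        masses_amu=np.array([_MASS[a.atom_name] for a in atoms]),
        bond_idx=np.array([(b[0], b[1]) for b in bonds], dtype=int),
        bond_r0=np.array([b[2] for b in bonds]),
        bond_k=np.array([b[3] for b in bonds]),
        angle_idx=np.array([(a[0], a[1], a[2]) for a in angles], dtype=int),
        angle_theta0=np.radians([a[3] for a in angles]),
        angle_k=np.array([a[4] for a in angles]),
        torsion_idx=t_idx,
        torsion_amp=t_amp,
        torsion_kappa=t_kap,
        torsion_chi0=t_chi,
        rep_idx=np.array(rep_pairs, dtype=int).reshape(-1, 2),
        rep_eps=5.0,
        rep_rc=2.5,
        hbond_donor=ix(don_res, "H"),
        hbond_acceptor=ix(acc_res, "O"),
        hbond_r0=2.0,
        hbond_depth=6.0,
        hbond_sigma=0.4,
        hbond_enabled=True,
        temperature=temperature,
        n_residues=n_residues,
        proline_like=tuple(sorted(pro)),
        contact_residues=contact_residues,
        torsion_map=torsion_map,
        designed_base=designed_base,
    )
    return model


@dataclass
class EndpointPair:
    """Minimized wrapped (state_a) and unwrapped (state_b) conformations."""

    state_a: Conformation
    state_b: Conformation
    flipped_torsions: list[tuple[int, str, float]]


def _minimize(model: ToyLoopModel, coords: np.ndarray, gtol: float = 1e-3) -> np.ndarray:
    x0 = np.asarray(coords, float).ravel()

    def fun(xf):
        e, f = model.energy_forces(xf.reshape(-1, 3))
        return e, -f.ravel()

    res = minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        options=dict(maxiter=5000, maxfun=20000, ftol=1e-14, gtol=1e-8),
    )
    x = res.x.reshape(-1, 3)
    gnorm = float(np.abs(model.gradient(x)).max())
    if gnorm > gtol:
        raise MinimizationError(
            f"minimization stalled: max |gradient| = {gnorm:.2e} kcal/mol/A "
            f"(> {gtol}); scipy status {res.status}: {res.message}"
        )
    return x


def generate_endpoint_conformations(
    model: ToyLoopModel,
    flips: list[tuple[int, str, float]],
) -> EndpointPair:
    """Minimized endpoint pair with the listed torsions rotated by delta.

    state_a is the wrapped (helix-like) state minimized with the contact
    engaged; state_b starts from the flipped torsions with the contact
    released, is minimized, and then re-minimized with the contact back on.
    Both returned states are local minima of the full model energy.
    """
    n = model.n_residues
    for res, kind, delta in flips:
        if kind not in ("phi", "psi"):
            raise ValueError(f"unknown torsion kind {kind!r}")
        if (res, kind) not in model.torsion_map:
            raise ValueError(f"torsion {kind} of residue {res} is not defined")
        if abs(delta) > 180.0:
            raise ValueError("|delta| must be <= 180 degrees")

    phi_a = np.full(n, PHI_WELLS[0])
    psi_a = np.full(n, PSI_WELLS[0])
    conf_a0 = model.build_conformation(phi_a, psi_a)
    model.hbond_enabled = True
    xa = _minimize(model, conf_a0.coords)

    phi_b = phi_a.copy()
    psi_b = psi_a.copy()
    for res, kind, delta in flips:
        if kind == "phi":
            phi_b[res - 1] += delta
        else:
            psi_b[res - 1] += delta
    conf_b0 = model.build_conformation(phi_b, psi_b)
    model.hbond_enabled = False
    try:
        xb = _minimize(model, conf_b0.coords)
    finally:
        model.hbond_enabled = True
    xb = _minimize(model, xb)  # must remain a minimum with the contact on

    # place both states in a common lab frame (rigid moves cost no energy)
    from .geometry import align_to

    xb = align_to(xb, xa)

    for res, kind, delta in flips:
        va = model.designed_torsion_value(xa, res, kind)
        vb = model.designed_torsion_value(xb, res, kind)
        d = abs(vb - va) % 360.0
        d = min(d, 360.0 - d)
        want = min(abs(delta) % 360.0, 360.0 - abs(delta) % 360.0)
        if abs(d - want) > 10.0:
            raise MinimizationError(
                f"designed flip not realized: {kind} of residue {res} differs "
                f"by {d:.1f} deg, wanted {want:.1f} +- 10"
            )
    return EndpointPair(
        model.to_conformation(xa), model.to_conformation(xb), list(flips)
    )
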