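"""Internal-coordinate peptide model: torsions + rigid placement -> Cartesians.

The flexible ligand is represented in internal coordinates (backbone phi/psi/
omega plus side-chain chi torsions) with a rigid-body placement (rotation
vector + translation) carrying it into the receptor frame.  Coordinates are
rebuilt deterministically with the NeRF (natural extension reference frame)
chain construction over a united-atom topology: backbone N/CA/C/O plus CB and
united side-chain pseudo-atoms (branched termini collapsed, aromatic rings as
a single centroid pseudo-atom).

Rebuilding is exact and involutive on ideal-geometry structures: measuring
torsions from built coordinates and rebuilding reproduces them to well below
1e-6 A, which is the contract the samplers rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .forcefield import (
    AtomSet,
    ForceFieldParams,
    atom_type,
    default_params,
    one_to_three,
    sidechain_rows,
    three_to_one,
)

# ideal backbone geometry (A, degrees)
B_N_CA = 1.458
B_CA_C = 1.525
B_C_N = 1.329
B_C_O = 1.231
A_N_CA_C = 111.2
A_CA_C_N = 116.2
A_C_N_CA = 121.7
A_CA_C_O = 120.8
A_N_CA_CB = 110.5
CB_IMPROPER = -122.6  # dihedral C-N-CA-CB, degrees (L-amino acids)

# documented extended-conformation backbone (antiparallel-beta values)
EXTENDED_PHI = -139.0
EXTENDED_PSI = 135.0
OMEGA_TRANS = 180.0


def _unit(v):
    n = math.sqrt(v[0] * v[0] + v[1] * v[1] + v[2] * v[2])
    return (v[0] / n, v[1] / n, v[2] / n)


def _place(a, b, c, blen, bang_deg, tors_deg):
    """NeRF: position of atom D bonded to c, given refs a-b-c, internal coords."""
    ang = math.radians(bang_deg)
    tor = math.radians(tors_deg)
    bc = _unit((c[0] - b[0], c[1] - b[1], c[2] - b[2]))
    ab = (b[0] - a[0], b[1] - a[1], b[2] - a[2])
    nx = ab[1] * bc[2] - ab[2] * bc[1]
    ny = ab[2] * bc[0] - ab[0] * bc[2]
    nz = ab[0] * bc[1] - ab[1] * bc[0]
    n = _unit((nx, ny, nz))
    mx = n[1] * bc[2] - n[2] * bc[1]
    my = n[2] * bc[0] - n[0] * bc[2]
    mz = n[0] * bc[1] - n[1] * bc[0]
    d1 = -blen * math.cos(ang)
    d2 = blen * math.sin(ang) * math.cos(tor)
    d3 = blen * math.sin(ang) * math.sin(tor)
    return (
        c[0] + d1 * bc[0] + d2 * mx + d3 * n[0],
        c[1] + d1 * bc[1] + d2 * my + d3 * n[1],
        c[2] + d1 * bc[2] + d2 * mz + d3 * n[2],
    )


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 else ang


def wrap_angle(deg: float) -> float:
    """Map an angle in degrees to (-180, 180]."""
    a = (deg + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


@dataclass
class _AtomRecipe:
    name: str
    resi: int  # 0-based residue index
    parent: int  # atom index of bonded parent (-1 for backbone anchors)
    blen: float
    bang: float
    tors_kind: str  # phi|psi|omega|o|cb|chi|fix
    tors_param: float  # chi slot index, or fixed offset in degrees
    ref_a: int
    ref_b: int


class PeptideTopology:
    """Static per-sequence structure: atom recipes, typing, exclusions."""

    def __init__(self, resnames: list[str], params: Optional[ForceFieldParams] = None):
        params = params or default_params()
        self.params = params
        self.resnames = [r.upper() for r in resnames]
        self.sequence = "".join(three_to_one(r) for r in self.resnames)
        self.n_res = len(resnames)

        self.recipes: list[_AtomRecipe] = []
        self.atom_names: list[str] = []
        self.atom_resi: list[int] = []
        # torsion vector layout: per residue [phi, psi, omega, chi...]
        self.slot: dict[tuple[int, str], int] = {}
        self.n_chi: list[int] = []
        self.sc_terminal: list[int] = []  # last side-chain atom per residue (-1)
        bonds: list[tuple[int, int]] = []

        nslot = 0
        for i in range(self.n_res):
            for key in ("phi", "psi", "omega"):
                self.slot[(i, key)] = nslot
                nslot += 1
            rows = sidechain_rows(params, self.resnames[i])
            kchi = 0
            for _, r in rows.iterrows():
                t = str(r["tors"])
                if t.startswith("chi"):
                    kchi = max(kchi, int(t[3:]))
            for k in range(kchi):
                self.slot[(i, f"chi{k + 1}")] = nslot
                nslot += 1
            self.n_chi.append(kchi)
        self.n_torsions = nslot

        def add(name, resi, parent, blen, bang, kind, parm, ra, rb):
            idx = len(self.recipes)
            self.recipes.append(_AtomRecipe(name, resi, parent, blen, bang, kind, parm, ra, rb))
            self.atom_names.append(name)
            self.atom_resi.append(resi)
            if parent >= 0:
                bonds.append((parent, idx))
            return idx

        atom_of: dict[tuple[int, str], int] = {}
        for i, rn in enumerate(self.resnames):
            if i == 0:
                iN = add("N", i, -1, 0, 0, "anchor", 0, -1, -1)
                iCA = add("CA", i, iN, B_N_CA, 0, "anchor", 0, -1, -1)
                iC = add("C", i, iCA, B_CA_C, A_N_CA_C, "anchor", 0, -1, -1)
            else:
                pN, pCA, pC = atom_of[(i - 1, "N")], atom_of[(i - 1, "CA")], atom_of[(i - 1, "C")]
                iN = add("N", i, pC, B_C_N, A_CA_C_N, "psi_prev", 0, pN, pCA)
                iCA = add("CA", i, iN, B_N_CA, A_C_N_CA, "omega", 0, pCA, pC)
                iC = add("C", i, iCA, B_CA_C, A_N_CA_C, "phi", 0, pC, iN)
            iO = add("O", i, iC, B_C_O, A_CA_C_O, "o", 0, iN, iCA)
            atom_of[(i, "N")], atom_of[(i, "CA")] = iN, iCA
            atom_of[(i, "C")], atom_of[(i, "O")] = iC, iO

            rows = sidechain_rows(params, rn)
            sc_last = -1
            for _, r in rows.iterrows():
                t, off = str(r["tors"]), float(r["offset"])
                pname = str(r["parent"])
                if t == "cb":
                    idx = add(str(r["atom"]), i, iCA, float(r["blen"]), float(r["bang"]),
                              "fixref", CB_IMPROPER, iC, iN)
                else:
                    p = atom_of[(i, pname)]
                    b = self.recipes[p].parent
                    a = self.recipes[b].parent if b >= 0 else -1
                    if t.startswith("chi"):
                        idx = add(str(r["atom"]), i, p, float(r["blen"]), float(r["bang"]),
                                  "chi", float(int(t[3:])), a, b)
                        self._chi_offsets = getattr(self, "_chi_offsets", {})
                        self._chi_offsets[idx] = off
                    else:  # fix: rigid offset from the parent frame
                        idx = add(str(r["atom"]), i, p, float(r["blen"]), float(r["bang"]),
                                  "fix", off, a, b)
                atom_of[(i, str(r["atom"]))] = idx
                sc_last = idx
            self.sc_terminal.append(sc_last)

        self.n_atoms = len(self.recipes)
        self._chi_offsets = getattr(self, "_chi_offsets", {})

        # typing arrays
        cls = np.empty(self.n_atoms, int)
        charge = np.empty(self.n_atoms)
        don = np.zeros(self.n_atoms, bool)
        acc = np.zeros(self.n_atoms, bool)
        bb = np.zeros(self.n_atoms, bool)
        for j, rec in enumerate(self.recipes):
            cid, q, d, a = atom_type(params, self.resnames[rec.resi], rec.name)
            cls[j], charge[j], don[j], acc[j] = cid, q, d, a
            bb[j] = rec.name in ("N", "CA", "C", "O")
        # free-peptide termini: N-terminal ammonium, C-terminal carboxylate
        for j, rec in enumerate(self.recipes):
            if rec.resi == 0 and rec.name == "N":
                cls[j], charge[j], don[j] = params.class_id("N_POS"), 1.0, True
            if rec.resi == self.n_res - 1 and rec.name == "O":
                cls[j], charge[j], acc[j] = params.class_id("O_NEG"), -1.0, True
        self.cls, self.charge = cls, charge
        self.is_donor, self.is_acceptor, self.is_backbone = don, acc, bb
        self.ca_indices = np.array(
            [j for j, r in enumerate(self.recipes) if r.name == "CA"], int)

        # nonbonded exclusions: graph distance <= 3 (1-2, 1-3, 1-4)
        adj = [[] for _ in range(self.n_atoms)]
        for p, q in bonds:
            adj[p].append(q)
            adj[q].append(p)
        excl = np.eye(self.n_atoms, dtype=bool)
        for s in range(self.n_atoms):
            dist = {s: 0}
            frontier = [s]
            for _ in range(3):
                nxt = []
                for u in frontier:
                    for v in adj[u]:
                        if v not in dist:
                            dist[v] = dist[u] + 1
                            nxt.append(v)
                frontier = nxt
            for v in dist:
                excl[s, v] = True
        self.exclusions = excl

    def chi_slots(self, resi: int) -> list[int]:
        return [self.slot[(resi, f"chi{k + 1}")] for k in range(self.n_chi[resi])]

    def backbone_slots(self, resi: int) -> list[int]:
        out = []
        if resi > 0:
            out.append(self.slot[(resi, "phi")])
        if resi < self.n_res - 1:
            out.append(self.slot[(resi, "psi")])
        return out

    def all_chi_slots(self) -> list[int]:
        return [s for (i, k), s in sorted(self.slot.items(), key=lambda kv: kv[1])
                if k.startswith("chi")]

    def all_backbone_slots(self) -> list[int]:
        out = []
        for i in range(self.n_res):
            out.extend(self.backbone_slots(i))
        return out

    # --- coordinate construction ------------------------------------------
    def build_canonical(self, torsions: np.ndarray) -> np.ndarray:
        """Cartesian coordinates in the canonical frame (first N at origin)."""
        t = torsions
        coords: list[tuple[float, float, float]] = [None] * self.n_atoms  # type: ignore
        for j, rec in enumerate(self.recipes):
            if rec.tors_kind == "anchor":
                if rec.name == "N":
                    coords[j] = (0.0, 0.0, 0.0)
                elif rec.name == "CA":
                    coords[j] = (B_N_CA, 0.0, 0.0)
                else:  # first C, in the xy-plane with positive y
                    ang = math.radians(A_N_CA_C)
                    coords[j] = (B_N_CA - B_CA_C * math.cos(ang),
                                 B_CA_C * math.sin(ang), 0.0)
                continue
            if rec.tors_kind == "psi_prev":
                tor = t[self.slot[(rec.resi - 1, "psi")]]
            elif rec.tors_kind == "omega":
                tor = t[self.slot[(rec.resi, "omega")]]
            elif rec.tors_kind == "phi":
                tor = t[self.slot[(rec.resi, "phi")]]
            elif rec.tors_kind == "o":
                tor = t[self.slot[(rec.resi, "psi")]] + 180.0
            elif rec.tors_kind == "fixref":  # CB improper off C-N-CA
                tor = rec.tors_param
            elif rec.tors_kind == "chi":
                k = int(rec.tors_param)
                tor = t[self.slot[(rec.resi, f"chi{k}")]] + self._chi_offsets.get(j, 0.0)
            else:  # fix
                a, b = coords[rec.ref_a], coords[rec.ref_b]
                c = coords[rec.parent]
                tor = rec.tors_param
                coords[j] = _place(a, b, c, rec.blen, rec.bang, tor)
                continue
            a, b = coords[rec.ref_a], coords[rec.ref_b]
            c = coords[rec.parent]
            coords[j] = _place(a, b, c, rec.blen, rec.bang, tor)
        return np.asarray(coords, float)


@dataclass
class PeptideConformation:
    """A flexible-ligand state: torsions + rigid placement (+ cached coords).

    ``placement`` is a 6-vector: rotation vector (radians, 3) followed by a
    translation (A, 3) mapping canonical-frame coordinates into the receptor
    frame.  ``coords`` is the derived Cartesian array; when a conformation is
    created directly from crystal coordinates, ``coords`` holds them verbatim
    and ``ideal_geometry`` is False.
    """

    topology: PeptideTopology
    torsions: np.ndarray
    placement: np.ndarray
    coords: np.ndarray = field(default=None)  # type: ignore
    is_analogue: np.ndarray = field(default=None)  # type: ignore
    original_resnames: list[str] = field(default_factory=list)
    ideal_geometry: bool = True

    def __post_init__(self) -> None:
        if self.coords is None:
            self.coords = self.rebuild()
        if self.is_analogue is None:
            self.is_analogue = np.zeros(self.topology.n_res, bool)
        if not self.original_resnames:
            self.original_resnames = list(self.topology.resnames)

    @property
    def sequence(self) -> str:
        return self.topology.sequence

    def __len__(self) -> int:
        return self.topology.n_res

    def rebuild(self) -> np.ndarray:
        """Deterministic torsion+placement -> Cartesian reconstruction."""
        canon = self.topology.build_canonical(self.torsions)
        rot = Rotation.from_rotvec(self.placement[:3])
        return rot.apply(canon) + self.placement[3:]

    def with_updates(self, torsions: Optional[np.ndarray] = None,
                     placement: Optional[np.ndarray] = None) -> "PeptideConformation":
        new = replace(
            self,
            torsions=self.torsions.copy() if torsions is None else np.asarray(torsions, float),
            placement=self.placement.copy() if placement is None else np.asarray(placement, float),
            coords=None,
            ideal_geometry=True,
        )
        return new

    def transformed(self, rot: Rotation, shift: np.ndarray) -> "PeptideConformation":
        """Apply an extra rigid motion on top of the current placement."""
        r0 = Rotation.from_rotvec(self.placement[:3])
        r = rot * r0
        t = rot.apply(self.placement[3:]) + shift
        return self.with_updates(placement=np.concatenate([r.as_rotvec(), t]))

    def ca_coords(self) -> np.ndarray:
        return self.coords[self.topology.ca_indices]

    def atom_set(self) -> AtomSet:
        top = self.topology
        return AtomSet(
            coords=self.coords.copy(),
            cls=top.cls.copy(),
            charge=top.charge.copy(),
            is_donor=top.is_donor.copy(),
            is_acceptor=top.is_acceptor.copy(),
            names=list(top.atom_names),
            resnames=[self.original_resnames[i] for i in top.atom_resi],
            resindex=np.asarray(top.atom_resi, int) + 1,
            chains=["P"] * top.n_atoms,
            is_backbone=top.is_backbone.copy(),
        )


def from_sequence(seq: str, params: Optional[ForceFieldParams] = None,
                  phi: float = EXTENDED_PHI, psi: float = EXTENDED_PSI) -> PeptideConformation:
    """Ideal-geometry conformation from a one-letter sequence (default extended)."""
    resnames = [one_to_three(ch) for ch in seq]
    top = PeptideTopology(resnames, params)
    t = np.zeros(top.n_torsions)
    for i in range(top.n_res):
        t[top.slot[(i, "phi")]] = -75.0 if resnames[i] == "PRO" else phi
        t[top.slot[(i, "psi")]] = psi
        t[top.slot[(i, "omega")]] = OMEGA_TRANS
        for s in top.chi_slots(i):
            t[s] = 180.0
    return PeptideConformation(top, t, np.zeros(6))


def measure_torsions(top: PeptideTopology, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Extract (torsions, placement) from Cartesian coordinates.

    Exact inverse of :meth:`PeptideConformation.rebuild` when the coordinates
    have ideal geometry; an approximation (ideal bond lengths/angles assumed)
    otherwise.
    """
    t = np.zeros(top.n_torsions)
    idx = {}
    for j, rec in enumerate(top.recipes):
        idx[(rec.resi, rec.name)] = j
    for i in range(top.n_res):
        N, CA, C = idx[(i, "N")], idx[(i, "CA")], idx[(i, "C")]
        if i > 0:
            pC, pCA = idx[(i - 1, "C")], idx[(i - 1, "CA")]
            t[top.slot[(i, "phi")]] = dihedral(coords[pC], coords[N], coords[CA], coords[C])
            t[top.slot[(i, "omega")]] = dihedral(coords[pCA], coords[pC], coords[N], coords[CA])
        else:
            t[top.slot[(i, "phi")]] = EXTENDED_PHI
            t[top.slot[(i, "omega")]] = OMEGA_TRANS
        if i < top.n_res - 1:
            nN = idx[(i + 1, "N")]
            t[top.slot[(i, "psi")]] = dihedral(coords[N], coords[CA], coords[C], coords[nN])
        else:
            O = idx[(i, "O")]
            t[top.slot[(i, "psi")]] = wrap_angle(
                dihedral(coords[N], coords[CA], coords[C], coords[O]) - 180.0)
    for j, rec in enumerate(top.recipes):
        if rec.tors_kind == "chi":
            k = int(rec.tors_param)
            off = top._chi_offsets.get(j, 0.0)
            if off == 0.0:  # primary chain atom defines the chi
                a, b = coords[rec.ref_a], coords[rec.ref_b]
                c, d = coords[rec.parent], coords[j]
                t[top.slot[(rec.resi, f"chi{k}")]] = dihedral(a, b, c, d)
    # placement from the first residue's N-CA-C frame
    N, CA, C = coords[idx[(0, "N")]], coords[idx[(0, "CA")]], coords[idx[(0, "C")]]
    e1 = (CA - N) / np.linalg.norm(CA - N)
    v = C - CA
    e2 = v - np.dot(v, e1) * e1
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    R = np.column_stack([e1, e2, e3])
    placement = np.concatenate([Rotation.from_matrix(R).as_rotvec(), N])
    return t, placement
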