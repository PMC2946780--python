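"""PDB structure I/O and peptide-MHC complex modelling.

Reads PDB files (via gemmi), classifies chains into receptor / peptide /
hetero groups, and converts between explicit structures and the
internal-coordinate ligand representation.  The peptide chain is
auto-detected as the shortest polymer chain of 6-25 residues (the length
range bound peptides occupy across both MHC classes), overridable by chain
ID.  Waters are always discarded; other hetero groups (e.g. a formic acid
molecule sitting in the groove) are kept as ``hetero_groups`` and join the
receptor side only on request.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .forcefield import (
    ANALOGUE_PARENTS,
    AtomSet,
    ForceFieldParams,
    atom_type,
    default_params,
    three_to_one,
    _THREE_TO_ONE,
)
from .peptide import (
    EXTENDED_PHI,
    EXTENDED_PSI,
    OMEGA_TRANS,
    PeptideConformation,
    PeptideTopology,
    measure_torsions,
)

PEPTIDE_MIN_LEN = 6
PEPTIDE_MAX_LEN = 25

# united-atom names mapped back to the full-atom PDB names they stand for;
# the united position is the centroid of the listed source atoms
_UNITED_SOURCES = {
    ("LEU", "CD"): ("CD1", "CD2"),
    ("VAL", "CG"): ("CG1", "CG2"),
    ("ILE", "CG"): ("CG1", "CG2"),
    ("ILE", "CD"): ("CD1", "CD"),
    ("ASP", "OD"): ("OD1", "OD2"),
    ("GLU", "OE"): ("OE1", "OE2"),
    ("ARG", "NH"): ("NH1", "NH2"),
    ("PHE", "RC"): ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    ("TYR", "RC"): ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    ("TRP", "RC"): ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    ("HIS", "RC"): ("CG", "ND1", "CD2", "CE1", "NE2"),
    ("HIS", "RN"): ("ND1", "NE2"),
    ("TYR", "OH"): ("OH",),
    ("TRP", "NE1"): ("NE1",),
}


@dataclass
class Atom:
    """A single (united) atom record."""

    name: str
    element: str
    pos: np.ndarray
    occupancy: float = 1.0
    is_hetero: bool = False
    residue_index: int = 1

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, float)
        if not np.isfinite(self.pos).all():
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    """Residue with analogue bookkeeping (chemical mimics map to a parent)."""

    code: str
    atoms: list[Atom] = field(default_factory=list)
    is_analogue: bool = False
    parent_code: str = ""

    def __post_init__(self) -> None:
        self.code = self.code.upper()
        if not self.parent_code:
            self.parent_code = (ANALOGUE_PARENTS.get(self.code, "ALA")
                                if self.is_analogue else self.code)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    domain_label: str = ""

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class PMHCComplex:
    """A parsed peptide-MHC structure: receptor, peptide and hetero groups."""

    receptor_chains: list[Chain]
    peptide: Chain
    hetero_groups: list[Chain] = field(default_factory=list)
    mhc_class: str = "I"
    allele: str = ""
    resolution: float | None = None

    def __post_init__(self) -> None:
        if len(self.peptide) < 1:
            raise ValueError("peptide chain is empty")
        if self.mhc_class not in ("I", "II"):
            raise ValueError(f"mhc_class must be I or II, got {self.mhc_class!r}")

    @property
    def peptide_sequence(self) -> str:
        return "".join(three_to_one(r.code) for r in self.peptide.residues)

    def total_atom_count(self) -> int:
        n = sum(len(r.atoms) for ch in self.receptor_chains for r in ch.residues)
        n += sum(len(r.atoms) for r in self.peptide.residues)
        n += sum(len(r.atoms) for g in self.hetero_groups for r in g.residues)
        return n


def _chain_atom_set(chains: list[Chain], params: ForceFieldParams) -> AtomSet:
    coords, cls, charge, don, acc = [], [], [], [], []
    names, resnames, resindex, chain_ids, bb = [], [], [], [], []
    for ch in chains:
        for ri, res in enumerate(ch.residues, start=1):
            code = res.parent_code if res.is_analogue else res.code
            for a in res.atoms:
                cid, q, d, ac = atom_type(params, code, a.name)
                coords.append(a.pos)
                cls.append(cid)
                charge.append(q)
                don.append(d)
                acc.append(ac)
                names.append(a.name)
                resnames.append(res.code)
                resindex.append(ri)
                chain_ids.append(ch.chain_id)
                bb.append(a.name in ("N", "CA", "C", "O"))
    return AtomSet(
        coords=np.asarray(coords, float).reshape(-1, 3),
        cls=np.asarray(cls, int),
        charge=np.asarray(charge, float),
        is_donor=np.asarray(don, bool),
        is_acceptor=np.asarray(acc, bool),
        names=names, resnames=resnames,
        resindex=np.asarray(resindex, int),
        chains=chain_ids,
        is_backbone=np.asarray(bb, bool),
    )


def receptor_atom_set(c: PMHCComplex, include_hetero: bool = False,
                      params: ForceFieldParams | None = None) -> AtomSet:
    params = params or default_params()
    chains = list(c.receptor_chains) + (list(c.hetero_groups) if include_hetero else [])
    return _chain_atom_set(chains, params)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _is_standard_or_analogue(name: str) -> bool:
    return name.upper() in _THREE_TO_ONE or name.upper() in ANALOGUE_PARENTS


def read_pdb(path, peptide_chain: str | None = None,
             mhc_class: str | None = None) -> PMHCComplex:
    """Parse a PDB file into a classified peptide-MHC complex.

    Alternate locations resolve to the highest-occupancy conformer; waters
    are dropped; non-water hetero compounds become ``hetero_groups``.  The
    peptide is the shortest polymer chain with 6-25 residues unless
    ``peptide_chain`` names one explicitly.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"malformed PDB file {path.name}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"malformed PDB file {path.name}: no models")
    model = st[0]

    polymer: list[Chain] = []
    hetero: list[Chain] = []
    for gch in model:
        poly_res: list[Residue] = []
        het_res: list[Residue] = []
        for ri, gres in enumerate(gch):
            if gres.is_water():
                continue
            # altloc resolution: highest occupancy per atom name
            best: dict[str, gemmi.Atom] = {}
            for ga in gres:
                prev = best.get(ga.name)
                if prev is None or ga.occ > prev.occ:
                    best[ga.name] = ga
            atoms = [
                Atom(name=ga.name, element=ga.element.name,
                     pos=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                     occupancy=min(max(ga.occ, 0.0), 1.0),
                     is_hetero=gres.het_flag == "H",
                     residue_index=len(poly_res) + 1)
                for ga in best.values()
            ]
            if _is_standard_or_analogue(gres.name):
                code = gres.name.upper()
                poly_res.append(Residue(
                    code=code, atoms=atoms,
                    is_analogue=code not in _THREE_TO_ONE))
            else:
                for a in atoms:
                    a.residue_index = len(het_res) + 1
                het_res.append(Residue(code=gres.name.upper(), atoms=atoms))
        if poly_res:
            polymer.append(Chain(gch.name, poly_res))
        if het_res:
            hetero.append(Chain(gch.name, het_res))

    if len(polymer) < 2:
        raise ValueError(
            f"classification error in {path.name}: need at least a receptor "
            f"and a peptide polymer chain, found {len(polymer)}")

    if peptide_chain is not None:
        match = [ch for ch in polymer if ch.chain_id == peptide_chain]
        if not match:
            raise ValueError(f"classification error: no chain {peptide_chain!r}")
        pep = match[0]
    else:
        candidates = [ch for ch in polymer
                      if PEPTIDE_MIN_LEN <= len(ch) <= PEPTIDE_MAX_LEN]
        if not candidates:
            raise ValueError(
                f"classification error in {path.name}: no polymer chain of "
                f"{PEPTIDE_MIN_LEN}-{PEPTIDE_MAX_LEN} residues to use as peptide")
        pep = min(candidates, key=lambda ch: (len(ch), ch.chain_id))
    receptors = [ch for ch in polymer if ch is not pep]

    cls = mhc_class or ("I" if len(pep) <= 11 else "II")
    _label_groove_domains(receptors, cls)
    reso = float(st.resolution) if st.resolution and st.resolution > 0 else None
    return PMHCComplex(receptor_chains=receptors, peptide=pep,
                       hetero_groups=hetero, mhc_class=cls,
                       allele=st.name or "", resolution=reso)


def _label_groove_domains(receptors: list[Chain], mhc_class: str) -> None:
    ordered = sorted(receptors, key=len, reverse=True)
    if mhc_class == "I" and ordered:
        ordered[0].domain_label = "G-ALPHA1/G-ALPHA2"
    elif mhc_class == "II" and len(ordered) >= 2:
        ordered[0].domain_label = "alpha1"
        ordered[1].domain_label = "beta1"


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _pdb_atom_line(serial: int, name: str, resname: str, chain: str,
                   resseq: int, pos, occ: float = 1.0, het: bool = False,
                   element: str = "") -> str:
    record = "HETATM" if het else "ATOM  "
    nm = f" {name:<3s}" if len(name) < 4 else name[:4]
    el = (element or name[0]).rjust(2)[:2]
    return (f"{record}{serial:5d} {nm:<4s} {resname:<3s} {chain:1s}{resseq:4d}    "
            f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{occ:6.2f}{0.0:6.2f}"
            f"          {el}\n")


def write_pdb(c: PMHCComplex, path) -> None:
    """Write a complex back out as a standard PDB file."""
    lines, serial = [], 1
    for ch in list(c.receptor_chains) + [c.peptide]:
        for ri, res in enumerate(ch.residues, start=1):
            for a in res.atoms:
                lines.append(_pdb_atom_line(serial, a.name, res.code,
                                            ch.chain_id, ri, a.pos, a.occupancy))
                serial += 1
        lines.append(f"TER   {serial:5d}\n")
        serial += 1
    for g in c.hetero_groups:
        for ri, res in enumerate(g.residues, start=1):
            for a in res.atoms:
                lines.append(_pdb_atom_line(serial, a.name, res.code,
                                            g.chain_id, ri, a.pos, a.occupancy,
                                            het=True))
                serial += 1
    lines.append("END\n")
    Path(path).write_text("".join(lines))


def write_poses(poses: list[PeptideConformation], path,
                original_resnames: bool = True) -> None:
    """Write docked ligand poses as a multi-MODEL PDB file."""
    lines = []
    for m, pose in enumerate(poses, start=1):
        lines.append(f"MODEL     {m:4d}\n")
        top = pose.topology
        serial = 1
        for j in range(top.n_atoms):
            resi = top.atom_resi[j]
            rn = (pose.original_resnames[resi] if original_resnames
                  else top.resnames[resi])
            lines.append(_pdb_atom_line(serial, top.atom_names[j], rn, "P",
                                        resi + 1, pose.coords[j]))
            serial += 1
        lines.append("ENDMDL\n")
    lines.append("END\n")
    Path(path).write_text("".join(lines))


# ---------------------------------------------------------------------------
# ligand preparation
# ---------------------------------------------------------------------------

def peptide_conformation(c: PMHCComplex,
                         params: ForceFieldParams | None = None) -> PeptideConformation:
    """Internal-coordinate view of the bound peptide, coordinates verbatim.

    United pseudo-atom positions are taken directly when the source names
    match the united topology (our own files) and as centroids of the
    full-atom groups they stand for otherwise (crystal structures).
    """
    params = params or default_params()
    resnames = [r.parent_code if r.is_analogue else r.code
                for r in c.peptide.residues]
    top = PeptideTopology(resnames, params)
    coords = np.zeros((top.n_atoms, 3))
    for j, rec in enumerate(top.recipes):
        res = c.peptide.residues[rec.resi]
        a = res.atom(rec.name)
        if a is not None:
            coords[j] = a.pos
            continue
        srcs = _UNITED_SOURCES.get((resnames[rec.resi], rec.name), ())
        found = [res.atom(s) for s in srcs]
        found = [f for f in found if f is not None]
        if found:
            coords[j] = np.mean([f.pos for f in found], axis=0)
        else:
            raise ValueError(
                f"peptide residue {rec.resi + 1} ({res.code}) lacks atom "
                f"{rec.name} and any mappable source atoms")
    torsions, placement = measure_torsions(top, coords)
    pc = PeptideConformation(
        top, torsions, placement, coords=coords,
        is_analogue=np.asarray([r.is_analogue for r in c.peptide.residues], bool),
        original_resnames=[r.code for r in c.peptide.residues],
        ideal_geometry=False)
    return pc


def split_complex(c: PMHCComplex, include_hetero: bool = False,
                  params: ForceFieldParams | None = None
                  ) -> tuple[AtomSet, PeptideConformation]:
    """Separate a complex into a receptor atom set and the flexible ligand.

    ``include_hetero`` moves hetero groups (e.g. a groove-bound formic acid)
    onto the receptor side so their field enters the maps.
    """
    return (receptor_atom_set(c, include_hetero, params),
            peptide_conformation(c, params))


def set_extended_conformation(p: PeptideConformation, seed: int,
                              box=None) -> PeptideConformation:
    """Randomized extended-conformation restart for re-docking.

    Backbone phi/psi go to the documented extended values (-139/+135, all
    omega trans); side-chain chi angles are drawn uniformly; the rigid-body
    placement is randomized (uniform orientation; translation inside the
    docking box when one is given).
    """
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    top = p.topology
    t = p.torsions.copy()
    for i in range(top.n_res):
        t[top.slot[(i, "phi")]] = -75.0 if top.resnames[i] == "PRO" else EXTENDED_PHI
        t[top.slot[(i, "psi")]] = EXTENDED_PSI
        t[top.slot[(i, "omega")]] = OMEGA_TRANS
        for s in top.chi_slots(i):
            t[s] = rng.uniform(-180.0, 180.0)
    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31 - 1)))
    if box is not None:
        trans = rng.uniform(box.lo, box.hi)
    else:
        trans = p.placement[3:] + rng.normal(scale=2.0, size=3)
    placement = np.concatenate([rot.as_rotvec(), trans])
    return p.with_updates(torsions=t, placement=placement)


def extract_core(p: PeptideConformation, register) -> np.ndarray:
    """0-based residue indices of the nonameric core window.

    Peptides of nine or fewer residues are used whole; longer peptides
    return the 9-residue window starting at the register position.
    """
    start = getattr(register, "start", register)  # RegisterAssignment or int
    n = len(p)
    if n <= 9:
        return np.arange(n)
    if not 1 <= start <= n - 8:
        raise IndexError(f"register start {start} exceeds peptide length {n}")
    return np.arange(start - 1, start + 8)


def read_fasta_sequences(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA file."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
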