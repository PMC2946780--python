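"""United-atom force-field parameters and the typed atom container.

The parameter set is a deliberately small, internally consistent united-atom
model: Lennard-Jones 6-12 with geometric combining, residue-level partial
charges, Coulomb electrostatics screened by a distance-dependent dielectric
(eps = 4r), a distance-well hydrogen bond zeroed at 3.65 A, a hydrophobic
contact ramp zeroed at 4.50 A, and a surface-area solvation term.  Parameters
live in versioned TSV tables under ``peptigrid/data`` and are loaded once.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

# physical constants
GAS_CONSTANT_KCAL = 1.98720425864083e-3  # kcal/(mol K)
COULOMB_KCAL = 332.06  # kcal A / (mol e^2)
PROBE_RADIUS = 1.4  # water probe, A

# interaction geometry defaults (A)
HBOND_CUTOFF = 3.65
HBOND_OPTIMUM = 2.90
HBOND_SWITCH_WIDTH = 0.15
VDW_CONTACT_CUTOFF = 4.50
HYDROPHOBIC_FULL = 3.00
NONBONDED_CUTOFF = 8.0
NONBONDED_SWITCH_START = 6.5
CLASH_FLOOR = 0.1
PAIR_ENERGY_CAP = 100.0  # kcal/mol
HBOND_WELL_DEPTH = 2.0  # kcal/mol, depth at the optimum
HYDROPHOBIC_CONTACT = 0.25  # kcal/mol per fully formed apolar contact

BACKBONE_ATOMS = ("N", "CA", "C", "O")
BACKBONE_CHARGES = {"N": -0.35, "CA": 0.25, "C": 0.45, "O": -0.35}
BACKBONE_CLASSES = {"N": "N_AMD", "CA": "C_ALI", "C": "C_CRB", "O": "O_CRB"}

# analogue / nonstandard residue codes mapped to the standard parent used for
# parameters; the original code is preserved on the Residue record
ANALOGUE_PARENTS = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HYP": "PRO", "MLY": "LYS",
    "CSO": "CYS", "PTR": "TYR", "SEP": "SER", "TPO": "THR", "ABA": "ALA",
    "AIB": "ALA", "NLE": "LEU", "ORN": "LYS", "DAL": "ALA",
}

_THREE_TO_ONE = {
    "GLY": "G", "ALA": "A", "SER": "S", "CYS": "C", "THR": "T", "VAL": "V",
    "LEU": "L", "ILE": "I", "MET": "M", "PRO": "P", "PHE": "F", "TYR": "Y",
    "TRP": "W", "ASP": "D", "GLU": "E", "ASN": "N", "GLN": "Q", "LYS": "K",
    "ARG": "R", "HIS": "H",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


def three_to_one(code: str) -> str:
    """One-letter code for a three-letter residue code (analogues via parent)."""
    code = code.upper()
    if code in _THREE_TO_ONE:
        return _THREE_TO_ONE[code]
    parent = ANALOGUE_PARENTS.get(code)
    if parent:
        return _THREE_TO_ONE[parent]
    return "X"


def one_to_three(letter: str) -> str:
    try:
        return _ONE_TO_THREE[letter.upper()]
    except KeyError:
        raise KeyError(f"unknown one-letter residue code {letter!r}") from None


def _read_table(name: str) -> pd.DataFrame:
    with resources.files("peptigrid.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


@dataclass
class ForceFieldParams:
    """Loaded parameter tables plus the interaction-geometry defaults.

    ``classes`` indexes per-class Lennard-Jones, solvation and hydrophobic
    parameters; ``topology`` holds the united side-chain build recipes;
    ``props`` holds per-residue entropy maxima.
    """

    classes: pd.DataFrame
    topology: pd.DataFrame
    props: pd.DataFrame
    hbond_cutoff: float = HBOND_CUTOFF
    hbond_optimum: float = HBOND_OPTIMUM
    vdw_contact_cutoff: float = VDW_CONTACT_CUTOFF
    nonbonded_cutoff: float = NONBONDED_CUTOFF
    clash_floor: float = CLASH_FLOOR
    pair_cap: float = PAIR_ENERGY_CAP
    coulomb_constant: float = COULOMB_KCAL
    class_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.class_index = {c: i for i, c in enumerate(self.classes["class"])}
        self._rmin_half = self.classes["rmin_half"].to_numpy(float)
        self._eps = self.classes["eps"].to_numpy(float)
        self._solv = self.classes["solv"].to_numpy(float)
        self._hydro = self.classes["hydrophobic"].to_numpy(float)
        self._entropy = dict(zip(self.props["residue"], self.props["entropy_max"]))

    # --- per-class lookups -------------------------------------------------
    def class_id(self, name: str) -> int:
        return self.class_index[name]

    def rmin_half(self, cls: np.ndarray) -> np.ndarray:
        return self._rmin_half[cls]

    def eps(self, cls: np.ndarray) -> np.ndarray:
        return self._eps[cls]

    def solv_param(self, cls: np.ndarray) -> np.ndarray:
        return self._solv[cls]

    def hydro_strength(self, cls: np.ndarray) -> np.ndarray:
        return self._hydro[cls]

    def entropy_max(self, residue: str) -> float:
        return float(self._entropy.get(residue, 0.0))

    # Geometric-mean LJ decomposition.  With A_ii = eps * rmin^12 and
    # B_ii = 2 eps rmin^6 (rmin = 2*rmin_half), sqrt(A_ii), sqrt(B_ii) give
    # per-atom coefficients whose products reproduce the homo-pair well
    # exactly and approximate hetero pairs by the geometric mean.
    def lj_coeffs(self, cls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        rmin = 2.0 * self._rmin_half[cls]
        eps = self._eps[cls]
        a = np.sqrt(eps * rmin**12)
        b = np.sqrt(2.0 * eps * rmin**6)
        return a, b

    def checksum(self) -> str:
        """Stable checksum of the parameter tables (recorded in reports)."""
        h = hashlib.sha256()
        for df in (self.classes, self.topology, self.props):
            h.update(df.to_csv(index=False).encode())
        return h.hexdigest()[:16]


_DEFAULT: Optional[ForceFieldParams] = None


def default_params() -> ForceFieldParams:
    """The packaged version-1 parameter set (loaded once, shared)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = ForceFieldParams(
            classes=_read_table("forcefield_v1.tsv"),
            topology=_read_table("residue_topology_v1.tsv"),
            props=_read_table("residue_props_v1.tsv"),
        )
    return _DEFAULT


@dataclass
class AtomSet:
    """A typed, array-backed set of atoms ready for energy evaluation.

    Columns are parallel numpy arrays; ``cls`` indexes the force-field class
    table.  This is the container every energy routine consumes, for both
    receptor and ligand sides.
    """

    coords: np.ndarray  # (n, 3) float64, A
    cls: np.ndarray  # (n,) int
    charge: np.ndarray  # (n,) float64, e
    is_donor: np.ndarray  # (n,) bool
    is_acceptor: np.ndarray  # (n,) bool
    names: list[str] = field(default_factory=list)
    resnames: list[str] = field(default_factory=list)
    resindex: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    chains: list[str] = field(default_factory=list)
    is_backbone: np.ndarray = field(default_factory=lambda: np.empty(0, bool))

    def __len__(self) -> int:
        return len(self.coords)

    def subset(self, mask: np.ndarray) -> "AtomSet":
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        return AtomSet(
            coords=self.coords[idx].copy(),
            cls=self.cls[idx].copy(),
            charge=self.charge[idx].copy(),
            is_donor=self.is_donor[idx].copy(),
            is_acceptor=self.is_acceptor[idx].copy(),
            names=[self.names[i] for i in idx] if self.names else [],
            resnames=[self.resnames[i] for i in idx] if self.resnames else [],
            resindex=self.resindex[idx].copy() if len(self.resindex) else np.empty(0, int),
            chains=[self.chains[i] for i in idx] if self.chains else [],
            is_backbone=self.is_backbone[idx].copy() if len(self.is_backbone) else np.empty(0, bool),
        )

    @staticmethod
    def concatenate(parts: list["AtomSet"]) -> "AtomSet":
        return AtomSet(
            coords=np.concatenate([p.coords for p in parts]),
            cls=np.concatenate([p.cls for p in parts]),
            charge=np.concatenate([p.charge for p in parts]),
            is_donor=np.concatenate([p.is_donor for p in parts]),
            is_acceptor=np.concatenate([p.is_acceptor for p in parts]),
            names=sum((p.names for p in parts), []),
            resnames=sum((p.resnames for p in parts), []),
            resindex=np.concatenate([p.resindex for p in parts]),
            chains=sum((p.chains for p in parts), []),
            is_backbone=np.concatenate([p.is_backbone for p in parts]),
        )


def sidechain_rows(params: ForceFieldParams, resname: str) -> pd.DataFrame:
    """Topology rows for a residue's side chain (analogues via parent code)."""
    name = resname.upper()
    if name not in set(params.topology["residue"]) and name != "GLY":
        name = ANALOGUE_PARENTS.get(name, "ALA")
    return params.topology[params.topology["residue"] == name]


def atom_type(params: ForceFieldParams, resname: str, atomname: str):
    """(class id, charge, donor, acceptor) for a named atom of a residue."""
    if atomname in BACKBONE_ATOMS:
        cid = params.class_id(BACKBONE_CLASSES[atomname])
        q = BACKBONE_CHARGES[atomname]
        return cid, q, atomname == "N", atomname == "O"
    rows = sidechain_rows(params, resname)
    match = rows[rows["atom"] == atomname]
    if len(match) == 0:
        # unknown side-chain atom: treat as aliphatic carbon, neutral
        return params.class_id("C_ALI"), 0.0, False, False
    r = match.iloc[0]
    return params.class_id(r["class"]), float(r["charge"]), bool(r["donor"]), bool(r["acceptor"])
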