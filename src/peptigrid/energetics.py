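"""Energy terms and the two weighted scoring functions.

Two scoring contexts exist, mirroring the docking-then-refinement protocol:

* docking:     E = E_vw + E_en + 2.16 E_el + 2.53 E_hb + 4.35 E_hp + 0.20 E_solv
* refinement:  E = E_vw + E_hb + E_tors + E_elec + E_solv + E_en

with a united-atom 6-12 van der Waals term (geometric combining), Coulomb
electrostatics under a distance-dependent dielectric eps = 4r (pair energy
falls as 1/r^2), a distance-well hydrogen bond identically zero beyond
3.65 A, an apolar contact ramp zero beyond 4.50 A, surface-area solvation,
a configurational side-chain entropy penalty proportional to burial, and a
cosine torsion series (refinement only).

All radial kernels share a smooth switching function so every term is
continuous at its cutoff, and distances are floored at 0.1 A with pair
energies capped at +100 kcal/mol so Monte Carlo stays numerically stable
through clashes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forcefield import (
    AtomSet,
    ForceFieldParams,
    HBOND_SWITCH_WIDTH,
    HBOND_WELL_DEPTH,
    HYDROPHOBIC_CONTACT,
    HYDROPHOBIC_FULL,
    NONBONDED_SWITCH_START,
    PROBE_RADIUS,
    default_params,
)

__all__ = [
    "EnergyBreakdown", "ScoringWeights", "docking_score", "refinement_score",
    "vdw_energy", "hbond_energy", "electrostatic_energy", "hydrophobic_energy",
    "solvation_energy", "entropy_term", "torsion_energy", "shrake_rupley_sasa",
]


@dataclass
class EnergyBreakdown:
    """Named energy terms, kcal/mol.  ``total`` is set by the applied score."""

    e_vw: float = 0.0
    e_en: float = 0.0
    e_el: float = 0.0
    e_hb: float = 0.0
    e_hp: float = 0.0
    e_solv: float = 0.0
    e_tors: float = 0.0
    e_elec: float = 0.0
    total: float = 0.0

    def as_dict(self) -> dict:
        return {
            "e_vw": self.e_vw, "e_en": self.e_en, "e_el": self.e_el,
            "e_hb": self.e_hb, "e_hp": self.e_hp, "e_solv": self.e_solv,
            "e_tors": self.e_tors, "e_elec": self.e_elec, "total": self.total,
        }


@dataclass
class ScoringWeights:
    """The docking-equation weights (dimensionless, printed values)."""

    w_el: float = 2.16
    w_hb: float = 2.53
    w_hp: float = 4.35
    w_solv: float = 0.20


def docking_score(b: EnergyBreakdown, w: ScoringWeights | None = None) -> float:
    """Weighted docking score; stores and returns breakdown.total."""
    w = w or ScoringWeights()
    b.total = (b.e_vw + b.e_en + w.w_el * b.e_el + w.w_hb * b.e_hb
               + w.w_hp * b.e_hp + w.w_solv * b.e_solv)
    return b.total


def refinement_score(b: EnergyBreakdown) -> float:
    """Unweighted refinement score; stores and returns breakdown.total."""
    b.total = b.e_vw + b.e_hb + b.e_tors + b.e_elec + b.e_solv + b.e_en
    return b.total


# ---------------------------------------------------------------------------
# radial kernels (shared by the pairwise route and the grid-field route)
# ---------------------------------------------------------------------------

def switch_off(r: np.ndarray, start: float, end: float) -> np.ndarray:
    """Smoothstep from 1 at ``start`` down to 0 at ``end`` (C1 continuous)."""
    x = np.clip((r - start) / (end - start), 0.0, 1.0)
    return 1.0 - x * x * (3.0 - 2.0 * x)


def _floored(r: np.ndarray, params: ForceFieldParams) -> np.ndarray:
    return np.maximum(r, params.clash_floor)


def lj_rep_kernel(r: np.ndarray, params: ForceFieldParams) -> np.ndarray:
    """Repulsive 1/r^12 kernel with long-range switch (unit coefficients)."""
    rf = _floored(r, params)
    s = switch_off(r, NONBONDED_SWITCH_START, params.nonbonded_cutoff)
    return s / rf**12


def lj_att_kernel(r: np.ndarray, params: ForceFieldParams) -> np.ndarray:
    """Attractive -1/r^6 kernel with long-range switch (unit coefficients)."""
    rf = _floored(r, params)
    s = switch_off(r, NONBONDED_SWITCH_START, params.nonbonded_cutoff)
    return -s / rf**6


def elec_kernel(r: np.ndarray, params: ForceFieldParams) -> np.ndarray:
    """k/(4 r^2): Coulomb with the eps = 4r distance-dependent dielectric."""
    rf = _floored(r, params)
    s = switch_off(r, NONBONDED_SWITCH_START, params.nonbonded_cutoff)
    return params.coulomb_constant * s / (4.0 * rf**2)


HBOND_WELL_SIGMA = 0.70  # A, width of the Gaussian distance well


def hbond_kernel(r: np.ndarray, params: ForceFieldParams) -> np.ndarray:
    """Purely attractive Gaussian distance well.

    Minimum -depth at the optimum donor-acceptor distance, identically
    zero beyond 3.65 A (switched smoothly over the last 0.15 A).  The well
    is bounded and wide enough to interpolate accurately on a 1 A lattice;
    steric repulsion between donor and acceptor heavy atoms is the van der
    Waals term's job.
    """
    d0 = params.hbond_optimum
    well = -HBOND_WELL_DEPTH * np.exp(-((r - d0) ** 2) / (2.0 * HBOND_WELL_SIGMA**2))
    s = switch_off(r, params.hbond_cutoff - HBOND_SWITCH_WIDTH, params.hbond_cutoff)
    return np.where(r > params.hbond_cutoff, 0.0, well * s)


def hydrophobic_kernel(r: np.ndarray, params: ForceFieldParams) -> np.ndarray:
    """Unit apolar contact: -1 in full contact, smooth ramp to 0 at 4.50 A.

    The ramp is a C1 smoothstep rather than a piecewise-linear clip, so
    the term has no slope kinks (which trilinear maps resolve poorly).
    """
    return -switch_off(r, HYDROPHOBIC_FULL, params.vdw_contact_cutoff)


# ---------------------------------------------------------------------------
# pairwise energies between explicit atom sets
# ---------------------------------------------------------------------------

def _pair_distances(a: AtomSet, b: AtomSet) -> np.ndarray:
    diff = a.coords[:, None, :] - b.coords[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


def _pair_mask(a: AtomSet, b: AtomSet, exclusions: np.ndarray | None) -> np.ndarray:
    """Boolean (na, nb) mask of pairs to include."""
    if a is b:
        mask = np.triu(np.ones((len(a), len(b)), bool), k=1)
    else:
        mask = np.ones((len(a), len(b)), bool)
    if exclusions is not None:
        mask &= ~exclusions
    return mask


def _cap(e: np.ndarray, params: ForceFieldParams) -> np.ndarray:
    return np.clip(e, -params.pair_cap, params.pair_cap)


def vdw_energy(a: AtomSet, b: AtomSet, params: ForceFieldParams | None = None,
               exclusions: np.ndarray | None = None) -> float:
    """Lennard-Jones 6-12 sum over included pairs (geometric combining).

    When ``a is b`` each unordered pair is counted once; ``exclusions`` marks
    bonded/1-3/1-4 pairs to skip.  Pair energies are capped at +-100 kcal/mol.
    """
    params = params or default_params()
    r = _pair_distances(a, b)
    mask = _pair_mask(a, b, exclusions)
    aa, ba = params.lj_coeffs(a.cls)
    ab, bb = params.lj_coeffs(b.cls)
    e = (np.outer(aa, ab) * lj_rep_kernel(r, params)
         + np.outer(ba, bb) * lj_att_kernel(r, params))
    return float(_cap(e, params)[mask].sum())


def electrostatic_energy(a: AtomSet, b: AtomSet, params: ForceFieldParams | None = None,
                         exclusions: np.ndarray | None = None) -> float:
    """Coulomb sum with eps = 4r: pair energy k q1 q2 / (4 r^2)."""
    params = params or default_params()
    r = _pair_distances(a, b)
    mask = _pair_mask(a, b, exclusions)
    e = np.outer(a.charge, b.charge) * elec_kernel(r, params)
    return float(_cap(e, params)[mask].sum())


def hbond_energy(donors: AtomSet, acceptors: AtomSet,
                 params: ForceFieldParams | None = None,
                 exclusions: np.ndarray | None = None) -> float:
    """Distance-well hydrogen bonding over donor/acceptor pairs.

    Identically zero for donor-acceptor separations above 3.65 A and smoothly
    switched over the final 0.15 A, so the term is continuous at the cutoff.
    Only atoms flagged as donors (in ``donors``) and acceptors (in
    ``acceptors``) contribute.
    """
    params = params or default_params()
    r = _pair_distances(donors, acceptors)
    mask = _pair_mask(donors, acceptors, exclusions)
    pair_on = np.outer(donors.is_donor, acceptors.is_acceptor)
    if donors is acceptors:
        # within one set, also count acceptor<-donor orderings in the triangle
        pair_on = pair_on | np.outer(donors.is_acceptor, acceptors.is_donor)
    e = np.where(pair_on, hbond_kernel(r, params), 0.0)
    return float(_cap(e, params)[mask].sum())


def hydrophobic_energy(a: AtomSet, b: AtomSet, params: ForceFieldParams | None = None,
                       exclusions: np.ndarray | None = None) -> float:
    """Favourable apolar-apolar contact ramp, zero beyond 4.50 A."""
    params = params or default_params()
    r = _pair_distances(a, b)
    mask = _pair_mask(a, b, exclusions)
    strength = HYDROPHOBIC_CONTACT * np.outer(
        params.hydro_strength(a.cls), params.hydro_strength(b.cls))
    e = strength * hydrophobic_kernel(r, params)
    return float(_cap(e, params)[mask].sum())


# ---------------------------------------------------------------------------
# surface, solvation, entropy, torsions
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


def shrake_rupley_sasa(coords: np.ndarray, radii: np.ndarray,
                       probe: float = PROBE_RADIUS, n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area by numeric sphere sampling."""
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float) + probe
    n = len(coords)
    pts = _sphere_points(n_points)
    out = np.empty(n)
    # neighbour lists via a distance matrix (systems here are small)
    diff = coords[:, None, :] - coords[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    for i in range(n):
        cut = (radii[i] + radii) ** 2
        nbr = np.flatnonzero((d2[i] < cut) & (np.arange(n) != i))
        surf = coords[i] + radii[i] * pts
        if len(nbr):
            dd = surf[:, None, :] - coords[nbr][None, :, :]
            buried = (np.einsum("ijk,ijk->ij", dd, dd)
                      < (radii[nbr] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        out[i] = 4.0 * np.pi * radii[i] ** 2 * frac
    return out


def solvation_energy(atoms: AtomSet, params: ForceFieldParams | None = None,
                     n_points: int = 960) -> float:
    """Surface-based solvation: sum of sigma_i x SASA_i over atoms."""
    params = params or default_params()
    sasa = shrake_rupley_sasa(atoms.coords, params.rmin_half(atoms.cls), n_points=n_points)
    return float(np.dot(params.solv_param(atoms.cls), sasa))


def burial_fraction(points: np.ndarray, environment: np.ndarray,
                    r_contact: float = 6.0, n_sat: float = 14.0) -> np.ndarray:
    """Smooth 0..1 burial estimate from the local heavy-atom density.

    A linearly decaying contact weight within ``r_contact`` is summed over
    environment atoms and saturates at ``n_sat`` effective contacts.  Cheap
    enough for per-step Monte Carlo use, monotone in true burial.
    """
    if len(environment) == 0:
        return np.zeros(len(points))
    diff = points[:, None, :] - environment[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    w = np.clip(1.0 - r / r_contact, 0.0, 1.0).sum(axis=1)
    return np.clip(w / n_sat, 0.0, 1.0)


def entropy_term(ligand, receptor: AtomSet, params: ForceFieldParams | None = None) -> float:
    """Side-chain configurational entropy penalty for the ligand.

    Each residue pays entropy_max x (buried fraction of its terminal
    side-chain atom); glycine/alanine/proline pay nothing by table.
    ``ligand`` is a PeptideConformation.
    """
    params = params or default_params()
    top = ligand.topology
    terminals = [t for t in top.sc_terminal if t >= 0]
    if not terminals:
        return 0.0
    pts = ligand.coords[terminals]
    frac = burial_fraction(pts, receptor.coords)
    total = 0.0
    for k, (resi, b) in enumerate(zip(
            [top.atom_resi[t] for t in terminals], frac)):
        total += params.entropy_max(top.resnames[resi]) * float(b)
    return total


# generic torsion barriers: (height kcal/mol, periodicity)
TORSION_BARRIERS = {"chi": (1.4, 3), "omega": (10.0, 2)}


def torsion_energy(ligand) -> float:
    """Cosine-series torsion energy over ligand omega and chi angles.

    E = sum V/2 (1 + cos(n phi)) for chi (threefold, staggered minima) and
    V/2 (1 - cos(2 phi)) for omega (planar minima).  Backbone phi/psi carry
    no explicit torsion potential (steric terms shape them instead).
    """
    top = ligand.topology
    t = np.radians(ligand.torsions)
    e = 0.0
    v, n = TORSION_BARRIERS["chi"]
    for s in top.all_chi_slots():
        e += 0.5 * v * (1.0 + np.cos(n * t[s]))
    v, n = TORSION_BARRIERS["omega"]
    for i in range(1, top.n_res):
        e += 0.5 * v * (1.0 - np.cos(n * t[top.slot[(i, "omega")]]))
    return float(e)
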