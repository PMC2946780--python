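"""Interface refinement, Calpha RMSD, register detection, dataset filtering.

Refinement relaxes ligand torsions and receptor side chains in the 4.00 A
interface zone under the unweighted refinement score, with harmonic
restraints on peptide Calpha positions.  Pose accuracy is the Calpha RMSD
over the nonameric core (whole peptide when nine residues or fewer),
computed in the shared receptor frame without superposition; a pose is
called correctly docked at 2.50 A or better.  The binding register of a
longer peptide is the 9-residue window making the most heavy-atom contacts
(<= 4.50 A) with the binding-site atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize as scipy_minimize

from .energetics import (
    EnergyBreakdown,
    burial_fraction,
    elec_kernel,
    hbond_kernel,
    lj_att_kernel,
    lj_rep_kernel,
    refinement_score,
    torsion_energy,
)
from .forcefield import AtomSet, default_params
from .mc_sampling import ligand_pair_table
from .peptide import PeptideConformation
from .structure_io import extract_core

CORRECT_DOCK_RMSD = 2.50  # A, inclusive threshold
REFINE_RADIUS = 4.00  # A, interface vicinity
CONTACT_DISTANCE = 4.50  # A, heavy-atom contact for register detection


@dataclass
class RegisterAssignment:
    """Start (1-based) of the nonameric core within the peptide."""

    start: int = 1
    whole_peptide: bool = False


@dataclass
class DockResult:
    """One docked case: pose, energies, register, accuracy call."""

    pose: PeptideConformation
    docking_breakdown: EnergyBreakdown | None = None
    refinement_breakdown: EnergyBreakdown | None = None
    register: RegisterAssignment = field(default_factory=RegisterAssignment)
    ca_rmsd: float | None = None
    correct: bool | None = None
    seed: int = 0
    params_echo: dict = field(default_factory=dict)

    def to_record(self) -> dict:
        rec = {
            "sequence": self.pose.sequence,
            "register_start": self.register.start,
            "ca_rmsd": self.ca_rmsd,
            "correct": self.correct,
            "seed": self.seed,
        }
        if self.docking_breakdown is not None:
            rec["docking_energy"] = self.docking_breakdown.total
        if self.refinement_breakdown is not None:
            rec["refinement_energy"] = self.refinement_breakdown.total
        return rec


class DatasetEntry(object):
    """A catalogued complex: PDB id, peptide, allele, optional TR type."""

    def __init__(self, pdb_id: str, peptide: str, allele: str,
                 resolution: float, tr_type: str | None = None):
        if not resolution > 0:
            raise ValueError(f"resolution must be positive, got {resolution}")
        self.pdb_id = pdb_id.lower()
        self.peptide = peptide.upper()
        self.allele = allele
        self.resolution = float(resolution)
        self.tr_type = tr_type or None

    def __repr__(self) -> str:
        return (f"DatasetEntry({self.pdb_id}, {self.peptide}, {self.allele}, "
                f"{self.resolution}, tr={self.tr_type})")

    def __eq__(self, other) -> bool:
        return (self.pdb_id, self.peptide, self.allele,
                self.resolution, self.tr_type) == (
            other.pdb_id, other.peptide, other.allele,
            other.resolution, other.tr_type)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def ca_rmsd(pose: PeptideConformation, reference: PeptideConformation,
            register: RegisterAssignment | int = 1) -> float:
    """Core Calpha RMSD between two conformations of the same peptide.

    Both conformations must share the sequence over the compared window and
    live in the same receptor frame (docking never moves the receptor, so no
    superposition is applied).
    """
    win = extract_core(pose, register)
    win_ref = extract_core(reference, register)
    seq_a = "".join(pose.sequence[i] for i in win)
    seq_b = "".join(reference.sequence[i] for i in win_ref)
    if seq_a != seq_b:
        raise ValueError(f"sequence mismatch over core window: {seq_a} vs {seq_b}")
    d = pose.ca_coords()[win] - reference.ca_coords()[win_ref]
    return float(np.sqrt(np.mean(np.einsum("ij,ij->i", d, d))))


def kabsch(mobile: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t minimizing |R x + t - ref|."""
    mc, rc = mobile.mean(axis=0), ref.mean(axis=0)
    h = (mobile - mc).T @ (ref - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, rc - r @ mc


def classify_correct(rmsd: float, threshold: float = CORRECT_DOCK_RMSD) -> bool:
    """Correctly docked iff RMSD <= threshold (inclusive 'at most')."""
    if rmsd < 0:
        raise ValueError(f"RMSD cannot be negative, got {rmsd}")
    return rmsd <= threshold


def detect_register(pose: PeptideConformation, site) -> RegisterAssignment:
    """Sliding-window register detection by binding-site contact counting.

    ``site`` is the binding-site atom coordinates (or an AtomSet).  Each
    9-residue window is scored by its number of heavy-atom contacts at
    4.50 A or less; the highest-scoring window wins, ties going to the
    smallest start.
    """
    coords = site.coords if hasattr(site, "coords") else np.asarray(site, float)
    n = len(pose)
    if n < 9:
        return RegisterAssignment(start=1, whole_peptide=True)
    if n == 9:
        return RegisterAssignment(start=1)
    resi = np.asarray(pose.topology.atom_resi, int)
    diff = pose.coords[:, None, :] - coords[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    contacts_per_atom = (r <= CONTACT_DISTANCE).sum(axis=1)
    per_res = np.array([contacts_per_atom[resi == i].sum() for i in range(n)])
    window_counts = np.convolve(per_res, np.ones(9, int), mode="valid")
    return RegisterAssignment(start=int(np.argmax(window_counts)) + 1)


def select_nonredundant(entries: list[DatasetEntry]) -> list[DatasetEntry]:
    """Highest-resolution representative per redundancy group.

    Plain pMHC entries group by (peptide, allele); entries carrying a TR
    type group by (peptide, allele, TR type).  'Highest resolution' is the
    numerically smallest Angstrom value; ties break by PDB id.
    """
    groups: dict[tuple, DatasetEntry] = {}
    for e in entries:
        key = (e.peptide, e.allele, e.tr_type)
        cur = groups.get(key)
        if cur is None or (e.resolution, e.pdb_id) < (cur.resolution, cur.pdb_id):
            groups[key] = e
    return sorted(groups.values(), key=lambda e: e.pdb_id)


def read_dataset_table(path) -> list[DatasetEntry]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        tr = r.get("tr_type")
        out.append(DatasetEntry(str(r["pdb_id"]), str(r["peptide"]),
                                str(r["allele"]), float(r["resolution"]),
                                None if pd.isna(tr) else str(tr)))
    return out


def write_dataset_table(entries: list[DatasetEntry], path) -> None:
    pd.DataFrame([{
        "pdb_id": e.pdb_id, "peptide": e.peptide, "allele": e.allele,
        "resolution": e.resolution, "tr_type": e.tr_type,
    } for e in entries]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# interface refinement
# ---------------------------------------------------------------------------

@dataclass
class RefineResult:
    receptor: AtomSet
    pose: PeptideConformation
    score_before: float
    score_after: float
    breakdown_before: EnergyBreakdown
    breakdown_after: EnergyBreakdown
    mobile_receptor: np.ndarray  # boolean mask over receptor atoms
    mobile_torsions: list[int]

    def __iter__(self):
        return iter((self.receptor, self.pose))


class _RefinementModel:
    """Fixed-pair-set refinement score: a deterministic function of the
    interface coordinates, so before/after comparisons are well defined."""

    def __init__(self, receptor: AtomSet, pose: PeptideConformation,
                 radius: float, params):
        self.params = params
        self.receptor = receptor
        self.topology = pose.topology
        lr = pose.coords[:, None, :] - receptor.coords[None, :, :]
        dist = np.sqrt(np.einsum("ijk,ijk->ij", lr, lr))
        near_lig = dist.min(axis=1) <= radius  # ligand atoms near receptor
        near_rec = dist.min(axis=0) <= radius  # receptor atoms near ligand

        # environment: receptor atoms whose field the interface feels
        self.env = np.flatnonzero(dist.min(axis=0) <= radius + 8.0)
        # mobile receptor: side-chain atoms of residues touching the ligand
        resids = np.array([(c, i) for c, i in zip(receptor.chains, receptor.resindex)],
                          dtype=object)
        touched = set()
        for j in np.flatnonzero(near_rec):
            touched.add((receptor.chains[j], int(receptor.resindex[j])))
        mobile = np.zeros(len(receptor), bool)
        for j in range(len(receptor)):
            if (receptor.chains[j], int(receptor.resindex[j])) in touched:
                if not receptor.is_backbone[j]:
                    mobile[j] = True
        self.mobile = mobile
        self.mobile_idx = np.flatnonzero(mobile)

        # mobile ligand torsions: residues with any atom in the vicinity
        resi = np.asarray(self.topology.atom_resi, int)
        touched_res = sorted(set(resi[near_lig].tolist()))
        slots: list[int] = []
        for i in touched_res:
            slots.extend(self.topology.backbone_slots(i))
            slots.extend(self.topology.chi_slots(i))
        self.mobile_torsions = sorted(slots)

        # receptor-internal pair list among environment atoms involving a
        # mobile atom; same-residue and sequence-adjacent pairs excluded
        env = self.env
        pairs_i, pairs_j = [], []
        env_mobile = [j for j in env if mobile[j]]
        chains, rix = receptor.chains, receptor.resindex
        envs = set(env.tolist())
        for j in env_mobile:
            for k in env:
                k = int(k)
                if k <= j and mobile[k]:
                    continue  # count mobile-mobile once
                if chains[j] == chains[k] and abs(int(rix[j]) - int(rix[k])) <= 1:
                    continue
                pairs_i.append(j)
                pairs_j.append(k)
        self.rr_i = np.asarray(pairs_i, int)
        self.rr_j = np.asarray(pairs_j, int)

        a, b = params.lj_coeffs(receptor.cls)
        self.rec_a, self.rec_b = a, b
        la, lb = params.lj_coeffs(self.topology.cls)
        self.lig_a, self.lig_b = la, lb
        self.tab = ligand_pair_table(self.topology, params)
        self.ca_ref = pose.ca_coords().copy()
        self.rec_ref = receptor.coords.copy()
        self.k_ca = 1.0  # kcal/(mol A^2), peptide Calpha restraint
        self.k_rec = 2.0  # receptor side-chain tether

    def _pair_terms(self, r, ai, aj, bi, bj, qi, qj, hb_on):
        p = self.params
        cap = p.pair_cap
        e_vw = np.clip(ai * aj * lj_rep_kernel(r, p)
                       + bi * bj * lj_att_kernel(r, p), -cap, cap).sum()
        e_el = np.clip(qi * qj * elec_kernel(r, p), -cap, cap).sum()
        e_hb = np.clip(hb_on * hbond_kernel(r, p), -cap, cap).sum()
        return float(e_vw), float(e_el), float(e_hb)

    def breakdown(self, rec_coords: np.ndarray, pose: PeptideConformation) -> EnergyBreakdown:
        p = self.params
        rec, top, tab = self.receptor, self.topology, self.tab
        bd = EnergyBreakdown()
        # receptor-ligand over the environment set
        env = self.env
        d = pose.coords[:, None, :] - rec_coords[env][None, :, :]
        r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        vw, el, hb = self._pair_terms(
            r,
            self.lig_a[:, None], self.rec_a[env][None, :],
            self.lig_b[:, None], self.rec_b[env][None, :],
            top.charge[:, None], rec.charge[env][None, :],
            (top.is_donor[:, None] & rec.is_acceptor[env][None, :])
            | (top.is_acceptor[:, None] & rec.is_donor[env][None, :]))
        bd.e_vw += vw
        bd.e_elec += el
        bd.e_hb += hb
        # intra-ligand
        dl = pose.coords[tab.i] - pose.coords[tab.j]
        rl = np.sqrt(np.einsum("ij,ij->i", dl, dl))
        vw, el, hb = self._pair_terms(rl, tab.aij, 1.0, tab.bij, 1.0,
                                      tab.qij, 1.0, tab.hb_on)
        bd.e_vw += vw
        bd.e_elec += el
        bd.e_hb += hb
        # receptor-internal pairs involving mobile atoms
        if len(self.rr_i):
            dr = rec_coords[self.rr_i] - rec_coords[self.rr_j]
            rr = np.sqrt(np.einsum("ij,ij->i", dr, dr))
            i, j = self.rr_i, self.rr_j
            vw, el, hb = self._pair_terms(
                rr, self.rec_a[i], self.rec_a[j], self.rec_b[i], self.rec_b[j],
                rec.charge[i], rec.charge[j],
                (rec.is_donor[i] & rec.is_acceptor[j])
                | (rec.is_acceptor[i] & rec.is_donor[j]))
            bd.e_vw += vw
            bd.e_elec += el
            bd.e_hb += hb
        bd.e_tors = torsion_energy(pose)
        buried = burial_fraction(pose.coords, rec_coords[env])
        bd.e_solv = float(np.dot(tab.solv_sigma, tab.smax * (1.0 - buried)))
        e_en = 0.0
        terminals = [t for t in top.sc_terminal if t >= 0]
        if terminals:
            bfrac = burial_fraction(pose.coords[terminals], rec_coords[env])
            for t, bf in zip(terminals, bfrac):
                e_en += p.entropy_max(top.resnames[top.atom_resi[t]]) * float(bf)
        bd.e_en = e_en
        refinement_score(bd)
        return bd

    def restraints(self, rec_coords: np.ndarray, pose: PeptideConformation) -> float:
        dca = pose.ca_coords() - self.ca_ref
        e = self.k_ca * float(np.einsum("ij,ij->", dca, dca))
        if len(self.mobile_idx):
            dr = rec_coords[self.mobile_idx] - self.rec_ref[self.mobile_idx]
            e += self.k_rec * float(np.einsum("ij,ij->", dr, dr))
        return e


def refine_interface(receptor: AtomSet, pose: PeptideConformation,
                     radius: float = REFINE_RADIUS, params=None,
                     max_rounds: int = 2) -> RefineResult:
    """Relax the interface under the refinement score.

    Only ligand torsions of residues within ``radius`` of the receptor and
    receptor side chains of residues within ``radius`` of the ligand move;
    every other atom is returned bit-identical.  The refined refinement
    score never exceeds the input score (inputs are returned unchanged if
    no improvement is found).
    """
    params = params or default_params()
    model = _RefinementModel(receptor, pose, radius, params)
    bd0 = model.breakdown(receptor.coords, pose)
    score0 = bd0.total

    best_rec = receptor.coords.copy()
    best_pose = pose
    best_obj = score0 + model.restraints(best_rec, best_pose)

    for _ in range(max_rounds):
        # ligand torsional relaxation, residue group at a time
        top = pose.topology
        resi_groups: dict[int, list[int]] = {}
        inv = {s: key for key, s in top.slot.items()}
        for s in model.mobile_torsions:
            resi_groups.setdefault(inv[s][0], []).append(s)
        for slots in resi_groups.values():
            x0 = best_pose.torsions[slots].copy()

            def obj_t(x, _slots=slots, _base=best_pose):
                t = _base.torsions.copy()
                t[_slots] = x
                cand = _base.with_updates(torsions=t)
                return (model.breakdown(best_rec, cand).total
                        + model.restraints(best_rec, cand))

            res = scipy_minimize(obj_t, x0, method="Powell",
                                 options={"maxfev": 60, "xtol": 1e-2, "ftol": 1e-3})
            if res.fun < best_obj:
                t = best_pose.torsions.copy()
                t[slots] = res.x
                best_pose = best_pose.with_updates(torsions=t)
                best_obj = float(res.fun)

        # receptor side-chain Cartesian relaxation (L-BFGS, numeric gradient)
        if len(model.mobile_idx):
            idx = model.mobile_idx
            x0 = best_rec[idx].ravel()

            def obj_r(x):
                rc = best_rec.copy()
                rc[idx] = x.reshape(-1, 3)
                return (model.breakdown(rc, best_pose).total
                        + model.restraints(rc, best_pose))

            res = scipy_minimize(obj_r, x0, method="L-BFGS-B",
                                 options={"maxiter": 15, "eps": 1e-4})
            if res.fun < best_obj:
                best_rec = best_rec.copy()
                best_rec[idx] = res.x.reshape(-1, 3)
                best_obj = float(res.fun)

    bd1 = model.breakdown(best_rec, best_pose)
    if bd1.total > score0:  # contract: never worse than the input score
        best_rec, best_pose, bd1 = receptor.coords.copy(), pose, bd0
    out_rec = receptor.subset(np.ones(len(receptor), bool))
    out_rec.coords = best_rec
    return RefineResult(
        receptor=out_rec, pose=best_pose,
        score_before=score0, score_after=bd1.total,
        breakdown_before=bd0, breakdown_after=bd1,
        mobile_receptor=model.mobile, mobile_torsions=model.mobile_torsions)


def clash_count(a: AtomSet, b: AtomSet, params=None, factor: float = 0.8) -> int:
    """Pairs closer than ``factor`` x the pair contact distance (rmin sum)."""
    params = params or default_params()
    diff = a.coords[:, None, :] - b.coords[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    rmin = params.rmin_half(a.cls)[:, None] + params.rmin_half(b.cls)[None, :]
    return int((r < factor * rmin).sum())
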