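"""Biased Monte Carlo docking of the flexible peptide in the grid.

Each step pseudo-randomly perturbs a small set of internal coordinates
(side-chain chi angles are favoured, with backbone pivot and rigid-body
pseudo-Brownian moves mixed in), locally minimizes the energy over just the
perturbed variables, and accepts by the Metropolis criterion
min(1, exp(-dG/RT)) at 300 K.  Loose harmonic restraints on the ligand
Calpha positions keep the molecule close to its starting conformation.  The
pose energy combines the grid receptor-ligand terms with intra-ligand terms
under the weighted docking score.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional

import numpy as np
from pydantic import BaseModel, model_validator
from scipy.optimize import minimize as scipy_minimize
from scipy.spatial.transform import Rotation

from .energetics import (
    EnergyBreakdown,
    ScoringWeights,
    burial_fraction,
    docking_score,
    elec_kernel,
    hbond_kernel,
    lj_att_kernel,
    lj_rep_kernel,
)
from .forcefield import GAS_CONSTANT_KCAL, PROBE_RADIUS, default_params
from .gridding import DockingBox, GridMaps, grid_energy
from .peptide import PeptideConformation


class MCParams(BaseModel):
    """Sampler settings.  Temperature defaults to exactly 300 K."""

    temperature_K: float = 300.0
    gas_constant: float = GAS_CONSTANT_KCAL
    n_steps: int = 500
    seed: int = 0
    p_sidechain: float = 0.5
    p_backbone: float = 0.3
    p_rigid: float = 0.2
    max_torsion_deg: float = 30.0
    max_translation: float = 1.0
    max_rotation_deg: float = 10.0
    restraint_k: float = 0.1  # kcal/(mol A^2) on Calpha displacement from the start
    minimizer_maxfev: int = 25
    early_stop: int = 250  # stop after this many steps without a new best

    @model_validator(mode="after")
    def _check_mix(self) -> "MCParams":
        s = self.p_sidechain + self.p_backbone + self.p_rigid
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"move-mix probabilities sum to {s}, not 1")
        return self

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature_K


@dataclass
class MoveProposal:
    kind: str  # sidechain | backbone | rigid
    torsion_slots: list[int]
    conformation: PeptideConformation
    dG: float = float("nan")


@dataclass
class DockTrajectory:
    """Accepted poses, the running best, and bookkeeping for reproducibility."""

    poses: list[dict] = dc_field(default_factory=list)
    best_pose: Optional[PeptideConformation] = None
    best_energy: float = float("inf")
    best_breakdown: Optional[EnergyBreakdown] = None
    acceptance_count: int = 0
    n_steps_run: int = 0
    seed: int = 0
    rng_snapshots: list[dict] = dc_field(default_factory=list)

    def best_energies(self) -> np.ndarray:
        """Best-so-far energy at each recorded pose (non-increasing)."""
        out, best = [], float("inf")
        for p in self.poses:
            best = min(best, p["energy"])
            out.append(best)
        return np.asarray(out)


# ---------------------------------------------------------------------------
# energy model used during docking
# ---------------------------------------------------------------------------

class _LigandPairTable:
    """Precomputed non-excluded intra-ligand pair arrays for fast evaluation."""

    def __init__(self, topology, params):
        iu, ju = np.triu_indices(topology.n_atoms, k=1)
        keep = ~topology.exclusions[iu, ju]
        self.i, self.j = iu[keep], ju[keep]
        a, b = params.lj_coeffs(topology.cls)
        self.aij = a[self.i] * a[self.j]
        self.bij = b[self.i] * b[self.j]
        self.qij = topology.charge[self.i] * topology.charge[self.j]
        d, c = topology.is_donor, topology.is_acceptor
        self.hb_on = ((d[self.i] & c[self.j]) | (c[self.i] & d[self.j])).astype(float)
        h = params.hydro_strength(topology.cls)
        self.solv_sigma = params.solv_param(topology.cls)
        self.smax = 4.0 * np.pi * (params.rmin_half(topology.cls) + PROBE_RADIUS) ** 2


def ligand_pair_table(topology, params) -> _LigandPairTable:
    tab = getattr(topology, "_pair_table", None)
    if tab is None:
        tab = _LigandPairTable(topology, params)
        topology._pair_table = tab
    return tab


class DockingEnergy:
    """Callable total docking energy: grid receptor-ligand + intra-ligand.

    Solvation during sampling uses the fast burial approximation
    (sigma_i x SASA_max_i x exposed fraction); the entropy term uses the
    same burial machinery on side-chain terminal atoms.
    """

    def __init__(self, maps: GridMaps, params=None,
                 weights: ScoringWeights | None = None):
        self.maps = maps
        self.params = params or default_params()
        self.weights = weights or ScoringWeights()

    def breakdown(self, lig: PeptideConformation) -> EnergyBreakdown:
        params = self.params
        bd = grid_energy(self.maps, lig, params)
        tab = ligand_pair_table(lig.topology, params)
        d = lig.coords[tab.i] - lig.coords[tab.j]
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        cap = params.pair_cap
        e_vw = np.clip(tab.aij * lj_rep_kernel(r, params)
                       + tab.bij * lj_att_kernel(r, params), -cap, cap).sum()
        e_el = np.clip(tab.qij * elec_kernel(r, params), -cap, cap).sum()
        e_hb = np.clip(tab.hb_on * hbond_kernel(r, params), -cap, cap).sum()
        bd.e_vw += float(e_vw)
        bd.e_el += float(e_el)
        bd.e_hb += float(e_hb)
        bd.e_elec = bd.e_el
        # fast surface terms against the receptor atoms backing the maps
        env = self.maps.included.coords
        buried = burial_fraction(lig.coords, env)
        bd.e_solv = float(np.dot(tab.solv_sigma, tab.smax * (1.0 - buried)))
        top = lig.topology
        e_en = 0.0
        terminals = [t for t in top.sc_terminal if t >= 0]
        if terminals:
            bfrac = burial_fraction(lig.coords[terminals], env)
            for t, b in zip(terminals, bfrac):
                e_en += self.params.entropy_max(top.resnames[top.atom_resi[t]]) * float(b)
        bd.e_en = e_en
        docking_score(bd, self.weights)
        return bd

    def __call__(self, lig: PeptideConformation) -> float:
        return self.breakdown(lig).total


def restraint_energy(lig: PeptideConformation, ref_ca: np.ndarray, k: float) -> float:
    """Harmonic positional restraint on ligand Calpha displacement."""
    d = lig.ca_coords() - ref_ca
    return float(k * np.einsum("ij,ij->", d, d))


# ---------------------------------------------------------------------------
# sampler operations
# ---------------------------------------------------------------------------

def place_probe(maps: GridMaps, box: DockingBox, seed: int = 0,
                params=None) -> np.ndarray:
    """Initial probe position: the best vdW node for a probe pseudo-atom.

    Scans the vdW channels over nodes in the central third of the box and
    returns the node where a single probe pseudo-atom has the lowest
    interpolated van der Waals energy (attractive + repulsive, so nodes
    inside receptor atoms are excluded naturally; ties break by node index
    order).  Deterministic; ``seed`` is accepted for interface symmetry.
    """
    from .gridding import CHANNELS, _from_transform_space

    params = params or default_params()
    nodes = maps.node_coords()
    stored = np.stack([maps.channels[c].ravel() for c in CHANNELS], axis=1)
    raw = _from_transform_space(stored)
    a, b = params.lj_coeffs(np.array([params.class_id("P_PRB")]))
    e = a[0] * raw[:, 0] + b[0] * raw[:, 1]
    core = (np.abs(nodes - box.center[None, :]) <= (box.dims / 6.0)[None, :]).all(axis=1)
    idx = np.flatnonzero(core)
    return nodes[idx[np.argmin(e[idx])]]


def metropolis_accept(dG: float, params: MCParams, rng: np.random.Generator) -> bool:
    """min(1, exp(-dG/RT)): downhill always accepted, uphill with Boltzmann
    probability at the simulation temperature."""
    if not np.isfinite(dG):
        return False
    if dG <= 0.0:
        return True
    return bool(rng.random() < np.exp(-dG / params.rt))


def propose_move(c: PeptideConformation, params: MCParams,
                 rng: np.random.Generator) -> MoveProposal:
    """Draw a move from the biased mix and apply the raw perturbation.

    Side-chain moves perturb 1-3 chi angles of one residue; backbone moves
    perturb 1-2 phi/psi angles; rigid moves apply a small pseudo-Brownian
    translation + rotation.  A side-chain draw on a chi-less peptide falls
    back to a backbone move.
    """
    top = c.topology
    u = rng.random()
    kind = ("sidechain" if u < params.p_sidechain
            else "backbone" if u < params.p_sidechain + params.p_backbone
            else "rigid")
    if kind == "sidechain":
        residues = [i for i in range(top.n_res) if top.n_chi[i] > 0]
        if not residues:
            kind = "backbone"
    if kind == "sidechain":
        resi = residues[rng.integers(len(residues))]
        slots = top.chi_slots(resi)
        k = min(len(slots), 1 + rng.integers(3))
        chosen = list(rng.choice(slots, size=k, replace=False))
        t = c.torsions.copy()
        for s in chosen:
            if rng.random() < 0.5:
                # biased-probability move: resample the torsion outright,
                # letting a side chain jump between rotamer wells
                t[s] = rng.uniform(-180.0, 180.0)
            else:
                t[s] += rng.uniform(-params.max_torsion_deg, params.max_torsion_deg)
        return MoveProposal(kind, sorted(int(s) for s in chosen), c.with_updates(torsions=t))
    if kind == "backbone":
        slots_all = top.all_backbone_slots()
        k = min(len(slots_all), 1 + rng.integers(2))
        chosen = list(rng.choice(slots_all, size=k, replace=False))
        t = c.torsions.copy()
        for s in chosen:
            t[s] += rng.uniform(-params.max_torsion_deg, params.max_torsion_deg)
        return MoveProposal(kind, sorted(int(s) for s in chosen), c.with_updates(torsions=t))
    # rigid-body pseudo-Brownian step
    shift = rng.uniform(-params.max_translation, params.max_translation, size=3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(-params.max_rotation_deg, params.max_rotation_deg))
    rot = Rotation.from_rotvec(axis * angle)
    return MoveProposal("rigid", [], c.transformed(rot, shift))


def local_minimize(c: PeptideConformation, energy: Callable[[PeptideConformation], float],
                   params: MCParams, torsion_slots: Optional[list[int]] = None,
                   rigid: bool = False,
                   bounds=None) -> tuple[PeptideConformation, float]:
    """Derivative-free local descent over the perturbed variables only.

    Powell minimization over the selected torsion slots (or the six
    rigid-body variables).  The returned energy never exceeds the input
    energy; a non-finite starting energy aborts the move.
    """
    e0 = energy(c)
    if not np.isfinite(e0):
        return c, float("inf")

    if rigid:
        x0 = c.placement.copy()

        def obj(x):
            return energy(c.with_updates(placement=x))
    else:
        slots = list(torsion_slots or [])
        if not slots:
            return c, e0
        x0 = c.torsions[slots].copy()

        def obj(x):
            t = c.torsions.copy()
            t[slots] = x
            return energy(c.with_updates(torsions=t))

    res = scipy_minimize(obj, x0, method="Powell", bounds=bounds,
                         options={"maxfev": params.minimizer_maxfev,
                                  "xtol": 1e-2, "ftol": 1e-3})
    if res.fun < e0:
        if rigid:
            best = c.with_updates(placement=res.x)
        else:
            t = c.torsions.copy()
            t[slots] = res.x
            best = c.with_updates(torsions=t)
        return best, float(res.fun)
    return c, e0


ROTAMER_STARTS = (180.0, -60.0, 60.0)


def repack_residue(pose: PeptideConformation, energy, params: MCParams,
                   resi: int) -> PeptideConformation:
    """Deterministic rotamer scan + minimization for one residue.

    Tries the current side-chain torsions and the three staggered rotamer
    starts (all-chi 180/-60/+60), minimizes each over the residue's chi
    angles, and keeps the best.  Crosses rotamer barriers that pure local
    descent cannot.
    """
    top = pose.topology
    slots = top.chi_slots(resi)
    if not slots:
        return pose
    chi_params = params.model_copy(update={"minimizer_maxfev": 40})
    best, best_e = local_minimize(pose, energy, chi_params, torsion_slots=slots)
    for base in ROTAMER_STARTS:
        t = pose.torsions.copy()
        t[slots] = base
        cand, e = local_minimize(pose.with_updates(torsions=t), energy,
                                 chi_params, torsion_slots=slots)
        if e < best_e:
            best, best_e = cand, e
    return best


def _descent_pass(pose: PeptideConformation, energy, params: MCParams,
                  passes: int) -> PeptideConformation:
    rigid_params = params.model_copy(update={"minimizer_maxfev": 150})
    tors_params = params.model_copy(update={"minimizer_maxfev": 60})
    top = pose.topology
    for _ in range(passes):
        pose, _e = local_minimize(pose, energy, rigid_params, rigid=True)
        for i in range(top.n_res):
            pose = repack_residue(pose, energy, params, i)
            slots = top.backbone_slots(i) + top.chi_slots(i)
            if slots:
                pose, _e = local_minimize(pose, energy, tors_params,
                                          torsion_slots=slots)
    pose, _e = local_minimize(pose, energy, rigid_params, rigid=True)
    return pose


def polish_pose(pose: PeptideConformation, energy, params: MCParams,
                passes: int = 2) -> PeptideConformation:
    """Deterministic local descent: rigid fit, rotamer repack, torsions.

    Runs the descent from three starts and keeps the lowest-energy result:
    the pose as sampled; the pose with side chains reset to the canonical
    trans rotamer; and the pose reset to the canonical extended
    conformation (extended backbone, trans side chains) at the sampled
    placement — groove-bound peptides adopt extended backbones, so the
    canonical conformer is the natural restart when sampling has drifted
    the backbone into a shallow local trap.  Powell + rotamer scans, no
    randomness; the returned energy never exceeds the input energy.
    """
    from .peptide import EXTENDED_PHI, EXTENDED_PSI, OMEGA_TRANS

    top = pose.topology
    starts = [pose]
    t = pose.torsions.copy()
    for s in top.all_chi_slots():
        t[s] = 180.0
    starts.append(pose.with_updates(torsions=t))
    t2 = t.copy()
    for i in range(top.n_res):
        t2[top.slot[(i, "phi")]] = -75.0 if top.resnames[i] == "PRO" else EXTENDED_PHI
        t2[top.slot[(i, "psi")]] = EXTENDED_PSI
        t2[top.slot[(i, "omega")]] = OMEGA_TRANS
    starts.append(pose.with_updates(torsions=t2))

    best, best_e = pose, energy(pose)
    for s in starts:
        cand = _descent_pass(s, energy, params, passes)
        e = energy(cand)
        if e < best_e:
            best, best_e = cand, e
    return best


def run_docking(maps: GridMaps, ligand: PeptideConformation, params: MCParams,
                energy: Optional[DockingEnergy] = None) -> DockTrajectory:
    """Biased Monte Carlo with Metropolis acceptance over the grid.

    propose -> minimize locally -> accept with min(1, exp(-dG/RT)).  Loose
    harmonic restraints on the ligand Calpha positions are measured from
    the starting conformation (the probe-anchored extended ligand), which
    keeps the sampled molecule close to its start as intended; the sampled
    objective is energy + restraint, and poses record both it and the
    unrestrained docking energy.
    """
    energy = energy or DockingEnergy(maps)
    rng = np.random.default_rng(params.seed)
    traj = DockTrajectory(seed=params.seed)
    traj.rng_snapshots.append(rng.bit_generator.state)

    ref_ca = ligand.ca_coords().copy()

    def obj(lig):
        return energy(lig) + restraint_energy(lig, ref_ca, params.restraint_k)

    current = ligand
    cur_bd = energy.breakdown(current)
    cur_obj = cur_bd.total + restraint_energy(current, ref_ca, params.restraint_k)
    traj.best_pose, traj.best_energy, traj.best_breakdown = current, cur_obj, cur_bd
    traj.poses.append({"step": 0, "energy": cur_obj, "unrestrained": cur_bd.total,
                       "torsions": current.torsions.copy(),
                       "placement": current.placement.copy()})

    since_best = 0
    for step in range(1, params.n_steps + 1):
        prop = propose_move(current, params, rng)
        cand, obj_e = local_minimize(
            prop.conformation, obj, params,
            torsion_slots=prop.torsion_slots, rigid=prop.kind == "rigid")
        prop.dG = obj_e - cur_obj
        if metropolis_accept(prop.dG, params, rng):
            current = cand
            cur_bd = energy.breakdown(current)
            cur_obj = cur_bd.total + restraint_energy(current, ref_ca, params.restraint_k)
            traj.acceptance_count += 1
            traj.poses.append({"step": step, "energy": cur_obj,
                               "unrestrained": cur_bd.total,
                               "torsions": current.torsions.copy(),
                               "placement": current.placement.copy()})
            if cur_obj < traj.best_energy:
                traj.best_pose, traj.best_energy = current, cur_obj
                traj.best_breakdown = cur_bd
                since_best = 0
                traj.n_steps_run = step
                continue
        since_best += 1
        traj.n_steps_run = step
        if since_best >= params.early_stop:
            break
    traj.rng_snapshots.append(rng.bit_generator.state)
    return traj
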