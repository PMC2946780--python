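"""Docking box, binding-site selection, and receptor grid potential maps.

The docking box uses standardized class-specific dimensions
(35.36 x 35.52 x 35.79 A for class I, 58.32 x 56.36 x 48.87 A for class II)
centred on the groove-domain Calpha centroid.  Binding-site atoms are picked
by 5.00 A spheres laid along the groove's principal axis, and per-channel
potential maps are precomputed on a 1.00 A cubic lattice.  Ligand scoring
against the maps interpolates per atom per channel (tricubic, in a
root-transform space chosen so the steep fields interpolate accurately); a
node value is, by construction, exactly the direct receptor-field
evaluation at that node (the same field routine computes both), so grid
and direct routes differ only by interpolation error.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .energetics import (
    EnergyBreakdown,
    elec_kernel,
    hbond_kernel,
    hydrophobic_kernel,
    lj_att_kernel,
    lj_rep_kernel,
)
from .forcefield import AtomSet, ForceFieldParams, HYDROPHOBIC_CONTACT, default_params

GRID_SPACING = 1.00  # A, cubic node side
SITE_RADIUS = 5.00  # A, binding-site selection spheres
BOX_DIMS_CLASS_I = (35.36, 35.52, 35.79)
BOX_DIMS_CLASS_II = (58.32, 56.36, 48.87)
OUT_OF_BOX_PENALTY = 10.0  # kcal/mol per atom
MAP_MARGIN = 8.0  # receptor atoms within this of the box also enter the maps

CHANNELS = ("vdw_repulsive", "vdw_attractive", "electrostatic",
            "hbond_donor", "hbond_acceptor", "hydrophobic")

# Raw 1/r^n-type fields diverge like r^-12 at receptor atoms, and linear
# blending of such node values poisons the interpolated energy up to a
# lattice spacing away from every contact.  Maps therefore store each
# channel under a root transform that makes it vary roughly like 1/r
# (smooth on the lattice); interpolation happens in transform space and is
# inverted afterwards.  Node-coincident points still reproduce the direct
# field exactly, because the transform round-trips.
# the electrostatic field saturates smoothly (tanh) at +-40 kcal/(mol e)
# in the shared field routine: the 1/r^2 divergence inside charged atoms
# is physically meaningless (clash region) and would dominate
# interpolation error; at the field strengths ligand atoms actually reach
# (|phi| < 15) the saturation changes values by under 5%
ELEC_FIELD_CAP = 40.0

FIELD_TRANSFORM_POWER = {
    "vdw_repulsive": 12.0,   # non-negative field
    "vdw_attractive": 3.0,   # non-positive field (empirically most accurate)
    "electrostatic": 1.0,    # signed, stored as-is (root transforms cusp at 0)
    "hbond_donor": 1.0,      # bounded well, stored as-is
    "hbond_acceptor": 1.0,   # bounded well, stored as-is
    "hydrophobic": 1.0,      # bounded ramp, stored as-is
}


def _to_transform_space(vals: np.ndarray) -> np.ndarray:
    out = vals.copy()
    for k, c in enumerate(CHANNELS):
        p = FIELD_TRANSFORM_POWER[c]
        if p != 1.0:
            out[:, k] = np.sign(vals[:, k]) * np.abs(vals[:, k]) ** (1.0 / p)
    return out


def _from_transform_space(vals: np.ndarray) -> np.ndarray:
    out = vals.copy()
    for k, c in enumerate(CHANNELS):
        p = FIELD_TRANSFORM_POWER[c]
        if p != 1.0:
            out[:, k] = np.sign(vals[:, k]) * np.abs(vals[:, k]) ** p
    return out


@dataclass
class DockingBox:
    """Axis-aligned docking box: centre + (length, breadth, height), A."""

    center: np.ndarray
    dims: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, float)
        self.dims = np.asarray(self.dims, float)
        if not (self.dims > 0).all():
            raise ValueError("box dimensions must be positive")

    @property
    def lo(self) -> np.ndarray:
        return self.center - self.dims / 2.0

    @property
    def hi(self) -> np.ndarray:
        return self.center + self.dims / 2.0

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return ((p >= self.lo) & (p <= self.hi)).all(axis=1)

    def ensure_contains(self, points: np.ndarray, pad: float = 1.0) -> "DockingBox":
        """Expand (symmetrically about the centre) until all points fit."""
        if self.contains(points).all():
            return self
        need = 2.0 * np.abs(np.atleast_2d(points) - self.center).max(axis=0) + pad
        new = np.maximum(self.dims, need)
        warnings.warn("docking box expanded to enclose binding-site atoms")
        return DockingBox(self.center.copy(), new)


@dataclass
class BindingSite:
    """Receptor atoms within the selection spheres ('in and on')."""

    atom_indices: np.ndarray
    centers: np.ndarray
    radius: float = SITE_RADIUS


def groove_mask(receptor: AtomSet, mhc_class: str) -> np.ndarray:
    """Heuristic groove-domain mask over receptor atoms.

    Class I grooves sit on the first ~180 residues of the heavy chain; class
    II grooves on the first ~95 residues of each of the alpha and beta
    chains.  Short chains (synthetic groove walls, single-domain receptors)
    are included whole.
    """
    limit = 180 if mhc_class.upper() == "I" else 95
    res = receptor.resindex
    return np.asarray(res <= limit, bool)


def make_docking_box(receptor: AtomSet, mhc_class: str,
                     override_dims=None) -> DockingBox:
    """Standardized-dimension box centred on the groove Calpha centroid."""
    mhc_class = str(mhc_class).upper()
    if override_dims is not None:
        dims = np.asarray(override_dims, float)
    elif mhc_class == "I":
        dims = np.asarray(BOX_DIMS_CLASS_I)
    elif mhc_class == "II":
        dims = np.asarray(BOX_DIMS_CLASS_II)
    else:
        raise ValueError(f"unknown MHC class {mhc_class!r} and no override dims")
    mask = groove_mask(receptor, mhc_class if mhc_class in ("I", "II") else "I")
    ca = mask & np.asarray([n == "CA" for n in receptor.names])
    pts = receptor.coords[ca] if ca.any() else receptor.coords
    return DockingBox(pts.mean(axis=0), dims)


def groove_axis(receptor: AtomSet, mhc_class: str) -> np.ndarray:
    """First principal axis of the groove-domain Calpha cloud (unit vector)."""
    mask = groove_mask(receptor, mhc_class)
    ca = mask & np.asarray([n == "CA" for n in receptor.names])
    pts = receptor.coords[ca] if ca.any() else receptor.coords
    centred = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    return axis / np.linalg.norm(axis)


def groove_opening(receptor: AtomSet, box: DockingBox, mhc_class: str,
                   maps: "GridMaps") -> np.ndarray:
    """Unit vector pointing out of the groove (floor -> solvent).

    The third principal axis of the groove Calpha cloud, signed toward the
    face of the box where the repulsive receptor field is weaker — the
    open mouth of the cleft rather than its floor.
    """
    mask = groove_mask(receptor, mhc_class)
    ca = mask & np.asarray([n == "CA" for n in receptor.names])
    pts = receptor.coords[ca] if ca.any() else receptor.coords
    centred = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    v = vt[2] / np.linalg.norm(vt[2])
    # compare repulsion just above vs just below the groove centre, within
    # the groove column (far-field vacuum on either side is uninformative)
    axis = vt[0] / np.linalg.norm(vt[0])
    nodes = maps.node_coords()
    rel = nodes - box.center[None, :]
    proj = rel @ v
    lateral = rel - np.outer(proj, v)
    lateral -= np.outer(lateral @ axis, axis)
    near_axis = np.linalg.norm(lateral, axis=1) < 5.0
    rep = np.clip(maps.channels["vdw_repulsive"].ravel(), 0.0, 100.0)
    sel_up = near_axis & (proj > 2.0) & (proj < 8.0)
    sel_dn = near_axis & (proj < -2.0) & (proj > -8.0)
    up = rep[sel_up].mean() if sel_up.any() else np.inf
    down = rep[sel_dn].mean() if sel_dn.any() else np.inf
    return v if up <= down else -v


def select_binding_site(receptor: AtomSet, box: DockingBox,
                        radius: float = SITE_RADIUS, mhc_class: str = "I",
                        centers: np.ndarray | None = None,
                        center_spacing: float = 1.5) -> BindingSite:
    """Atoms at distance <= radius from any selection sphere centre.

    Default centres: a chain of points every ``center_spacing`` Angstrom
    along the groove principal axis, spanning the central 60% of the box
    length, each replicated on a small cross-section pattern (+-2.5 A in
    the two perpendicular directions) — spheres from and around the groove
    centre, covering walls and floor linings without gaps.
    """
    if centers is None:
        mask = groove_mask(receptor, mhc_class)
        ca = mask & np.asarray([n == "CA" for n in receptor.names])
        pts = receptor.coords[ca] if ca.any() else receptor.coords
        _, _, vt = np.linalg.svd(pts - pts.mean(axis=0), full_matrices=False)
        axis, perp1, perp2 = (v / np.linalg.norm(v) for v in vt)
        half_span = 0.3 * box.dims[0]
        n_centers = max(2, int(np.ceil(2 * half_span / center_spacing)) + 1)
        along = np.linspace(-half_span, half_span, n_centers)
        cross = [(0.0, 0.0)] + [(a, b) for a in (-2.5, 0.0, 2.5)
                                for b in (-2.5, 0.0, 2.5) if (a, b) != (0.0, 0.0)]
        centers = np.array([
            box.center + t * axis + dy * perp1 + dz * perp2
            for t in along for dy, dz in cross])
    centers = np.atleast_2d(np.asarray(centers, float))
    diff = receptor.coords[:, None, :] - centers[None, :, :]
    d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    sel = np.flatnonzero((d <= radius).any(axis=1))
    if len(sel) == 0:
        warnings.warn("binding-site selection is empty")
    return BindingSite(sel, centers, radius)


def _field_coeffs(atoms: AtomSet, params: ForceFieldParams):
    a, b = params.lj_coeffs(atoms.cls)
    return {
        "vdw_repulsive": a,
        "vdw_attractive": b,
        "electrostatic": atoms.charge,
        "hbond_donor": atoms.is_acceptor.astype(float),   # field felt by ligand donors
        "hbond_acceptor": atoms.is_donor.astype(float),   # field felt by ligand acceptors
        "hydrophobic": params.hydro_strength(atoms.cls),
    }


def receptor_fields(atoms: AtomSet, points: np.ndarray,
                    params: ForceFieldParams | None = None,
                    chunk: int = 2048) -> np.ndarray:
    """(n_points, 6) per-channel receptor field values at arbitrary points.

    This single routine backs both grid construction (points = lattice
    nodes) and direct evaluation (points = ligand atom positions), which is
    what makes node-coincident grid and direct energies agree exactly.
    """
    params = params or default_params()
    coeff = _field_coeffs(atoms, params)
    out = np.zeros((len(points), len(CHANNELS)))
    for s in range(0, len(points), chunk):
        p = points[s:s + chunk]
        diff = p[:, None, :] - atoms.coords[None, :, :]
        r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        out[s:s + chunk, 0] = lj_rep_kernel(r, params) @ coeff["vdw_repulsive"]
        out[s:s + chunk, 1] = lj_att_kernel(r, params) @ coeff["vdw_attractive"]
        out[s:s + chunk, 2] = ELEC_FIELD_CAP * np.tanh(
            (elec_kernel(r, params) @ coeff["electrostatic"]) / ELEC_FIELD_CAP)
        hb = hbond_kernel(r, params)
        out[s:s + chunk, 3] = hb @ coeff["hbond_donor"]
        out[s:s + chunk, 4] = hb @ coeff["hbond_acceptor"]
        out[s:s + chunk, 5] = hydrophobic_kernel(r, params) @ coeff["hydrophobic"]
    return out


def _catmull_rom_weights(t: np.ndarray) -> np.ndarray:
    """(n, 4) cubic interpolation weights for fractional offsets t in [0,1)."""
    t2, t3 = t * t, t * t * t
    return np.stack([
        0.5 * (-t + 2.0 * t2 - t3),
        0.5 * (2.0 - 5.0 * t2 + 3.0 * t3),
        0.5 * (t + 4.0 * t2 - 3.0 * t3),
        0.5 * (-t2 + t3),
    ], axis=1)


@dataclass
class GridMaps:
    """Per-channel potential arrays over the docking box at fixed spacing."""

    origin: np.ndarray
    spacing: float
    shape: tuple[int, int, int]
    channels: dict[str, np.ndarray]
    box: DockingBox
    included: AtomSet = field(repr=False, default=None)  # receptor atoms in the maps
    out_of_box_penalty: float = OUT_OF_BOX_PENALTY
    params_checksum: str = ""

    def _stack(self) -> np.ndarray:
        s = getattr(self, "_stacked", None)
        if s is None:
            s = np.stack([self.channels[c] for c in CHANNELS], axis=-1)
            self._stacked = s
        return s

    def node_coords(self) -> np.ndarray:
        ax = [self.origin[k] + self.spacing * np.arange(self.shape[k]) for k in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def interpolate(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-channel field values at points; returns (values, inside).

        Tricubic (Catmull-Rom) interpolation in the root-transform space
        the maps are stored in, inverted before returning, so values are on
        the raw field scale.  Catmull-Rom weights reproduce node values
        exactly and are C1 between nodes.  Values for points outside the
        box are zero (callers apply the out-of-box penalty); points in the
        thin margin between the lattice hull and the box face are clamped
        onto the hull.
        """
        points = np.atleast_2d(points)
        inside = self.box.contains(points)
        vals = np.zeros((len(points), len(CHANNELS)))
        if inside.any():
            p = points[inside]
            f = (p - self.origin) / self.spacing
            hi = np.asarray(self.shape) - 1
            f = np.clip(f, 0.0, hi - 1e-9)
            i0 = np.minimum(f.astype(int), hi - 1)
            t = f - i0
            w = [_catmull_rom_weights(t[:, k]) for k in range(3)]
            acc = np.zeros((len(p), len(CHANNELS)))
            stack = self._stack()
            for dx in range(4):
                ix = np.clip(i0[:, 0] + dx - 1, 0, hi[0])
                for dy in range(4):
                    iy = np.clip(i0[:, 1] + dy - 1, 0, hi[1])
                    for dz in range(4):
                        iz = np.clip(i0[:, 2] + dz - 1, 0, hi[2])
                        ww = (w[0][:, dx] * w[1][:, dy] * w[2][:, dz])[:, None]
                        acc += ww * stack[ix, iy, iz]
            vals[inside] = _from_transform_space(acc)
        return vals, inside


def build_grid_maps(receptor: AtomSet, site: BindingSite, box: DockingBox,
                    params: ForceFieldParams | None = None,
                    spacing: float = GRID_SPACING) -> GridMaps:
    """Precompute per-channel receptor potential maps over the box.

    The field sums over binding-site atoms plus every receptor atom within
    8 A of the box, which bounds map cost without materially changing
    near-field values.
    """
    params = params or default_params()
    near = ((receptor.coords > (box.lo - MAP_MARGIN)[None, :])
            & (receptor.coords < (box.hi + MAP_MARGIN)[None, :])).all(axis=1)
    mask = near.copy()
    mask[site.atom_indices] = True
    included = receptor.subset(mask)

    shape = tuple(int(np.floor(d / spacing)) + 1 for d in box.dims)
    extent = (np.asarray(shape) - 1) * spacing
    origin = box.center - extent / 2.0
    maps = GridMaps(origin=origin, spacing=spacing, shape=shape, channels={},
                    box=box, included=included,
                    params_checksum=params.checksum())
    vals = _to_transform_space(receptor_fields(included, maps.node_coords(), params))
    for k, c in enumerate(CHANNELS):
        maps.channels[c] = np.ascontiguousarray(vals[:, k].reshape(shape))
    return maps


def _ligand_coeffs(ligand, params: ForceFieldParams):
    top = ligand.topology
    a, b = params.lj_coeffs(top.cls)
    return (a, b, top.charge, top.is_donor.astype(float),
            top.is_acceptor.astype(float),
            HYDROPHOBIC_CONTACT * params.hydro_strength(top.cls))


def _assemble(vals: np.ndarray, inside: np.ndarray, ligand, params,
              penalty: float) -> EnergyBreakdown:
    a, b, q, don, acc, hp = _ligand_coeffs(ligand, params)
    cap = params.pair_cap
    e_vw = np.clip(a * vals[:, 0] + b * vals[:, 1], -cap, cap)
    e_el = np.clip(q * vals[:, 2], -cap, cap)
    e_hb = np.clip(don * vals[:, 3] + acc * vals[:, 4], -cap, cap)
    e_hp = np.clip(hp * vals[:, 5], -cap, cap)
    out = ~inside
    bd = EnergyBreakdown(
        e_vw=float(e_vw[inside].sum()) + penalty * int(out.sum()),
        e_el=float(e_el[inside].sum()),
        e_hb=float(e_hb[inside].sum()),
        e_hp=float(e_hp[inside].sum()),
    )
    bd.e_elec = bd.e_el
    return bd


def grid_energy(maps: GridMaps, ligand, params: ForceFieldParams | None = None) -> EnergyBreakdown:
    """Receptor-ligand energy terms from the maps (intra-ligand NOT included)."""
    params = params or default_params()
    vals, inside = maps.interpolate(ligand.coords)
    return _assemble(vals, inside, ligand, params, maps.out_of_box_penalty)


def direct_receptor_energy(maps: GridMaps, ligand,
                           params: ForceFieldParams | None = None) -> EnergyBreakdown:
    """Exact (non-interpolated) receptor-ligand terms, same conventions as
    :func:`grid_energy` — the oracle the maps are validated against."""
    params = params or default_params()
    inside = maps.box.contains(ligand.coords)
    vals = np.zeros((len(ligand.coords), len(CHANNELS)))
    if inside.any():
        vals[inside] = receptor_fields(maps.included, ligand.coords[inside], params)
    return _assemble(vals, inside, ligand, params, maps.out_of_box_penalty)


def per_atom_interaction(maps: GridMaps, ligand, params: ForceFieldParams | None = None,
                         direct: bool = False) -> np.ndarray:
    """(n_atoms, 4) per-atom receptor-ligand energies: vdW, elec, hbond, hp.

    ``direct=True`` evaluates the fields exactly at the atom positions;
    otherwise values come from map interpolation.  Out-of-box atoms carry
    the penalty in the vdW column.  This is the quantity the grid/direct
    oracle compares.
    """
    params = params or default_params()
    if direct:
        inside = maps.box.contains(ligand.coords)
        vals = np.zeros((len(ligand.coords), len(CHANNELS)))
        if inside.any():
            vals[inside] = receptor_fields(maps.included, ligand.coords[inside], params)
    else:
        vals, inside = maps.interpolate(ligand.coords)
    a, b, q, don, acc, hp = _ligand_coeffs(ligand, params)
    cap = params.pair_cap
    out = np.zeros((len(ligand.coords), 4))
    out[:, 0] = np.clip(a * vals[:, 0] + b * vals[:, 1], -cap, cap)
    out[:, 1] = np.clip(q * vals[:, 2], -cap, cap)
    out[:, 2] = np.clip(don * vals[:, 3] + acc * vals[:, 4], -cap, cap)
    out[:, 3] = np.clip(hp * vals[:, 5], -cap, cap)
    out[~inside] = 0.0
    out[~inside, 0] = maps.out_of_box_penalty
    return out


def save_maps(maps: GridMaps, path) -> None:
    """Cache maps as .npz alongside a JSON header (origin, spacing, dims)."""
    import pathlib

    path = pathlib.Path(path)
    np.savez_compressed(path, **{c: maps.channels[c] for c in CHANNELS})
    header = {
        "origin": maps.origin.tolist(), "spacing": maps.spacing,
        "shape": list(maps.shape), "channels": list(CHANNELS),
        "box_center": maps.box.center.tolist(), "box_dims": maps.box.dims.tolist(),
        "out_of_box_penalty": maps.out_of_box_penalty,
        "params_checksum": maps.params_checksum,
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=1))
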