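"""Docking box, binding-site spheres, grid maps and interpolation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from peptigrid.forcefield import AtomSet
from peptigrid.gridding import (
    BOX_DIMS_CLASS_I,
    BOX_DIMS_CLASS_II,
    DockingBox,
    build_grid_maps,
    grid_energy,
    make_docking_box,
    receptor_fields,
    select_binding_site,
)


def test_class_default_box_dimensions_are_exact(receptor):
    box_i = make_docking_box(receptor, "I")
    assert tuple(box_i.dims) == BOX_DIMS_CLASS_I == (35.36, 35.52, 35.79)
    box_ii = make_docking_box(receptor, "II")
    assert tuple(box_ii.dims) == BOX_DIMS_CLASS_II == (58.32, 56.36, 48.87)
    with pytest.raises(ValueError):
        make_docking_box(receptor, "III")
    over = make_docking_box(receptor, "III", override_dims=(20, 20, 20))
    assert tuple(over.dims) == (20.0, 20.0, 20.0)


def test_box_encloses_native_peptide(workspace, native):
    assert workspace.box.contains(native.coords).all()


def test_binding_site_sphere_boundary_is_inclusive(params):
    """Atoms exactly on a 5.00 A sphere are selected ('in and on')."""
    centers = np.zeros((1, 3))
    coords = np.array([[5.0, 0, 0], [5.01, 0, 0], [1.0, 0, 0]])
    rec = AtomSet(
        coords=coords, cls=np.zeros(3, int), charge=np.zeros(3),
        is_donor=np.zeros(3, bool), is_acceptor=np.zeros(3, bool),
        names=["CA"] * 3, resnames=["ALA"] * 3, resindex=np.arange(1, 4),
        chains=["A"] * 3, is_backbone=np.ones(3, bool))
    box = DockingBox(np.zeros(3), np.array([20.0, 20, 20]))
    site = select_binding_site(rec, box, radius=5.00, centers=centers)
    assert site.atom_indices.tolist() == [0, 2]


def test_binding_site_counts_constructed_atoms(workspace, receptor):
    """Every selected atom lies within 5.00 A of some sphere centre."""
    site = workspace.site
    assert len(site.atom_indices) > 0
    d = np.linalg.norm(
        receptor.coords[site.atom_indices][:, None, :] - site.centers[None, :, :],
        axis=-1).min(axis=1)
    assert (d <= 5.00 + 1e-9).all()


def test_grid_shape_follows_spacing_rule(workspace):
    maps = workspace.maps
    expected = tuple(int(np.floor(d / 1.0)) + 1 for d in maps.box.dims)
    assert maps.shape == expected
    assert maps.spacing == 1.00
    for arr in maps.channels.values():
        assert np.isfinite(arr).all()


def test_far_node_fields_are_negligible(workspace):
    maps = workspace.maps
    corner = maps.box.center + maps.box.dims / 2.0 - 0.5
    vals = receptor_fields(maps.included, corner[None, :])
    assert np.abs(vals).max() < 1.0


def test_node_values_equal_direct_field_evaluation(workspace, rng):
    """Interpolating exactly at nodes reproduces the direct field, to 1e-9
    (after inverting the storage transform)."""
    maps = workspace.maps
    nodes = maps.node_coords()
    pick = rng.choice(len(nodes), size=20, replace=False)
    direct = receptor_fields(maps.included, nodes[pick])
    vals, inside = maps.interpolate(nodes[pick])
    assert inside.all()
    scale = np.maximum(1.0, np.abs(direct))
    assert (np.abs(direct - vals) / scale).max() < 1e-9


def test_interpolation_identity_on_nodes(workspace, native):
    """A point exactly on a node interpolates to that node's field value."""
    maps = workspace.maps
    node = maps.origin + maps.spacing * np.array([10, 12, 14])
    vals, inside = maps.interpolate(node[None, :])
    assert inside.all()
    expect = receptor_fields(maps.included, node[None, :])[0]
    scale = np.maximum(1.0, np.abs(expect))
    assert (np.abs(vals[0] - expect) / scale).max() < 1e-12


def test_ligand_outside_box_pays_per_atom_penalty(workspace, native):
    far = native.transformed(Rotation.identity(), np.array([500.0, 0, 0]))
    bd = grid_energy(workspace.maps, far)
    n = len(far.coords)
    assert bd.e_vw == pytest.approx(n * workspace.maps.out_of_box_penalty)
    assert bd.e_el == bd.e_hb == bd.e_hp == 0.0


def _perturbed_poses(native, rng, n):
    for _ in range(n):
        rot = Rotation.from_rotvec(rng.normal(scale=0.12, size=3))
        shift = rng.normal(scale=1.0, size=3)
        t = native.torsions.copy()
        chi = native.topology.all_chi_slots()
        t[chi] += rng.uniform(-40, 40, len(chi))
        yield native.with_updates(torsions=t).transformed(rot, shift)


def test_grid_direct_equivalence_on_random_poses(workspace, native, rng):
    """Per-atom interpolated energies track the direct field evaluation
    over sampled near-groove poses; whole-pose sums stay within a few
    kcal/mol of the direct route."""
    from peptigrid.gridding import per_atom_interaction

    atom_errs, pose_errs = [], []
    for pose in _perturbed_poses(native, rng, 40):
        g = per_atom_interaction(workspace.maps, pose)
        d = per_atom_interaction(workspace.maps, pose, direct=True)
        atom_errs.append(np.abs(g - d).sum(axis=1))
        pose_errs.append(abs(g.sum() - d.sum()))
    atom_errs = np.concatenate(atom_errs)
    assert np.median(atom_errs) < 0.5
    # coarse whole-pose sanity for this deliberately rough pose ensemble
    assert np.median(pose_errs) < 10.0


def test_maps_depend_only_on_receptor(receptor, workspace, params):
    """Rebuilding the maps yields bit-identical arrays (no ligand input)."""
    rebuilt = build_grid_maps(receptor, workspace.site, workspace.box, params)
    for c in workspace.maps.channels:
        assert np.array_equal(rebuilt.channels[c], workspace.maps.channels[c])


def test_finer_spacing_reduces_interpolation_error(receptor, params, native, rng):
    """Halving the node spacing strictly reduces the median grid error."""
    center = native.coords.mean(axis=0)
    box = DockingBox(center, np.array([14.0, 14.0, 14.0]))
    site = select_binding_site(receptor, box)
    maps1 = build_grid_maps(receptor, site, box, params, spacing=1.0)
    maps2 = build_grid_maps(receptor, site, box, params, spacing=0.5)
    errs1, errs2 = [], []
    for _ in range(30):
        pts = center + rng.uniform(-4, 4, size=(12, 3))
        ref = receptor_fields(maps1.included, pts, params)
        v1, _ = maps1.interpolate(pts)
        ref2 = receptor_fields(maps2.included, pts, params)
        v2, _ = maps2.interpolate(pts)
        errs1.append(np.abs(v1 - ref).sum())
        errs2.append(np.abs(v2 - ref2).sum())
    assert np.median(errs2) < np.median(errs1)


def test_box_expansion_warns_and_contains():
    box = DockingBox(np.zeros(3), np.array([10.0, 10, 10]))
    pts = np.array([[8.0, 0, 0]])
    with pytest.warns(UserWarning):
        grown = box.ensure_contains(pts)
    assert grown.contains(pts).all()
    assert box.ensure_contains(np.array([[1.0, 0, 0]])) is box
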