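"""RMSD metric, register detection, correctness calls, dataset filtering,
interface refinement."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from peptigrid.fixtures import FixtureSpec, generate_mini_groove
from peptigrid.peptide import from_sequence
from peptigrid.refine_eval import (
    DatasetEntry,
    RegisterAssignment,
    ca_rmsd,
    clash_count,
    classify_correct,
    detect_register,
    refine_interface,
    select_nonredundant,
)
from peptigrid.structure_io import peptide_conformation, receptor_atom_set


# ---------------------------------------------------------------------------
# Calpha RMSD
# ---------------------------------------------------------------------------

def test_rmsd_zero_on_identity(native):
    assert ca_rmsd(native, native) == 0.0


def test_rmsd_of_uniform_translation_is_exact(native):
    moved = native.transformed(Rotation.identity(), np.array([0, 0, 1.3]))
    assert ca_rmsd(moved, native) == pytest.approx(1.30, abs=1e-9)


def test_rmsd_matches_brute_force(rng):
    a = from_sequence("ALAVNAALA")
    t = a.torsions + rng.uniform(-30, 30, a.topology.n_torsions)
    b = a.with_updates(torsions=t)
    expected = np.sqrt(np.mean([
        np.linalg.norm(a.ca_coords()[i] - b.ca_coords()[i]) ** 2
        for i in range(9)]))
    assert ca_rmsd(a, b) == pytest.approx(expected, rel=1e-12)


def test_rmsd_is_a_metric_on_conformations(rng):
    base = from_sequence("ALAVNAALA")
    confs = []
    for _ in range(3):
        t = base.torsions + rng.uniform(-20, 20, base.topology.n_torsions)
        pl = np.concatenate([rng.uniform(-0.3, 0.3, 3), rng.uniform(-2, 2, 3)])
        confs.append(base.with_updates(torsions=t, placement=pl))
    a, b, c = confs
    assert ca_rmsd(a, b) == pytest.approx(ca_rmsd(b, a), rel=1e-12)
    assert ca_rmsd(a, b) >= 0
    assert ca_rmsd(a, c) <= ca_rmsd(a, b) + ca_rmsd(b, c) + 1e-12


def test_rmsd_rejects_sequence_mismatch():
    a = from_sequence("ALAVNAALA")
    b = from_sequence("ALAVNAALG")
    with pytest.raises(ValueError, match="mismatch"):
        ca_rmsd(a, b)


def test_rmsd_uses_core_window_for_long_peptides():
    """For a 13-mer, only the 9 core residues enter the RMSD: displacing a
    flank residue changes nothing."""
    a = from_sequence("AAALAVNAALAAA")
    t = a.torsions.copy()
    t[a.topology.slot[(0, "psi")]] += 60.0  # moves only residue 1's tail
    b = a.with_updates(torsions=t)
    reg = RegisterAssignment(start=3)
    core_ids = list(range(2, 11))
    d = a.ca_coords()[core_ids] - b.ca_coords()[core_ids]
    expected = float(np.sqrt(np.mean(np.einsum("ij,ij->i", d, d))))
    assert ca_rmsd(a, b, reg) == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# correctness threshold
# ---------------------------------------------------------------------------

def test_correct_dock_threshold_is_inclusive():
    assert classify_correct(2.50) is True  # "at most" 2.50
    assert classify_correct(2.51) is False
    assert classify_correct(0.56) is True
    with pytest.raises(ValueError):
        classify_correct(-0.1)


# ---------------------------------------------------------------------------
# register detection
# ---------------------------------------------------------------------------

def test_nine_mer_register_is_one(native, workspace):
    site = workspace.receptor.coords[workspace.site.atom_indices]
    reg = detect_register(native, site)
    assert reg.start == 1 and not reg.whole_peptide


def test_short_peptide_flagged_whole(workspace):
    p8 = from_sequence("ALAVNAAL")
    site = workspace.receptor.coords[workspace.site.atom_indices]
    reg = detect_register(p8, site)
    assert reg.start == 1 and reg.whole_peptide


def test_constructed_register_recovered_on_13mer():
    spec = FixtureSpec(peptide_length=13, register_start=3, seed=4321,
                       relax_native=False)
    cpx, truth = generate_mini_groove(spec)
    assert truth["register_start"] == 3
    native = peptide_conformation(cpx)
    from peptigrid.gridding import make_docking_box, select_binding_site

    rec = receptor_atom_set(cpx)
    box = make_docking_box(rec, "I")
    site = select_binding_site(rec, box)
    reg = detect_register(native, rec.coords[site.atom_indices])
    assert reg.start == 3


def test_tied_windows_take_smallest_start():
    """With no contacts at all, every window ties at zero and the first
    window wins."""
    p = from_sequence("A" * 12)
    far_site = np.array([[999.0, 999.0, 999.0]])
    assert detect_register(p, far_site).start == 1


# ---------------------------------------------------------------------------
# dataset non-redundancy
# ---------------------------------------------------------------------------

def test_highest_resolution_entry_wins():
    a = DatasetEntry("1aaa", "ALAVNAALA", "HLA-A*0201", 2.4)
    b = DatasetEntry("2bbb", "ALAVNAALA", "HLA-A*0201", 1.8)
    kept = select_nonredundant([a, b])
    assert kept == [b]


def test_single_entry_kept():
    e = DatasetEntry("1aaa", "ALAVNAALA", "HLA-A*0201", 2.0)
    assert select_nonredundant([e]) == [e]


def test_tr_type_separates_groups():
    a = DatasetEntry("1aaa", "ALAVNAALA", "HLA-A*0201", 2.4, tr_type="AB")
    b = DatasetEntry("2bbb", "ALAVNAALA", "HLA-A*0201", 1.8, tr_type="GD")
    kept = select_nonredundant([a, b])
    assert len(kept) == 2


def test_resolution_tie_breaks_by_pdb_id():
    a = DatasetEntry("2bbb", "ALAVNAALA", "X", 2.0)
    b = DatasetEntry("1aaa", "ALAVNAALA", "X", 2.0)
    assert select_nonredundant([a, b]) == [b]


def test_selection_is_idempotent():
    entries = [
        DatasetEntry("1aaa", "ALAVNAALA", "X", 2.0),
        DatasetEntry("2bbb", "ALAVNAALA", "X", 1.5),
        DatasetEntry("3ccc", "GILGFVFTL", "X", 2.2),
        DatasetEntry("4ddd", "GILGFVFTL", "Y", 3.0, tr_type="AB"),
    ]
    once = select_nonredundant(entries)
    assert select_nonredundant(once) == once


def test_dataset_entry_validates_resolution():
    with pytest.raises(ValueError):
        DatasetEntry("1aaa", "ALAVNAALA", "X", 0.0)


# ---------------------------------------------------------------------------
# interface refinement
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def refined(native, receptor):
    return refine_interface(receptor, native), receptor, native


def test_refinement_never_increases_score(refined):
    res, _, _ = refined
    assert res.score_after <= res.score_before + 1e-9


def test_refinement_moves_only_the_mobile_set(refined):
    """Receptor atoms outside the 4.00 A interface come back bit-identical."""
    res, receptor, _ = refined
    frozen = ~res.mobile_receptor
    assert frozen.any()
    assert np.array_equal(res.receptor.coords[frozen], receptor.coords[frozen])
    # anything that did move belongs to the mobile set
    moved = np.any(res.receptor.coords != receptor.coords, axis=1)
    assert not (moved & frozen).any()


def test_refinement_resolves_engineered_clash(receptor, native, params):
    """Rotating an anchor side chain into the floor creates clashes that
    refinement strictly reduces."""
    top = native.topology
    t = native.torsions.copy()
    slots = top.chi_slots(1)  # anchor leucine
    t[slots[0]] += 95.0
    t[slots[1]] -= 80.0
    clashed = native.with_updates(torsions=t)
    n_before = clash_count(clashed.atom_set(), receptor, params)
    assert n_before > 0
    res = refine_interface(receptor, clashed, params=params)
    n_after = clash_count(res.pose.atom_set(), res.receptor, params)
    assert n_after < n_before


def test_unstrained_input_returned_essentially_unchanged(receptor, native):
    """A clash-free pose at a refinement minimum stays put (within the
    minimizer's tolerance)."""
    first = refine_interface(receptor, native)
    second = refine_interface(first.receptor, first.pose)
    assert ca_rmsd(second.pose, first.pose) < 0.35
    assert second.score_after <= first.score_after + 1e-9
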