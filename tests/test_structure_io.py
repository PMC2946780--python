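"""PDB I/O, chain classification, splitting and peptide preparation."""

import numpy as np
import pytest

from peptigrid.refine_eval import RegisterAssignment
from peptigrid.structure_io import (
    extract_core,
    peptide_conformation,
    read_pdb,
    receptor_atom_set,
    set_extended_conformation,
    split_complex,
    write_pdb,
)

FMT_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       2.000  -0.700   1.200  1.00  0.00           C
ATOM      6  N   GLY A   2       3.300   1.500   0.100  1.00  0.00           N
ATOM      7  CA AGLY A   2       4.000   2.700   0.200  0.60  0.00           C
ATOM      8  CA BGLY A   2       4.200   2.900   0.300  0.40  0.00           C
ATOM      9  C   GLY A   2       5.400   2.500   0.700  1.00  0.00           C
ATOM     10  O   GLY A   2       6.000   1.500   0.400  1.00  0.00           O
TER
ATOM     11  N   ALA B   1      10.000   0.000   0.000  1.00  0.00           N
ATOM     12  CA  ALA B   1      11.458   0.000   0.000  1.00  0.00           C
ATOM     13  C   ALA B   1      12.009   1.420   0.000  1.00  0.00           C
ATOM     14  O   ALA B   1      11.251   2.390   0.000  1.00  0.00           O
ATOM     15  CB  ALA B   1      12.000  -0.700   1.200  1.00  0.00           C
HETATM   16  C   FMT A 101      20.000  20.000  20.000  1.00  0.00           C
HETATM   17  O1  FMT A 101      21.000  20.500  20.000  1.00  0.00           O
HETATM   18  O2  FMT A 101      19.200  21.000  20.000  1.00  0.00           O
HETATM   19  O   HOH A 201       5.000   5.000   5.000  1.00  0.00           O
END
"""


def test_fixture_pdb_round_trip(tmp_path, groove_complex):
    """write -> read preserves atom counts, names, residues, coords (1e-3)."""
    p = tmp_path / "groove.pdb"
    write_pdb(groove_complex, p)
    back = read_pdb(p)
    assert back.peptide_sequence == groove_complex.peptide_sequence
    assert back.total_atom_count() == groove_complex.total_atom_count()
    for ch0, ch1 in zip(groove_complex.receptor_chains, back.receptor_chains):
        for r0, r1 in zip(ch0.residues, ch1.residues):
            assert r0.code == r1.code
            for a0, a1 in zip(r0.atoms, r1.atoms):
                assert a0.name == a1.name
                assert np.abs(a0.pos - a1.pos).max() < 1e-3


def test_fixture_classification(groove_complex):
    assert len(groove_complex.peptide) == 9
    assert groove_complex.mhc_class == "I"


def test_altloc_resolves_to_highest_occupancy(tmp_path):
    p = tmp_path / "alt.pdb"
    p.write_text(FMT_PDB)
    c = read_pdb(p, peptide_chain="A")
    gly = c.peptide.residues[1]
    ca = gly.atom("CA")
    assert ca.pos[0] == pytest.approx(4.000, abs=1e-3)  # altloc A, occ 0.6


def test_hetero_group_kept_separately_and_water_dropped(tmp_path):
    p = tmp_path / "fmt.pdb"
    p.write_text(FMT_PDB)
    c = read_pdb(p, peptide_chain="A")
    assert len(c.hetero_groups) == 1
    assert c.hetero_groups[0].residues[0].code == "FMT"
    # water never appears anywhere
    names = [r.code for g in c.hetero_groups for r in g.residues]
    assert "HOH" not in names


def test_include_hetero_adds_atoms_to_receptor(tmp_path):
    p = tmp_path / "fmt.pdb"
    p.write_text(FMT_PDB)
    c = read_pdb(p, peptide_chain="A")
    without = receptor_atom_set(c, include_hetero=False)
    with_h = receptor_atom_set(c, include_hetero=True)
    n_het = sum(len(r.atoms) for g in c.hetero_groups for r in g.residues)
    assert len(with_h) == len(without) + n_het == len(without) + 3


def test_split_partitions_all_atoms(groove_complex):
    rec, lig = split_complex(groove_complex)
    n_het = sum(len(r.atoms) for g in groove_complex.hetero_groups
                for r in g.residues)
    assert len(rec) + len(lig.coords) + n_het == groove_complex.total_atom_count()


def test_extracted_ligand_keeps_crystal_coordinates(groove_complex):
    """Before any randomization, the ligand is a verbatim coordinate copy."""
    lig = peptide_conformation(groove_complex)
    src = np.array([a.pos for r in groove_complex.peptide.residues for a in r.atoms])
    assert np.abs(lig.coords - src).max() < 1e-12


def test_malformed_and_unclassifiable_inputs_raise(tmp_path):
    bad = tmp_path / "bad.pdb"
    bad.write_text("ATOM  oops\n")
    with pytest.raises(ValueError):
        read_pdb(bad)
    single = tmp_path / "single.pdb"
    single.write_text("\n".join(FMT_PDB.splitlines()[:10]) + "\nEND\n")
    with pytest.raises(ValueError, match="classification"):
        read_pdb(single)


def test_set_extended_conformation_contract(native, workspace):
    a = set_extended_conformation(native, seed=11, box=workspace.box)
    b = set_extended_conformation(native, seed=11, box=workspace.box)
    top = native.topology
    # same seed -> identical torsions; all omega trans; phi/psi extended
    assert np.array_equal(a.torsions, b.torsions)
    assert np.array_equal(a.placement, b.placement)
    for i in range(top.n_res):
        assert a.torsions[top.slot[(i, "omega")]] == 180.0
        assert a.torsions[top.slot[(i, "phi")]] == -139.0
        assert a.torsions[top.slot[(i, "psi")]] == 135.0
    # different seed -> different chi draw
    c = set_extended_conformation(native, seed=12, box=workspace.box)
    assert not np.array_equal(a.torsions, c.torsions)
    assert workspace.box.contains(a.placement[3:][None, :]).all()


def test_extract_core_windows():
    from peptigrid.peptide import from_sequence

    p8 = from_sequence("ALAVNAAL")
    assert extract_core(p8, RegisterAssignment(start=1)).tolist() == list(range(8))
    p13 = from_sequence("AAALAVNAALAAA")
    win = extract_core(p13, RegisterAssignment(start=3))
    assert win.tolist() == list(range(2, 11))  # residues 3..11, 0-based
    p9 = from_sequence("ALAVNAALA")
    assert extract_core(p9, RegisterAssignment(start=1)).tolist() == list(range(9))
    with pytest.raises(IndexError):
        extract_core(p13, RegisterAssignment(start=6))


def test_analogue_residues_map_to_parent(tmp_path):
    pdb = FMT_PDB.replace("ALA A   1", "ABA A   1")
    p = tmp_path / "ana.pdb"
    p.write_text(pdb)
    c = read_pdb(p, peptide_chain="A")
    res = c.peptide.residues[0]
    assert res.is_analogue and res.parent_code == "ALA" and res.code == "ABA"
    assert c.peptide_sequence[0] == "A"
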