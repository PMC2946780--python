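"""Energy terms: closed-form checks, brute-force oracles, invariances."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from peptigrid.energetics import (
    EnergyBreakdown,
    ScoringWeights,
    docking_score,
    electrostatic_energy,
    entropy_term,
    hbond_energy,
    hbond_kernel,
    hydrophobic_energy,
    hydrophobic_kernel,
    refinement_score,
    shrake_rupley_sasa,
    solvation_energy,
    torsion_energy,
    vdw_energy,
)
from peptigrid.forcefield import AtomSet, COULOMB_KCAL, HBOND_WELL_DEPTH, default_params
from peptigrid.peptide import from_sequence


def _atoms(coords, cls_name="C_ALI", charge=0.0, donor=False, acceptor=False,
           params=None):
    params = params or default_params()
    coords = np.atleast_2d(np.asarray(coords, float))
    n = len(coords)
    return AtomSet(
        coords=coords,
        cls=np.full(n, params.class_id(cls_name)),
        charge=np.full(n, charge),
        is_donor=np.full(n, donor),
        is_acceptor=np.full(n, acceptor),
        names=["X"] * n, resnames=["UNK"] * n,
        resindex=np.arange(1, n + 1), chains=["Z"] * n,
        is_backbone=np.zeros(n, bool),
    )


# ---------------------------------------------------------------------------
# scoring equations
# ---------------------------------------------------------------------------

def test_docking_score_reproduces_printed_weights():
    w = ScoringWeights()
    assert (w.w_el, w.w_hb, w.w_hp, w.w_solv) == (2.16, 2.53, 4.35, 0.20)
    assert docking_score(EnergyBreakdown()) == 0.0
    assert docking_score(EnergyBreakdown(e_hb=1.0)) == pytest.approx(2.53)
    ones = EnergyBreakdown(e_vw=1, e_en=1, e_el=1, e_hb=1, e_hp=1, e_solv=1)
    assert docking_score(ones) == pytest.approx(11.24)
    assert ones.total == pytest.approx(11.24)


def test_refinement_score_is_unweighted_sum(rng):
    assert refinement_score(EnergyBreakdown()) == 0.0
    assert refinement_score(EnergyBreakdown(e_tors=2.5)) == pytest.approx(2.5)
    vals = rng.normal(size=6)
    b = EnergyBreakdown(e_vw=vals[0], e_hb=vals[1], e_tors=vals[2],
                        e_elec=vals[3], e_solv=vals[4], e_en=vals[5])
    assert refinement_score(b) == pytest.approx(vals.sum())


def test_docking_and_refinement_scores_differ_in_general():
    b = EnergyBreakdown(e_vw=1, e_en=1, e_el=1, e_hb=1, e_hp=1, e_solv=1,
                        e_tors=1, e_elec=1)
    assert docking_score(b) != refinement_score(b)


# ---------------------------------------------------------------------------
# van der Waals
# ---------------------------------------------------------------------------

def test_vdw_pair_at_minimum_distance_gives_minus_well_depth(params):
    rmin = 2.0 * 2.0  # two C_ALI atoms
    a = _atoms([[0, 0, 0]])
    b = _atoms([[rmin, 0, 0]])
    assert vdw_energy(a, b, params) == pytest.approx(-0.15, abs=1e-9)


def test_vdw_zero_beyond_cutoff(params):
    a = _atoms([[0, 0, 0]])
    b = _atoms([[50.0, 0, 0]])
    assert vdw_energy(a, b, params) == 0.0


def test_vdw_matches_brute_force_double_loop(params, rng):
    pts1 = rng.uniform(0, 6, (10, 3))
    pts2 = rng.uniform(2, 8, (10, 3)) + np.array([4.0, 0, 0])
    a, b = _atoms(pts1), _atoms(pts2)
    from peptigrid.energetics import lj_att_kernel, lj_rep_kernel

    ca, cb = params.lj_coeffs(a.cls), params.lj_coeffs(b.cls)
    expected = 0.0
    for i in range(10):
        for j in range(10):
            r = np.array([np.linalg.norm(pts1[i] - pts2[j])])
            e = (ca[0][i] * cb[0][j] * lj_rep_kernel(r, params)
                 + ca[1][i] * cb[1][j] * lj_att_kernel(r, params))[0]
            expected += np.clip(e, -100, 100)
    assert vdw_energy(a, b, params) == pytest.approx(expected, rel=1e-12)


def test_vdw_pair_energy_is_capped_for_clashes(params):
    a = _atoms([[0, 0, 0]])
    b = _atoms([[0.05, 0, 0]])
    assert vdw_energy(a, b, params) == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# electrostatics, eps = 4r
# ---------------------------------------------------------------------------

def test_electrostatics_fall_as_inverse_square():
    """Doubling the separation divides the energy by four (eps = 4r)."""
    a = _atoms([[0, 0, 0]], charge=1.0)
    b1 = _atoms([[3.0, 0, 0]], charge=-1.0)
    b2 = _atoms([[6.0, 0, 0]], charge=-1.0)
    e1, e2 = electrostatic_energy(a, b1), electrostatic_energy(a, b2)
    assert e1 == pytest.approx(4.0 * e2, rel=1e-9)
    assert e1 == pytest.approx(-COULOMB_KCAL / (4.0 * 9.0), rel=1e-9)


def test_electrostatics_zero_charge_gives_zero():
    a = _atoms([[0, 0, 0]], charge=0.0)
    b = _atoms([[3.0, 0, 0]], charge=-1.0)
    assert electrostatic_energy(a, b) == 0.0


def test_electrostatics_match_brute_force(params, rng):
    pts1 = rng.uniform(0, 5, (6, 3))
    pts2 = rng.uniform(0, 5, (6, 3)) + np.array([5.0, 0, 0])
    q1, q2 = rng.uniform(-1, 1, 6), rng.uniform(-1, 1, 6)
    a, b = _atoms(pts1), _atoms(pts2)
    a.charge, b.charge = q1, q2
    from peptigrid.energetics import elec_kernel

    expected = 0.0
    for i in range(6):
        for j in range(6):
            r = np.array([np.linalg.norm(pts1[i] - pts2[j])])
            expected += np.clip(q1[i] * q2[j] * elec_kernel(r, params), -100, 100)[0]
    assert electrostatic_energy(a, b, params) == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def test_hbond_zero_beyond_365(params):
    d = _atoms([[0, 0, 0]], "N_AMD", donor=True)
    a = _atoms([[3.70, 0, 0]], "O_CRB", acceptor=True)
    assert hbond_energy(d, a, params) == 0.0


def test_hbond_minimum_at_optimum_distance(params):
    d = _atoms([[0, 0, 0]], "N_AMD", donor=True)
    at = _atoms([[params.hbond_optimum, 0, 0]], "O_CRB", acceptor=True)
    e_opt = hbond_energy(d, at, params)
    assert e_opt == pytest.approx(-HBOND_WELL_DEPTH, rel=1e-6)
    for r in (2.5, 3.2, 3.5):
        other = _atoms([[r, 0, 0]], "O_CRB", acceptor=True)
        assert hbond_energy(d, other, params) >= e_opt


def test_hbond_continuous_at_cutoff(params):
    lo = hbond_kernel(np.array([3.649]), params)[0]
    hi = hbond_kernel(np.array([3.651]), params)[0]
    assert abs(lo - hi) < 1e-3


def test_hbond_requires_donor_acceptor_typing(params):
    d = _atoms([[0, 0, 0]], "C_ALI")  # not a donor
    a = _atoms([[2.9, 0, 0]], "O_CRB", acceptor=True)
    assert hbond_energy(d, a, params) == 0.0


# ---------------------------------------------------------------------------
# hydrophobic contacts
# ---------------------------------------------------------------------------

def test_hydrophobic_zero_beyond_contact_cutoff(params):
    a = _atoms([[0, 0, 0]])
    b = _atoms([[5.0, 0, 0]])
    assert hydrophobic_energy(a, b, params) == 0.0


def test_hydrophobic_polar_pairs_contribute_nothing(params):
    a = _atoms([[0, 0, 0]], "O_CRB")  # polar: strength 0
    b = _atoms([[3.0, 0, 0]])
    assert hydrophobic_energy(a, b, params) == 0.0


def test_hydrophobic_matches_brute_force(params, rng):
    pts1 = rng.uniform(0, 4, (8, 3))
    pts2 = rng.uniform(0, 4, (8, 3)) + np.array([2.0, 0, 0])
    a, b = _atoms(pts1), _atoms(pts2)
    from peptigrid.forcefield import HYDROPHOBIC_CONTACT

    expected = 0.0
    h = params.hydro_strength(a.cls)
    for i in range(8):
        for j in range(8):
            r = np.array([np.linalg.norm(pts1[i] - pts2[j])])
            expected += np.clip(
                HYDROPHOBIC_CONTACT * h[i] * h[j] * hydrophobic_kernel(r, params),
                -100, 100)[0]
    assert hydrophobic_energy(a, b, params) == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# solvation / SASA
# ---------------------------------------------------------------------------

def test_sasa_isolated_sphere_matches_analytic_area():
    rho = 1.8
    area = shrake_rupley_sasa(np.zeros((1, 3)), np.array([rho]))[0]
    exact = 4.0 * np.pi * (rho + 1.4) ** 2
    assert area == pytest.approx(exact, rel=0.02)


def test_sasa_two_atom_overlap_matches_independent_oracle():
    """Cross-check the packaged sampler against biotite's implementation."""
    import biotite.structure as struc

    coords = np.array([[0.0, 0, 0], [2.5, 0, 0]])
    radii = np.array([1.8, 1.6])
    mine = shrake_rupley_sasa(coords, radii, n_points=960)
    arr = struc.AtomArray(2)
    arr.coord = coords.astype(np.float32)
    arr.element = np.array(["C", "O"])
    theirs = struc.sasa(arr, vdw_radii=radii, point_number=2000, probe_radius=1.4)
    assert np.abs(mine - theirs).max() / theirs.max() < 0.02


def test_buried_atom_contributes_no_solvation(params):
    # central atom fully caged by 12 neighbours
    phi = np.pi * (1 + 5**0.5)
    k = np.arange(12) + 0.5
    cage = 2.4 * np.column_stack([
        np.cos(phi * k) * np.sin(np.arccos(1 - 2 * k / 12)),
        np.sin(phi * k) * np.sin(np.arccos(1 - 2 * k / 12)),
        1 - 2 * k / 12,
    ])
    coords = np.vstack([[0, 0, 0], cage])
    sasa = shrake_rupley_sasa(coords, np.full(13, 2.0))
    assert sasa[0] == 0.0


def test_entropy_term_behaviour(params, receptor):
    gly = from_sequence("GGGGG")
    assert entropy_term(gly, receptor, params) == 0.0
    lys = from_sequence("KKK")
    far = lys.transformed(Rotation.identity(), np.array([500.0, 0, 0]))
    assert entropy_term(far, receptor, params) == 0.0


def test_entropy_monotone_in_burial(params, receptor, native):
    """A groove-buried lysine pays more entropy than an exposed one, and
    always strictly less than the tabulated maximum."""
    lys = from_sequence("KKK")
    # place near the groove centre (partially buried)
    shift = native.coords.mean(axis=0) - lys.coords.mean(axis=0)
    near = lys.transformed(Rotation.identity(), shift)
    e_near = entropy_term(near, receptor, params)
    above = near.transformed(Rotation.identity(), np.array([0, 0, 12.0]))
    e_above = entropy_term(above, receptor, params)
    assert 0.0 < e_near < 3 * params.entropy_max("LYS")
    assert e_near > e_above


# ---------------------------------------------------------------------------
# invariances
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("fn", [vdw_energy, electrostatic_energy, hydrophobic_energy])
def test_pairwise_terms_are_symmetric(fn, params, rng):
    a = _atoms(rng.uniform(0, 5, (5, 3)), charge=0.3)
    b = _atoms(rng.uniform(3, 8, (5, 3)), charge=-0.2)
    assert fn(a, b, params) == pytest.approx(fn(b, a, params), rel=1e-12)


def test_rigid_motion_leaves_energies_unchanged(params, rng):
    pts1, pts2 = rng.uniform(0, 5, (6, 3)), rng.uniform(3, 9, (6, 3))
    a, b = _atoms(pts1, charge=0.4), _atoms(pts2, charge=-0.4)
    rot = Rotation.from_rotvec([0.3, -1.1, 0.7])
    shift = np.array([5.0, -2.0, 8.0])
    a2 = _atoms(rot.apply(pts1) + shift, charge=0.4)
    b2 = _atoms(rot.apply(pts2) + shift, charge=-0.4)
    for fn in (vdw_energy, electrostatic_energy, hydrophobic_energy):
        assert fn(a, b, params) == pytest.approx(fn(a2, b2, params), abs=1e-6)
    # surface sampling is the one non-analytic term: rotation changes the
    # energy only within the sampler's resolution (~0.3% here)
    e0, e1 = solvation_energy(a, params), solvation_energy(a2, params)
    assert e0 == pytest.approx(e1, rel=5e-3)


@pytest.mark.parametrize("kernel,cutoff", [
    ("lj", 8.0), ("elec", 8.0), ("hbond", 3.65), ("hydrophobic", 4.50),
])
def test_every_cutoff_is_continuous(kernel, cutoff, params):
    from peptigrid.energetics import elec_kernel, lj_att_kernel, lj_rep_kernel

    fns = {
        "lj": lambda r: lj_rep_kernel(r, params) + lj_att_kernel(r, params),
        "elec": lambda r: elec_kernel(r, params),
        "hbond": lambda r: hbond_kernel(r, params),
        "hydrophobic": lambda r: hydrophobic_kernel(r, params),
    }
    f = fns[kernel]
    eps = 1e-4
    below = f(np.array([cutoff - eps]))[0]
    above = f(np.array([cutoff + eps]))[0]
    assert abs(below - above) < 1e-3


def test_torsion_energy_minimal_for_trans_conformers():
    ext = from_sequence("ALAVNAALA")  # all omega/chi trans
    assert torsion_energy(ext) == pytest.approx(0.0, abs=1e-9)
    t = ext.torsions.copy()
    t[ext.topology.chi_slots(1)[0]] = 120.0  # eclipsed chi
    strained = ext.with_updates(torsions=t)
    assert torsion_energy(strained) > 1.0
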