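"""Structure I/O, residue correspondence, Kabsch superposition and refinement."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from qtykit import (
    Atom,
    StructureModel,
    TMTopology,
    build_correspondence,
    correspondence_coords,
    extract_tm_domain,
    kabsch_superpose,
    read_structure,
    refine_superpose,
    superpose_structures,
    write_pdb,
)


def ca_model(res_seqs, coords, chain="A", res_name="ALA"):
    return StructureModel([
        Atom(chain, r, "", res_name, "CA", "C", float(x), float(y), float(z))
        for r, (x, y, z) in zip(res_seqs, coords)
    ])


def helix_coords(n, rng=None, jitter=0.0):
    t = np.arange(n)
    xyz = np.column_stack([2.3 * np.cos(1.75 * t), 2.3 * np.sin(1.75 * t), 1.5 * t])
    if jitter:
        xyz = xyz + rng.normal(0, jitter, xyz.shape)
    return xyz


# ---------------------------------------------------------------- file I/O

MINIMAL_PDB = (
    "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00 10.00           C\n"
    "END\n"
)

ALTLOC_PDB = (
    "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60 10.00           C\n"
    "ATOM      2  CA BALA A   1       9.000   9.000   9.000  0.40 10.00           C\n"
    "ATOM      3  CB AALA A   1       1.000   0.000   0.000  0.50 10.00           C\n"
    "ATOM      4  CB BALA A   1       9.000   9.000   9.000  0.50 10.00           C\n"
    "END\n"
)

HETATM_ONLY_PDB = (
    "HETATM    1  O   HOH A 101       0.000   0.000   0.000  1.00 10.00           O\n"
    "HETATM    2 MG    MG A 102       1.000   1.000   1.000  1.00 10.00          MG\n"
    "END\n"
)

MINIMAL_MMCIF = """\
data_toy
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_seq_id
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_asym_id
ATOM 1 C CA . ALA A 1 1.000 2.000 3.000 1.00 10.00 42 B
"""


def test_read_minimal_pdb(tmp_path):
    p = tmp_path / "m.pdb"
    p.write_text(MINIMAL_PDB)
    model = read_structure(p, format="pdb")
    assert len(model) == 1
    a = model.atoms[0]
    assert (a.x, a.y, a.z) == (1.0, 2.0, 3.0)
    assert (a.chain, a.res_seq, a.res_name, a.atom_name, a.element) == ("A", 1, "ALA", "CA", "C")


def test_altloc_highest_occupancy_then_alphabetical(tmp_path):
    p = tmp_path / "alt.pdb"
    p.write_text(ALTLOC_PDB)
    model = read_structure(p)
    by_name = {a.atom_name: a for a in model.atoms}
    assert len(model) == 2
    assert by_name["CA"].altloc == "A" and by_name["CA"].x == 0.0  # occupancy 0.6 wins
    assert by_name["CB"].altloc == "A"  # tie 0.5/0.5 -> alphabetically first


def test_hetatm_only_file_is_empty_error(tmp_path):
    p = tmp_path / "het.pdb"
    p.write_text(HETATM_ONLY_PDB)
    with pytest.raises(ValueError, match="no ATOM records"):
        read_structure(p)


def test_read_mmcif_uses_auth_numbering(tmp_path):
    p = tmp_path / "m.cif"
    p.write_text(MINIMAL_MMCIF)
    model = read_structure(p, format="mmcif")
    a = model.atoms[0]
    assert (a.chain, a.res_seq) == ("B", 42)
    assert (a.x, a.y, a.z) == (1.0, 2.0, 3.0)


def test_pdb_roundtrip(tmp_path):
    model = ca_model(range(1, 6), helix_coords(5))
    p = tmp_path / "out.pdb"
    write_pdb(model, p)
    back = read_structure(p)
    assert np.allclose(back.coords(), model.coords(), atol=1e-3)
    assert [a.res_seq for a in back.atoms] == [a.res_seq for a in model.atoms]


def test_invalid_format_and_malformed_file(tmp_path):
    with pytest.raises(ValueError, match="format"):
        read_structure("x.pdb", format="xyz")
    p = tmp_path / "bad.cif"
    p.write_text("this is not a coordinate file")
    with pytest.raises(ValueError):
        read_structure(p, format="mmcif")


# ---------------------------------------------------------------- correspondence

def test_by_resnum_overlap():
    a = ca_model(range(1, 11), helix_coords(10))
    b = ca_model(range(3, 13), helix_coords(10))
    corr = build_correspondence(a, b, mode="by_resnum")
    assert len(corr.pairs) == 8
    assert corr.pairs[0] == ((3, ""), (3, ""))
    assert corr.pairs[-1] == ((10, ""), (10, ""))


def test_identical_chains_fully_paired():
    a = ca_model(range(1, 11), helix_coords(10))
    corr = build_correspondence(a, a)
    assert len(corr.pairs) == 10


def test_residue_without_ca_is_excluded():
    a = ca_model(range(1, 11), helix_coords(10))
    atoms_b = [x for x in a.atoms if x.res_seq != 5]
    atoms_b.append(Atom("A", 5, "", "ALA", "CB", "C", 0.0, 0.0, 0.0))
    b = StructureModel(atoms_b)
    corr = build_correspondence(a, b)
    assert len(corr.pairs) == 9
    assert ((5, ""), (5, "")) not in corr.pairs


def test_by_position_and_empty_correspondence():
    a = ca_model(range(1, 8), helix_coords(7))
    b = ca_model(range(101, 106), helix_coords(5))
    corr = build_correspondence(a, b, mode="by_position")
    assert len(corr.pairs) == 5
    with pytest.raises(ValueError, match="empty correspondence"):
        build_correspondence(a, b, mode="by_resnum")
    P, Q = correspondence_coords(a, b, corr)
    assert P.shape == Q.shape == (5, 3)


# ---------------------------------------------------------------- Kabsch

def test_kabsch_identity():
    P = helix_coords(10)
    res = kabsch_superpose(P, P)
    assert res.rmsd_all == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(res.rotation, np.eye(3), atol=1e-10)
    assert np.allclose(res.translation, 0.0, atol=1e-10)


def test_kabsch_recovers_rigid_motion():
    P = helix_coords(10)
    R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    Q = P @ R.T + np.array([1.0, 2.0, 3.0])
    res = kabsch_superpose(P, Q)
    assert res.rmsd_all <= 1e-10
    # the fit is the inverse of the applied motion
    assert np.allclose(res.rotation, R.T, atol=1e-8)
    assert np.allclose(res.apply(Q), P, atol=1e-8)


def test_kabsch_matches_scipy_align_vectors(rng):
    for _ in range(20):
        n = rng.integers(4, 30)
        P = rng.normal(size=(n, 3)) * 5
        Q = rng.normal(size=(n, 3)) * 5
        ours = kabsch_superpose(P, Q)
        rot, rssd = Rotation.align_vectors(P - P.mean(0), Q - Q.mean(0))
        assert ours.rmsd_all == pytest.approx(rssd / np.sqrt(n), abs=1e-8)
        assert np.allclose(ours.rotation, rot.as_matrix(), atol=1e-6)


def test_kabsch_symmetry(rng):
    P = rng.normal(size=(15, 3))
    Q = rng.normal(size=(15, 3))
    assert kabsch_superpose(P, Q).rmsd_all == pytest.approx(
        kabsch_superpose(Q, P).rmsd_all, abs=1e-9
    )


def test_kabsch_proper_rotation_on_reflection_prone_inputs(rng):
    # mirrored and near-planar clouds push the SVD toward a reflection
    for _ in range(20):
        P = rng.normal(size=(8, 3))
        P[:, 2] *= 1e-4  # near-planar
        Q = P.copy()
        Q[:, 0] *= -1  # mirror image
        res = kabsch_superpose(P, Q)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(res.rotation.T @ res.rotation, np.eye(3), atol=1e-8)


def test_kabsch_degenerate_and_size_errors():
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(ValueError, match="degenerate"):
        kabsch_superpose(line, line)
    with pytest.raises(ValueError, match="at least 3"):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
    with pytest.raises(ValueError, match="both"):
        kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


# ---------------------------------------------------------------- refinement

def test_refine_on_clean_pair_equals_kabsch():
    P = helix_coords(20)
    R = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
    Q = P @ R.T + 5.0
    res = refine_superpose(P, Q)
    assert res.n_used_pairs == res.n_input_pairs == 20
    assert res.rmsd_refined == pytest.approx(kabsch_superpose(P, Q).rmsd_all, abs=1e-12)


def test_refine_zero_cycles_reports_unrefined_rmsd(rng):
    P = rng.normal(size=(20, 3)) * 4
    Q = P + rng.normal(0, 0.5, P.shape)
    res = refine_superpose(P, Q, cycles=0)
    assert res.rmsd_refined == res.rmsd_all


def test_refine_rejects_planted_outlier(rng):
    P = helix_coords(50, rng=rng, jitter=0.0)
    Q = P + rng.normal(0, 0.2, P.shape)
    Q[25] += np.array([20.0, 0.0, 0.0])
    res = refine_superpose(P, Q)
    assert res.n_used_pairs < 50
    # the planted pair stays ~20 Å away under the final fit, i.e. it was rejected
    assert np.linalg.norm(P[25] - res.apply(Q[25])) > 5.0
    assert res.rmsd_all > 1.0
    assert res.rmsd_refined < 0.5


def test_refine_rmsd_monotone_over_cycles(rng):
    P = rng.normal(size=(60, 3)) * 8
    Q = P + rng.normal(0, 1.0, P.shape)
    res = refine_superpose(P, Q, cycles=10, reject_factor=1.2)
    rmsds = [r for _, r in res.cycle_log]
    assert all(b <= a + 1e-12 for a, b in zip(rmsds, rmsds[1:]))
    assert res.rmsd_refined <= res.rmsd_all


# ---------------------------------------------------------------- TM extraction

def test_extract_tm_domain_counts():
    model = ca_model(range(1, 51), helix_coords(50))
    topo = TMTopology("s", ((10, 20), (30, 40)))
    sub = extract_tm_domain(model, topo)
    assert len(sub) == 22
    assert all(topo.covers(a.res_seq) for a in sub.atoms)


def test_extract_tm_domain_partial_span_and_empty():
    model = ca_model(range(1, 51), helix_coords(50))
    sub = extract_tm_domain(model, TMTopology("s", ((45, 60),)))
    assert sorted(a.res_seq for a in sub.atoms) == list(range(45, 51))
    with pytest.raises(ValueError, match="TM spans"):
        extract_tm_domain(model, TMTopology("s", ()))
    with pytest.raises(ValueError, match="TM spans"):
        extract_tm_domain(model, TMTopology("s", ((200, 210),)))


# ---------------------------------------------------------------- end to end

def test_superpose_structures_recovers_rigid_copy():
    model = ca_model(range(1, 31), helix_coords(30))
    R = Rotation.from_euler("xyz", [35, -10, 70], degrees=True).as_matrix()
    moved = model.transformed(R, np.array([4.0, -2.0, 9.0]))
    res, back = superpose_structures(model, moved)
    assert res.rmsd_refined <= 1e-6
    assert np.allclose(back.coords(), model.coords(), atol=1e-6)


def test_superpose_structures_tm_only_requires_topology():
    model = ca_model(range(1, 31), helix_coords(30))
    with pytest.raises(ValueError, match="topology"):
        superpose_structures(model, model, tm_only=True)
    topo = TMTopology("s", ((5, 25),))
    res, _ = superpose_structures(model, model, tm_only=True, topo=topo)
    assert res.n_input_pairs == 21
    assert res.rmsd_refined == pytest.approx(0.0, abs=1e-12)
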