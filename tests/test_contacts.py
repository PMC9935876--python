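"""Contact detection against hand-built geometries and brute-force
all-pairs oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from pcpcad.contacts import (
    AtomSelection,
    distance_query,
    find_hydrogen_bonds,
    find_salt_bridges,
    min_domain_distances,
)
from pcpcad.structure import AtomRecord, Structure, load_vdw_radii

RADII = load_vdw_radii()


def make_atom(chain, resnum, resname, name, coords, element=None):
    element = element or name[0]
    return AtomRecord(chain, resnum, "", resname, name, element,
                      np.asarray(coords, float), RADII.get(element, RADII["default"]))


def pair_structure(atom_a, atom_b):
    return Structure(id="pair", atoms=[atom_a, atom_b])


def test_backbone_hbond_within_cutoff():
    st = pair_structure(make_atom("A", 1, "GLY", "N", [0, 0, 0]),
                        make_atom("B", 1, "GLY", "O", [3.0, 0, 0]))
    hb = find_hydrogen_bonds(st, "A", "B")
    assert len(hb) == 1
    assert hb[0].distance == pytest.approx(3.0)


def test_hbond_cutoff_excludes_long_pairs():
    st = pair_structure(make_atom("A", 1, "GLY", "N", [0, 0, 0]),
                        make_atom("B", 1, "GLY", "O", [3.8, 0, 0]))
    assert find_hydrogen_bonds(st, "A", "B", d_max=3.5) == []


def test_proline_backbone_nitrogen_is_not_a_donor():
    st = pair_structure(make_atom("A", 1, "PRO", "N", [0, 0, 0]),
                        make_atom("B", 1, "GLY", "O", [3.0, 0, 0]))
    assert find_hydrogen_bonds(st, "A", "B") == []


def test_salt_bridge_arg_glu():
    st = pair_structure(make_atom("A", 1, "ARG", "NH1", [0, 0, 0]),
                        make_atom("B", 1, "GLU", "OE1", [3.1, 0, 0]))
    sb = find_salt_bridges(st, "A", "B")
    assert len(sb) == 1 and sb[0].distance == pytest.approx(3.1)
    # the same pair must not double as an H-bond
    assert find_hydrogen_bonds(st, "A", "B") == []


def test_salt_bridge_cutoff():
    st = pair_structure(make_atom("A", 1, "LYS", "NZ", [0, 0, 0]),
                        make_atom("B", 1, "ASP", "OD1", [4.5, 0, 0]))
    assert find_salt_bridges(st, "A", "B", d_max=4.0) == []


def test_one_salt_bridge_per_residue_pair():
    st = Structure(id="multi", atoms=[
        make_atom("A", 1, "ARG", "NH1", [0, 0, 0]),
        make_atom("A", 1, "ARG", "NH2", [0, 1.8, 0]),
        make_atom("B", 5, "GLU", "OE1", [3.2, 0, 0]),
        make_atom("B", 5, "GLU", "OE2", [3.2, 1.8, 0]),
    ])
    sb = find_salt_bridges(st, "A", "B")
    assert len(sb) == 1
    per_atom = find_salt_bridges(st, "A", "B", per_atom=True)
    assert len(per_atom) >= 2
    assert sb[0].distance == pytest.approx(min(r.distance for r in per_atom))


def test_planted_contacts_recovered_exactly(toy_bundle):
    st, ann, truth = toy_bundle
    planted_sb = {(t["residue_A"], t["residue_B"]) for t in truth if t["kind"] == "salt_bridge"}
    planted_hb = {(t["residue_A"], t["residue_B"]) for t in truth if t["kind"] == "hbond"}
    sb = find_salt_bridges(st, "A", "B")
    hb = find_hydrogen_bonds(st, "A", "B")
    assert {(r.atom_A.residue_number, r.atom_B.residue_number) for r in sb} == planted_sb
    assert {(r.atom_A.residue_number, r.atom_B.residue_number) for r in hb} == planted_hb


def test_hbond_and_salt_bridge_sets_disjoint(toy_bundle):
    st, _, _ = toy_bundle
    hb = {(id(r.atom_A), id(r.atom_B)) for r in find_hydrogen_bonds(st, "A", "B")}
    sb = {(id(r.atom_A), id(r.atom_B)) for r in find_salt_bridges(st, "A", "B", per_atom=True)}
    assert hb.isdisjoint(sb)


def test_contact_distances_recomputable(toy_bundle):
    st, _, _ = toy_bundle
    for rec in find_salt_bridges(st, "A", "B") + find_hydrogen_bonds(st, "A", "B"):
        d = np.linalg.norm(rec.atom_A.coords - rec.atom_B.coords)
        assert rec.distance == pytest.approx(d, abs=1e-6)


def test_chain_order_symmetry(toy_bundle):
    st, _, _ = toy_bundle
    fwd = find_salt_bridges(st, "A", "B")
    rev = find_salt_bridges(st, "B", "A")
    fwd_pairs = {frozenset([r.atom_A.residue_key, r.atom_B.residue_key]) for r in fwd}
    rev_pairs = {frozenset([r.atom_A.residue_key, r.atom_B.residue_key]) for r in rev}
    assert fwd_pairs == rev_pairs


def test_min_domain_distances_match_brute_force(toy_bundle):
    st, ann, truth = toy_bundle
    table = min_domain_distances(st, ann)
    atoms_A = st.select(chain="A")
    atoms_B = st.select(chain="B")
    for row in table.itertuples():
        sub_A = np.array([a.coords for a in atoms_A if a.domain == row.domain_A])
        sub_B = np.array([b.coords for b in atoms_B if b.domain == row.domain_B])
        assert row.min_distance == pytest.approx(cdist(sub_A, sub_B).min(), abs=1e-9)
    planted_vdw = [t for t in truth if t["kind"] == "vdw"][0]
    got = table[(table.domain_A == planted_vdw["domain_A"])
                & (table.domain_B == planted_vdw["domain_B"])].min_distance.iloc[0]
    assert got == pytest.approx(5.0, abs=1e-6)


def test_distance_query_matches_brute_force(rng):
    atoms = []
    for chain in ("A", "B"):
        for i in range(20):
            atoms.append(make_atom(chain, i + 1, "GLY", "CA",
                                   rng.uniform(0, 30, 3), element="C"))
    st = Structure(id="rand", atoms=atoms)
    d, a, b = distance_query(st, AtomSelection(chain="A"), AtomSelection(chain="B"))
    coords_A = np.array([x.coords for x in atoms[:20]])
    coords_B = np.array([x.coords for x in atoms[20:]])
    assert d == pytest.approx(cdist(coords_A, coords_B).min(), abs=1e-12)
    assert a.chain_id == "A" and b.chain_id == "B"


def test_distance_query_same_selection_is_zero():
    st = Structure(id="one", atoms=[make_atom("A", 1, "GLY", "CA", [1, 2, 3]),
                                    make_atom("A", 2, "GLY", "CA", [7, 2, 3])])
    sel = AtomSelection(chain="A", residues=(1,))
    d, _, _ = distance_query(st, sel, sel)
    assert d == 0.0


def test_distance_query_two_atoms():
    st = Structure(id="two", atoms=[make_atom("A", 1, "GLY", "CA", [0, 0, 0]),
                                    make_atom("B", 1, "GLY", "CA", [6.3, 0, 0])])
    d, _, _ = distance_query(st, AtomSelection(chain="A"), AtomSelection(chain="B"))
    assert d == pytest.approx(6.3)


def test_distance_query_empty_selection_names_predicate():
    st = Structure(id="one", atoms=[make_atom("A", 1, "GLY", "CA", [0, 0, 0])])
    with pytest.raises(ValueError, match="chain=Q"):
        distance_query(st, AtomSelection(chain="Q"), AtomSelection(chain="A"))


def test_detection_equals_brute_force_on_random_structures(rng):
    """Randomly placed donors/acceptors: KDTree detection must equal the
    O(n²) filter exactly."""
    for _ in range(5):
        atoms = []
        for chain in ("A", "B"):
            for i in range(15):
                kind = rng.choice(["N_don", "O_acc", "NZ", "OE1"])
                resname, name = {
                    "N_don": ("GLY", "N"), "O_acc": ("GLY", "O"),
                    "NZ": ("LYS", "NZ"), "OE1": ("GLU", "OE1"),
                }[kind]
                atoms.append(make_atom(chain, i + 1, resname, name, rng.uniform(0, 12, 3)))
        st = Structure(id="rand", atoms=atoms)
        hb = find_hydrogen_bonds(st, "A", "B")
        atoms_A, atoms_B = atoms[:15], atoms[15:]
        expected = set()
        for a in atoms_A:
            for b in atoms_B:
                d = np.linalg.norm(a.coords - b.coords)
                if d > 3.5 or d == 0:
                    continue
                donor_ok = (
                    (a.atom_name == "N" or (a.residue_name == "LYS" and a.atom_name == "NZ"))
                    and b.atom_name in {"O", "OE1"}
                ) or (
                    (b.atom_name == "N" or (b.residue_name == "LYS" and b.atom_name == "NZ"))
                    and a.atom_name in {"O", "OE1"}
                )
                ionic = {a.atom_name, b.atom_name} == {"NZ", "OE1"}
                if donor_ok and not ionic:
                    expected.add((a.residue_number, b.residue_number, a.atom_name, b.atom_name))
        got = {(r.atom_A.residue_number, r.atom_B.residue_number,
                r.atom_A.atom_name, r.atom_B.atom_name) for r in hb}
        assert got == expected
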