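"""Contacts, hydrogen bonds, pocket insertions and interface fingerprints."""

import numpy as np
import pytest

from ddpks import synthdata
from ddpks.interface import (
    compare_fingerprints,
    detect_hbonds,
    find_contacts,
    interface_fingerprint,
    pocket_insertion,
)
from ddpks.refmap import ReferenceMap
from ddpks.rigid import apply_transform
from ddpks.structio import Atom, AtomicModel, Chain, Residue, Selection, StructureError, select


def _point_model(points_a, points_b, resname="ALA"):
    """Two chains of single-CA residues at given coordinates."""
    def chain(cid, pts):
        return Chain(cid, [
            Residue(i + 1, resname, [Atom("CA", "C", np.asarray(p, float))])
            for i, p in enumerate(pts)
        ])
    m = AtomicModel("pts", [chain("A", points_a), chain("B", points_b)])
    sel_a = select(m, "A", (1, len(points_a)))
    sel_b = select(m, "B", (1, len(points_b)))
    return m, sel_a, sel_b


def brute_force_contacts(model, sel_a, sel_b, cutoff):
    """All-pairs O(n^2) oracle for the contact relation."""
    out = {}
    for ca, ra, rna, at_a in sel_a.atoms():
        for cb, rb, rnb, at_b in sel_b.atoms():
            d = float(np.linalg.norm(at_a.xyz - at_b.xyz))
            if d <= cutoff:
                key = (ra, rb)
                rec = out.setdefault(key, [d, 0])
                rec[0] = min(rec[0], d)
                rec[1] += 1
    return out


def test_single_pair_contact():
    m, sa, sb = _point_model([(0, 0, 0)], [(3, 0, 0)])
    contacts = find_contacts(m, sa, sb, cutoff=4.5)
    assert len(contacts) == 1
    assert contacts[0].min_distance == pytest.approx(3.0)
    assert contacts[0].n_atom_pairs == 1


@pytest.mark.parametrize("seed", range(10))
def test_contacts_equal_brute_force(seed):
    rng = np.random.default_rng(seed)
    pa = rng.uniform(0, 25, size=(100, 3))
    pb = rng.uniform(0, 25, size=(100, 3))
    cutoff = float(rng.uniform(3.5, 6.0))
    m, sa, sb = _point_model(pa, pb)
    got = {(c.resnum_a, c.resnum_b): (c.min_distance, c.n_atom_pairs)
           for c in find_contacts(m, sa, sb, cutoff)}
    expected = brute_force_contacts(m, sa, sb, cutoff)
    assert set(got) == set(expected)
    for key, (dmin, n) in expected.items():
        assert got[key][0] == pytest.approx(dmin)
        assert got[key][1] == n


def test_contact_relation_symmetric():
    rng = np.random.default_rng(2)
    m, sa, sb = _point_model(rng.uniform(0, 15, (30, 3)), rng.uniform(0, 15, (30, 3)))
    fwd = {(c.resnum_a, c.resnum_b) for c in find_contacts(m, sa, sb, 5.0)}
    rev = {(c.resnum_b, c.resnum_a) for c in find_contacts(m, sb, sa, 5.0)}
    assert fwd == rev


def test_empty_selection_errors():
    m, sa, sb = _point_model([(0, 0, 0)], [(3, 0, 0)])
    with pytest.raises(StructureError):
        find_contacts(m, sa, Selection(m, []), 4.5)


def _hbond_model(distance):
    """Backbone carbonyl O on chain A, asparagine side-chain ND2 on chain B."""
    res_a = Residue(10, "ALA", [
        Atom("CA", "C", np.array([0.0, 0.0, 0.0])),
        Atom("C", "C", np.array([1.2, 0.0, 0.0])),
        Atom("O", "O", np.array([2.0, 0.0, 0.0])),
    ])
    res_b = Residue(20, "ASN", [
        Atom("CA", "C", np.array([2.0 + distance, 3.0, 0.0])),
        Atom("CG", "C", np.array([2.0 + distance, 1.2, 0.0])),
        Atom("ND2", "N", np.array([2.0 + distance, 0.0, 0.0])),
    ])
    m = AtomicModel("hb", [Chain("A", [res_a]), Chain("B", [res_b])])
    return m, select(m, "A", (10, 10)), select(m, "B", (20, 20))


def test_hbond_detected_at_2p9():
    m, sa, sb = _hbond_model(2.9)
    bonds = detect_hbonds(m, sa, sb, da_cutoff=3.5)
    assert len(bonds) == 1
    b = bonds[0]
    assert b.distance == pytest.approx(2.9)
    assert b.donor == ("B", 20, "ND2") and b.acceptor == ("A", 10, "O")
    assert b.donor_is_sidechain and not b.acceptor_is_sidechain


def test_no_hbond_beyond_cutoff():
    m, sa, sb = _hbond_model(3.8)
    assert detect_hbonds(m, sa, sb, da_cutoff=3.5) == []


def _pocket_model(separation):
    """Leucine-like side chain facing a 4-residue pocket ring."""
    side = Residue(935, "LEU", [
        Atom("CA", "C", np.array([0.0, 0.0, 0.0])),
        Atom("CB", "C", np.array([1.5, 0.0, 0.0])),
        Atom("CG", "C", np.array([2.8, 0.0, 0.0])),
        Atom("CD1", "C", np.array([3.6, 1.0, 0.0])),
        Atom("CD2", "C", np.array([3.6, -1.0, 0.0])),
    ])
    pocket_residues = []
    for i, angle in enumerate(np.linspace(0, 2 * np.pi, 4, endpoint=False)):
        c = np.array([3.0 + separation, 2.5 * np.sin(angle), 2.5 * np.cos(angle)])
        pocket_residues.append(Residue(53 + 2 * i, "VAL", [
            Atom("CA", "C", c + np.array([2.0, 0, 0])),
            Atom("CB", "C", c),
        ]))
    m = AtomicModel("pocket", [Chain("A", [side]), Chain("B", pocket_residues)])
    return m


def test_pocket_fully_buried_side_chain():
    m = _pocket_model(0.0)
    result = pocket_insertion(m, ("A", 935), [("B", 53 + 2 * i) for i in range(4)])
    assert result.burial_fraction == 1.0
    assert result.inserted_verdict
    assert result.n_pocket_residues_contacted >= 3


def test_pocket_far_side_chain_not_inserted():
    m = _pocket_model(15.0)
    result = pocket_insertion(m, ("A", 935), [("B", 53 + 2 * i) for i in range(4)])
    assert result.burial_fraction == 0.0
    assert not result.inserted_verdict


def test_pocket_glycine_errors():
    m = _pocket_model(0.0)
    m.chain("A").residues[0].name = "GLY"
    m.chain("A").residues[0].atoms = m.chain("A").residues[0].atoms[:1]
    with pytest.raises(StructureError, match="side-chain"):
        pocket_insertion(m, ("A", 935), [("B", 53)])


def test_fingerprint_identity_maps():
    m, sa, sb = _point_model([(0, 0, 0), (10, 0, 0)], [(3, 0, 0)])
    contacts = find_contacts(m, sa, sb, 4.5)
    rm = ReferenceMap.identity("x", 50)
    fp = interface_fingerprint(contacts, [], rm, rm)
    assert fp.pairs == frozenset({(1, 1)})


def test_fingerprint_invariant_to_numbering_offset():
    """A paralog numbered +7 relative to the reference yields the same
    reference-numbered fingerprint."""
    rng = np.random.default_rng(4)
    pa = rng.uniform(0, 12, (20, 3))
    pb = rng.uniform(0, 12, (20, 3))
    m1, sa1, sb1 = _point_model(pa, pb)
    fp1 = interface_fingerprint(find_contacts(m1, sa1, sb1, 5.0), [],
                                ReferenceMap.identity("ref", 40),
                                ReferenceMap.identity("ref", 40))

    def offset_chain(cid, pts):
        return Chain(cid, [Residue(i + 8, "ALA", [Atom("CA", "C", p)])
                           for i, p in enumerate(pts)])

    m2 = AtomicModel("off", [offset_chain("A", pa), offset_chain("B", pb)])
    sa2 = select(m2, "A", (8, 27))
    sb2 = select(m2, "B", (8, 27))
    rm_off = ReferenceMap("off", {i: i + 7 for i in range(1, 41)})
    fp2 = interface_fingerprint(find_contacts(m2, sa2, sb2, 5.0), [], rm_off, rm_off)
    assert fp1.pairs == fp2.pairs


def test_fingerprint_invariant_under_rigid_transform():
    rng = np.random.default_rng(6)
    pa = rng.uniform(0, 12, (20, 3))
    pb = rng.uniform(0, 12, (20, 3))
    m1, sa1, sb1 = _point_model(pa, pb)
    rm = ReferenceMap.identity("x", 40)
    fp1 = interface_fingerprint(find_contacts(m1, sa1, sb1, 5.0), [], rm, rm)
    m2 = apply_transform(m1, synthdata.random_transform(rng))
    sa2 = select(m2, "A", (1, 20))
    sb2 = select(m2, "B", (1, 20))
    fp2 = interface_fingerprint(find_contacts(m2, sa2, sb2, 5.0), [], rm, rm)
    assert fp1.pairs == fp2.pairs


def test_compare_fingerprints_jaccard():
    rm = ReferenceMap.identity("x", 100)

    def fp(pairs):
        from ddpks.interface import InterfaceFingerprint

        return InterfaceFingerprint("p", ("DH", "KR_c"), frozenset(pairs), frozenset())

    a = fp({(1073, 2276), (1074, 2272), (1076, 2272), (1073, 2280),
            (1073, 2283), (1074, 2275)})
    assert compare_fingerprints(a, a) == 1.0
    b = fp({(1073, 2276), (1074, 2272), (1, 2), (3, 4)})
    # |A u B| = 8, |A n B| = 2
    assert compare_fingerprints(a, b) == pytest.approx(0.25)
    disjoint = fp({(5, 6)})
    assert compare_fingerprints(a, disjoint) == 0.0
    with pytest.raises(ValueError):
        compare_fingerprints(fp(set()), fp(set()))
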