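"""Residue-residue interface characterization.

Contacts, hydrogen bonds and pocket insertions between two atom selections,
re-expressed as fingerprints in Pks16 reference numbering so the same
interface (e.g. the KS/DH or DH/KR_c connection) can be compared across the
40 paralogs regardless of native numbering shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .refmap import ReferenceMap
from .structio import BACKBONE_ATOMS, AtomicModel, Selection, StructureError

__all__ = [
    "Contact",
    "HydrogenBond",
    "PocketInsertion",
    "InterfaceFingerprint",
    "find_contacts",
    "detect_hbonds",
    "pocket_insertion",
    "interface_fingerprint",
    "compare_fingerprints",
]

CONTACT_CUTOFF = 4.5      # heavy-atom contact
HBOND_CUTOFF = 3.5        # donor-acceptor N/O distance
SALT_BRIDGE_CUTOFF = 4.0  # charged-group atoms
BURIAL_CUTOFF = 5.0
BURIAL_MIN = 0.6
POCKET_MIN_RESIDUES = 3

# charged side-chain atoms for salt-bridge flagging
_CHARGED_ATOMS = {
    "ARG": {"NH1", "NH2", "NE"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}


@dataclass
class Contact:
    chain_a: str
    resnum_a: int
    resname_a: str
    chain_b: str
    resnum_b: int
    resname_b: str
    min_distance: float
    n_atom_pairs: int
    salt_bridge: bool = False


@dataclass
class HydrogenBond:
    donor: tuple[str, int, str]     # chain, resnum, atom
    acceptor: tuple[str, int, str]
    distance: float
    donor_is_sidechain: bool = False
    acceptor_is_sidechain: bool = False


@dataclass
class PocketInsertion:
    inserted: tuple[str, int, str]
    pocket: list[tuple[str, int]]
    burial_fraction: float
    n_pocket_residues_contacted: int
    inserted_verdict: bool
    parameters: dict = field(default_factory=dict)


@dataclass
class InterfaceFingerprint:
    paralog: str
    domain_pair: tuple[str, str]
    pairs: frozenset  # of (ref_pos_a, ref_pos_b)
    hbond_pairs: frozenset
    n_unmapped_dropped: int = 0


def _sel_atoms(sel: Selection):
    return sel.atoms()


def _check_disjoint(a: Selection, b: Selection):
    if set(a.triples) & set(b.triples):
        raise StructureError("selections share atoms; interface requires disjoint selections")


def find_contacts(model: AtomicModel, sel_a: Selection, sel_b: Selection,
                  cutoff: float = CONTACT_CUTOFF) -> list[Contact]:
    """Residue pairs with any heavy-atom pair within ``cutoff`` Angstrom.

    Sorted by (resnum_a, resnum_b); salt bridges (charged-group atoms within
    4 A) are flagged on the contact, not a separate record.
    """
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise StructureError("empty selection")
    _check_disjoint(sel_a, sel_b)
    atoms_a = _sel_atoms(sel_a)
    atoms_b = _sel_atoms(sel_b)
    xa = np.array([at.xyz for _, _, _, at in atoms_a])
    xb = np.array([at.xyz for _, _, _, at in atoms_b])
    pairs = cKDTree(xa).query_ball_tree(cKDTree(xb), cutoff)
    by_res: dict[tuple, dict] = {}
    for ia, neighbors in enumerate(pairs):
        ca, ra, rna, at_a = atoms_a[ia]
        for ib in neighbors:
            cb, rb, rnb, at_b = atoms_b[ib]
            d = float(np.linalg.norm(at_a.xyz - at_b.xyz))
            key = (ca, ra, rna, cb, rb, rnb)
            rec = by_res.setdefault(key, {"min": d, "n": 0, "salt": False})
            rec["min"] = min(rec["min"], d)
            rec["n"] += 1
            if (
                d <= SALT_BRIDGE_CUTOFF
                and at_a.name in _CHARGED_ATOMS.get(rna, ())
                and at_b.name in _CHARGED_ATOMS.get(rnb, ())
            ):
                rec["salt"] = True
    out = [
        Contact(ca, ra, rna, cb, rb, rnb, rec["min"], rec["n"], rec["salt"])
        for (ca, ra, rna, cb, rb, rnb), rec in by_res.items()
    ]
    out.sort(key=lambda c: (c.resnum_a, c.resnum_b, c.chain_a, c.chain_b))
    return out


def _h_neighbors(res, heavy_name: str):
    """Hydrogens bonded (within 1.3 A) to a heavy atom, if any are present."""
    heavy = res.atom(heavy_name)
    return [
        a for a in res.atoms
        if a.is_hydrogen and np.linalg.norm(a.xyz - heavy.xyz) < 1.3
    ]


def detect_hbonds(model: AtomicModel, sel_a: Selection, sel_b: Selection,
                  da_cutoff: float = HBOND_CUTOFF) -> list[HydrogenBond]:
    """N/O donor-acceptor pairs across two selections.

    Geometric criterion: donor-acceptor distance <= cutoff; when hydrogens
    are present on the donor, the D-H...A angle must additionally be >= 120
    degrees.  In an N-O pair the nitrogen is taken as donor; O-O pairs take
    the first selection's oxygen as donor.
    """
    _check_disjoint(sel_a, sel_b)
    bonds = []
    atoms_a = [(c, r, rn, a) for c, r, rn, a in _sel_atoms(sel_a)
               if a.element.upper() in ("N", "O")]
    atoms_b = [(c, r, rn, a) for c, r, rn, a in _sel_atoms(sel_b)
               if a.element.upper() in ("N", "O")]
    for ca, ra, rna, at_a in atoms_a:
        res_a = model.chain(ca).residue(ra)
        for cb, rb, rnb, at_b in atoms_b:
            d = float(np.linalg.norm(at_a.xyz - at_b.xyz))
            if d > da_cutoff or d < 1.5:
                continue
            ea, eb = at_a.element.upper(), at_b.element.upper()
            if ea == "N" or (ea == "O" and eb == "O"):
                donor, acceptor = (ca, ra, rna, at_a, res_a), (cb, rb, rnb, at_b)
            else:
                donor = (cb, rb, rnb, at_b, model.chain(cb).residue(rb))
                acceptor = (ca, ra, rna, at_a)
            dch, drn, drna, dat, dres = donor
            ach, arn, arna, aat = acceptor
            hyds = _h_neighbors(dres, dat.name)
            if hyds:
                ok = False
                for h in hyds:
                    v1 = dat.xyz - h.xyz
                    v2 = aat.xyz - h.xyz
                    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= 120.0:
                        ok = True
                if not ok:
                    continue
            bonds.append(HydrogenBond(
                (dch, drn, dat.name), (ach, arn, aat.name), d,
                donor_is_sidechain=dat.name not in BACKBONE_ATOMS,
                acceptor_is_sidechain=aat.name not in BACKBONE_ATOMS,
            ))
    bonds.sort(key=lambda b: (b.donor, b.acceptor))
    return bonds


def pocket_insertion(
    model: AtomicModel,
    inserted: tuple[str, int],
    pocket: list[tuple[str, int]],
    contact_cutoff: float = CONTACT_CUTOFF,
    burial_cutoff: float = BURIAL_CUTOFF,
) -> PocketInsertion:
    """Quantify a side chain inserting into a pocket of residues.

    Burial fraction = inserted side-chain heavy atoms within ``burial_cutoff``
    of any pocket heavy atom, over all inserted side-chain heavy atoms.
    Verdict "inserted" requires burial >= 0.6 and >= 3 distinct pocket
    residues contacted at ``contact_cutoff``.
    """
    ch, num = inserted
    chain = model.chain(ch)
    if chain is None or chain.residue(num) is None:
        raise StructureError(f"inserted residue {ch}:{num} absent")
    res = chain.residue(num)
    side = res.side_chain_heavy_atoms()
    if not side:
        raise StructureError(f"residue {res.name}{num} has no side-chain heavy atoms (GLY?)")
    pocket_atoms = []
    for pch, pnum in pocket:
        pc = model.chain(pch)
        pr = pc.residue(pnum) if pc else None
        if pr is None:
            raise StructureError(f"pocket residue {pch}:{pnum} absent")
        pocket_atoms.extend(((pch, pnum), a) for a in pr.heavy_atoms())
    pxyz = np.array([a.xyz for _, a in pocket_atoms])
    tree = cKDTree(pxyz)
    buried = sum(1 for a in side if tree.query(a.xyz)[0] <= burial_cutoff)
    burial = buried / len(side)
    contacted = set()
    for a in side:
        for idx in tree.query_ball_point(a.xyz, contact_cutoff):
            contacted.add(pocket_atoms[idx][0])
    verdict = burial >= BURIAL_MIN and len(contacted) >= POCKET_MIN_RESIDUES
    return PocketInsertion(
        (ch, num, res.name),
        sorted(set(pocket)),
        burial,
        len(contacted),
        verdict,
        parameters={
            "contact_cutoff": contact_cutoff,
            "burial_cutoff": burial_cutoff,
            "burial_min": BURIAL_MIN,
            "pocket_min_residues": POCKET_MIN_RESIDUES,
        },
    )


def interface_fingerprint(
    contacts: list[Contact],
    hbonds: list[HydrogenBond],
    rm_a: ReferenceMap,
    rm_b: ReferenceMap,
    paralog: str = "",
    domain_pair: tuple[str, str] = ("", ""),
) -> InterfaceFingerprint:
    """Re-express an interface in reference numbering (set semantics)."""
    pairs = set()
    dropped = 0
    for c in contacts:
        ra = rm_a.to_reference(c.resnum_a)
        rb = rm_b.to_reference(c.resnum_b)
        if ra is None or rb is None:
            dropped += 1
            continue
        pairs.add((ra, rb))
    hpairs = set()
    for h in hbonds:
        ra = rm_a.to_reference(h.donor[1])
        rb = rm_b.to_reference(h.acceptor[1])
        if ra is None or rb is None:
            dropped += 1
            continue
        hpairs.add((ra, rb))
    return InterfaceFingerprint(paralog, domain_pair, frozenset(pairs),
                                frozenset(hpairs), dropped)


def compare_fingerprints(fp_a: InterfaceFingerprint, fp_b: InterfaceFingerprint) -> float:
    """Jaccard index over reference-numbered contact pairs."""
    if fp_a.domain_pair != fp_b.domain_pair:
        raise ValueError(f"domain pairs differ: {fp_a.domain_pair} vs {fp_b.domain_pair}")
    if not fp_a.pairs and not fp_b.pairs:
        raise ValueError("both fingerprints empty")
    inter = len(fp_a.pairs & fp_b.pairs)
    union = len(fp_a.pairs | fp_b.pairs)
    return inter / union
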