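"""Rigid-body superposition and fragment merging.

A full-length PKS homodimer exceeds the size a single structure prediction
can cover, so each synthase is predicted as two overlapping dimeric fragments
(KS+AT+DH and KS*+DH+...+ACP, sharing the KS dimer) and reassembled here: the
second fragment is superposed onto the first through the shared KS dimer and
each chain is stitched at a junction reference position (default 935, just
downstream of the conserved KS-DH linker proline).  The seam is reported, not
repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .refmap import DomainRegistry, ReferenceMap
from .structio import AtomicModel, Chain, StructureError

__all__ = [
    "RigidTransform",
    "SuperpositionResult",
    "FragmentSpec",
    "MergedModel",
    "kabsch",
    "superpose_domain",
    "merge_fragments",
    "apply_transform",
]

MIN_PAIRED_CA = 20
CLASH_CUTOFF = 2.0  # Angstrom, informational seam metric


@dataclass
class RigidTransform:
    """Proper rotation + translation, x -> R x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3, translation length 3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("improper rotation (reflection)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_atoms: int
    chain_pairing: dict[str, str] = field(default_factory=dict)


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit of ``mobile`` onto ``target`` (ordered pairs).

    SVD solution with the determinant sign correction that suppresses
    reflections.  Collinear/degenerate point sets warn but still return the
    best proper rotation.
    """
    mobile = np.asarray(mobile, dtype=float).reshape(-1, 3)
    target = np.asarray(target, dtype=float).reshape(-1, 3)
    if mobile.shape != target.shape:
        raise ValueError(f"shape mismatch {mobile.shape} vs {target.shape}")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 points, got {n}")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-9 * max(s[0], 1.0):
        import warnings

        warnings.warn("degenerate (collinear) point set; rotation ill-determined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = ct - rot @ cm
    transform = RigidTransform(rot, t)
    diff = transform.apply(mobile) - target
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return transform, rmsd


def apply_transform(obj, t: RigidTransform):
    """Apply a rigid transform to coordinates or (a copy of) an AtomicModel."""
    if isinstance(obj, AtomicModel):
        out = obj.copy()
        for chain in out.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    atom.xyz = t.apply(atom.xyz)
        return out
    return t.apply(obj)


def _domain_ca(model: AtomicModel, chain: Chain, ref_positions: list[int],
               rm: ReferenceMap) -> dict[int, np.ndarray]:
    """CA coordinates keyed by reference position present on one chain."""
    out = {}
    for ref in ref_positions:
        native = rm.to_native(ref)
        if native is None:
            continue
        res = chain.residue(native)
        if res is None or res.hetero:
            continue
        ca = res.atom("CA")
        if ca is not None:
            out[ref] = ca.xyz
    return out


def _chain_pairings(mobile: AtomicModel, target: AtomicModel):
    """Candidate chain pairings mobile -> target (both orders for dimers)."""
    mids, tids = mobile.chain_ids(), target.chain_ids()
    if len(mids) == 2 and len(tids) == 2:
        yield {mids[0]: tids[0], mids[1]: tids[1]}
        yield {mids[0]: tids[1], mids[1]: tids[0]}
    else:
        n = min(len(mids), len(tids))
        yield dict(zip(mids[:n], tids[:n]))


def superpose_domain(
    mobile: AtomicModel,
    target: AtomicModel,
    domain: str,
    registry: DomainRegistry,
    rm_mobile: ReferenceMap | None = None,
    rm_target: ReferenceMap | None = None,
    chains_mobile: list[str] | None = None,
    chains_target: list[str] | None = None,
) -> SuperpositionResult:
    """Superpose two models through shared reference positions of one domain.

    CA atoms only.  Residues are paired via the intersection of reference
    positions mapped in both models.  For dimers both chain pairings
    (A->A/B->B and A->B/B->A) are tried and the lower-RMSD one kept.
    Explicit chain lists restrict the fit (e.g. frame on "the AT of chain B").
    """
    ref_positions = registry.positions(domain)

    def _identity_for(model):
        top = max(r.number for c in model.chains for r in c.polymer_residues())
        return ReferenceMap.identity(model.id, top)

    rm_mobile = rm_mobile or _identity_for(mobile)
    rm_target = rm_target or _identity_for(target)

    mob = mobile if chains_mobile is None else AtomicModel(
        mobile.id, [c for c in mobile.chains if c.chain_id in chains_mobile])
    tgt = target if chains_target is None else AtomicModel(
        target.id, [c for c in target.chains if c.chain_id in chains_target])
    if not mob.chains or not tgt.chains:
        raise StructureError("requested chains absent")

    best: SuperpositionResult | None = None
    for pairing in _chain_pairings(mob, tgt):
        mob_pts, tgt_pts = [], []
        for mcid, tcid in pairing.items():
            mca = _domain_ca(mob, mob.chain(mcid), ref_positions, rm_mobile)
            tca = _domain_ca(tgt, tgt.chain(tcid), ref_positions, rm_target)
            shared = sorted(set(mca) & set(tca))
            mob_pts.extend(mca[r] for r in shared)
            tgt_pts.extend(tca[r] for r in shared)
        if len(mob_pts) < MIN_PAIRED_CA:
            continue
        transform, rmsd = kabsch(np.array(mob_pts), np.array(tgt_pts))
        if best is None or rmsd < best.rmsd:
            best = SuperpositionResult(transform, rmsd, len(mob_pts), pairing)
    if best is None:
        raise StructureError(
            f"domain {domain}: fewer than {MIN_PAIRED_CA} paired CA atoms in every pairing"
        )
    return best


@dataclass
class FragmentSpec:
    """Which fragment contributes which side of the junction.

    The KS+AT+DH fragment supplies residues up to and including the junction
    reference position; the AT-less fragment supplies everything downstream.
    """

    junction: int = 935
    superpose_on: str = "KS"


@dataclass
class MergedModel:
    model: AtomicModel
    junction_report: dict
    provenance: dict


def merge_fragments(
    frag1: AtomicModel,
    frag2: AtomicModel,
    spec: FragmentSpec,
    registry: DomainRegistry,
    rm1: ReferenceMap | None = None,
    rm2: ReferenceMap | None = None,
) -> MergedModel:
    """Merge two overlapping dimeric fragment predictions into one model.

    frag2 is rigidly moved onto frag1 through the shared domain (default KS)
    dimer; per output chain, residues numbered <= junction (native numbering)
    come from frag1 and residues > junction from the transformed frag2,
    respecting the RMSD-selected chain pairing.  Native numbering is kept;
    the seam is characterized (CA-CA junction distance, inter-fragment
    clashes < 2 A) but never repaired.
    """
    sup = superpose_domain(frag2, frag1, spec.superpose_on, registry, rm2, rm1)
    frag2_t = apply_transform(frag2, sup.transform)

    def _native_junction(rm, frag):
        if rm is None:
            return spec.junction
        native = rm.to_native(spec.junction)
        if native is None:
            raise StructureError(f"junction reference {spec.junction} unmapped in {frag.id}")
        return native

    j1 = _native_junction(rm1, frag1)
    j2 = _native_junction(rm2, frag2)

    merged = AtomicModel(id=f"Merged_{frag1.id}")
    report: dict = {"junction_reference": spec.junction, "chains": {}}
    for c2 in frag2_t.chains:
        c1_id = sup.chain_pairing[c2.chain_id]
        c1 = frag1.chain(c1_id)
        part1 = [r for r in c1.residues if r.hetero or r.number <= j1]
        part2 = [r for r in c2.residues if not r.hetero and r.number > j2]
        nums1 = {r.number for r in part1 if not r.hetero}
        nums2 = {r.number for r in part2}
        dup = nums1 & nums2
        if dup:
            raise StructureError(f"chain {c1_id}: duplicated residue numbers at seam: {sorted(dup)[:5]}")
        chain = Chain(c1_id, sorted(part1 + part2, key=lambda r: (r.hetero, r.number)))
        merged.chains.append(chain)

        # seam metrics
        ca_j = c1.residue(j1).atom("CA") if c1.residue(j1) else None
        nxt = min(nums2) if nums2 else None
        ca_n = chain.residue(nxt).atom("CA") if nxt is not None else None
        dist = (
            float(np.linalg.norm(ca_j.xyz - ca_n.xyz))
            if ca_j is not None and ca_n is not None
            else None
        )
        xyz1 = np.array([a.xyz for r in part1 if not r.hetero for a in r.heavy_atoms()])
        xyz2 = np.array([a.xyz for r in part2 for a in r.heavy_atoms()])
        n_clash = 0
        if len(xyz1) and len(xyz2):
            n_clash = int(cKDTree(xyz1).count_neighbors(cKDTree(xyz2), CLASH_CUTOFF))
        report["chains"][c1_id] = {
            "junction_ca_ca_distance": dist,
            "n_clashes_lt_2A": n_clash,
        }
    merged.chains.sort(key=lambda c: c.chain_id)
    merged.validate()
    report["superposition_rmsd"] = sup.rmsd
    report["chain_pairing"] = sup.chain_pairing
    return MergedModel(
        merged,
        report,
        {"frag1": frag1.id, "frag2": frag2.id, "superposed_on": spec.superpose_on},
    )
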