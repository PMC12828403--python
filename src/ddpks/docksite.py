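"""Consensus ACP docking-site identification and reaction-chamber mapping.

Across an ensemble of independent structure predictions, the ACP repeatedly
docks its catalytic partners at recurring sites.  Each prediction is placed
in a canonical enzyme frame (e.g. Pks16's ER of chain A), the ACP placement
is recorded as a pose (the CA positions of the ACP core, reference
2524-2575, plus the phosphopantetheinylated serine at 2543), poses are
clustered by core-CA RMSD in the common frame, the largest cluster is the
consensus site, and an overlay of per-enzyme consensus poses in the Pks16
dimer frame summarizes the reaction chamber the ACP traverses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import ConvexHull, QhullError, distance

from .refmap import DomainRegistry, ReferenceMap
from .rigid import apply_transform, superpose_domain
from .structio import AtomicModel, StructureError

__all__ = [
    "DockPose",
    "PoseCluster",
    "ConsensusResult",
    "ChamberSummary",
    "extract_pose",
    "pose_distance",
    "cluster_poses",
    "consensus_site",
    "chamber_summary",
    "ACP_CORE",
    "ACP_SERINE",
    "DEFAULT_TAU",
    "TAU_SENSITIVITY_GRID",
]

ACP_CORE = (2524, 2575)   # reference span of the ACP core used as pose anchor
ACP_SERINE = 2543         # phosphopantetheinylated serine, reference numbering
MIN_ACP_CORE_CA = 10
FRAME_RMSD_MAX = 5.0      # above this the enzyme framing is flagged unreliable
DEFAULT_TAU = 8.0         # average-linkage cut height, Angstrom
TAU_SENSITIVITY_GRID = (4.0, 6.0, 8.0, 10.0, 12.0)


@dataclass
class DockPose:
    source_id: str
    paralog: str
    enzyme: str
    anchors: dict[int, np.ndarray]      # reference position -> CA xyz in frame
    serine_ca: np.ndarray | None
    frame_rmsd: float
    acp_chain: str = ""
    unreliable: bool = False

    def anchor_positions(self) -> list[int]:
        return sorted(self.anchors)


@dataclass
class PoseCluster:
    members: list[DockPose]
    medoid: DockPose
    mean_pairwise_distance: float

    def __len__(self):
        return len(self.members)

    def paralogs(self) -> set[str]:
        return {p.paralog for p in self.members}


@dataclass
class ConsensusResult:
    enzyme: str
    clusters: list[PoseCluster]          # sorted by size (desc)
    consensus_index: int
    membership: dict[str, dict]          # paralog -> {has_consensus, n_poses, n_consensus_poses}
    tau: float

    @property
    def consensus(self) -> PoseCluster:
        return self.clusters[self.consensus_index]

    def n_carriers(self) -> int:
        return sum(1 for m in self.membership.values() if m["has_consensus"])


@dataclass
class ChamberSummary:
    chambers: list[dict]                 # exactly 2 for a C2 dimer
    parameters: dict = field(default_factory=dict)


def _count_contacts(model, enzyme_natives, acp_chain_id, cutoff=4.5):
    from scipy.spatial import cKDTree

    exyz, axyz = [], []
    for chain in model.chains:
        for res in chain.polymer_residues():
            if chain.chain_id == acp_chain_id:
                axyz.extend(a.xyz for a in res.heavy_atoms())
            elif res.number in enzyme_natives:
                exyz.extend(a.xyz for a in res.heavy_atoms())
    if not exyz or not axyz:
        return 0
    return int(cKDTree(np.array(exyz)).count_neighbors(cKDTree(np.array(axyz)), cutoff))


def extract_pose(
    model: AtomicModel,
    enzyme: str,
    registry: DomainRegistry,
    canonical_frame_model: AtomicModel,
    rm: ReferenceMap | None = None,
    rm_canonical: ReferenceMap | None = None,
    frame_chains: list[str] | None = None,
    paralog: str = "",
    source_id: str = "",
) -> list[DockPose]:
    """Frame a prediction on the canonical enzyme and read off the ACP pose(s).

    The model is superposed onto ``canonical_frame_model`` through the enzyme
    domain's CA atoms (optionally restricted to specific canonical chains,
    matching the per-enzyme frame conventions).  Every chain carrying at
    least ``MIN_ACP_CORE_CA`` mapped ACP-core residues yields one pose; the
    first pose in the returned list is the copy with the most enzyme-ACP
    heavy-atom contacts (the one actually docked).
    """
    sup = superpose_domain(
        model, canonical_frame_model, enzyme, registry,
        rm_mobile=rm, rm_target=rm_canonical, chains_target=frame_chains,
    )
    framed = apply_transform(model, sup.transform)
    if rm is None:
        top = max(r.number for c in model.chains for r in c.polymer_residues())
        rm = ReferenceMap.identity(model.id, top)
    core_refs = list(range(ACP_CORE[0], ACP_CORE[1] + 1))
    enzyme_natives = {rm.to_native(p) for p in registry.positions(enzyme)} - {None}
    poses = []
    for chain in framed.chains:
        anchors = {}
        for ref in core_refs:
            native = rm.to_native(ref)
            if native is None:
                continue
            res = chain.residue(native)
            if res is None or res.hetero:
                continue
            ca = res.atom("CA")
            if ca is not None:
                anchors[ref] = ca.xyz
        if len(anchors) < MIN_ACP_CORE_CA:
            continue
        ser_native = rm.to_native(ACP_SERINE)
        ser = None
        if ser_native is not None:
            res = chain.residue(ser_native)
            if res is not None and res.atom("CA") is not None:
                ser = res.atom("CA").xyz
        n_contacts = _count_contacts(framed, enzyme_natives, chain.chain_id)
        poses.append((n_contacts, DockPose(
            source_id or model.id, paralog or model.id, enzyme, anchors, ser,
            sup.rmsd, chain.chain_id, unreliable=sup.rmsd > FRAME_RMSD_MAX,
        )))
    if not poses:
        raise StructureError(f"{model.id}: no chain with >= {MIN_ACP_CORE_CA} mapped ACP core CAs")
    poses.sort(key=lambda t: (-t[0], t[1].acp_chain))
    return [p for _, p in poses]


def pose_distance(p: DockPose, q: DockPose) -> float:
    """RMSD over shared ACP-core CA anchors in the common frame (no re-fit)."""
    if p.enzyme != q.enzyme:
        raise ValueError(f"enzyme domains differ: {p.enzyme} vs {q.enzyme}")
    shared = sorted(set(p.anchors) & set(q.anchors))
    if len(shared) < MIN_ACP_CORE_CA:
        raise ValueError(f"only {len(shared)} shared anchors (< {MIN_ACP_CORE_CA})")
    a = np.array([p.anchors[r] for r in shared])
    b = np.array([q.anchors[r] for r in shared])
    return float(np.sqrt(((a - b) ** 2).sum() / len(shared)))


def _distance_matrix(poses: list[DockPose]) -> np.ndarray:
    n = len(poses)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = pose_distance(poses[i], poses[j])
    return dm


def cluster_poses(poses: list[DockPose], tau: float = DEFAULT_TAU) -> list[PoseCluster]:
    """Average-linkage agglomerative clustering of poses, cut at ``tau``.

    Order-independent: poses are canonicalized by (source_id, acp_chain)
    before clustering, so permuting the input cannot change the result.
    """
    if not poses:
        raise ValueError("no poses")
    poses = sorted(poses, key=lambda p: (p.source_id, p.acp_chain))
    if len(poses) == 1:
        return [PoseCluster(poses, poses[0], 0.0)]
    dm = _distance_matrix(poses)
    labels = fcluster(linkage(distance.squareform(dm, checks=False), method="average"),
                      t=tau, criterion="distance")
    clusters = []
    for lab in sorted(set(labels)):
        idx = [i for i, l in enumerate(labels) if l == lab]
        members = [poses[i] for i in idx]
        sub = dm[np.ix_(idx, idx)]
        sums = sub.sum(axis=1)
        order = sorted(range(len(idx)),
                       key=lambda k: (sums[k], members[k].source_id, members[k].acp_chain))
        medoid = members[order[0]]
        mean_pd = float(sub[np.triu_indices(len(idx), 1)].mean()) if len(idx) > 1 else 0.0
        clusters.append(PoseCluster(members, medoid, mean_pd))
    clusters.sort(key=lambda c: (-len(c), c.mean_pairwise_distance,
                                 min(p.source_id for p in c.members)))
    return clusters


def consensus_site(clusters: list[PoseCluster],
                   all_poses: list[DockPose] | None = None,
                   tau: float = DEFAULT_TAU) -> ConsensusResult:
    """The consensus docking site is the largest cluster.

    Ties break toward the smaller mean pairwise distance.  A paralog carries
    the site iff at least one of its poses is a member (synthases are
    counted, not poses).
    """
    if not clusters:
        raise ValueError("no clusters")
    ordered = sorted(clusters, key=lambda c: (-len(c), c.mean_pairwise_distance,
                                              min(p.source_id for p in c.members)))
    consensus = ordered[0]
    if all_poses is None:
        all_poses = [p for c in ordered for p in c.members]
    membership: dict[str, dict] = {}
    consensus_ids = {(id(p)) for p in consensus.members}
    for p in all_poses:
        rec = membership.setdefault(p.paralog, {"has_consensus": False,
                                                "n_poses": 0, "n_consensus_poses": 0})
        rec["n_poses"] += 1
        if id(p) in consensus_ids:
            rec["has_consensus"] = True
            rec["n_consensus_poses"] += 1
    return ConsensusResult(consensus.medoid.enzyme, ordered, 0, membership, tau)


def chamber_summary(
    anchors_by_enzyme: dict[str, np.ndarray | list],
    chamber_centers: np.ndarray | None = None,
) -> ChamberSummary:
    """Summarize the reaction chamber from per-enzyme consensus serine anchors.

    All anchors must already sit in one common (Pks16 dimer) frame.  Each C2
    dimer has two equivalent chambers; with explicit ``chamber_centers``
    (one per protomer's KS active-site side, shape (2, 3)) anchors are
    assigned to the nearer center, otherwise all anchors go to chamber 1 and
    chamber 2 is reported as its C2-equivalent copy.  Per chamber: convex
    hull volume of the anchors (0 with a flag when fewer than 4 points or
    degenerate) and maximum pairwise displacement.
    """
    flat: list[tuple[str, np.ndarray]] = []
    for enzyme, val in anchors_by_enzyme.items():
        arr = np.asarray(val, dtype=float)
        if arr.ndim == 1:
            arr = arr.reshape(1, 3)
        for row in arr:
            flat.append((enzyme, row))
    if not flat:
        raise ValueError("no anchors")

    if chamber_centers is not None:
        centers = np.asarray(chamber_centers, dtype=float).reshape(2, 3)
        groups: list[list] = [[], []]
        for enzyme, xyz in flat:
            d = np.linalg.norm(centers - xyz, axis=1)
            groups[int(np.argmin(d))].append((enzyme, xyz))
        mirrored = False
    else:
        groups = [flat, flat]
        mirrored = True

    chambers = []
    for k, group in enumerate(groups):
        flag = ""
        if not group:
            chambers.append({"enzymes": [], "hull_volume": 0.0,
                             "max_displacement": 0.0, "flag": "empty"})
            continue
        xyz = np.array([g[1] for g in group])
        if len(xyz) > 1:
            pd = distance.pdist(xyz)
            max_disp = float(pd.max())
        else:
            max_disp = 0.0
        volume = 0.0
        if len(xyz) >= 4:
            try:
                volume = float(ConvexHull(xyz).volume)
            except QhullError:
                flag = "degenerate"
        else:
            flag = "fewer_than_4_anchors"
        if mirrored and k == 1:
            flag = (flag + ";" if flag else "") + "C2_equivalent_copy"
        chambers.append({
            "enzymes": [g[0] for g in group],
            "hull_volume": volume,
            "max_displacement": max_disp,
            "flag": flag,
        })
    return ChamberSummary(chambers, {"n_anchors": len(flat),
                                     "mirrored": chamber_centers is None})
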