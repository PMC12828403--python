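"""Pose extraction, pose metric, consensus clustering, chamber summary."""

import numpy as np
import pytest

from ddpks import docksite, synthdata
from ddpks.docksite import (
    ACP_SERINE,
    chamber_summary,
    cluster_poses,
    consensus_site,
    extract_pose,
    pose_distance,
)
from ddpks.rigid import RigidTransform, apply_transform
from ddpks.synthdata import PoseEnsembleSpec, _complex_model, ensemble_registry


@pytest.fixture(scope="module")
def canonical():
    return _complex_model("canonical", "ER", RigidTransform.identity())


@pytest.fixture(scope="module")
def registry():
    return ensemble_registry("ER")


def test_extract_pose_self_framing(canonical, registry):
    poses = extract_pose(canonical, "ER", registry, canonical)
    assert len(poses) == 1
    p = poses[0]
    assert p.frame_rmsd < 1e-9
    native_ser = canonical.chain("P").residue(ACP_SERINE).atom("CA").xyz
    assert np.allclose(p.serine_ca, native_ser)


@pytest.mark.parametrize("seed", range(5))
def test_extract_pose_frame_invariant(canonical, registry, seed):
    """A rigidly moved complex yields the identical pose after re-framing."""
    rng = np.random.default_rng(seed)
    moved = apply_transform(canonical, synthdata.random_transform(rng))
    p0 = extract_pose(canonical, "ER", registry, canonical)[0]
    p1 = extract_pose(moved, "ER", registry, canonical)[0]
    for ref in p0.anchors:
        assert np.abs(p0.anchors[ref] - p1.anchors[ref]).max() < 1e-6


def test_pose_distance_metric_properties(canonical, registry):
    p = extract_pose(canonical, "ER", registry, canonical)[0]
    assert pose_distance(p, p) == 0.0
    shifted = _complex_model("shifted", "ER",
                             RigidTransform(np.eye(3), np.array([5.0, 0.0, 0.0])))
    q = extract_pose(shifted, "ER", registry, canonical)[0]
    assert pose_distance(p, q) == pytest.approx(5.0)
    assert pose_distance(q, p) == pytest.approx(5.0)


@pytest.mark.parametrize("seed", range(5))
def test_pose_distance_equals_coordinate_rmsd_oracle(canonical, registry, seed):
    rng = np.random.default_rng(seed)
    t1 = RigidTransform(np.eye(3), rng.uniform(-10, 10, 3))
    t2 = RigidTransform(np.eye(3), rng.uniform(-10, 10, 3))
    p = extract_pose(_complex_model("m1", "ER", t1), "ER", registry, canonical)[0]
    q = extract_pose(_complex_model("m2", "ER", t2), "ER", registry, canonical)[0]
    shared = sorted(set(p.anchors) & set(q.anchors))
    a = np.array([p.anchors[r] for r in shared])
    b = np.array([q.anchors[r] for r in shared])
    oracle = np.sqrt(((a - b) ** 2).sum() / len(shared))
    assert pose_distance(p, q) == pytest.approx(oracle)


def _poses_at(translations, canonical, registry, prefix="m"):
    poses = []
    for i, t in enumerate(translations):
        model = _complex_model(f"{prefix}{i:03d}", "ER",
                               RigidTransform(np.eye(3), np.asarray(t, float)))
        poses.append(extract_pose(model, "ER", registry, canonical)[0])
    return poses


def test_all_identical_poses_form_one_cluster(canonical, registry):
    poses = _poses_at([np.zeros(3)] * 6, canonical, registry)
    clusters = cluster_poses(poses, tau=8.0)
    assert len(clusters) == 1
    assert len(clusters[0]) == 6


def test_two_planted_sites_recovered(canonical, registry):
    """Two sites 12 A apart with 2 A jitter at tau = 8 separate cleanly."""
    rng = np.random.default_rng(0)
    site1 = [rng.normal(0, 2.0, 3) for _ in range(8)]
    site2 = [np.array([12.0, 0, 0]) + rng.normal(0, 2.0, 3) for _ in range(6)]
    poses = _poses_at(site1 + site2, canonical, registry)
    clusters = cluster_poses(poses, tau=8.0)
    assert len(clusters) == 2
    assert sorted(len(c) for c in clusters) == [6, 8]


def test_clustering_permutation_invariant(canonical, registry):
    rng = np.random.default_rng(1)
    translations = ([rng.normal(0, 2.0, 3) for _ in range(10)]
                    + [np.array([40.0, 0, 0]) + rng.normal(0, 2.0, 3) for _ in range(3)])
    poses = _poses_at(translations, canonical, registry)
    c1 = cluster_poses(poses, tau=8.0)
    c2 = cluster_poses(poses[::-1], tau=8.0)
    ids1 = [sorted(p.source_id for p in c.members) for c in c1]
    ids2 = [sorted(p.source_id for p in c.members) for c in c2]
    assert ids1 == ids2


def test_consensus_site_single_cluster(canonical, registry):
    poses = _poses_at([np.zeros(3)] * 4, canonical, registry)
    for i, p in enumerate(poses):
        p.paralog = f"Pks{i:02d}"
    result = consensus_site(cluster_poses(poses, 8.0), poses)
    assert result.n_carriers() == 4
    assert all(m["has_consensus"] for m in result.membership.values())


def test_planted_ensemble_membership_matches_truth():
    """40 synthetic paralogs, 27 planted carriers: consensus membership
    recovers the planted carrier set exactly."""
    ens = synthdata.make_pose_ensemble(PoseEnsembleSpec(seed=5, n_poses_per=3))
    poses = [
        extract_pose(rec["model"], "ER", ens["registry"], ens["canonical"],
                     paralog=rec["paralog"], source_id=rec["source_id"])[0]
        for rec in ens["records"]
    ]
    result = consensus_site(cluster_poses(poses, 8.0), poses)
    predicted = {p for p, m in result.membership.items() if m["has_consensus"]}
    assert predicted == ens["carriers"]
    assert result.n_carriers() == 27


def test_chamber_coincident_anchors():
    anchors = {e: np.array([1.0, 2.0, 3.0]) for e in ("KS", "AT", "KR", "DH", "ER")}
    summary = chamber_summary(anchors)
    assert len(summary.chambers) == 2
    assert summary.chambers[0]["hull_volume"] == 0.0
    assert summary.chambers[0]["max_displacement"] == 0.0


def test_chamber_tetrahedron_volume_closed_form():
    """Regular tetrahedron, edge a = 10: V = a^3 / (6 sqrt 2) = 117.85 A^3."""
    a = 10.0
    verts = np.array([
        [1.0, 1.0, 1.0],
        [1.0, -1.0, -1.0],
        [-1.0, 1.0, -1.0],
        [-1.0, -1.0, 1.0],
    ]) * (a / (2 * np.sqrt(2)))
    anchors = dict(zip(["KS", "AT", "KR", "ER"], verts))
    summary = chamber_summary(anchors)
    expected = a ** 3 / (6 * np.sqrt(2))
    assert summary.chambers[0]["hull_volume"] == pytest.approx(expected, rel=1e-3)
    assert summary.chambers[0]["max_displacement"] == pytest.approx(a, rel=1e-9)


def test_chamber_assignment_by_center_proximity():
    centers = np.array([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]])
    anchors = {"KS": [[1.0, 0, 0], [99.0, 0, 0]], "ER": [[2.0, 0, 0]]}
    summary = chamber_summary(anchors, chamber_centers=centers)
    assert sorted(summary.chambers[0]["enzymes"]) == ["ER", "KS"]
    assert summary.chambers[1]["enzymes"] == ["KS"]
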