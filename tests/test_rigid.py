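"""Superposition, transforms, fragment merging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddpks import synthdata
from ddpks.rigid import (
    FragmentSpec,
    RigidTransform,
    apply_transform,
    kabsch,
    merge_fragments,
    superpose_domain,
)
from ddpks.structio import StructureError


def _random_rotation(rng):
    return synthdata.random_transform(rng, max_translation=0.0).rotation


def test_kabsch_identity():
    pts = np.random.default_rng(0).normal(size=(10, 3))
    t, rmsd = kabsch(pts, pts)
    assert np.allclose(t.rotation, np.eye(3), atol=1e-9)
    assert np.allclose(t.translation, 0.0, atol=1e-9)
    assert rmsd < 1e-12


@pytest.mark.parametrize("seed", range(5))
def test_kabsch_recovers_planted_rotation(seed):
    rng = np.random.default_rng(seed)
    mobile = rng.normal(size=(30, 3)) * 10
    r0 = _random_rotation(rng)
    t0 = rng.uniform(-20, 20, size=3)
    target = mobile @ r0.T + t0
    t, rmsd = kabsch(mobile, target)
    assert np.abs(t.rotation - r0).max() < 1e-6
    assert np.abs(t.translation - t0).max() < 1e-6
    assert rmsd < 1e-6


def test_kabsch_noisy_rmsd_matches_expectation_band():
    """With iid noise sigma on N fitted points the residual RMSD concentrates
    around sigma * sqrt(3 * (1 - 3/N)) (6 of 3N dofs absorbed by the fit)."""
    sigma, n = 0.5, 100
    rng = np.random.default_rng(123)
    rmsds = []
    for _ in range(100):
        mobile = rng.normal(size=(n, 3)) * 10
        r0 = _random_rotation(rng)
        target = mobile @ r0.T + rng.uniform(-5, 5, 3) + rng.normal(0, sigma, size=(n, 3))
        _, rmsd = kabsch(mobile, target)
        rmsds.append(rmsd)
    expected = sigma * np.sqrt(3 * (1 - 3 / n))
    assert abs(np.mean(rmsds) - expected) / expected < 0.10


def test_kabsch_rejects_too_few_points():
    with pytest.raises(ValueError):
        kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


def test_kabsch_collinear_warns_but_returns():
    pts = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.warns(UserWarning, match="degenerate"):
        t, rmsd = kabsch(pts, pts + 1.0)
    assert rmsd < 1e-9


def test_transform_group_properties():
    rng = np.random.default_rng(5)
    t = synthdata.random_transform(rng)
    x = rng.normal(size=(20, 3))
    assert np.allclose(RigidTransform.identity().apply(x), x)
    roundtrip = t.inverse().apply(t.apply(x))
    assert np.abs(roundtrip - x).max() < 1e-9
    composed = t.compose(t.inverse())
    assert np.allclose(composed.rotation, np.eye(3), atol=1e-9)
    assert np.allclose(composed.translation, 0.0, atol=1e-9)


@settings(max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_transforms_are_isometries(seed):
    """Pairwise distances are preserved to 1e-9 under any rigid transform."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(50, 3)) * 30
    t = synthdata.random_transform(rng)
    y = t.apply(x)
    from scipy.spatial.distance import pdist

    assert np.abs(pdist(x) - pdist(y)).max() < 1e-9


def test_reflection_rejected():
    with pytest.raises(ValueError, match="improper"):
        RigidTransform(np.diag([-1.0, 1.0, 1.0]), np.zeros(3))


def test_superpose_domain_self_is_exact(toy_dimer, toy_registry):
    model, _ = toy_dimer
    res = superpose_domain(model, model, "KS", toy_registry)
    assert res.rmsd < 1e-9
    assert res.chain_pairing == {"A": "A", "B": "B"}


def test_superpose_domain_selects_swapped_pairing(toy_dimer, toy_registry):
    """Chains relabeled A<->B plus an arbitrary rigid move: the lower-RMSD
    pairing must be the swap, recovered to numerical precision."""
    rng = np.random.default_rng(9)
    # break the exact C2 symmetry so the two pairings are distinguishable
    model = synthdata.add_noise(toy_dimer[0], 0.2, rng)
    moved = apply_transform(model, synthdata.random_transform(rng))
    swapped = moved.copy()
    swapped.chains[0].chain_id, swapped.chains[1].chain_id = "B", "A"
    res = superpose_domain(swapped, model, "KS", toy_registry)
    assert res.rmsd < 1e-6
    assert res.chain_pairing == {"B": "A", "A": "B"}


def test_superpose_domain_too_few_atoms_errors(toy_dimer, toy_registry):
    from ddpks.refmap import DomainRegistry

    model, _ = toy_dimer
    tiny = DomainRegistry({"KS": [(1, 5)]})
    with pytest.raises(StructureError, match="paired CA"):
        superpose_domain(model, model, "KS", tiny)


def _split(parent, meta, transform=None, sigma=0.0, seed=0):
    return synthdata.make_fragment_pair(
        parent, junction=meta["domain_ranges"]["AT"][1],
        shared_span=meta["domain_ranges"]["KS"],
        transform2=transform, noise_sigma=sigma, seed=seed)


def test_merge_lossless_reconstruction(toy_dimer, toy_registry):
    """Exact fragments, identity transform: the merge is the parent."""
    parent, meta = toy_dimer
    frag1, frag2, _ = _split(parent, meta)
    merged = merge_fragments(frag1, frag2,
                             FragmentSpec(junction=meta["domain_ranges"]["AT"][1]),
                             toy_registry)
    assert np.abs(parent.coords() - merged.model.coords()).max() < 1e-9
    j = meta["domain_ranges"]["AT"][1]
    for chain_id in ("A", "B"):
        ca_j = parent.chain(chain_id).residue(j).atom("CA").xyz
        ca_n = parent.chain(chain_id).residue(j + 1).atom("CA").xyz
        expected = float(np.linalg.norm(ca_j - ca_n))
        got = merged.junction_report["chains"][chain_id]["junction_ca_ca_distance"]
        assert got == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("seed", range(5))
def test_merge_recovers_noisy_planted_transform(toy_dimer, toy_registry, seed):
    parent, meta = toy_dimer
    rng = np.random.default_rng(seed)
    sigma = 0.3
    frag1, frag2, _ = _split(parent, meta, synthdata.random_transform(rng), sigma, seed)
    merged = merge_fragments(frag1, frag2,
                             FragmentSpec(junction=meta["domain_ranges"]["AT"][1]),
                             toy_registry)
    rmsd = np.sqrt(((parent.coords() - merged.model.coords()) ** 2).sum()
                   / len(parent.coords()))
    assert rmsd <= 2 * sigma


def test_merge_idempotent(toy_dimer, toy_registry):
    """Re-splitting a merged model and merging again reproduces it exactly."""
    parent, meta = toy_dimer
    frag1, frag2, _ = _split(parent, meta)
    spec = FragmentSpec(junction=meta["domain_ranges"]["AT"][1])
    merged = merge_fragments(frag1, frag2, spec, toy_registry)
    f1b, f2b, _ = _split(merged.model, meta)
    merged2 = merge_fragments(f1b, f2b, spec, toy_registry)
    assert np.abs(merged.model.coords() - merged2.model.coords()).max() < 1e-9


def test_merge_short_shared_span_errors(toy_dimer, toy_registry):
    parent, meta = toy_dimer
    frag1, frag2, _ = synthdata.make_fragment_pair(
        parent, junction=meta["domain_ranges"]["AT"][1], shared_span=(1, 8))
    from ddpks.refmap import DomainRegistry

    reg = DomainRegistry({"KS": [(1, 8)]})
    with pytest.raises(StructureError):
        merge_fragments(frag1, frag2,
                        FragmentSpec(junction=meta["domain_ranges"]["AT"][1]), reg)
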