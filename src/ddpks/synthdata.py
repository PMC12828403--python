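"""Synthetic fixtures with planted ground truth for every pipeline stage.

The generators emulate the geometry and sequence features the analyses
consume — C2-symmetric multidomain dimers, overlapping fragment pairs
related by a known rigid transform plus coordinate noise, enzyme+ACP pose
ensembles with one planted consensus site plus outliers, and paralog
sequence pairs at controlled identity with planted unique/shared tryptic
peptides — so the merge, interface, consensus and peptide stages can all be
scored against known truth without any external data.

Toy domains are idealized alpha-helical CA traces (rise 1.5 A, radius
2.3 A) with minimal backbone atoms; they are shapes, not chemistry.  All
randomness flows through explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .paralogpep import Peptide
from .refmap import DomainRegistry
from .rigid import RigidTransform, apply_transform
from .structio import AA1TO3, Atom, AtomicModel, Chain, Residue

__all__ = [
    "SynthDimerSpec",
    "PoseEnsembleSpec",
    "ParalogPairSpec",
    "make_dimer",
    "make_fragment_pair",
    "make_pose_ensemble",
    "make_paralog_pair",
    "random_transform",
    "add_noise",
]

HELIX_RISE = 1.5
HELIX_RADIUS = 2.3
HELIX_TURN_DEG = 100.0
MIN_DOMAIN_LENGTH = 20
CLASH_MIN_DISTANCE = 2.5


def random_transform(rng: np.random.Generator, max_translation: float = 50.0) -> RigidTransform:
    """Uniform random proper rotation plus a random translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.uniform(-max_translation, max_translation, size=3)
    return RigidTransform(rot, t)


def add_noise(model: AtomicModel, sigma: float, rng: np.random.Generator) -> AtomicModel:
    """Iid Gaussian coordinate noise, sigma per coordinate, on a copy."""
    out = model.copy()
    if sigma > 0:
        for chain in out.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    atom.xyz = atom.xyz + rng.normal(0.0, sigma, size=3)
    return out


def _helix_residues(n: int, start_number: int, sequence: str | None = None) -> list[Residue]:
    """Idealized alpha-helical trace along +z with minimal backbone atoms."""
    residues = []
    for i in range(n):
        theta = np.radians(HELIX_TURN_DEG * i)
        radial = np.array([np.cos(theta), np.sin(theta), 0.0])
        ca = HELIX_RADIUS * radial + np.array([0.0, 0.0, HELIX_RISE * i])
        aa1 = sequence[i] if sequence else "A"
        res = Residue(start_number + i, AA1TO3.get(aa1, "ALA"))
        res.atoms = [
            Atom("N", "N", ca + np.array([0.0, 0.0, -0.75]) - 0.4 * radial),
            Atom("CA", "C", ca),
            Atom("C", "C", ca + np.array([0.0, 0.0, 0.75]) + 0.2 * radial),
            Atom("O", "O", ca + np.array([0.0, 0.0, 1.0]) + 1.2 * radial),
            Atom("CB", "C", ca + 1.5 * radial),
        ]
        residues.append(res)
    return residues


@dataclass
class SynthDimerSpec:
    """Ordered domain layout of one protomer plus the C2 placement of its partner."""

    domains: list[tuple[str, int]]           # (name, length >= 20)
    seed: int = 0
    spacing: float = 22.0                    # inter-domain offset along x, Angstrom
    c2_offset: float = 18.0                  # gap between protomer and C2 axis
    placements: list[RigidTransform] | None = None

    def __post_init__(self):
        if not self.domains:
            raise ValueError("need at least one domain")
        for name, length in self.domains:
            if length < MIN_DOMAIN_LENGTH:
                raise ValueError(f"domain {name}: length {length} < {MIN_DOMAIN_LENGTH}")


def make_dimer(spec: SynthDimerSpec) -> tuple[AtomicModel, dict]:
    """Build a C2-symmetric toy multidomain dimer with recorded ground truth.

    Chain A concatenates one helix bundle per domain, placed by per-domain
    rigid transforms; chain B is the exact C2 image of chain A about an axis
    parallel to z, displaced beyond the protomer.  Placements causing
    inter-chain clashes are jittered and retried up to 10 times.
    """
    rng = np.random.default_rng(spec.seed)
    n_dom = len(spec.domains)
    base_placements = spec.placements or [
        RigidTransform(np.eye(3), np.array([i * spec.spacing, 0.0, 0.0]))
        for i in range(n_dom)
    ]
    cx = n_dom * spec.spacing + spec.c2_offset
    c2 = RigidTransform(np.diag([-1.0, -1.0, 1.0]), np.array([2 * cx, 0.0, 0.0]))

    for attempt in range(10):
        placements = base_placements if attempt == 0 else [
            RigidTransform(p.rotation, p.translation + rng.normal(0, 2.0, size=3))
            for p in base_placements
        ]
        chain_a = Chain("A")
        ranges: dict[str, tuple[int, int]] = {}
        number = 1
        for (name, length), placement in zip(spec.domains, placements):
            residues = _helix_residues(length, number)
            for res in residues:
                for atom in res.atoms:
                    atom.xyz = placement.apply(atom.xyz)
            chain_a.residues.extend(residues)
            ranges[name] = (number, number + length - 1)
            number += length
        chain_b = Chain("B", [
            Residue(r.number, r.name,
                    [Atom(a.name, a.element, c2.apply(a.xyz)) for a in r.atoms])
            for r in chain_a.residues
        ])
        model = AtomicModel("synth_dimer", [chain_a, chain_b])
        from scipy.spatial import cKDTree

        xa = np.array([a.xyz for r in chain_a.residues for a in r.atoms])
        xb = np.array([a.xyz for r in chain_b.residues for a in r.atoms])
        d, _ = cKDTree(xb).query(xa, k=1)
        if d.min() > CLASH_MIN_DISTANCE:
            model.validate()
            meta = {
                "domain_ranges": ranges,
                "placements": placements,
                "c2_transform": c2,
                "seed": spec.seed,
            }
            return model, meta
    raise ValueError("could not place domains without clashes in 10 tries")


def dimer_registry(meta: dict) -> DomainRegistry:
    """Domain registry matching a generated dimer's residue numbering."""
    return DomainRegistry({name: [rr] for name, rr in meta["domain_ranges"].items()})


def make_fragment_pair(
    parent: AtomicModel,
    junction: int,
    shared_span: tuple[int, int],
    transform2: RigidTransform | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    frag1_end: int | None = None,
) -> tuple[AtomicModel, AtomicModel, dict]:
    """Cut a parent dimer into two overlapping fragments with known truth.

    Fragment 1 keeps residues 1..frag1_end (default: through the junction);
    fragment 2 keeps the shared span (the common superposition domain, e.g.
    KS) plus everything downstream of the junction, then is moved by
    ``transform2`` with iid Gaussian noise added to both fragments.
    """
    last = max(r.number for c in parent.chains for r in c.polymer_residues())
    if not shared_span[0] <= junction < last:
        raise ValueError(f"junction {junction} not interior to parent [1,{last}]")
    frag1_end = junction if frag1_end is None else frag1_end
    transform2 = transform2 or RigidTransform.identity()
    rng = np.random.default_rng(seed)

    def subset(name, keep):
        m = AtomicModel(name)
        for chain in parent.chains:
            residues = [r for r in chain.residues if not r.hetero and keep(r.number)]
            if residues:
                m.chains.append(Chain(chain.chain_id, [
                    Residue(r.number, r.name,
                            [Atom(a.name, a.element, a.xyz.copy()) for a in r.atoms])
                    for r in residues
                ]))
        return m

    frag1 = subset("frag1", lambda n: n <= frag1_end)
    frag2 = subset("frag2", lambda n: shared_span[0] <= n <= shared_span[1] or n > junction)
    frag2 = apply_transform(frag2, transform2)
    frag1 = add_noise(frag1, noise_sigma, rng)
    frag2 = add_noise(frag2, noise_sigma, rng)
    truth = {"transform2": transform2, "parent": parent, "junction": junction,
             "shared_span": shared_span, "noise_sigma": noise_sigma, "seed": seed}
    return frag1, frag2, truth


@dataclass
class PoseEnsembleSpec:
    """Ensemble of enzyme+ACP models with one planted consensus docking site."""

    n_paralogs: int = 40
    n_carriers: int = 27
    n_poses_per: int = 5
    jitter_sigma: float = 2.0           # per-coordinate, consensus poses
    outlier_min_separation: float = 30.0
    outlier_fraction: float = 0.3       # among carrier poses after the first
    enzyme: str = "ER"
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.n_carriers <= self.n_paralogs:
            raise ValueError("n_carriers must be within [0, n_paralogs]")
        if self.jitter_sigma < 0 or self.outlier_min_separation <= 0:
            raise ValueError("jitter/separation must be positive")


# numbering conventions of the toy complexes (reference = native)
_ENZYME_SPAN = {"KS": (60, 159), "AT": (700, 799), "MT": (1300, 1399),
                "DH": (1000, 1099), "KR": (1700, 1799), "ER": (1850, 1949)}
_ACP_SPAN = (2524, 2583)
_CONSENSUS_OFFSET = np.array([14.0, 6.0, 40.0])


def ensemble_registry(enzyme: str) -> DomainRegistry:
    """Registry for the toy enzyme+ACP complexes (reference numbering)."""
    return DomainRegistry({enzyme: [_ENZYME_SPAN[enzyme]], "ACP": [list(_ACP_SPAN)]})


def _complex_model(model_id: str, enzyme: str, acp_transform: RigidTransform) -> AtomicModel:
    e0, e1 = _ENZYME_SPAN[enzyme]
    enzyme_chain = Chain("E", _helix_residues(e1 - e0 + 1, e0))
    acp_res = _helix_residues(_ACP_SPAN[1] - _ACP_SPAN[0] + 1, _ACP_SPAN[0])
    for res in acp_res:
        for atom in res.atoms:
            atom.xyz = acp_transform.apply(atom.xyz + _CONSENSUS_OFFSET)
    return AtomicModel(model_id, [enzyme_chain, Chain("P", acp_res)])


def make_pose_ensemble(spec: PoseEnsembleSpec) -> dict:
    """Generate an ensemble of enzyme+ACP predictions with planted truth.

    Carrier paralogs contribute at least one consensus pose (the planted
    site perturbed by per-coordinate Gaussian jitter); every other pose may
    be an outlier displaced at least ``outlier_min_separation`` in a random
    direction.  Non-carriers contribute only outliers.  Each model is
    additionally moved by a random global rigid transform so that pose
    extraction must re-frame it.  Returns models, the canonical frame model,
    the registry, and the planted labels.
    """
    rng = np.random.default_rng(spec.seed)
    paralogs = [f"Pks{i + 1:02d}" for i in range(spec.n_paralogs)]
    carrier_idx = rng.choice(spec.n_paralogs, size=spec.n_carriers, replace=False)
    carriers = {paralogs[i] for i in carrier_idx}

    canonical = _complex_model("canonical", spec.enzyme, RigidTransform.identity())
    records = []
    for paralog in paralogs:
        is_carrier = paralog in carriers
        for j in range(spec.n_poses_per):
            if is_carrier and (j == 0 or rng.uniform() > spec.outlier_fraction):
                pose_class = "consensus"
                jitter = rng.normal(0.0, spec.jitter_sigma, size=3)
                acp_t = RigidTransform(np.eye(3), jitter)
            else:
                pose_class = "outlier"
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                dist = spec.outlier_min_separation * rng.uniform(1.0, 2.0)
                acp_t = RigidTransform(np.eye(3), dist * direction)
            model = _complex_model(f"{paralog}_pose{j}", spec.enzyme, acp_t)
            model = apply_transform(model, random_transform(rng))
            records.append({"model": model, "paralog": paralog,
                            "source_id": model.id, "pose_class": pose_class})
    return {
        "records": records,
        "canonical": canonical,
        "registry": ensemble_registry(spec.enzyme),
        "carriers": carriers,
        "spec": spec,
    }


@dataclass
class ParalogPairSpec:
    """Paralog sequence pair at controlled identity with planted peptide classes."""

    length: int = 2600
    identity: float = 96.0               # percent
    n_unique_a: int = 29
    n_unique_b: int = 0
    n_shared: int = 58
    seed: int = 0


_INTERIOR_AA = "ACDEFGHILMNQSTVWY"       # no K/R (cut sites), no P (suppression)


def make_paralog_pair(spec: ParalogPairSpec) -> tuple[str, str, list[Peptide], dict]:
    """Build (seqA, seqB, detected peptides, truth classes).

    Both sequences are concatenations of tryptic blocks (interior residues
    from a K/R/P-free alphabet, K or R terminator), so 0-missed digestion
    recovers the blocks exactly.  seqB differs from seqA by single-residue
    substitutions: one inside each block planted as a unique peptide, plus
    filler substitutions in undetected blocks until the target identity is
    met.  Shared detected peptides are left untouched in both.
    """
    rng = np.random.default_rng(spec.seed)
    blocks = []
    total = 0
    while total < spec.length:
        interior = "".join(rng.choice(list(_INTERIOR_AA), size=int(rng.integers(7, 15))))
        terminator = "K" if rng.uniform() < 0.5 else "R"
        blocks.append(interior + terminator)
        total += len(blocks[-1])
    n_detected = spec.n_unique_a + spec.n_unique_b + spec.n_shared
    if n_detected > len(blocks):
        raise ValueError("sequence too short for the requested planted peptides")

    length = sum(len(b) for b in blocks)
    n_subs_target = round((1.0 - spec.identity / 100.0) * length)
    n_forced = spec.n_unique_a + spec.n_unique_b
    if n_subs_target < n_forced:
        raise ValueError(
            f"identity {spec.identity}% allows only {n_subs_target} substitutions, "
            f"but {n_forced} unique peptides are planted"
        )

    order = rng.permutation(len(blocks))
    idx_a = list(order[: spec.n_unique_a])
    idx_b = list(order[spec.n_unique_a: spec.n_unique_a + spec.n_unique_b])
    idx_shared = list(order[spec.n_unique_a + spec.n_unique_b: n_detected])
    idx_free = list(order[n_detected:])

    blocks_b = list(blocks)

    def substitute(block: str) -> str:
        pos = int(rng.integers(0, len(block) - 1))      # never the terminator
        choices = [c for c in _INTERIOR_AA if c != block[pos]]
        return block[:pos] + str(rng.choice(choices)) + block[pos + 1:]

    for i in idx_a + idx_b:
        blocks_b[i] = substitute(blocks[i])

    remaining = n_subs_target - n_forced
    capacity = sum(len(blocks[i]) - 1 for i in idx_free)
    if remaining > capacity:
        raise ValueError(
            f"identity {spec.identity}% needs {remaining} filler substitutions but "
            f"only {capacity} positions are free of planted peptides"
        )
    free_cycle = list(idx_free)
    rng.shuffle(free_cycle)
    used: dict[int, set[int]] = {}
    k = 0
    while remaining > 0:
        i = free_cycle[k % len(free_cycle)]
        taken = used.setdefault(i, set())
        open_pos = [p for p in range(len(blocks[i]) - 1) if p not in taken]
        if open_pos:
            pos = open_pos[int(rng.integers(0, len(open_pos)))]
            old = blocks_b[i]
            choices = [c for c in _INTERIOR_AA if c != old[pos]]
            blocks_b[i] = old[:pos] + str(rng.choice(choices)) + old[pos + 1:]
            taken.add(pos)
            remaining -= 1
        k += 1

    seq_a = "".join(blocks)
    seq_b = "".join(blocks_b)

    detected: list[tuple[str, str]] = []
    detected += [(blocks[i], "unique_a") for i in idx_a]
    detected += [(blocks_b[i], "unique_b") for i in idx_b]
    detected += [(blocks[i], "shared") for i in idx_shared]
    rng.shuffle(detected)

    # verify the planted classes hold as exact-substring facts
    for pep, cls in detected:
        in_a, in_b = pep in seq_a, pep in seq_b
        got = {(True, False): "unique_a", (False, True): "unique_b",
               (True, True): "shared"}.get((in_a, in_b), "unmatched")
        if got != cls:
            raise RuntimeError(
                f"planted peptide {pep} classifies as {got}, expected {cls}; "
                f"re-seed the generator"
            )
    truth = {pep: cls for pep, cls in detected}
    peptides = [Peptide(pep, "detected") for pep, _ in detected]
    return seq_a, seq_b, peptides, truth
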