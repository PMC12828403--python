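"""Reference numbering across the PKS paralog family.

Interface positions throughout the family are expressed in Pks16 coordinates
("reference numbering").  This module provides the optimal global pairwise
alignment used to establish those coordinates, percent identity, the
reference-position <-> native-position map for any paralog, the curated
domain registry, and the mutation utility used to build interface-abrogated
constructs (e.g. the KS* triple aspartate at reference 86-88).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "AlignmentResult",
    "ReferenceMap",
    "DomainRegistry",
    "MutationSpec",
    "MISSING",
    "global_align",
    "percent_identity",
    "build_reference_map",
    "map_positions",
    "mutate_positions",
    "load_registry",
    "default_registry",
]

VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")

#: sentinel for a reference position with no counterpart in the target
MISSING = None

#: identity floor below which a reference map is flagged unreliable
IDENTITY_FLOOR = 15.0


class SequenceError(ValueError):
    pass


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    matches: int
    aligned_columns: int

    def __post_init__(self):
        assert self.aligned_a.replace("-", "") and self.aligned_b.replace("-", "")
        assert len(self.aligned_a) == len(self.aligned_b) == self.aligned_columns


@dataclass
class ReferenceMap:
    """Partial, strictly monotone bijection reference_position <-> native_position."""

    paralog: str
    ref_to_native: dict[int, int]
    unreliable: bool = False

    def __post_init__(self):
        self.native_to_ref = {v: k for k, v in self.ref_to_native.items()}
        if len(self.native_to_ref) != len(self.ref_to_native):
            raise ValueError("reference map not bijective")
        items = sorted(self.ref_to_native.items())
        for (r0, n0), (r1, n1) in zip(items, items[1:]):
            if n1 <= n0:
                raise ValueError("reference map not monotone")

    def to_native(self, ref_pos: int):
        return self.ref_to_native.get(ref_pos, MISSING)

    def to_reference(self, native_pos: int):
        return self.native_to_ref.get(native_pos, MISSING)

    @classmethod
    def identity(cls, paralog: str, length: int) -> "ReferenceMap":
        return cls(paralog, {i: i for i in range(1, length + 1)})

    def to_tsv(self) -> str:
        lines = ["reference_position\tnative_position"]
        lines += [f"{r}\t{n}" for r, n in sorted(self.ref_to_native.items())]
        return "\n".join(lines) + "\n"


@dataclass
class DomainRegistry:
    """Reference (Pks16-numbered) residue ranges per domain."""

    ranges: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self):
        for name, rr in self.ranges.items():
            rr.sort()
            for (a0, b0), (a1, b1) in zip(rr, rr[1:]):
                if a1 <= b0:
                    raise ValueError(f"domain {name}: overlapping ranges {rr}")

    def domains(self) -> list[str]:
        return list(self.ranges)

    def positions(self, domain: str) -> list[int]:
        if domain not in self.ranges:
            raise KeyError(f"unknown domain {domain!r}; have {sorted(self.ranges)}")
        out = []
        for a, b in self.ranges[domain]:
            out.extend(range(a, b + 1))
        return out

    def contains(self, domain: str, position: int) -> bool:
        return any(a <= position <= b for a, b in self.ranges.get(domain, []))


@dataclass
class MutationSpec:
    """(reference_position, new 1-letter residue) substitutions."""

    changes: list[tuple[int, str]]

    def __post_init__(self):
        for pos, aa in self.changes:
            if aa not in VALID_AA or len(aa) != 1:
                raise SequenceError(f"bad replacement residue {aa!r} at {pos}")


def _check_seq(seq: str, label: str) -> str:
    if not seq:
        raise SequenceError(f"{label}: empty sequence")
    seq = seq.upper()
    bad = sorted(set(seq) - VALID_AA)
    if bad:
        raise SequenceError(f"{label}: non-amino-acid characters {bad}")
    return seq


def _aligner(matrix: str = "BLOSUM62", gap_open: float = 11.0, gap_extend: float = 1.0):
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = substitution_matrices.load(matrix)
    al.open_gap_score = -abs(gap_open)
    al.extend_gap_score = -abs(gap_extend)
    return al


def global_align(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> AlignmentResult:
    """Optimal global alignment with affine gaps.

    The first gap residue scores ``-gap_open``, each additional one
    ``-gap_extend``; end gaps are penalized.  The traceback is deterministic
    (first alignment in the aligner's fixed enumeration order).
    """
    a = _check_seq(a, "sequence a")
    b = _check_seq(b, "sequence b")
    al = _aligner(matrix, gap_open, gap_extend)
    aln = al.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(ga, gb))
    return AlignmentResult(ga, gb, float(aln.score), matches, len(ga))


def percent_identity(aln: AlignmentResult) -> float:
    """100 * matches / aligned columns (gap columns included), to 0.1."""
    if aln.aligned_columns == 0:
        raise ValueError("alignment has zero columns")
    return round(100.0 * aln.matches / aln.aligned_columns, 1)


def build_reference_map(reference_seq: str, target_seq: str, paralog: str = "") -> ReferenceMap:
    """Map reference (Pks16) positions onto a paralog via global alignment.

    Reference position i maps to target position j iff the alignment pairs
    them with no gap in either row.  Identity below ``IDENTITY_FLOOR`` flags
    (not fails) the map as unreliable.
    """
    aln = global_align(reference_seq, target_seq)
    mapping: dict[int, int] = {}
    i = j = 0
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca != "-":
            i += 1
        if cb != "-":
            j += 1
        if ca != "-" and cb != "-":
            mapping[i] = j
    rm = ReferenceMap(paralog, mapping)
    if percent_identity(aln) < IDENTITY_FLOOR:
        rm.unreliable = True
    return rm


def map_positions(rm: ReferenceMap, positions: list[int]) -> list:
    """Order-preserving mapping; unmapped positions become MISSING (None)."""
    return [rm.to_native(p) for p in positions]


def mutate_positions(seq: str, rm: ReferenceMap, spec: MutationSpec) -> str:
    """Apply reference-numbered substitutions to a native sequence."""
    seq = _check_seq(seq, "sequence")
    out = list(seq)
    unmapped = [p for p, _ in spec.changes if rm.to_native(p) is MISSING]
    if unmapped:
        raise SequenceError(f"positions with no native counterpart: {unmapped}")
    for pos, aa in spec.changes:
        native = rm.to_native(pos)
        if not 1 <= native <= len(seq):
            raise SequenceError(f"mapped position {native} outside sequence of length {len(seq)}")
        out[native - 1] = aa
    return "".join(out)


# ---------------------------------------------------------------------------
# Domain registry config (plain-text "name: a-b, c-d" lines)


def load_registry(path: str | Path) -> DomainRegistry:
    ranges: dict[str, list[tuple[int, int]]] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ValueError(f"bad registry line: {raw!r}")
        name, spans = line.split(":", 1)
        rr = []
        for span in spans.split(","):
            span = span.strip()
            if not span:
                continue
            a, b = span.split("-")
            rr.append((int(a), int(b)))
        ranges[name.strip()] = rr
    return DomainRegistry(ranges)


def default_registry() -> DomainRegistry:
    """Curated Pks16 reference domain ranges shipped with the package."""
    return load_registry(Path(__file__).parent / "data" / "domains_pks16.cfg")
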