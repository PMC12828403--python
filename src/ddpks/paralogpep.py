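"""Peptide-level paralog disambiguation and protein-table filters.

Two near-identical paralogs (Pks16 and Pks17, ~96% identical) cannot be told
apart by shared peptides; only peptides whose sequence occurs in exactly one
of the pair are informative.  This module performs in-silico tryptic
digestion, exact peptide-to-protein occurrence counting, the unique/shared/
unmatched classification of detected peptides against a paralog pair, and
the simple count-threshold filters applied to search-engine protein tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "Peptide",
    "PeptideClassification",
    "tryptic_digest",
    "map_peptide",
    "classify_peptides",
    "filter_protein_table",
    "strip_modifications",
]


@dataclass(frozen=True)
class Peptide:
    sequence: str
    source: str = "in-silico"       # detected | in-silico
    missed_cleavages: int = 0

    def __post_init__(self):
        if not self.sequence or not self.sequence.isupper() or not self.sequence.isalpha():
            raise ValueError(f"bad peptide sequence {self.sequence!r}")


@dataclass
class PeptideClassification:
    peptide: Peptide
    occurrences_a: int
    occurrences_b: int
    verdict: str                     # unique_a | unique_b | shared | unmatched
    multiplicity: int = 1            # how many times it was detected

    def __post_init__(self):
        expected = _verdict(self.occurrences_a, self.occurrences_b)
        if self.verdict != expected:
            raise ValueError(f"verdict {self.verdict} inconsistent with counts")


def _verdict(occ_a: int, occ_b: int) -> str:
    if occ_a and not occ_b:
        return "unique_a"
    if occ_b and not occ_a:
        return "unique_b"
    if occ_a and occ_b:
        return "shared"
    return "unmatched"


def tryptic_digest(seq: str, max_missed: int = 2) -> list[Peptide]:
    """In-silico trypsin digestion.

    Cleaves C-terminal to K or R except when the next residue is P; emits
    every peptide with 0..max_missed internal missed cleavages, ordered by
    start position then length.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    cut_after = [
        i for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    ]
    starts = [0] + [i + 1 for i in cut_after]
    ends = cut_after + [len(seq) - 1]
    peptides = []
    for si, start in enumerate(starts):
        for missed in range(0, max_missed + 1):
            ei = si + missed
            if ei >= len(ends):
                break
            peptides.append(Peptide(seq[start:ends[ei] + 1], "in-silico", missed))
    return peptides


def map_peptide(peptide: Peptide | str, targets: list[tuple[str, str]]) -> dict[str, int]:
    """Exact substring occurrence counts per target (overlaps counted)."""
    pep = peptide.sequence if isinstance(peptide, Peptide) else peptide
    out = {}
    for tid, tseq in targets:
        count = 0
        start = 0
        while True:
            idx = tseq.find(pep, start)
            if idx < 0:
                break
            count += 1
            start = idx + 1
        out[tid] = count
    return out


def strip_modifications(annotated: str) -> str:
    """Strip search-engine modification annotations to the bare sequence.

    Removes bracketed/parenthesized tokens (e.g. ``M[+15.995]``, ``(ox)``),
    terminal dot-notation flanks (``K.PEPTIDER.A``) and uppercases.
    """
    s = re.sub(r"\[[^\]]*\]|\([^)]*\)", "", annotated)
    parts = s.split(".")
    if len(parts) == 3:          # flank.sequence.flank
        s = parts[1]
    s = re.sub(r"[^A-Za-z]", "", s).upper()
    return s


def classify_peptides(
    detected: list[Peptide | str],
    paralog_a: tuple[str, str],
    paralog_b: tuple[str, str],
    collapse_il: bool = False,
) -> tuple[list[PeptideClassification], dict[str, int]]:
    """Classify detected peptides as unique to either paralog, shared or unmatched.

    Duplicate detected peptides are collapsed with their multiplicity
    recorded.  ``collapse_il=True`` treats isoleucine and leucine as one
    symbol (MS cannot distinguish them); the default keeps them distinct.
    """
    if not detected:
        raise ValueError("no detected peptides")

    def norm(s: str) -> str:
        return s.replace("I", "J").replace("L", "J") if collapse_il else s

    seqs: dict[str, int] = {}
    for p in detected:
        s = p.sequence if isinstance(p, Peptide) else strip_modifications(p)
        seqs[s] = seqs.get(s, 0) + 1

    ta = (paralog_a[0], norm(paralog_a[1]))
    tb = (paralog_b[0], norm(paralog_b[1]))
    results = []
    summary = {"n_unique_a": 0, "n_unique_b": 0, "n_shared": 0, "n_unmatched": 0}
    for s in sorted(seqs):
        occ = map_peptide(norm(s), [ta, tb])
        verdict = _verdict(occ[ta[0]], occ[tb[0]])
        results.append(PeptideClassification(
            Peptide(s, "detected"), occ[ta[0]], occ[tb[0]], verdict, seqs[s]))
        summary["n_" + verdict] += 1
    return results, summary


def filter_protein_table(
    table: pd.DataFrame,
    min_unique_peptides: int = 0,
    min_psms: int = 0,
    unique_col: str = "n_unique_peptides",
    psm_col: str = "n_psms",
) -> tuple[pd.DataFrame, int]:
    """Threshold filter on a search-engine protein table (stable row order)."""
    for col in (unique_col, psm_col):
        if col not in table.columns:
            raise KeyError(f"missing column {col!r}; have {list(table.columns)}")
    keep = (table[unique_col] >= min_unique_peptides) & (table[psm_col] >= min_psms)
    out = table.loc[keep]
    return out, int(keep.sum())
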