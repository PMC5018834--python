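"""Canonical H2A isoform classification at the Ser40/Ala40 site.

Canonical (replication-dependent) H2A genes occur in multi-copy families of
near-identical isoforms. The residue homologous to mouse H2A position 40
(histone numbering, initiator Met removed) sits in the L1 loop and is either
serine — the O-GlcNAc acceptor — or alanine. This module anchors "position
40" in an arbitrary isoform sequence by global pairwise alignment to a
reference, classifies each record, and summarizes Ser40/total ratios per
species. A star multiple alignment against the reference and p-distances feed
the tree-building code in :mod:`h2agc.trees`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


class Category(str, Enum):
    SER40 = "SER40"
    ALA40 = "ALA40"
    OTHER = "OTHER"
    UNALIGNED = "UNALIGNED"


@dataclass(frozen=True)
class IsoformRecord:
    id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES - {"X"}
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-standard residues {sorted(bad)}"
            )


@dataclass(frozen=True)
class Position40Call:
    record_id: str
    anchored_index: int | None
    residue: str | None
    category: Category
    context: str  # three-residue window around the anchored site (39-41)


@dataclass(frozen=True)
class SpeciesSummary:
    species: str
    n_ser40: int
    n_total: int

    @property
    def ratio_text(self) -> str:
        return f"{self.n_ser40}/{self.n_total}"


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()

#: anchoring is rejected below this fraction of identical aligned ref columns
MIN_REF_IDENTITY = 0.40


def _align(ref: str, seq: str):
    """First (deterministic) global alignment of seq against ref."""
    return _ALIGNER.align(ref, seq)[0]


def _ref_identity(alignment, ref_len: int) -> float:
    ident = 0
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        ident += sum(
            1
            for a, b in zip(alignment.target[t0:t1], alignment.query[q0:q1])
            if a == b
        )
    return ident / ref_len


def anchor_position(seq: str, ref: str, ref_pos: int) -> int | None:
    """Position in ``seq`` homologous to ``ref_pos`` (1-based) of ``ref``.

    Global pairwise alignment (BLOSUM62, gap open 10, extend 1, end gaps
    penalized). Returns None when ``ref_pos`` aligns to a gap or when the
    alignment identity to the reference falls below :data:`MIN_REF_IDENTITY`
    (guards against anchoring non-homologous input).
    """
    if not seq:
        raise ValueError("empty query sequence")
    if not ref:
        raise ValueError("empty reference sequence")
    if not (1 <= ref_pos <= len(ref)):
        raise ValueError(f"ref_pos {ref_pos} outside reference (len {len(ref)})")
    alignment = _align(ref, seq)
    if _ref_identity(alignment, len(ref)) < MIN_REF_IDENTITY:
        return None
    t = ref_pos - 1
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        if t0 <= t < t1:
            return q0 + (t - t0) + 1
    return None  # ref_pos falls in a deletion


def classify(record: IsoformRecord, ref: str, ref_pos: int = 40) -> Position40Call:
    """Classify an isoform by the residue homologous to ``ref_pos`` of ``ref``."""
    idx = anchor_position(record.sequence, ref, ref_pos)
    if idx is None:
        return Position40Call(record.id, None, None, Category.UNALIGNED, "")
    residue = record.sequence[idx - 1]
    context = record.sequence[max(0, idx - 2) : idx + 1]
    if residue == "S":
        cat = Category.SER40
    elif residue == "A":
        cat = Category.ALA40
    else:
        cat = Category.OTHER
    return Position40Call(record.id, idx, residue, cat, context)


def summarize(
    records: Sequence[IsoformRecord], ref: str, ref_pos: int = 40
) -> list[SpeciesSummary]:
    """Per-species Ser40/total counts, in order of first appearance."""
    order: list[str] = []
    ser: dict[str, int] = {}
    tot: dict[str, int] = {}
    for rec in records:
        if rec.species not in tot:
            order.append(rec.species)
            ser[rec.species] = 0
            tot[rec.species] = 0
        tot[rec.species] += 1
        if classify(rec, ref, ref_pos).category is Category.SER40:
            ser[rec.species] += 1
    return [SpeciesSummary(sp, ser[sp], tot[sp]) for sp in order]


def p_distance(a: str, b: str) -> float:
    """Proportion of mismatching columns between two aligned rows.

    Columns where either row carries a gap ('-') or ambiguity ('X') are
    excluded from both numerator and denominator.
    """
    if len(a) != len(b):
        raise ValueError(f"aligned rows differ in length: {len(a)} vs {len(b)}")
    compared = mismatch = 0
    for x, y in zip(a, b):
        if x in "-X" or y in "-X":
            continue
        compared += 1
        if x != y:
            mismatch += 1
    if compared == 0:
        raise ValueError("no comparable columns")
    return mismatch / compared


def star_msa(records: Sequence[IsoformRecord], ref: str) -> list[str]:
    """Star multiple alignment: every record pairwise-aligned to ``ref``.

    Columns are the reference positions plus merged insertion columns (the
    union, per reference gap position, of the longest insertion any record
    carries there). Deterministic for a fixed input order, and the column set
    is invariant under input permutation.
    """
    if len(records) < 2:
        raise ValueError("star_msa needs at least 2 records")
    n_ref = len(ref)
    # per record: residue (or '-') aligned to each ref position, and
    # insertions keyed by the ref position they follow (0 = before ref[0])
    per_record: list[tuple[list[str], dict[int, str]]] = []
    ins_width = [0] * (n_ref + 1)
    for rec in records:
        alignment = _align(ref, rec.sequence)
        cols = ["-"] * n_ref
        inserts: dict[int, str] = {}
        t = q = 0
        for tc, qc in zip(*alignment.indices):
            # indices: -1 marks a gap in that row at this column
            if tc >= 0 and qc >= 0:
                cols[tc] = rec.sequence[qc]
            elif tc < 0 and qc >= 0:
                # insertion in the record relative to ref; attach after the
                # number of ref residues consumed so far
                inserts[t] = inserts.get(t, "") + rec.sequence[qc]
            if tc >= 0:
                t = tc + 1
        per_record.append((cols, inserts))
        for pos, s in inserts.items():
            ins_width[pos] = max(ins_width[pos], len(s))

    rows: list[str] = []
    for cols, inserts in per_record:
        parts: list[str] = []
        for pos in range(n_ref + 1):
            if ins_width[pos]:
                s = inserts.get(pos, "")
                parts.append(s.ljust(ins_width[pos], "-"))
            if pos < n_ref:
                parts.append(cols[pos])
        rows.append("".join(parts))
    return rows
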