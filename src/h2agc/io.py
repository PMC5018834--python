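"""Shared readers and writers: FASTA, BED, GFF3, TSV, newick.

FASTA goes through Biopython; newick through scikit-bio; BED and GFF3 are
plain tab-separated text handled with small explicit parsers that convert
GFF3's 1-based inclusive coordinates to the internal BED-style 0-based
half-open convention on read (and back on write). Malformed records are
rejected with file, line, and reason.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

from .isoforms import IsoformRecord
from .peaks import GeneModel, GenomicInterval, Peak


class FormatError(ValueError):
    pass


# ------------------------------------------------------------------ FASTA


def read_fasta_records(path: str | Path) -> list[IsoformRecord]:
    """FASTA -> IsoformRecord list; ``species=`` key parsed from the header."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        species = ""
        for token in rec.description.split():
            if token.startswith("species="):
                species = token[len("species="):]
        records.append(IsoformRecord(rec.id, species, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta_records(records: Iterable[IsoformRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=f"species={r.species}")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


# -------------------------------------------------------------------- BED


def read_bed_peaks(path: str | Path) -> list[Peak]:
    """BED (3+ columns) -> peaks; column 4, when present, is the peak name."""
    peaks = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path} line {lineno}: need >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(
                    f"{path} line {lineno}: non-integer coordinates"
                ) from None
            name = fields[3] if len(fields) > 3 and fields[3] else f"peak{lineno}"
            try:
                peaks.append(Peak(name, GenomicInterval(fields[0], start, end)))
            except ValueError as exc:
                raise FormatError(f"{path} line {lineno}: {exc}") from None
    return peaks


def write_bed_peaks(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.peak_id}\n")


# ------------------------------------------------------------------- GFF3


def read_genes_gff3(path: str | Path) -> list[GeneModel]:
    """GFF3 gene/exon features -> gene models (coordinates converted to
    0-based half-open). Exons attach to their gene via the Parent attribute
    (transcript levels are flattened: any exon whose Parent chain mentions the
    gene id, or whose Parent IS a gene id, is kept; overlapping exons are
    merged)."""
    gene_rows: dict[str, tuple[str, int, int, str]] = {}
    exon_rows: dict[str, list[tuple[int, int]]] = {}
    parent_of: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path} line {lineno}: need 9 GFF3 columns")
            chrom, _, ftype, start_s, end_s, _, strand, _, attrs_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(
                    f"{path} line {lineno}: non-integer coordinates"
                ) from None
            attrs = dict(
                kv.split("=", 1) for kv in attrs_s.split(";") if "=" in kv
            )
            start0, end0 = start1 - 1, end1  # 1-based inclusive -> half-open
            if ftype == "gene":
                gid = attrs.get("ID")
                if not gid:
                    raise FormatError(f"{path} line {lineno}: gene without ID")
                gene_rows[gid] = (chrom, start0, end0, strand)
            elif ftype in ("mRNA", "transcript"):
                tid, parent = attrs.get("ID"), attrs.get("Parent")
                if tid and parent:
                    parent_of[tid] = parent
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if not parent:
                    raise FormatError(f"{path} line {lineno}: exon without Parent")
                for p in parent.split(","):
                    gid = parent_of.get(p, p)
                    exon_rows.setdefault(gid, []).append((start0, end0))
    genes = []
    for gid, (chrom, start, end, strand) in gene_rows.items():
        merged: list[tuple[int, int]] = []
        for s, e in sorted(exon_rows.get(gid, [])):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        genes.append(
            GeneModel(
                gene_id=gid,
                interval=GenomicInterval(chrom, start, end, strand),
                exons=tuple(
                    GenomicInterval(chrom, s, e, strand) for s, e in merged
                ),
            )
        )
    return genes


def write_genes_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\th2agc\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={g.gene_id}\n"
            )
            for i, ex in enumerate(g.exons, 1):
                fh.write(
                    f"{ex.chrom}\th2agc\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{ex.strand}\t.\tID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


# -------------------------------------------------------------------- TSV


def read_expression_tsv(path: str | Path) -> dict[str, float]:
    """Two-column TSV (gene_id, value), optional header."""
    table: dict[str, float] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[0].lower() in ("gene_id", "gene"):
                continue
            if len(row) < 2:
                raise FormatError(f"{path} line {lineno}: need 2 TSV columns")
            try:
                table[row[0]] = float(row[1])
            except ValueError:
                raise FormatError(
                    f"{path} line {lineno}: non-numeric value {row[1]!r}"
                ) from None
    return table


def write_expression_tsv(table: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tvalue\n")
        for gid, value in table.items():
            fh.write(f"{gid}\t{value:.6g}\n")


def read_gene_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


# ----------------------------------------------------------------- newick


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")
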