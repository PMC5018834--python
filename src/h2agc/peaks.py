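"""ChIP-seq peak annotation against gene models and expression association.

Peaks are categorized by their midpoint: TSS if the midpoint lies within
±``tss_halfwidth`` (default 2 kb) of any gene's strand-aware transcription
start site, else gene body (GB) if it lies inside any gene interval, else
intergenic. TSS takes priority over GB, so the three categories partition
the peak set. Coordinates are BED-style 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

Category = Literal["TSS", "GB", "INTERGENIC"]


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in "+-.":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware gene with exons; TSS = start on +, end-1 on -."""

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.interval.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on wrong chromosome")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = ex.end

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1


@dataclass(frozen=True)
class Peak:
    peak_id: str
    interval: GenomicInterval

    @property
    def midpoint(self) -> int:
        return (self.interval.start + self.interval.end) // 2


@dataclass(frozen=True)
class CategoryReport:
    counts: dict[str, int]
    fractions: dict[str, float]
    exon_fraction: float | None
    intron_fraction: float | None
    n_peaks: int


class _GeneIndex:
    """Per-chromosome arrays for midpoint-vs-gene queries."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, list[GeneModel]]] = {}
        chroms: dict[str, list[GeneModel]] = {}
        for g in genes:
            chroms.setdefault(g.interval.chrom, []).append(g)
        for chrom, gs in chroms.items():
            starts = np.array([g.interval.start for g in gs])
            ends = np.array([g.interval.end for g in gs])
            tss = np.array([g.tss for g in gs])
            self.by_chrom[chrom] = (starts, ends, tss, gs)

    def tss_hits(self, chrom: str, pos: int, halfwidth: int) -> list[GeneModel]:
        if chrom not in self.by_chrom:
            return []
        _, _, tss, gs = self.by_chrom[chrom]
        mask = np.abs(tss - pos) <= halfwidth
        return [g for g, m in zip(gs, mask) if m]

    def body_hits(self, chrom: str, pos: int) -> list[GeneModel]:
        if chrom not in self.by_chrom:
            return []
        starts, ends, _, gs = self.by_chrom[chrom]
        mask = (starts <= pos) & (pos < ends)
        return [g for g, m in zip(gs, mask) if m]


def assign_category(
    peak: Peak,
    genes: Sequence[GeneModel] | _GeneIndex,
    tss_halfwidth: int = 2000,
) -> tuple[Category, list[str]]:
    """Category of one peak plus all owning gene ids (TSS priority over GB)."""
    index = genes if isinstance(genes, _GeneIndex) else _GeneIndex(genes)
    mid = peak.midpoint
    chrom = peak.interval.chrom
    hits = index.tss_hits(chrom, mid, tss_halfwidth)
    if hits:
        return "TSS", sorted(g.gene_id for g in hits)
    hits = index.body_hits(chrom, mid)
    if hits:
        return "GB", sorted(g.gene_id for g in hits)
    return "INTERGENIC", []


def category_fractions(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    tss_halfwidth: int = 2000,
) -> CategoryReport:
    """Counts and fractions of TSS/GB/intergenic peaks plus exon/intron split.

    The exon/intron fractions are computed over the genic peaks (midpoint
    inside any gene interval, regardless of TSS/GB category); both are None
    when no peak is genic.
    """
    if not peaks:
        raise ValueError("empty peak list: category fractions are undefined")
    index = _GeneIndex(genes)
    counts = {"TSS": 0, "GB": 0, "INTERGENIC": 0}
    n_exonic = n_genic = 0
    for p in peaks:
        cat, _ = assign_category(p, index, tss_halfwidth)
        counts[cat] += 1
        owners = index.body_hits(p.interval.chrom, p.midpoint)
        if owners:
            n_genic += 1
            if any(p.midpoint in ex for g in owners for ex in g.exons):
                n_exonic += 1
    n = len(peaks)
    fractions = {k: v / n for k, v in counts.items()}
    if n_genic:
        exon_fraction = n_exonic / n_genic
        intron_fraction = 1.0 - exon_fraction
    else:
        exon_fraction = intron_fraction = None
    return CategoryReport(counts, fractions, exon_fraction, intron_fraction, n)


def exon_intron_fraction(
    peaks: Sequence[Peak], genes: Sequence[GeneModel]
) -> tuple[float | None, float | None]:
    """(exonic, intronic) fractions among peaks with a genic midpoint."""
    if not peaks:
        return None, None
    report = category_fractions(peaks, genes)
    return report.exon_fraction, report.intron_fraction


def target_genes(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    tss_halfwidth: int = 2000,
) -> set[str]:
    """Genes owning at least one TSS- or GB-assigned peak."""
    index = _GeneIndex(genes)
    targets: set[str] = set()
    for p in peaks:
        cat, owners = assign_category(p, index, tss_halfwidth)
        if cat != "INTERGENIC":
            targets.update(owners)
    return targets


def venn(set_a: set[str], set_b: set[str]) -> tuple[int, int, int]:
    """(only A, shared, only B) counts."""
    shared = set_a & set_b
    return len(set_a - shared), len(shared), len(set_b - shared)


@dataclass(frozen=True)
class ExpressionAssociation:
    target_summary: dict[str, float]
    background_summary: dict[str, float]
    n_target: int
    n_background: int
    p_value: float


def _five_number(values: np.ndarray) -> dict[str, float]:
    q = np.percentile(values, [0, 25, 50, 75, 100])
    return {
        "min": float(q[0]), "q1": float(q[1]), "median": float(q[2]),
        "q3": float(q[3]), "max": float(q[4]),
    }


def expression_association(
    targets: set[str],
    expr: Mapping[str, float],
    background: set[str],
) -> ExpressionAssociation:
    """Rank-sum comparison of target-gene expression against the background.

    Tests whether target genes are expressed higher than the non-target
    background (one-sided Wilcoxon rank-sum / Mann-Whitney U, normal
    approximation with tie correction). Targets are compared against the
    background with the targets removed, so under a random-subset null the
    p-value is uniform. A completely tied comparison returns p = 0.5.
    """
    if not targets <= background:
        raise ValueError("targets must be a subset of background")
    t_vals = np.array([expr[g] for g in targets if g in expr])
    b_vals = np.array([expr[g] for g in background - targets if g in expr])
    if len(t_vals) < 2:
        raise ValueError("need at least 2 target genes with expression values")
    if len(b_vals) < 2:
        raise ValueError("need at least 2 background genes with expression values")
    if np.ptp(np.concatenate([t_vals, b_vals])) == 0:
        p = 0.5  # complete tie carries no directional information
    else:
        _, p = stats.mannwhitneyu(
            t_vals, b_vals, alternative="greater", method="asymptotic"
        )
    return ExpressionAssociation(
        target_summary=_five_number(t_vals),
        background_summary=_five_number(b_vals),
        n_target=len(t_vals),
        n_background=len(b_vals),
        p_value=float(p),
    )
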