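"""Seeded synthetic-data generators for every pipeline stage.

Each generator consumes a :class:`SimConfig` seed, derives its own
independent RNG sub-stream (so adding a call to one generator never perturbs
another), and returns machine-readable ground truth alongside the data, which
lets tests score the corresponding pipeline stage without re-deriving the
answer.

What is emulated and what is not: spectra carry Gaussian m/z jitter, peak
dropout, uniform chemical noise and log-normal intensities, but no isotope
envelopes or charge-state interference; isoform families evolve by gene
duplication/loss on a Yule species tree with per-site substitutions, with the
GlcNAc-acceptor site (position 40 of the root sequence) evolving at the base
rate times a multiplier (default 0: frozen); genomes are single-chromosome
gene grids with planted peak-category and exon fractions; expression is a
two-component Gaussian with a planted shift for target genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skbio import TreeNode

from .glyco_ms import FragmentIon, Peptide, Spectrum, ion_mz, peptide_mass, theoretical_fragments
from .isoforms import IsoformRecord
from .masses import DEFAULT_MASS_TABLE
from .peaks import GeneModel, GenomicInterval, Peak

_STREAMS = {"spectrum": 1, "family": 2, "genome": 3, "expression": 4}


@dataclass(frozen=True)
class SimConfig:
    """Root seed for all generators; identical config => identical outputs."""

    seed: int = 0

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _STREAMS[stream]])
        )


# ---------------------------------------------------------------- spectra


def sim_spectrum(
    peptide: Peptide,
    charge: int = 3,
    jitter_ppm: float = 5.0,
    n_noise: int = 100,
    dropout: float = 0.0,
    config: SimConfig = SimConfig(),
    max_fragment_charge: int = 2,
    include_internal: bool = False,
) -> tuple[Spectrum, list[FragmentIon]]:
    """Noisy HCD spectrum of a peptide plus the ground-truth ion list.

    Fragments follow the labile-glycan model (HexNAc lost from fragments, kept
    on the precursor). Each theoretical fragment is emitted with Gaussian m/z
    jitter of ``jitter_ppm`` ppm, independently dropped with probability
    ``dropout``; ``n_noise`` uniform noise peaks span the observed m/z range.
    Intensities are log-normal.
    """
    if not (0.0 <= dropout <= 1.0):
        raise ValueError("dropout must be in [0, 1]")
    rng = config.rng("spectrum")
    ions = theoretical_fragments(
        peptide, max_charge=max_fragment_charge,
        include_internal=include_internal, glycan_retained=False,
    )
    kept: list[FragmentIon] = []
    peaks: list[tuple[float, float]] = []
    for ion in ions:
        if rng.random() < dropout:
            continue
        mz = ion.mz * (1.0 + rng.normal(0.0, jitter_ppm) * 1e-6)
        peaks.append((mz, float(rng.lognormal(mean=10.0, sigma=1.0))))
        kept.append(ion)
    if peaks:
        lo = min(mz for mz, _ in peaks)
        hi = max(mz for mz, _ in peaks)
    else:
        lo, hi = 100.0, ion_mz(peptide_mass(peptide), 1)
    for _ in range(n_noise):
        peaks.append(
            (float(rng.uniform(lo, hi)), float(rng.lognormal(mean=8.0, sigma=1.0)))
        )
    peaks.sort(key=lambda p: p[0])
    spectrum = Spectrum(
        precursor_mz=ion_mz(peptide_mass(peptide), charge),
        precursor_charge=charge,
        peaks=tuple(peaks),
        title=f"sim:{peptide.sequence}/{charge}",
    )
    return spectrum, kept


def sim_localization_pair(
    peptide: Peptide,
    site: int,
    jitter_ppm: float = 0.0,
    n_noise: int = 0,
    config: SimConfig = SimConfig(),
    max_fragment_charge: int = 2,
) -> tuple[Spectrum, Spectrum]:
    """Unmodified/modified spectrum pair with a planted O-HexNAc site.

    ``site`` is a protein coordinate inside the peptide. Modification-specific
    y ions are those whose residue span excludes the site (y_j with
    j <= n - local(site)): they appear only in the modified spectrum, so the
    localization window rule confines the site to peptide-local 1..local(site).
    Both spectra share the b ladder and the remaining y ions; jitter and noise
    are applied independently to each.
    """
    rng = config.rng("spectrum")
    n = len(peptide)
    s_local = peptide.local_index(site)
    if not (1 <= s_local <= n):
        raise ValueError(f"site {site} outside peptide span")
    ions = theoretical_fragments(
        peptide, max_charge=max_fragment_charge, glycan_retained=False
    )
    shared = [
        i for i in ions
        if i.series == "b" or (i.index_y is not None and i.index_y > n - s_local)
    ]
    specific = [
        i for i in ions
        if i.series == "y" and i.index_y is not None and i.index_y <= n - s_local
    ]

    def build(ion_list, charge, mass):
        peaks = [
            (i.mz * (1.0 + rng.normal(0.0, jitter_ppm) * 1e-6),
             float(rng.lognormal(10.0, 1.0)))
            for i in ion_list
        ]
        lo = min(mz for mz, _ in peaks)
        hi = max(mz for mz, _ in peaks)
        peaks += [
            (float(rng.uniform(lo, hi)), float(rng.lognormal(8.0, 1.0)))
            for _ in range(n_noise)
        ]
        peaks.sort(key=lambda p: p[0])
        return Spectrum(ion_mz(mass, charge), charge, tuple(peaks))

    base = peptide_mass(peptide)
    unmod = build(shared, 3, base)
    mod = build(shared + specific, 3, base + DEFAULT_MASS_TABLE.hexnac)
    return unmod, mod


# ------------------------------------------------------- isoform families


@dataclass(frozen=True)
class BirthDeathParams:
    """Birth-and-death gene-family model on a Yule species tree.

    Rates are per gene lineage per unit time; ``substitution_rate`` is per
    site per unit time. ``site40_multiplier`` scales the substitution rate at
    the acceptor site (0 freezes it). With ``plant_basal_duplication`` the
    family starts as two copies at the species root — one Ser40, one Ala40 —
    emulating an ancient duplication that predates every speciation.
    """

    duplication_rate: float = 0.3
    loss_rate: float = 0.1
    substitution_rate: float = 0.05
    site40_multiplier: float = 0.0
    tree_depth: float = 1.0
    n_species: int = 6
    plant_basal_duplication: bool = True

    def __post_init__(self) -> None:
        if min(self.duplication_rate, self.loss_rate, self.substitution_rate) < 0:
            raise ValueError("rates must be >= 0")
        if self.site40_multiplier < 0:
            raise ValueError("site40_multiplier must be >= 0")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")


@dataclass(frozen=True)
class FamilySim:
    records: list[IsoformRecord]
    true_tree: TreeNode | None
    site40_states: dict[str, str]  # leaf id -> residue at site 40
    extinct: bool


@dataclass
class _SpNode:
    name: str
    length: float
    children: list["_SpNode"] = field(default_factory=list)


def _yule_species_tree(n: int, depth: float, rng: np.random.Generator) -> _SpNode:
    """Pure-birth species tree with n tips, rescaled to total depth ``depth``."""
    root = _SpNode("sp_root", 0.0)
    if n == 1:
        leaf = _SpNode("sp1", depth)
        root.children.append(leaf)
        return root
    # grow: each tip splits at exponential times until n tips exist
    tips: list[tuple[_SpNode, float]] = [(root, 0.0)]  # (node, birth time)
    t = 0.0
    while len(tips) < n:
        t += rng.exponential(1.0 / len(tips))
        k = rng.integers(len(tips))
        node, birth = tips.pop(int(k))
        node.length = t - birth if node is not root else 0.0
        left, right = _SpNode("", t), _SpNode("", t)
        node.children = [left, right]
        tips.append((left, t))
        tips.append((right, t))
    total = t + rng.exponential(1.0 / n)  # tail before the present
    for i, (node, birth) in enumerate(sorted(tips, key=lambda x: x[1]), 1):
        node.name = f"sp{i}"
        node.length = total - birth
    _rescale(root, depth / total if total > 0 else 1.0)
    return root


def _rescale(node: _SpNode, factor: float) -> None:
    node.length *= factor
    for c in node.children:
        _rescale(c, factor)


def _mutate(
    seq: str, t: float, params: BirthDeathParams, rng: np.random.Generator,
    site40_index: int,
) -> str:
    """Apply per-site substitutions over a branch of length t."""
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    p = 1.0 - math.exp(-params.substitution_rate * t)
    p40 = 1.0 - math.exp(-params.substitution_rate * params.site40_multiplier * t)
    out = list(seq)
    hits = rng.random(len(seq))
    for i in range(len(seq)):
        prob = p40 if i == site40_index else p
        if hits[i] < prob:
            choices = alphabet.replace(out[i], "")
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def sim_isoform_family(
    params: BirthDeathParams = BirthDeathParams(),
    root_sequence: str | None = None,
    config: SimConfig = SimConfig(),
) -> FamilySim:
    """Simulate an isoform gene family by birth-and-death on a species tree.

    Returns extant sequences labeled by species, the true gene tree (pruned
    to extant leaves, as a scikit-bio TreeNode) and per-leaf site-40 states.
    If every copy is lost the result is flagged ``extinct`` rather than
    raising. Leaf ids are ``<species>|g<k>``.
    """
    from .data import reference_h2a  # default root: Ser40-type mouse H2A

    rng = config.rng("family")
    if root_sequence is None:
        root_sequence = reference_h2a()
    site40_index = 39  # 0-based index of position 40 in the root coordinate
    sp_root = _yule_species_tree(params.n_species, params.tree_depth, rng)

    counter = [0]

    def new_gene(parent_gt: TreeNode, birth: float) -> TreeNode:
        counter[0] += 1
        node = TreeNode(name=f"g{counter[0]}")
        node.length = 0.0
        node._birth = birth  # type: ignore[attr-defined]
        parent_gt.append(node)
        return node

    gt_root = TreeNode(name="gene_root")
    records: list[IsoformRecord] = []
    states: dict[str, str] = {}

    # initial copies at the species root
    initial: list[tuple[TreeNode, str]] = []
    if params.plant_basal_duplication:
        s_seq = root_sequence[:site40_index] + "S" + root_sequence[site40_index + 1:]
        a_seq = root_sequence[:site40_index] + "A" + root_sequence[site40_index + 1:]
        for seq in (s_seq, a_seq):
            initial.append((new_gene(gt_root, 0.0), seq))
    else:
        initial.append((new_gene(gt_root, 0.0), root_sequence))

    def descend(sp: _SpNode, genes: list[tuple[TreeNode, str]], t0: float) -> None:
        """Evolve gene copies along the branch leading to ``sp`` and recurse."""
        survivors: list[tuple[TreeNode, str]] = []
        for gnode, seq in genes:
            # birth-death of this copy (and its in-branch duplicates) along
            # the branch; duplicates inherit the mutated parent sequence
            stack = [(gnode, 0.0)]
            while stack:
                node, elapsed = stack.pop()
                remaining = sp.length - elapsed
                total_rate = params.duplication_rate + params.loss_rate
                wait = (
                    rng.exponential(1.0 / total_rate)
                    if total_rate > 0 else math.inf
                )
                if wait >= remaining:
                    node.length += remaining
                    survivors.append(
                        (node, _mutate(seq, sp.length, params, rng, site40_index))
                    )
                    continue
                node.length += wait
                if rng.random() < params.loss_rate / total_rate:
                    node._lost = True  # type: ignore[attr-defined]
                    continue
                for _ in range(2):
                    child = new_gene(node, t0 + elapsed + wait)
                    stack.append((child, elapsed + wait))
        if not sp.children:  # species tip: emit extant records
            for i, (gnode, seq) in enumerate(survivors, 1):
                leaf_id = f"{sp.name}|{gnode.name}"
                gnode.name = leaf_id
                records.append(IsoformRecord(leaf_id, sp.name, seq))
                states[leaf_id] = seq[site40_index]
            return
        for child in sp.children:
            branched: list[tuple[TreeNode, str]] = []
            for gnode, seq in survivors:
                sub = new_gene(gnode, t0 + sp.length)
                branched.append((sub, seq))
            descend(child, branched, t0 + sp.length)

    if sp_root.children:
        for child in sp_root.children:
            branched = []
            for gnode, seq in initial:
                sub = new_gene(gnode, 0.0)
                branched.append((sub, seq))
            descend(child, branched, 0.0)
    else:
        descend(sp_root, initial, 0.0)

    if not records:
        return FamilySim([], None, {}, extinct=True)

    names = {r.id for r in records}
    pruned = gt_root.shear(names) if len(names) >= 2 else None
    if pruned is not None:
        pruned.prune()
    return FamilySim(records, pruned, states, extinct=False)


# ---------------------------------------------------------------- genomes


def sim_genome_and_peaks(
    n_genes: int = 200,
    chrom_length: int | None = None,
    n_exons: int = 4,
    exon_length: int = 600,
    intron_length: int = 1800,
    planted_fractions: dict[str, float] | None = None,
    planted_exon_fraction: float = 0.6,
    n_peaks: int = 2000,
    tss_halfwidth: int = 2000,
    peak_width_median: int = 500,
    config: SimConfig = SimConfig(),
) -> tuple[list[GeneModel], list[Peak], list[str]]:
    """Synthetic gene grid plus peaks with planted category fractions.

    Genes alternate strands on one chromosome, spaced so TSS windows never
    overlap a neighboring gene; each peak's category is drawn from
    ``planted_fractions`` (keys TSS/GB/INTERGENIC) and its midpoint placed
    uniformly within a region of that type. GB midpoints land in an exon with
    probability ``planted_exon_fraction``. Returns (genes, peaks, truth
    labels) where truth[i] is the planted category of peaks[i].
    """
    if planted_fractions is None:
        planted_fractions = {"TSS": 0.30, "GB": 0.55, "INTERGENIC": 0.15}
    if abs(sum(planted_fractions.values()) - 1.0) > 1e-9:
        raise ValueError("planted fractions must sum to 1")
    rng = config.rng("genome")

    gene_length = n_exons * exon_length + (n_exons - 1) * intron_length
    gap = 3 * tss_halfwidth  # keeps TSS windows clear of neighboring genes
    pitch = gene_length + gap
    needed = n_genes * pitch + gap
    if chrom_length is None:
        chrom_length = needed
    elif chrom_length < needed:
        raise ValueError(
            f"chrom_length {chrom_length} cannot fit {n_genes} genes "
            f"of {gene_length} bp with {gap} bp gaps (need {needed})"
        )

    genes: list[GeneModel] = []
    for k in range(n_genes):
        start = gap + k * pitch
        end = start + gene_length
        strand = "+" if k % 2 == 0 else "-"
        exons = []
        pos = start
        for _ in range(n_exons):
            exons.append(GenomicInterval("chr1", pos, pos + exon_length, strand))
            pos += exon_length + intron_length
        genes.append(
            GeneModel(
                gene_id=f"gene{k + 1}",
                interval=GenomicInterval("chr1", start, end, strand),
                exons=tuple(exons),
            )
        )

    cats = sorted(planted_fractions)
    probs = [planted_fractions[c] for c in cats]
    peaks: list[Peak] = []
    truth: list[str] = []
    for i in range(n_peaks):
        cat = cats[rng.choice(len(cats), p=probs)]
        gene = genes[int(rng.integers(n_genes))]
        iv = gene.interval
        if cat == "TSS":
            # upstream side of the window only, so TSS peaks are never genic
            if iv.strand == "+":
                mid = int(rng.integers(gene.tss - tss_halfwidth, gene.tss))
            else:
                mid = int(rng.integers(gene.tss + 1, gene.tss + tss_halfwidth + 1))
        elif cat == "GB":
            # inside the gene, > tss_halfwidth away from the TSS
            exonic = rng.random() < planted_exon_fraction
            regions = _gb_blocks(gene, tss_halfwidth, exonic)
            if not regions:
                raise ValueError("gene too short for a GB region; enlarge genes")
            lengths = np.array([b - a for a, b in regions], dtype=float)
            r = regions[int(rng.choice(len(regions), p=lengths / lengths.sum()))]
            mid = int(rng.integers(r[0], r[1]))
        else:  # INTERGENIC: middle of the gap downstream of this gene
            gap_start = iv.end + tss_halfwidth + 1
            gap_end = iv.end + gap - tss_halfwidth - 1
            mid = int(rng.integers(gap_start, gap_end))
        width = int(np.clip(rng.lognormal(math.log(peak_width_median), 0.4), 50, None))
        width = min(width, 2 * mid)  # keep start >= 0 without moving the midpoint
        start = mid - width // 2
        end = start + width  # floor((start+end)/2) == mid for any width
        peaks.append(Peak(f"peak{i + 1}", GenomicInterval("chr1", start, end)))
        truth.append(cat)
    return genes, peaks, truth


def _gb_blocks(
    gene: GeneModel, tss_halfwidth: int, exonic: bool
) -> list[tuple[int, int]]:
    """Exonic or intronic sub-intervals of a gene > tss_halfwidth from its TSS."""
    iv = gene.interval
    if iv.strand == "+":
        zone = (gene.tss + tss_halfwidth + 1, iv.end)
    else:
        zone = (iv.start, gene.tss - tss_halfwidth)
    blocks: list[tuple[int, int]] = []
    if exonic:
        sources = [(ex.start, ex.end) for ex in gene.exons]
    else:
        sources = [
            (a.end, b.start) for a, b in zip(gene.exons, gene.exons[1:])
        ]
    for s, e in sources:
        lo, hi = max(s, zone[0]), min(e, zone[1])
        if lo < hi:
            blocks.append((lo, hi))
    return blocks


# ------------------------------------------------------------- expression


def sim_expression(
    genes: Sequence[str],
    targets: set[str],
    shift: float = 1.0,
    noise: float = 1.0,
    config: SimConfig = SimConfig(),
) -> dict[str, float]:
    """Log-ratio expression table: background N(0, σ), targets N(δ, σ)."""
    if not targets <= set(genes):
        raise ValueError("targets must be a subset of genes")
    rng = config.rng("expression")
    table: dict[str, float] = {}
    for g in genes:
        mu = shift if g in targets else 0.0
        table[g] = float(mu + rng.normal(0.0, noise)) if noise > 0 else float(mu)
    return table
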