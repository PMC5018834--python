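# Methods

## Mass arithmetic and fragment model

All masses are monoisotopic (the observed G37–K74 precursor values match
monoisotopic, not average, arithmetic). The residue table is hard-coded:
exactly the 20 standard residues, water 18.010565 Da, proton 1.007276 Da,
HexNAc 203.079373 Da. A peptide's neutral mass is the residue sum plus water
plus modification deltas; an ion's m/z is (M + z·m_p)/z. m/z is carried at
full precision internally and rounded to two decimals only when compared with
reported values.

Lys-C (Achromobacter protease I) cleavage: after every lysine, including
Lys–Pro bonds (unlike trypsin). Missed cleavages default to 0 and are
configurable; with 0 the digest is a partition of the protein, which the test
suite asserts as an invariant.

Fragmentation follows a labile-glycan model: in HCD the O-linked HexNAc is
lost before backbone cleavage, so fragment ladders are generated without the
glycan delta by default (the precursor keeps it); `glycan_retained=True`
produces the retained-glycan ladders. b ions are prefix sums, y ions suffix
sums plus water, internal y∧b ions are b-type (residue span + one proton, no
water), which is the only internal form produced. The HexNAc oxocarbenium
reporter (m/z 204.087) is available as a constant but not required for
localization.

Spectrum matching assigns each theoretical ion to its nearest peak within a
ppm tolerance (default 10 ppm, Orbitrap-class accuracy). When the expected
m/z jitter σ is known — as with the synthetic generator — matching should use
roughly 4σ: at 5 ppm jitter a 10 ppm (2σ) window randomly loses ~5% of shared
ions from one spectrum of a pair, which the localization rule would misread
as modification-specific ions.

### Site localization

Given an unmodified/modified spectrum pair annotated against the same
peptide's ladders, the y ions present only in the modified spectrum are
diagnostic: a modification-specific y_j places the site N-terminal of its
span, i.e. within peptide-local positions 1..(n−j). The window is taken from
the largest specific y index; candidate sites are the Ser/Thr residues inside
the window; the call is made only when exactly one candidate exists, else
"ambiguous". With no specific ions the window is the whole peptide. For
G37–K74, specific y33 gives window 37–41 with Ser40 as the only candidate.

## Isoform classification and trees

"Position 40" in an arbitrary isoform is anchored by global pairwise
alignment to the packaged Ser40-type mouse reference (BLOSUM62, gap open 10,
extend 1, end gaps penalized). Canonical H2A isoforms are >90% identical, so
the result is insensitive to reasonable parameter choices; an identity floor
(≥40% of reference columns identical) rejects non-homologous input as
UNALIGNED rather than mis-anchoring it. Categories: SER40 (S), ALA40 (A),
OTHER (anything else anchored), UNALIGNED. The reported three-residue context
lets the Y-S-E epitope be checked directly.

The packaged mouse fixtures are reconstructions, labelled synthetic: the
G37–K74 span of the Ser40-type record is the experimentally identified Lys-C
peptide (cross-validated in the tests against the observed precursor m/z),
embedded in the canonical mouse H2A backbone; the Ala40-type record is its
Ser40Ala counterpart. Database-derived per-species isoform inventories
(wallaby 3/5, platypus 0/24, zebrafish 0/29) depend on a genome-database
release and are not shipped; the per-species summary is instead exercised on
synthetic families with planted ratios.

Trees are built by neighbor joining on p-distances (mismatches over compared
columns, gaps and X excluded) from a star multiple alignment against the
reference — deterministic and oracle-checkable, and adequate for
near-identical histone sequences; no maximum-likelihood claim is made. NJ
ties in the Q criterion are broken by the lexicographically smallest sorted
leaf-label tuple, so the tree is independent of input order; negative branch
lengths are clamped to 0. On additive matrices the implementation is exact,
which the tests verify against a brute-force Q-matrix oracle and scikit-bio's
independent implementation.

Type-dependent clustering is scored as B/W: the mean cophenetic (path-length)
distance between leaves of different Ser40/Ala40 categories over the mean
within-category distance. B/W > 1 means isoforms cluster by type rather than
by species, the expected signature when an ancient duplication predates the
speciations; a star tree scores exactly 1. The score is undefined (None) when
either category has fewer than two leaves.

## Peak annotation

Coordinates are BED-style 0-based half-open everywhere; GFF3 input is
converted on read. Peaks are assigned by midpoint — summit information is not
present in plain BED, and the midpoint is deterministic and order-free: TSS
if within ±2 kb (configurable) of any strand-aware TSS, else GB if inside any
gene interval, else intergenic. TSS has priority over GB so the categories
partition the peaks; all qualifying genes are reported as owners, with no
arbitrary single-owner choice. A "target gene" is any gene owning a TSS- or
GB-assigned peak; this definition is recorded in the JSON report. Exon/intron
fractions are computed over peaks whose midpoint lies inside a gene, a peak
counting as exonic when its midpoint falls in an exon of an owning gene.

Expression association uses the one-sided Wilcoxon rank-sum (Mann–Whitney U,
asymptotic with tie correction; adequate at n ≥ 20) for targets > background.
Targets are compared against the background **minus** the targets: with
overlapping groups the null distribution of the statistic is not the standard
one, and the random-subset null would not give uniform p-values. A completely
tied comparison returns p = 0.5 by convention. Calibration is asserted in the
tests: type-I error 0.05 ± 0.02 over 1000 null seeds, power ≥ 95% at δ = 1,
σ = 1, n_target = 200 vs 1800.

## Synthetic generators

One root RNG per generator, derived from the config seed plus a fixed
per-generator stream id, so outputs are byte-reproducible and adding a call
to one generator does not perturb another.

- **Spectra**: every theoretical fragment (labile model) with Gaussian m/z
  jitter at σ ppm, independent dropout, uniform noise peaks over the observed
  range, log-normal intensities. No isotope envelopes, charge-state
  interference, or instrument-realistic intensity structure — a green
  matching test establishes tolerance logic, not instrument fidelity.
  The localization-pair generator plants a site s and makes the y ions whose
  span excludes s (j ≤ n − local(s)) modification-specific, so the window
  rule confines the site to 1..local(s).
- **Isoform families**: a pure-birth (Yule) species tree rescaled to depth
  1.0 (time units are arbitrary; all rates are per unit of that depth),
  default 6 species. Gene copies evolve down it with duplication rate 0.3 and
  loss rate 0.1 per copy — moderate turnover that keeps 50 simulations within
  seconds while producing multi-copy families; substitutions are applied per
  site at rate 0.05 per unit time over each species-tree branch (in-branch
  duplicates inherit full-branch substitutions — a deliberate
  simplification). Site 40 evolves at the base rate × multiplier, default 0
  (frozen). By default the family starts as two basal copies, one Ser40 and
  one Ala40, emulating a duplication older than every speciation: with the
  site frozen, the Ser40 leaves are exactly the descendants of the planted
  copy, which the tests assert via the returned gene tree. Total loss of the
  family returns an explicit extinct result.
- **Genomes**: genes on a regular grid (4 exons of 600 bp, introns of
  1800 bp), alternating strands, gaps of 3× the TSS half-width so category
  regions never collide; each peak's category is drawn from the planted
  fractions and its midpoint placed uniformly in a region of that type (TSS
  midpoints on the upstream, non-genic side of the window; GB midpoints in
  exon vs intron per the planted exon fraction). Peak widths are log-normal
  with median 500 bp — arbitrary but fixed; truth is defined by the midpoint,
  matching the annotator. The grid geometry makes planted labels exactly
  recoverable, so fraction-recovery tests measure only binomial sampling
  noise, not assignment ambiguity.
- **Expression**: background N(0, σ), targets N(δ, σ), defaults δ = 1,
  σ = 1.

## Numerical and degenerate-input choices

- Digestion rejects unknown residues naming the character and position.
- `pair_precursors` compares neutral masses (charges may differ) with the
  ppm tolerance taken on the heavy mass; empty input yields empty output.
- `category_fractions` rejects an empty peak list; exon/intron fractions are
  absent (None), not zero, when no peak is genic.
- `anchor_position` returns absent when the reference position falls in a
  deletion, and UNALIGNED below the identity floor.
- NJ requires ≥3 labels and a symmetric zero-diagonal matrix.

## Limitations

- No search-engine scoring, FDR, isotope deconvolution, or vendor raw
  formats; the spectrum matcher is a transparent tolerance-based annotator,
  not a probabilistic search engine, and no claim is made to reproduce any
  particular search configuration.
- The isoform survey makes no claim about database-release-dependent species
  counts, and the NJ/star-MSA route is not expected to reproduce any specific
  published tree topology.
- Peak categorization by midpoint + TSS priority is a documented convention;
  published analyses may have used summits or different precedence rules.
- The expression model is a two-component Gaussian log-ratio; real array
  normalization is out of scope.
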