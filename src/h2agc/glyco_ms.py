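"""Glycopeptide mass spectrometry: digestion, fragment ions, site localization.

This module re-creates the computational core of an HCD glycoproteomics
identification: Lys-C in-silico digestion, neutral/charged mass arithmetic,
pairing of precursor ions separated by one HexNAc (Δ = 203.079373 Da),
theoretical b/y/internal fragment ladders under a labile-glycan model, ppm
spectrum annotation, and localization of the O-GlcNAc site from
modification-specific y ions.

Coordinates follow the histone convention: protein position 1 is the residue
after the cleaved initiator Met, so Ser40 of H2A means the serine in the
G37-K74 Lys-C peptide.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .masses import DEFAULT_MASS_TABLE, MassTable

Modification = tuple[int, float, str]  # (protein position, delta Da, label)


@dataclass(frozen=True)
class Peptide:
    """A digested protein span with optional covalent modifications.

    ``start_pos``/``end_pos`` are 1-based inclusive coordinates in the parent
    protein; each modification site must fall inside that span.
    """

    sequence: str
    start_pos: int
    end_pos: int
    modifications: tuple[Modification, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        if len(self.sequence) != self.end_pos - self.start_pos + 1:
            raise ValueError(
                f"length {len(self.sequence)} inconsistent with span "
                f"{self.start_pos}-{self.end_pos}"
            )
        for pos, _, label in self.modifications:
            if not (self.start_pos <= pos <= self.end_pos):
                raise ValueError(
                    f"modification {label!r} at {pos} outside span "
                    f"{self.start_pos}-{self.end_pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def local_index(self, protein_pos: int) -> int:
        """1-based position within the peptide of a protein coordinate."""
        return protein_pos - self.start_pos + 1


@dataclass(frozen=True)
class FragmentIon:
    """A typed backbone fragment with charge and m/z.

    ``composition_span`` is (first, last) in 1-based peptide-local positions.
    For a b ion it is (1, i); for a y ion over an n-mer, (n-j+1, n); an
    internal y∧b ion covers (n-j+1, i).
    """

    series: Literal["b", "y", "internal_by"]
    charge: int
    mz: float
    composition_span: tuple[int, int]
    index_b: int | None = None
    index_y: int | None = None
    glycan_retained: bool = False

    @property
    def label(self) -> str:
        if self.series == "b":
            name = f"b{self.index_b}"
        elif self.series == "y":
            name = f"y{self.index_y}"
        else:
            name = f"y{self.index_y}-b{self.index_b}"
        if self.glycan_retained:
            name += "+HexNAc"
        return f"{name}^{self.charge}+"


@dataclass(frozen=True)
class Spectrum:
    """A centroided MS/MS spectrum; peaks sorted by m/z ascending."""

    precursor_mz: float
    precursor_charge: int
    peaks: tuple[tuple[float, float], ...]
    title: str = ""

    def __post_init__(self) -> None:
        mzs = [mz for mz, _ in self.peaks]
        if any(mz <= 0 for mz in mzs):
            raise ValueError("all peak m/z must be > 0")
        if mzs != sorted(mzs):
            raise ValueError("peaks must be sorted by m/z ascending")
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("intensities must be >= 0")


@dataclass(frozen=True)
class AnnotatedSpectrum:
    """Peak-to-theoretical-ion matches with signed ppm errors."""

    spectrum: Spectrum
    matches: tuple[tuple[int, FragmentIon, float], ...]

    def matched_ions(self) -> list[FragmentIon]:
        return [ion for _, ion, _ in self.matches]


@dataclass(frozen=True)
class LocalizationResult:
    """Inferred modification window and site in protein coordinates."""

    window: tuple[int, int]
    candidate_sites: tuple[int, ...]
    call: int | Literal["ambiguous"]
    evidence: tuple[str, ...] = ()


def digest(
    protein: str,
    enzyme: str = "lysC",
    missed_cleavages: int = 0,
    table: MassTable = DEFAULT_MASS_TABLE,
) -> list[Peptide]:
    """Lys-C in-silico digestion of a protein sequence.

    Achromobacter protease I (Lys-C) cleaves C-terminal to every lysine,
    including Lys-Pro bonds (unlike trypsin). With 0 missed cleavages the
    peptides are maximal spans ending at K or the C-terminus, and their
    concatenation reconstructs the protein.
    """
    if enzyme != "lysC":
        raise ValueError(f"unsupported enzyme {enzyme!r}")
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    if not protein:
        raise ValueError("empty protein sequence")
    for i, aa in enumerate(protein, start=1):
        if aa not in table:
            raise ValueError(f"unknown residue {aa!r} at position {i}")

    # cut points: after every K, plus the C-terminus
    ends = [i for i, aa in enumerate(protein, start=1) if aa == "K"]
    if not ends or ends[-1] != len(protein):
        ends.append(len(protein))
    starts = [1] + [e + 1 for e in ends[:-1]]
    base = [
        Peptide(protein[s - 1 : e], s, e) for s, e in zip(starts, ends)
    ]
    if missed_cleavages == 0:
        return base
    out = list(base)
    for k in range(1, missed_cleavages + 1):
        for i in range(len(base) - k):
            s = base[i].start_pos
            e = base[i + k].end_pos
            out.append(Peptide(protein[s - 1 : e], s, e))
    out.sort(key=lambda p: (p.start_pos, p.end_pos))
    return out


def peptide_mass(peptide: Peptide, table: MassTable = DEFAULT_MASS_TABLE) -> float:
    """Neutral monoisotopic mass: residue sum + water + modification deltas."""
    mass = sum(table.residue(aa) for aa in peptide.sequence) + table.water
    mass += sum(delta for _, delta, _ in peptide.modifications)
    return mass


def ion_mz(neutral_mass: float, charge: int, table: MassTable = DEFAULT_MASS_TABLE) -> float:
    """m/z of an ion: (M + z·m_proton) / z."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    if neutral_mass < 0:
        raise ValueError("neutral mass must be >= 0")
    return (neutral_mass + charge * table.proton) / charge


def neutral_mass(mz: float, charge: int, table: MassTable = DEFAULT_MASS_TABLE) -> float:
    """Inverse of :func:`ion_mz`."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return mz * charge - charge * table.proton


def pair_precursors(
    ions: Sequence[tuple[float, int]],
    delta: float = DEFAULT_MASS_TABLE.hexnac,
    tol_ppm: float = 20.0,
    table: MassTable = DEFAULT_MASS_TABLE,
) -> list[tuple[tuple[float, int], tuple[float, int]]]:
    """Find (light, heavy) precursor pairs separated by ``delta`` Da.

    Comparison is on neutral masses so the members of a pair may carry
    different charges. A pair qualifies when
    ``|M_heavy - M_light - delta|`` is within ``tol_ppm`` of the heavy
    neutral mass. Output is sorted by light neutral mass.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    with_mass = sorted(
        ((neutral_mass(mz, z, table), (mz, z)) for mz, z in ions),
        key=lambda t: t[0],
    )
    masses = [m for m, _ in with_mass]
    pairs = []
    for i, (m_light, light) in enumerate(with_mass):
        target = m_light + delta
        tol = tol_ppm * 1e-6 * target
        lo = bisect.bisect_left(masses, target - tol, i + 1)
        hi = bisect.bisect_right(masses, target + tol, i + 1)
        for j in range(lo, hi):
            m_heavy, heavy = with_mass[j]
            if abs(m_heavy - m_light - delta) <= tol_ppm * 1e-6 * m_heavy:
                pairs.append(((m_light, light), heavy))
    pairs.sort(key=lambda t: t[0][0])
    return [(light, heavy) for (_, light), heavy in pairs]


def theoretical_fragments(
    peptide: Peptide,
    max_charge: int = 2,
    include_internal: bool = False,
    glycan_retained: bool = False,
    table: MassTable = DEFAULT_MASS_TABLE,
) -> list[FragmentIon]:
    """Enumerate b, y and (optionally) internal y∧b fragment ions.

    Under the labile-glycan model (``glycan_retained=False``, the default)
    HexNAc deltas are dropped from all fragment masses — in HCD the O-glycan
    is lost before backbone cleavage — while the precursor retains them.
    Internal ions are b-type: a residue span with one proton, no water.
    """
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")
    n = len(peptide)
    seq = peptide.sequence
    res = [table.residue(aa) for aa in seq]
    # per-local-position modification deltas, only if retained in fragments
    mod_delta = [0.0] * (n + 1)
    if glycan_retained:
        for pos, delta, _ in peptide.modifications:
            mod_delta[peptide.local_index(pos)] += delta

    prefix = [0.0] * (n + 1)  # prefix[i] = residues 1..i (+ retained deltas)
    for i in range(1, n + 1):
        prefix[i] = prefix[i - 1] + res[i - 1] + mod_delta[i]

    def span_mass(first: int, last: int) -> float:
        return prefix[last] - prefix[first - 1]

    ions: list[FragmentIon] = []
    for z in range(1, max_charge + 1):
        for i in range(1, n):
            ions.append(
                FragmentIon(
                    series="b", charge=z, index_b=i,
                    mz=ion_mz(span_mass(1, i), z, table),
                    composition_span=(1, i), glycan_retained=glycan_retained,
                )
            )
        for j in range(1, n):
            first = n - j + 1
            ions.append(
                FragmentIon(
                    series="y", charge=z, index_y=j,
                    mz=ion_mz(span_mass(first, n) + table.water, z, table),
                    composition_span=(first, n), glycan_retained=glycan_retained,
                )
            )
        if include_internal:
            for j in range(1, n):
                first = n - j + 1
                for i in range(first, n):
                    ions.append(
                        FragmentIon(
                            series="internal_by", charge=z,
                            index_b=i, index_y=j,
                            mz=ion_mz(span_mass(first, i), z, table),
                            composition_span=(first, i),
                            glycan_retained=glycan_retained,
                        )
                    )
    return ions


def match_spectrum(
    spectrum: Spectrum,
    ions: Iterable[FragmentIon],
    tol_ppm: float = 10.0,
) -> AnnotatedSpectrum:
    """Match theoretical ions to the nearest spectrum peak within ``tol_ppm``.

    A peak may satisfy several ions, but each (peak, ion) pair appears once;
    matches carry the signed ppm error (observed - theoretical).
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    mzs = [mz for mz, _ in spectrum.peaks]
    matches = []
    for ion in ions:
        if not mzs:
            break
        i = bisect.bisect_left(mzs, ion.mz)
        best = None
        for k in (i - 1, i):
            if 0 <= k < len(mzs):
                err = (mzs[k] - ion.mz) / ion.mz * 1e6
                if abs(err) <= tol_ppm and (best is None or abs(err) < abs(best[1])):
                    best = (k, err)
        if best is not None:
            matches.append((best[0], ion, best[1]))
    return AnnotatedSpectrum(spectrum=spectrum, matches=tuple(matches))


def localize_glycosite(
    pair: tuple[AnnotatedSpectrum, AnnotatedSpectrum],
    peptide: Peptide,
) -> LocalizationResult:
    """Localize an O-HexNAc site from modification-specific y ions.

    Both spectra must be annotated against the same peptide's ladders; the
    first member of ``pair`` is the unmodified species, the second the
    modified one. A y_j ion observed only in the modified spectrum shows the
    glycan-bearing residue lies N-terminal of that ion, confining the site to
    peptide-local positions 1..(n-j). The window is intersected over all such
    diagnostic ions; candidate sites are the Ser/Thr residues inside it. The
    call is the unique candidate if exactly one exists.
    """
    unmod, mod = pair
    n = len(peptide)

    def y_keys(annotated: AnnotatedSpectrum) -> set[tuple[int, int]]:
        return {
            (ion.index_y, ion.charge)
            for ion in annotated.matched_ions()
            if ion.series == "y"
        }

    specific = y_keys(mod) - y_keys(unmod)
    evidence = tuple(sorted(f"y{j}^{z}+" for j, z in specific))
    if specific:
        j_max = max(j for j, _ in specific)
        window_local = (1, n - j_max)
    else:
        window_local = (1, n)
    window = (
        peptide.start_pos + window_local[0] - 1,
        peptide.start_pos + window_local[1] - 1,
    )
    candidates = tuple(
        peptide.start_pos + i
        for i in range(window_local[0] - 1, window_local[1])
        if peptide.sequence[i] in "ST"
    )
    call: int | str = candidates[0] if len(candidates) == 1 else "ambiguous"
    return LocalizationResult(
        window=window, candidate_sites=candidates, call=call, evidence=evidence
    )
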