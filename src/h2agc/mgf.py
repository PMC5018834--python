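"""Mascot generic format (MGF) reading and writing.

Implemented in-package (no MGF library in the runtime environment): the
subset handled is BEGIN IONS/END IONS blocks with TITLE, PEPMASS and CHARGE
headers followed by "m/z intensity" peak lines, which covers everything the
pipeline produces or consumes. Round-trip (write then read) preserves every
field to 1e-6.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

from .glyco_ms import Spectrum


class MGFError(ValueError):
    pass


_CHARGE_RE = re.compile(r"^(\d+)\+?$")


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Parse an MGF file into a list of :class:`Spectrum`."""
    spectra: list[Spectrum] = []
    in_block = False
    block_start = 0
    title = ""
    pepmass: float | None = None
    charge: int | None = None
    peaks: list[tuple[float, float]] = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                if in_block:
                    raise MGFError(f"line {lineno}: nested BEGIN IONS")
                in_block = True
                block_start = lineno
                title, pepmass, charge, peaks = "", None, None, []
            elif line == "END IONS":
                if not in_block:
                    raise MGFError(f"line {lineno}: END IONS without BEGIN IONS")
                if pepmass is None:
                    raise MGFError(
                        f"block starting at line {block_start}"
                        f" (title {title!r}): missing PEPMASS"
                    )
                peaks.sort(key=lambda p: p[0])
                spectra.append(
                    Spectrum(
                        precursor_mz=pepmass,
                        precursor_charge=charge if charge is not None else 1,
                        peaks=tuple(peaks),
                        title=title,
                    )
                )
                in_block = False
            elif not in_block:
                raise MGFError(f"line {lineno}: data outside BEGIN IONS block")
            elif "=" in line:
                key, _, value = line.partition("=")
                key = key.upper()
                if key == "TITLE":
                    title = value
                elif key == "PEPMASS":
                    try:
                        pepmass = float(value.split()[0])
                    except ValueError:
                        raise MGFError(f"line {lineno}: bad PEPMASS {value!r}") from None
                elif key == "CHARGE":
                    m = _CHARGE_RE.match(value.strip())
                    if not m:
                        raise MGFError(f"line {lineno}: bad CHARGE {value!r}")
                    charge = int(m.group(1))
                # other headers silently ignored
            else:
                fields = line.split()
                if len(fields) < 2:
                    raise MGFError(f"line {lineno}: bad peak line {line!r}")
                try:
                    peaks.append((float(fields[0]), float(fields[1])))
                except ValueError:
                    raise MGFError(f"line {lineno}: bad peak line {line!r}") from None
    if in_block:
        raise MGFError(f"block starting at line {block_start}: missing END IONS")
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            if s.title:
                fh.write(f"TITLE={s.title}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={s.precursor_charge}+\n")
            for mz, intensity in s.peaks:
                fh.write(f"{mz:.6f} {intensity:.6f}\n")
            fh.write("END IONS\n")
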