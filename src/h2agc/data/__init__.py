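"""Packaged sequence fixtures.

The mouse H2A fixtures are RECONSTRUCTED (synthetic) stand-ins, not database
exports: the G37-K74 span of the Ser40-type record is the experimentally
identified Lys-C peptide (cross-validated in the test suite against the
observed precursor m/z 1327.02 at z=3), embedded in the canonical mouse H2A
backbone; the Ala40-type record is its Ser40Ala counterpart. Residue 1 is the
residue after the cleaved initiator Met (histone numbering), so Ser40 of the
Ser40-type record sits in the Y-S-E context of the L1 loop.
"""

from importlib import resources

from ..io import read_fasta_records


def _fixture_path():
    return resources.files(__package__) / "mouse_h2a_synthetic.fasta"


def mouse_h2a_records():
    """The two reconstructed mouse canonical H2A fixtures (Ser40, Ala40)."""
    with resources.as_file(_fixture_path()) as path:
        return read_fasta_records(path)


def reference_h2a() -> str:
    """Ser40-type mouse H2A sequence used as the anchoring reference."""
    return mouse_h2a_records()[0].sequence
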