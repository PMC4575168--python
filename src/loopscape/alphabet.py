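"""Amino-acid and codon alphabets shared across the package.

The amino-acid alphabet is fixed to the 20 canonical one-letter codes plus
``'*'`` for stop.  ``'X'`` and other ambiguity codes are rejected at
validation boundaries.
"""

from __future__ import annotations

import re

AA20: str = "ACDEFGHIKLMNPQRSTVWY"
STOP: str = "*"
AA21: str = AA20 + STOP

NUCLEOTIDES: str = "ACGT"

# Standard genetic code, DNA codons.
CODON_TABLE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

# One deterministic codon per amino acid, used when a designed site fixes the
# residue identity (conserved / fixed-set sites) and for back-translating the
# framework reference.
PREFERRED_CODON: dict[str, str] = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "TTG",
    "M": "ATG", "N": "AAT", "P": "CCA", "Q": "CAA", "R": "AGA",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
    "*": "TAA",
}

_SITE_LABEL_RE = re.compile(r"^([A-Z]?)(\d+)([a-z]*)$")


def validate_aa(aa: str) -> str:
    """Return ``aa`` if it is a canonical amino-acid letter, else raise."""
    if len(aa) != 1 or aa not in AA20:
        raise ValueError(f"unknown amino-acid letter: {aa!r}")
    return aa


def translate(dna: str) -> str:
    """Translate an in-frame DNA string; trailing partial codons are an error."""
    if len(dna) % 3 != 0:
        raise ValueError(f"sequence length {len(dna)} is not a multiple of 3")
    dna = dna.upper()
    try:
        return "".join(CODON_TABLE[dna[i:i + 3]] for i in range(0, len(dna), 3))
    except KeyError as exc:
        raise ValueError(f"untranslatable codon {exc.args[0]!r}") from None


def back_translate(protein: str) -> str:
    return "".join(PREFERRED_CODON[a] for a in protein)


def site_sort_key(label: str) -> tuple[int, str]:
    """Sort key for reference site labels like ``'D23'``, ``'28a'``, ``'54a'``.

    Orders by residue number, then insertion suffix; the optional leading
    wild-type letter is ignored.  Labels without a residue number sort last,
    lexicographically.
    """
    m = _SITE_LABEL_RE.match(label)
    if m is None:
        return (1 << 31, label)
    return int(m.group(2)), m.group(3)


def site_number(label: str) -> int:
    m = _SITE_LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"unparseable site label: {label!r}")
    return int(m.group(2))
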