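"""IUPAC nucleotide ambiguity codes as sets, built from Biopython's tables.

Every ambiguity code denotes a set of unambiguous nucleotides (R = {A,G},
N = {A,C,G,T}, ...).  The consensus and degeneracy-recoding stages both work
on these denoted sets, so the two directions of the table live here.
"""

from __future__ import annotations

from Bio.Data.IUPACData import ambiguous_dna_values

from .errors import InvalidSymbolError

#: code -> frozenset of unambiguous bases (uppercase; no gap)
CODE_TO_SET: dict[str, frozenset[str]] = {
    code: frozenset(bases)
    for code, bases in ambiguous_dna_values.items()
    if code != "X"  # Biopython lists X as a synonym of N; keep N canonical
}

#: frozenset of bases -> canonical single-letter code
SET_TO_CODE: dict[frozenset[str], str] = {s: c for c, s in CODE_TO_SET.items()}

GAP = "-"


def nucleotide_set(symbol: str) -> frozenset[str]:
    """Return the set of bases denoted by one IUPAC symbol (gap not allowed)."""
    try:
        return CODE_TO_SET[symbol.upper()]
    except KeyError:
        raise InvalidSymbolError(f"not an IUPAC nucleotide code: {symbol!r}") from None


def set_code(bases: frozenset[str]) -> str:
    """Return the IUPAC code denoting exactly ``bases``."""
    try:
        return SET_TO_CODE[bases]
    except KeyError:
        raise InvalidSymbolError(f"no IUPAC code for base set {sorted(bases)}") from None


def union_code(symbols) -> str:
    """IUPAC code denoting the union of the sets denoted by ``symbols``."""
    union: frozenset[str] = frozenset()
    for s in symbols:
        union = union | nucleotide_set(s)
    return set_code(union)


def pattern_for_codons(codons) -> str:
    """Minimal IUPAC triplet whose per-position sets cover a codon family.

    The expansion of the returned pattern is a superset of the family (it is
    the per-position closure), which is exactly the degeneracy-coding
    convention: Gly {GGA,GGC,GGG,GGT} -> GGN, Ser2 {AGC,AGT} -> AGY.
    """
    codons = list(codons)
    if not codons:
        raise InvalidSymbolError("empty codon family")
    out = []
    for pos in range(3):
        out.append(set_code(frozenset(c[pos] for c in codons)))
    return "".join(out)
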