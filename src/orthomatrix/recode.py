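"""Degeneracy recoding of codon alignments (degen1 semantics).

Each sense codon is replaced by a degenerate IUPAC triplet covering its
synonymous family, so that after recoding only nonsynonymous differences
remain informative.  Families are the standard-code amino acids with three
special cases: the six-fold leucine family is coded YTN, the six-fold
arginine family MGN, and serine is split into its two codon subfamilies TCN
and AGY (which are not interconvertible by synonymous change at a single
position).  The family table is regenerated from the standard genetic code
at import time rather than hard-coded, so it can be audited against the code
itself.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .errors import InvalidAlignmentError, InvalidSymbolError
from .iupac import GAP, nucleotide_set, pattern_for_codons

log = logging.getLogger(__name__)

_STANDARD = unambiguous_dna_by_id[1]


def _standard_families() -> dict[str, tuple[str, ...]]:
    """Codon families of the standard code, with the degen special cases."""
    by_aa: dict[str, list[str]] = {}
    for codon, aa in _STANDARD.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    families: dict[str, list[str]] = {}
    for aa, codons in by_aa.items():
        if aa == "S":
            families["Ser_TCN"] = [c for c in codons if c.startswith("TC")]
            families["Ser_AGY"] = [c for c in codons if c.startswith("AG")]
        else:
            families[aa] = codons
    return {k: tuple(sorted(v)) for k, v in families.items()}


@dataclass
class DegenMap:
    """Mapping codon family -> degenerate IUPAC triplet pattern.

    Invariants checked on construction: every sense codon belongs to exactly
    one family, each family's pattern expands to a superset of the family,
    and distinct families have distinct patterns.
    """

    families: dict[str, tuple[str, ...]] = field(default_factory=_standard_families)
    patterns: dict[str, str] = field(init=False)
    codon_to_family: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        self.patterns = {}
        self.codon_to_family = {}
        for fam, codons in self.families.items():
            if fam == "L":
                # six-fold Leu: TTR + CTN share only positions 1 (Y) and 2 (T)
                pattern = "YTN"
            elif fam == "R":
                pattern = "MGN"
            else:
                pattern = pattern_for_codons(codons)
            self.patterns[fam] = pattern
            for c in codons:
                if c in self.codon_to_family:
                    raise InvalidSymbolError(f"codon {c} assigned to two families")
                self.codon_to_family[c] = fam
        if len(self.codon_to_family) != 61:
            raise InvalidSymbolError(
                f"family table covers {len(self.codon_to_family)} sense codons, expected 61"
            )
        if len(set(self.patterns.values())) != len(self.patterns):
            raise InvalidSymbolError("distinct families must map to distinct patterns")
        for fam, codons in self.families.items():
            expansion = set(_expand(self.patterns[fam]))
            if not set(codons) <= expansion:
                raise InvalidSymbolError(f"pattern {self.patterns[fam]} does not cover {fam}")


def _expand(triplet: str):
    sets = [sorted(nucleotide_set(s)) for s in triplet]
    for combo in itertools.product(*sets):
        yield "".join(combo)


_DEFAULT_MAP: DegenMap | None = None


def default_map() -> DegenMap:
    global _DEFAULT_MAP
    if _DEFAULT_MAP is None:
        _DEFAULT_MAP = DegenMap()
    return _DEFAULT_MAP


def degen_codon(codon: str, degen_map: DegenMap | None = None) -> str:
    """Recode one codon to its family's degenerate pattern.

    Rules: a codon containing a gap becomes ``---``; an unambiguous sense
    codon becomes its family pattern; an ambiguous codon whose compatible
    sense codons all fall in one family becomes that family's pattern,
    otherwise ``NNN``; codons compatible only with stops become ``NNN``
    (these matrices are protein-coding, so a stop is treated as missing).
    """
    if degen_map is None:
        degen_map = default_map()
    if len(codon) != 3:
        raise InvalidAlignmentError(f"not a triplet: {codon!r}")
    cod = codon.upper()
    if GAP in cod:
        return "---"
    if cod in degen_map.patterns.values() or cod == "NNN":
        # family patterns are fixed points: YTN and MGN deliberately expand
        # beyond their own families (Leu/Phe, Arg/Ser2 ambiguity overlap)
        return cod
    families = set()
    any_stop = False
    for expanded in _expand(cod):  # validates symbols via nucleotide_set
        fam = degen_map.codon_to_family.get(expanded)
        if fam is None:
            any_stop = True
        else:
            families.add(fam)
    if not families:
        log.debug("stop-only codon %s recoded to NNN", cod)
        return "NNN"
    if len(families) == 1 and not any_stop:
        return degen_map.patterns[next(iter(families))]
    return "NNN"


def degen_sequence(seq: str, degen_map: DegenMap | None = None) -> str:
    """Apply degen_codon to every in-frame triplet of one row."""
    if len(seq) % 3 != 0:
        raise InvalidAlignmentError(f"sequence length {len(seq)} not divisible by 3")
    return "".join(degen_codon(seq[i : i + 3], degen_map) for i in range(0, len(seq), 3))


def degen_alignment(alignment, degen_map: DegenMap | None = None):
    """Recode every row of a codon alignment; dimensions are unchanged.

    Accepts and returns the orthomap ``CodonAlignment`` container.
    """
    from .orthomap import CodonAlignment  # local import to avoid a cycle

    rows = {taxon: degen_sequence(row, degen_map) for taxon, row in alignment.rows.items()}
    return CodonAlignment(gene_id=alignment.gene_id, rows=rows)
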