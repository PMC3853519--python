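"""Ortholog-hit reduction: one aligned codon sequence per taxon and locus.

An orthology search typically returns several scored protein/CDS hits per
taxon for each orthologous group (isoforms, alleles, fragments, paralogs).
This module reduces them to a single row per taxon by either of two
procedures: "consensus" (combine all retained rows into one sequence using
IUPAC ambiguity codes, treating gaps as missing data) or "representative"
(pick the single row — or the column-wise merge of mutually non-overlapping
fragments — that aligns best to a chosen reference taxon).  Upstream of the
reduction sit the search filters: an E-value cutoff, retention of only the
top-scoring quartile of hits, and a reciprocal-best-hit check against the
reference proteome.

The search engines themselves (profile HMMs, BLAST, GeneWise) are out of
scope; any deterministic pairwise scorer satisfying the simple callable
contract can be plugged in, and a BLOSUM62 global aligner is bundled as the
default.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .errors import (
    EmptyInputError,
    FrameInconsistencyError,
    InvalidAlignmentError,
    InvalidInputError,
)
from .iupac import GAP, set_code, nucleotide_set

PairwiseScorer = Callable[[str, str], float]


class Blosum62Scorer:
    """Global protein alignment score: BLOSUM62, gap open -11, extend -1.

    Deterministic and symmetric, which is all the scorer contract requires.
    """

    def __init__(self) -> None:
        self._aligner = Align.PairwiseAligner()
        self._aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        self._aligner.open_gap_score = -11.0
        self._aligner.extend_gap_score = -1.0
        self._aligner.mode = "global"

    def __call__(self, a: str, b: str) -> float:
        return float(self._aligner.score(a, b))

    def align(self, a: str, b: str):
        """Best global alignment (first in Biopython's deterministic order)."""
        return self._aligner.align(a, b)[0]


class NucleotideScorer:
    """Global nucleotide alignment score: match +1, mismatch -1, gap -2/-1."""

    def __init__(self) -> None:
        self._aligner = Align.PairwiseAligner()
        self._aligner.match_score = 1.0
        self._aligner.mismatch_score = -1.0
        self._aligner.open_gap_score = -2.0
        self._aligner.extend_gap_score = -1.0
        self._aligner.mode = "global"

    def __call__(self, a: str, b: str) -> float:
        return float(self._aligner.score(a, b))


@dataclass
class OrthologHit:
    """One scored protein/CDS hit of a taxon against an orthologous group."""

    gene_id: str
    taxon: str
    seq_id: str
    protein: str
    cds: str
    score: float
    evalue: float

    def __post_init__(self) -> None:
        if len(self.cds) != 3 * len(self.protein):
            raise InvalidInputError(
                f"hit {self.seq_id!r}: CDS length {len(self.cds)} != 3 x protein length"
            )
        if self.evalue < 0:
            raise InvalidInputError(f"hit {self.seq_id!r}: negative E-value")


@dataclass
class OrthologGroup:
    """Per-taxon collections of hits for one gene, plus the reference taxon."""

    gene_id: str
    hits: dict[str, list[OrthologHit]]
    reference_taxon: str

    def __post_init__(self) -> None:
        for taxon, hits in self.hits.items():
            for h in hits:
                if h.gene_id != self.gene_id:
                    raise InvalidInputError(
                        f"hit {h.seq_id!r} has gene {h.gene_id!r}, group is {self.gene_id!r}"
                    )

    def n_hits(self) -> int:
        return sum(len(v) for v in self.hits.values())


@dataclass
class CodonAlignment:
    """In-frame nucleotide alignment over {A,C,G,T, ambiguity codes, '-'}."""

    gene_id: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise InvalidAlignmentError(f"gene {self.gene_id}: rows have unequal lengths")
        if lengths and next(iter(lengths)) % 3 != 0:
            raise InvalidAlignmentError(f"gene {self.gene_id}: length not divisible by 3")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


def filter_hits(
    group: OrthologGroup,
    evalue_cutoff: float = 1e-5,
    quartile: float = 0.25,
) -> OrthologGroup:
    """E-value cutoff plus top-scoring-quartile retention, per taxon.

    Hits with E-value above the cutoff are removed; of the survivors for each
    taxon, the ceil(quartile * n) highest-scoring are retained (minimum one
    whenever any survive).  Score ties are broken by sequence id so the
    result is deterministic.
    """
    out: dict[str, list[OrthologHit]] = {}
    for taxon, hits in group.hits.items():
        passing = [h for h in hits if h.evalue <= evalue_cutoff]
        if not passing:
            out[taxon] = []
            continue
        k = max(1, math.ceil(quartile * len(passing)))
        ranked = sorted(passing, key=lambda h: (-h.score, h.seq_id))
        out[taxon] = ranked[:k]
    return OrthologGroup(gene_id=group.gene_id, hits=out, reference_taxon=group.reference_taxon)


def reciprocal_best_hit(
    hit: OrthologHit,
    reference_proteome: Mapping[str, str],
    scorer: PairwiseScorer | None = None,
) -> bool:
    """True iff the hit's best reference protein belongs to its own group.

    ``reference_proteome`` maps gene id -> reference-taxon protein.  Score
    ties are broken by the lexicographically smallest gene id, so the test is
    deterministic.
    """
    if not reference_proteome:
        raise InvalidInputError("empty reference proteome")
    if scorer is None:
        scorer = Blosum62Scorer()
    best_gene = None
    best_score = -math.inf
    for gene_id in sorted(reference_proteome):
        s = scorer(hit.protein, reference_proteome[gene_id])
        if s > best_score:
            best_score = s
            best_gene = gene_id
    return best_gene == hit.gene_id


def backtranslate(
    protein_alignment: Mapping[str, str],
    cds_lookup: Mapping[str, str],
    gene_id: str = "",
) -> CodonAlignment:
    """Replace each aligned residue by its source codon; gaps become ``---``.

    Each ungapped protein row must translate exactly from its CDS under the
    standard genetic code; a mismatch raises an error naming the row and the
    alignment column.
    """
    rows: dict[str, str] = {}
    for taxon, prot_row in protein_alignment.items():
        cds = cds_lookup[taxon]
        codons: list[str] = []
        i = 0
        for col, aa in enumerate(prot_row):
            if aa == GAP:
                codons.append("---")
                continue
            codon = cds[3 * i : 3 * i + 3]
            if len(codon) < 3:
                raise FrameInconsistencyError(
                    f"{taxon}: CDS exhausted at alignment column {col + 1}"
                )
            translated = str(Seq(codon).translate())
            if translated != aa.upper() and not (translated == "*" and aa.upper() == "X"):
                raise FrameInconsistencyError(
                    f"{taxon}: column {col + 1} residue {aa!r} does not match "
                    f"codon {codon} ({translated})"
                )
            codons.append(codon)
            i += 1
        if 3 * i != len(cds):
            raise FrameInconsistencyError(
                f"{taxon}: {len(cds) - 3 * i} CDS bases left over after back-translation"
            )
        rows[taxon] = "".join(codons)
    return CodonAlignment(gene_id=gene_id, rows=rows)


def build_consensus(rows: Sequence[str]) -> str:
    """IUPAC consensus of aligned rows, treating gaps as missing data.

    Per column the output symbol denotes exactly the union of the nucleotide
    sets denoted by the non-gap input symbols; a column that is gap in every
    row stays a gap.  Ambiguity codes in the input contribute their whole
    denoted set.
    """
    if not rows:
        raise EmptyInputError("no rows to combine")
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise InvalidAlignmentError("consensus rows have unequal lengths")
    out: list[str] = []
    for col in range(lengths.pop()):
        union: frozenset[str] = frozenset()
        for r in rows:
            sym = r[col]
            if sym != GAP:
                union = union | nucleotide_set(sym)
        out.append(GAP if not union else set_code(union))
    return "".join(out)


def _nongap_mask(row: str) -> int:
    m = 0
    for i, c in enumerate(row):
        if c != GAP:
            m |= 1 << i
    return m


def _merge(rows: Sequence[str], length: int) -> str:
    out = [GAP] * length
    for r in rows:
        for i, c in enumerate(r):
            if c != GAP:
                out[i] = c
    return "".join(out)


def choose_representative(
    rows: Sequence[str],
    reference_row: str,
    scorer: PairwiseScorer | None = None,
) -> str:
    """Best single row, or merge of mutually non-overlapping fragments.

    Candidates are every subset of rows in which no column is non-gap in two
    members ("non-overlapping"; the tolerance is zero shared columns).  Each
    candidate is merged column-wise and scored ungapped against the ungapped
    reference row; the highest score wins, with ties broken by fewest merged
    rows and then by the lexicographically smallest merged sequence.
    """
    if not rows:
        raise EmptyInputError("no candidate rows")
    lengths = {len(r) for r in rows} | {len(reference_row)}
    if len(lengths) > 1:
        raise InvalidAlignmentError("representative rows have unequal lengths")
    if len(rows) == 1:
        return rows[0]
    if scorer is None:
        scorer = NucleotideScorer()
    length = len(reference_row)
    masks = [_nongap_mask(r) for r in rows]
    ref_ungapped = reference_row.replace(GAP, "")
    best: tuple[float, int, str] | None = None
    best_seq = None
    for size in range(1, len(rows) + 1):
        for combo in itertools.combinations(range(len(rows)), size):
            m = 0
            ok = True
            for i in combo:
                if m & masks[i]:
                    ok = False
                    break
                m |= masks[i]
            if not ok:
                continue
            merged = _merge([rows[i] for i in combo], length)
            score = scorer(merged.replace(GAP, ""), ref_ungapped)
            key = (-score, size, merged)
            if best is None or key < best:
                best = key
                best_seq = merged
    assert best_seq is not None
    return best_seq


def anchor_alignment(
    hits: Sequence[OrthologHit],
    reference_protein: str,
    reference_cds: str,
    aligner: Blosum62Scorer | None = None,
    gene_id: str = "",
) -> CodonAlignment:
    """Reference-anchored codon alignment of hits (the bundled naive aligner).

    Each hit's protein is globally aligned to the reference protein; columns
    where the reference has a residue define the frame, and hit insertions
    relative to the reference are dropped.  All rows therefore share the
    reference length, and rows from different taxa are mutually comparable.
    The reference row itself is included under the reference hit id ``ref``.
    """
    if aligner is None:
        aligner = Blosum62Scorer()
    prot_rows: dict[str, str] = {"ref": reference_protein}
    cds_lookup: dict[str, str] = {"ref": reference_cds}
    for hit in hits:
        aln = aligner.align(hit.protein, reference_protein)
        q, r = str(aln[0]), str(aln[1])
        row = [GAP] * len(reference_protein)
        pos = 0
        for qa, ra in zip(q, r):
            if ra != GAP:
                if qa != GAP:
                    row[pos] = qa
                pos += 1
        prot_rows[hit.seq_id] = "".join(row)
        # drop codons of residues that fell in insertion columns
        kept_cds = []
        qi = 0
        for qa, ra in zip(q, r):
            if qa != GAP:
                if ra != GAP:
                    kept_cds.append(hit.cds[3 * qi : 3 * qi + 3])
                qi += 1
        cds_lookup[hit.seq_id] = "".join(kept_cds)
    return backtranslate(prot_rows, cds_lookup, gene_id=gene_id)
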