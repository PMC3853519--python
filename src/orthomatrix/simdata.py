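"""Synthetic phylogenomic datasets with known truth.

Everything downstream of wet-lab sequencing is exercised against data
generated here: a birth-death species tree, per-gene codon sequences evolved
along it under a simple substitution process with a synonymous/nonsynonymous
rate split, gene duplications planted on chosen branches (with true
ortholog/paralog labels retained), multiple transcripts per taxon and locus
(isoforms, alleles, fragments), and reads with configurable length, error
rate and quality profile.  A fixed seed makes every output byte-identical
across runs.

The substitution process is per-site nucleotide substitution filtered
through the genetic code, not a full codon model: proposals arrive at a
Poisson rate given by the branch length (expected proposals per site);
synonymous proposals are accepted at ``synonymous_rate_multiplier`` times
the rate of nonsynonymous ones, and proposals creating stop codons are
rejected.  That is the minimal structure that makes degeneracy recoding
consequential downstream.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .errors import InvalidParameterError
from .readqc import QualityRead, write_fastq

log = logging.getLogger(__name__)

_NT = "ACGT"
_STANDARD = unambiguous_dna_by_id[1]
_STOPS = set(_STANDARD.stop_codons)
_SENSE = sorted(_STANDARD.forward_table)  # 61 codons
_AA_OF: dict[str, str] = dict(_STANDARD.forward_table)


@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed fixes every random draw."""

    seed: int
    n_taxa: int = 20
    n_genes: int = 50
    gene_length_codons: int = 200
    dup_probability: float = 0.0
    isoform_rate: float = 0.1
    allele_rate: float = 0.1
    fragment_rate: float = 0.05
    synonymous_rate_multiplier: float = 5.0
    read_length: int = 100
    read_error_rate: float = 0.005
    quality_mean: float = 35.0
    quality_sd: float = 4.0
    reads_per_transcript: int = 20
    dup_min_taxa: int = 3
    birth_rate: float = 1.0
    tree_height: float = 0.5
    allele_heterozygosity: float = 0.005

    def __post_init__(self) -> None:
        for name in ("dup_probability", "isoform_rate", "allele_rate", "fragment_rate",
                     "read_error_rate", "allele_heterozygosity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidParameterError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_taxa", "n_genes", "gene_length_codons", "read_length",
                     "reads_per_transcript"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.n_taxa < 2:
            raise InvalidParameterError("n_taxa must be >= 2")
        if self.synonymous_rate_multiplier <= 0:
            raise InvalidParameterError("synonymous_rate_multiplier must be positive")
        if self.tree_height <= 0 or self.birth_rate <= 0:
            raise InvalidParameterError("tree_height and birth_rate must be positive")


@dataclass
class GeneFamilyTruth:
    """Ground truth for one simulated gene family."""

    gene_id: str
    is_clean: bool
    duplication_events: list[tuple[str, float]]  # (branch clade label, time fraction)
    per_sequence_labels: dict[str, tuple[str, str]]  # seq_id -> (taxon, ortholog|paralog)
    syn_events: int = 0
    nonsyn_events: int = 0

    def __post_init__(self) -> None:
        if self.is_clean != (not self.duplication_events):
            raise InvalidParameterError("is_clean must hold exactly when no duplication planted")


@dataclass
class GeneFamily:
    truth: GeneFamilyTruth
    cds_by_taxon: dict[str, list[tuple[str, str]]]  # taxon -> [(seq_id, cds)]


@dataclass
class Transcript:
    id: str
    taxon: str
    gene_id: str
    source_seq_id: str
    seq: str


@dataclass
class SequencingArtifacts:
    transcripts: dict[str, list[Transcript]]  # per taxon
    reads: dict[str, list[QualityRead]]  # per taxon
    reads_per_transcript_id: dict[str, int]


def simulate_species_tree(
    n_taxa: int, seed: int, birth_rate: float = 1.0, tree_height: float = 0.5
) -> dendropy.Tree:
    """Pure-birth species tree with ``n_taxa`` leaves, rescaled to a fixed height.

    Leaves are labeled T01, T02, ...; branch lengths are in expected
    substitution proposals per site, with the deepest root-to-tip path equal
    to ``tree_height``.  Deterministic under a fixed seed.
    """
    if n_taxa < 2:
        raise InvalidParameterError("n_taxa must be >= 2")
    from dendropy.model import birthdeath

    tree = birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=random.Random(seed),
    )
    for i, leaf in enumerate(sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)):
        leaf.taxon.label = f"T{i + 1:02d}"
    depth = max(
        sum(e.length or 0.0 for e in _path_edges(leaf)) for leaf in tree.leaf_node_iter()
    )
    if depth > 0:
        scale = tree_height / depth
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale
    return tree


def _path_edges(leaf: dendropy.Node):
    edges = []
    node = leaf
    while node.parent_node is not None:
        edges.append(node.edge)
        node = node.parent_node
    return edges


class _CodonEvolver:
    """Proposal/acceptance substitution engine over in-frame sequences."""

    def __init__(self, rng: np.random.Generator, syn_multiplier: float):
        self.rng = rng
        if syn_multiplier >= 1.0:
            self.p_syn, self.p_nonsyn = 1.0, 1.0 / syn_multiplier
        else:
            self.p_syn, self.p_nonsyn = syn_multiplier, 1.0
        self.syn_events = 0
        self.nonsyn_events = 0

    def random_cds(self, n_codons: int) -> str:
        idx = self.rng.integers(0, len(_SENSE), size=n_codons)
        return "".join(_SENSE[i] for i in idx)

    def evolve(self, seq: str, branch_length: float) -> str:
        n_sites = len(seq)
        n_attempts = int(self.rng.poisson(branch_length * n_sites))
        if n_attempts == 0:
            return seq
        chars = list(seq)
        positions = self.rng.integers(0, n_sites, size=n_attempts)
        shifts = self.rng.integers(1, 4, size=n_attempts)
        accept_draws = self.rng.random(n_attempts)
        for pos, shift, draw in zip(positions, shifts, accept_draws):
            old = chars[pos]
            new = _NT[(_NT.index(old) + shift) % 4]
            cstart = (pos // 3) * 3
            codon = chars[cstart:cstart + 3]
            codon[pos - cstart] = new
            new_codon = "".join(codon)
            if new_codon in _STOPS:
                continue
            old_codon = "".join(chars[cstart:cstart + 3])
            synonymous = _AA_OF[new_codon] == _AA_OF[old_codon]
            p = self.p_syn if synonymous else self.p_nonsyn
            if draw < p:
                chars[pos] = new
                if synonymous:
                    self.syn_events += 1
                else:
                    self.nonsyn_events += 1
        return "".join(chars)


def _clade_label(node: dendropy.Node) -> str:
    return ",".join(sorted(l.taxon.label for l in node.leaf_iter()))


def simulate_gene_families(
    tree: dendropy.Tree, config: SimulationConfig
) -> list[GeneFamily]:
    """Evolve ``n_genes`` codon gene families along the species tree.

    With probability ``dup_probability`` a gene receives one duplication,
    planted at a uniform time fraction on a branch whose subtree spans at
    least ``dup_min_taxa`` taxa; both copies then evolve independently down
    that subtree, and every emitted sequence keeps its ortholog/paralog
    truth label.  Sequences are free of internal stop codons by construction.
    """
    if config.gene_length_codons == 0:
        raise InvalidParameterError("gene_length_codons must be positive")
    rng = np.random.default_rng([config.seed, 1])
    eligible = [
        nd
        for nd in tree.preorder_node_iter()
        if nd.parent_node is not None
        and not nd.is_leaf()
        and sum(1 for _ in nd.leaf_iter()) >= config.dup_min_taxa
    ]
    if not eligible:
        eligible = [nd for nd in tree.preorder_node_iter() if nd.parent_node is not None and not nd.is_leaf()]
    families: list[GeneFamily] = []
    for g in range(config.n_genes):
        gene_id = f"g{g + 1:04d}"
        evolver = _CodonEvolver(rng, config.synonymous_rate_multiplier)
        root_seq = evolver.random_cds(config.gene_length_codons)
        dup_node = None
        dup_fraction = 0.0
        events: list[tuple[str, float]] = []
        if config.dup_probability > 0 and rng.random() < config.dup_probability and eligible:
            dup_node = eligible[int(rng.integers(0, len(eligible)))]
            dup_fraction = float(rng.random())
            events.append((_clade_label(dup_node), dup_fraction))
        cds_by_taxon: dict[str, list[tuple[str, str]]] = {}
        labels: dict[str, tuple[str, str]] = {}

        def emit(leaf: dendropy.Node, seq: str, copy: int) -> None:
            taxon = leaf.taxon.label
            seq_id = f"{gene_id}_c{copy}"
            cds_by_taxon.setdefault(taxon, []).append((seq_id, seq))
            labels[f"{taxon}|{seq_id}"] = (taxon, "paralog" if copy else "ortholog")

        def recurse(node: dendropy.Node, seq: str, copy: int) -> None:
            if node.is_leaf():
                emit(node, seq, copy)
                return
            for child in node.child_nodes():
                b = child.edge.length or 0.0
                if dup_node is not None and child is dup_node and copy == 0:
                    at_dup = evolver.evolve(seq, b * dup_fraction)
                    rest = b * (1.0 - dup_fraction)
                    recurse(child, evolver.evolve(at_dup, rest), 0)
                    recurse(child, evolver.evolve(at_dup, rest), 1)
                else:
                    recurse(child, evolver.evolve(seq, b), copy)

        recurse(tree.seed_node, root_seq, 0)
        truth = GeneFamilyTruth(
            gene_id=gene_id,
            is_clean=not events,
            duplication_events=events,
            per_sequence_labels=labels,
            syn_events=evolver.syn_events,
            nonsyn_events=evolver.nonsyn_events,
        )
        families.append(GeneFamily(truth=truth, cds_by_taxon=cds_by_taxon))
    return families


def _codon_substring(rng: np.random.Generator, n_codons: int, lo: float, hi: float) -> tuple[int, int]:
    span = max(1, int(n_codons * (lo + (hi - lo) * rng.random())))
    start = int(rng.integers(0, n_codons - span + 1))
    return start, start + span


def _substitute_no_stops(rng: np.random.Generator, seq: str, rate: float) -> str:
    chars = list(seq)
    n_subs = int(rng.binomial(len(seq), rate))
    positions = rng.integers(0, len(seq), size=n_subs)
    shifts = rng.integers(1, 4, size=n_subs)
    for pos, shift in zip(positions, shifts):
        new = _NT[(_NT.index(chars[pos]) + shift) % 4]
        cstart = (pos // 3) * 3
        codon = chars[cstart:cstart + 3]
        codon[pos - cstart] = new
        if "".join(codon) in _STOPS:
            continue
        chars[pos] = new
    return "".join(chars)


def emit_sequencing_artifacts(
    families: list[GeneFamily], config: SimulationConfig
) -> SequencingArtifacts:
    """Turn gene-family CDS into per-taxon transcript FASTA and read FASTQ.

    Each taxon-locus sequence always yields its base transcript; with the
    configured rates it additionally yields an isoform (internal codon-run
    deletion), an allele (codon-safe substitutions at the heterozygosity
    rate), and/or a fragment (codon-aligned substring).  Reads are uniform
    substrings with per-base errors at ``read_error_rate`` and Phred scores
    drawn i.i.d. normal truncated to [2, 41]; reads from transcripts shorter
    than the read length cover the whole transcript and are logged.
    """
    if not families:
        raise InvalidParameterError("no gene families to emit")
    rng = np.random.default_rng([config.seed, 2])
    transcripts: dict[str, list[Transcript]] = {}
    for fam in families:
        gene = fam.truth.gene_id
        for taxon in sorted(fam.cds_by_taxon):
            for seq_id, cds in fam.cds_by_taxon[taxon]:
                base = Transcript(
                    id=f"{taxon}.{seq_id}", taxon=taxon, gene_id=gene,
                    source_seq_id=seq_id, seq=cds,
                )
                out = [base]
                n_codons = len(cds) // 3
                if rng.random() < config.isoform_rate and n_codons >= 10:
                    s, e = _codon_substring(rng, n_codons, 0.1, 0.3)
                    out.append(Transcript(
                        id=f"{base.id}.iso", taxon=taxon, gene_id=gene,
                        source_seq_id=seq_id, seq=cds[: 3 * s] + cds[3 * e:],
                    ))
                if rng.random() < config.allele_rate:
                    out.append(Transcript(
                        id=f"{base.id}.al", taxon=taxon, gene_id=gene,
                        source_seq_id=seq_id,
                        seq=_substitute_no_stops(rng, cds, config.allele_heterozygosity),
                    ))
                if rng.random() < config.fragment_rate and n_codons >= 10:
                    s, e = _codon_substring(rng, n_codons, 0.3, 0.6)
                    out.append(Transcript(
                        id=f"{base.id}.frag", taxon=taxon, gene_id=gene,
                        source_seq_id=seq_id, seq=cds[3 * s: 3 * e],
                    ))
                transcripts.setdefault(taxon, []).extend(out)
    reads: dict[str, list[QualityRead]] = {}
    counts: dict[str, int] = {}
    for taxon in sorted(transcripts):
        taxon_reads: list[QualityRead] = []
        for tr in transcripts[taxon]:
            counts[tr.id] = config.reads_per_transcript
            for i in range(config.reads_per_transcript):
                if len(tr.seq) <= config.read_length:
                    log.debug("transcript %s shorter than read length; emitting fragment-sized read", tr.id)
                    start, seg = 0, tr.seq
                else:
                    start = int(rng.integers(0, len(tr.seq) - config.read_length + 1))
                    seg = tr.seq[start:start + config.read_length]
                chars = list(seg)
                err = rng.random(len(chars)) < config.read_error_rate
                shifts = rng.integers(1, 4, size=len(chars))
                for p in np.nonzero(err)[0]:
                    chars[p] = _NT[(_NT.index(chars[p]) + shifts[p]) % 4]
                quals = np.clip(
                    np.rint(rng.normal(config.quality_mean, config.quality_sd, size=len(chars))),
                    2, 41,
                ).astype(int)
                rid = f"{tr.id}:{start}:{i}"
                taxon_reads.append(QualityRead(id=rid, bases="".join(chars), quals=list(quals), description=rid))
        reads[taxon] = taxon_reads
    return SequencingArtifacts(transcripts=transcripts, reads=reads, reads_per_transcript_id=counts)


def write_dataset(
    tree: dendropy.Tree,
    families: list[GeneFamily],
    artifacts: SequencingArtifacts,
    outdir: str | Path,
) -> None:
    """Write Newick species tree, per-taxon FASTA/FASTQ, and the truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "species_tree.nwk").write_text(
        tree.as_string(schema="newick", unquoted_underscores=True)
    )
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("gene_id\tis_clean\tsequence\ttaxon\tstatus\n")
        for fam in families:
            for key, (taxon, status) in sorted(fam.truth.per_sequence_labels.items()):
                fh.write(f"{fam.truth.gene_id}\t{int(fam.truth.is_clean)}\t{key}\t{taxon}\t{status}\n")
    with open(outdir / "hits.tsv", "w") as fh:
        fh.write("transcript_id\ttaxon\tgene_id\n")
        for taxon in sorted(artifacts.transcripts):
            for tr in artifacts.transcripts[taxon]:
                fh.write(f"{tr.id}\t{tr.taxon}\t{tr.gene_id}\n")
    for taxon in sorted(artifacts.transcripts):
        with open(outdir / f"{taxon}.transcripts.fasta", "w") as fh:
            for tr in artifacts.transcripts[taxon]:
                fh.write(f">{tr.id}\n{tr.seq}\n")
        with open(outdir / f"{taxon}.fastq", "w") as fh:
            write_fastq(artifacts.reads[taxon], fh)
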