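"""Supermatrix assembly, occupancy filtering, and pipeline orchestration.

The product of the pipeline is a concatenated, partitioned codon supermatrix:
per-gene alignments are concatenated in gene-id order (gaps filled for taxa
missing from a gene), degeneracy-recoded so only nonsynonymous signal
remains, and filtered so every retained site carries data in at least
``min_taxa`` taxa (default four).  ``run_pipeline`` drives the whole chain —
read QC, ortholog-hit filtering and reduction, gene-tree paralogy screening
with the strict filter, recoding, concatenation, occupancy filtering — and
reports the gene accounting at every stage.

Sites "represented by sequence data" are those holding any non-gap, non-N
symbol; ambiguity codes other than N count as data, since they constrain the
nucleotide.  Matrix completeness uses the same cell-level definition.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .errors import (
    EmptyInputError,
    InvalidInputError,
    InvalidParameterError,
    PipelineStageError,
    UndefinedCoverageError,
)
from .orthomap import (
    Blosum62Scorer,
    CodonAlignment,
    OrthologGroup,
    OrthologHit,
    anchor_alignment,
    build_consensus,
    choose_representative,
    filter_hits,
)
from .paraguard import PruneResult, estimate_gene_tree, prune_paralogs, strict_gene_filter
from .readqc import AssemblyMetrics, ContigSet, FilterParams, assembly_metrics, phred_filter
from .recode import degen_alignment
from .simdata import GeneFamily, SequencingArtifacts, Transcript
from .treekit import nj_tree, rf_distance

log = logging.getLogger(__name__)

_MISSING = frozenset("-Nn?")


@dataclass
class SuperMatrix:
    """Concatenated partitioned alignment; coordinates 1-based inclusive."""

    rows: dict[str, str]
    partitions: list[tuple[str, int, int]]
    min_taxa: int = 4

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise InvalidInputError("supermatrix rows have unequal lengths")
        length = lengths.pop() if lengths else 0
        pos = 1
        for gene, start, end in self.partitions:
            if start != pos or end < start - 1:
                raise InvalidInputError(f"partition {gene} does not tile the matrix")
            pos = end + 1
        if self.partitions and pos != length + 1:
            raise InvalidInputError("partitions do not cover the matrix")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


@dataclass
class CoverageStat:
    read_length: int
    median_reads_mapped: float
    median_group_length: float
    coverage: float


@dataclass
class MatrixReport:
    length: int
    n_taxa: int
    completeness_overall: float
    completeness_by_taxon: dict[str, float]


def concatenate_supermatrix(
    alignments: Sequence[CodonAlignment], taxa: Sequence[str]
) -> SuperMatrix:
    """Concatenate per-gene alignments in gene-id order, gap-filling absences."""
    ids = [a.gene_id for a in alignments]
    if len(set(ids)) != len(ids):
        raise InvalidInputError("duplicate gene ids in concatenation")
    ordered = sorted(alignments, key=lambda a: a.gene_id)
    parts: list[tuple[str, int, int]] = []
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    pos = 1
    for aln in ordered:
        n = aln.length
        parts.append((aln.gene_id, pos, pos + n - 1))
        pos += n
        for t in taxa:
            chunks[t].append(aln.rows.get(t, "-" * n))
    rows = {t: "".join(chunks[t]) for t in taxa}
    return SuperMatrix(rows=rows, partitions=parts)


def _data_mask(matrix: SuperMatrix) -> tuple[list[str], np.ndarray]:
    taxa = list(matrix.rows)
    arr = np.vstack([
        np.frombuffer(matrix.rows[t].encode("ascii"), dtype=np.uint8) for t in taxa
    ])
    missing = np.zeros(arr.shape, dtype=bool)
    for ch in _MISSING:
        missing |= arr == ord(ch)
    return taxa, ~missing


def occupancy_filter(matrix: SuperMatrix, min_taxa: int = 4) -> SuperMatrix:
    """Remove columns with data in fewer than ``min_taxa`` taxa.

    Partition coordinates are recomputed; partitions left empty are dropped.
    Idempotent, and never increases matrix length.
    """
    if matrix.length == 0:
        return matrix
    taxa, data = _data_mask(matrix)
    keep = data.sum(axis=0) >= min_taxa
    removed = int((~keep).sum())
    if removed:
        log.info("occupancy filter removed %d of %d sites", removed, matrix.length)
    arr = np.vstack([
        np.frombuffer(matrix.rows[t].encode("ascii"), dtype=np.uint8) for t in taxa
    ])[:, keep]
    rows = {t: arr[i].tobytes().decode("ascii") for i, t in enumerate(taxa)}
    parts: list[tuple[str, int, int]] = []
    pos = 1
    for gene, start, end in matrix.partitions:
        n = int(keep[start - 1 : end].sum())
        if n > 0:
            parts.append((gene, pos, pos + n - 1))
            pos += n
    return SuperMatrix(rows=rows, partitions=parts, min_taxa=min_taxa)


def coverage_per_base(
    read_length: int,
    reads_mapped_per_sequence: Sequence[int],
    sequence_lengths: Sequence[int],
) -> CoverageStat:
    """Depth statistic: read length x median mapped reads / median length."""
    if not reads_mapped_per_sequence or not sequence_lengths:
        raise EmptyInputError("coverage requires non-empty count and length lists")
    med_reads = float(np.median(reads_mapped_per_sequence))
    med_len = float(np.median(sequence_lengths))
    if med_len == 0:
        raise UndefinedCoverageError("median sequence length is zero")
    return CoverageStat(
        read_length=read_length,
        median_reads_mapped=med_reads,
        median_group_length=med_len,
        coverage=read_length * med_reads / med_len,
    )


def matrix_report(matrix: SuperMatrix) -> MatrixReport:
    """Length, taxon count, and completeness (non-gap, non-N cell fraction)."""
    if not matrix.rows:
        return MatrixReport(0, 0, 0.0, {})
    taxa, data = _data_mask(matrix)
    per_taxon = {t: float(data[i].mean()) if matrix.length else 0.0 for i, t in enumerate(taxa)}
    overall = float(data.mean()) if matrix.length else 0.0
    return MatrixReport(
        length=matrix.length,
        n_taxa=len(taxa),
        completeness_overall=overall,
        completeness_by_taxon=per_taxon,
    )


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs, with study defaults."""

    seed: int = 0
    filter_params: FilterParams = field(default_factory=FilterParams)
    evalue_cutoff: float = 1e-5
    quartile: float = 0.25
    mode: str = "consensus"  # or "representative"
    reference_taxon: str | None = None
    rbh: bool = True
    strict: bool = True
    collapse_threshold: float | None = None
    min_taxa: int = 4
    degen: bool = True
    occupancy_after_degen: bool = True
    bootstrap_replicates: int = 1000  # for the exported external-ML settings
    search_replicates: int = 5

    def __post_init__(self) -> None:
        if self.mode not in ("consensus", "representative"):
            raise InvalidParameterError(f"unknown reduction mode {self.mode!r}")
        if self.min_taxa < 1:
            raise InvalidParameterError("min_taxa must be >= 1")


@dataclass
class PipelineInputs:
    """Stage inputs: assemblies plus the orthology-search hit assignment.

    ``hit_gene`` maps transcript id to the orthologous group it matched —
    the hit table an upstream profile-HMM/BLAST search would produce (the
    search itself is out of scope).  Reads are optional; when present they
    only feed the QC report and the coverage statistic.
    """

    transcripts: dict[str, list[Transcript]]
    reference_taxon: str
    reads: dict[str, list] | None = None
    read_length: int | None = None
    true_tree: dendropy.Tree | None = None

    @classmethod
    def from_simulation(
        cls,
        artifacts: SequencingArtifacts,
        reference_taxon: str | None = None,
        true_tree: dendropy.Tree | None = None,
        read_length: int | None = None,
    ) -> "PipelineInputs":
        taxa = sorted(artifacts.transcripts)
        return cls(
            transcripts=artifacts.transcripts,
            reference_taxon=reference_taxon or taxa[0],
            reads=artifacts.reads,
            read_length=read_length,
            true_tree=true_tree,
        )


@dataclass
class PipelineResult:
    supermatrix: SuperMatrix
    tree: dendropy.Tree | None
    report: dict
    prune_results: list[PruneResult]
    gene_alignments: dict[str, CodonAlignment]
    assembly: AssemblyMetrics | None
    coverage: CoverageStat | None


def _translate(cds: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(cds[: len(cds) - len(cds) % 3]).translate())


def _kmer_index(proteins: Mapping[str, str], k: int = 5) -> dict[str, set[str]]:
    index: dict[str, set[str]] = {}
    for gene, prot in proteins.items():
        for i in range(len(prot) - k + 1):
            index.setdefault(prot[i : i + k], set()).add(gene)
    return index


def _rbh_pass(
    hit: OrthologHit,
    proteome: Mapping[str, str],
    index: Mapping[str, set[str]],
    scorer: Blosum62Scorer,
    k: int = 5,
    top: int = 3,
) -> bool:
    """Reciprocal-best check with a k-mer prescreen standing in for BLAST seeding."""
    votes: dict[str, int] = {}
    prot = hit.protein
    for i in range(len(prot) - k + 1):
        for gene in index.get(prot[i : i + k], ()):
            votes[gene] = votes.get(gene, 0) + 1
    candidates = sorted(votes, key=lambda g: (-votes[g], g))[:top]
    if hit.gene_id not in candidates and hit.gene_id in proteome:
        candidates.append(hit.gene_id)
    if not candidates:
        return False
    best_gene, best_score = None, -np.inf
    for gene in sorted(candidates):
        s = scorer(prot, proteome[gene])
        if s > best_score:
            best_gene, best_score = gene, s
    return best_gene == hit.gene_id


def run_pipeline(
    config: PipelineConfig, inputs: PipelineInputs, outdir: str | Path | None = None
) -> PipelineResult:
    """Execute QC -> orthology reduction -> paralogy filter -> recode -> supermatrix.

    The report carries the gene accounting at each stage (genes in, clean,
    flagged, kept) and, when a true species tree is provided, the
    Robinson-Foulds distance of the final NJ tree to it.
    """
    report: dict = {}
    taxa = sorted(inputs.transcripts)
    scorer = Blosum62Scorer()

    # --- read QC -----------------------------------------------------------
    assembly = None
    coverage = None
    if inputs.reads is not None:
        try:
            kept_total = discarded_total = 0
            for taxon in taxa:
                kept, discarded = phred_filter(inputs.reads.get(taxon, []), config.filter_params)
                kept_total += len(kept)
                discarded_total += discarded
            report["reads_in"] = kept_total + discarded_total
            report["reads_kept"] = kept_total
            report["reads_discarded"] = discarded_total
        except Exception as exc:  # pragma: no cover - defensive
            raise PipelineStageError("read-qc", "all taxa", exc)
    all_transcripts = [tr for t in taxa for tr in inputs.transcripts[t]]
    if all_transcripts:
        assembly = assembly_metrics(ContigSet([len(tr.seq) for tr in all_transcripts]))
        report["transcripts"] = assembly.count
        report["assembly_n50"] = assembly.n50
    if inputs.reads is not None and inputs.read_length:
        n_reads_by_tr: dict[str, int] = {}
        for taxon in taxa:
            for read in inputs.reads.get(taxon, []):
                tr_id = read.id.rsplit(":", 2)[0]
                n_reads_by_tr[tr_id] = n_reads_by_tr.get(tr_id, 0) + 1
        counts = [n_reads_by_tr.get(tr.id, 0) for tr in all_transcripts]
        coverage = coverage_per_base(
            inputs.read_length, counts, [len(tr.seq) for tr in all_transcripts]
        )
        report["coverage_per_base"] = coverage.coverage

    # --- reference proteome ------------------------------------------------
    ref = inputs.reference_taxon
    if ref not in inputs.transcripts:
        raise InvalidInputError(f"reference taxon {ref!r} has no transcripts")
    ref_best: dict[str, Transcript] = {}
    for tr in inputs.transcripts[ref]:
        cur = ref_best.get(tr.gene_id)
        if cur is None or (len(tr.seq), cur.id) > (len(cur.seq), tr.id):
            ref_best[tr.gene_id] = tr
    proteome = {g: _translate(tr.seq) for g, tr in ref_best.items()}
    kmer_index = _kmer_index(proteome)

    # --- orthology: hits, filters, anchored alignments ---------------------
    genes = sorted({tr.gene_id for t in taxa for tr in inputs.transcripts[t]} & set(proteome))
    report["genes_in"] = len(genes)
    gene_rows: dict[str, dict[str, str]] = {}
    gene_hits: dict[str, OrthologGroup] = {}
    rbh_dropped = 0
    for gene in genes:
        try:
            ref_prot = proteome[gene]
            hits_by_taxon: dict[str, list[OrthologHit]] = {}
            for taxon in taxa:
                for tr in inputs.transcripts[taxon]:
                    if tr.gene_id != gene:
                        continue
                    cds = tr.seq[: len(tr.seq) - len(tr.seq) % 3]
                    prot = _translate(cds)
                    if "*" in prot:
                        continue
                    score = scorer(prot, ref_prot)
                    evalue = len(prot) * len(ref_prot) * 2.0 ** (-max(score, 0.0))
                    hits_by_taxon.setdefault(taxon, []).append(
                        OrthologHit(
                            gene_id=gene, taxon=taxon, seq_id=tr.id,
                            protein=prot, cds=cds, score=score, evalue=evalue,
                        )
                    )
            group = filter_hits(
                OrthologGroup(gene_id=gene, hits=hits_by_taxon, reference_taxon=ref),
                config.evalue_cutoff,
                config.quartile,
            )
            if config.rbh:
                screened: dict[str, list[OrthologHit]] = {}
                for taxon, hits in group.hits.items():
                    keep = [h for h in hits if _rbh_pass(h, proteome, kmer_index, scorer)]
                    rbh_dropped += len(hits) - len(keep)
                    screened[taxon] = keep
                group = OrthologGroup(gene_id=gene, hits=screened, reference_taxon=ref)
            gene_hits[gene] = group
            retained = [h for hits in group.hits.values() for h in hits]
            if not retained:
                continue
            aln = anchor_alignment(retained, ref_prot, ref_best[gene].seq, scorer, gene_id=gene)
            rows = {
                f"{h.taxon}|{h.seq_id}": aln.rows[h.seq_id] for h in retained
            }
            gene_rows[gene] = rows
        except Exception as exc:
            raise PipelineStageError("orthology", f"gene {gene}", exc)
    report["rbh_dropped_hits"] = rbh_dropped

    # --- gene trees and the paralogy screen --------------------------------
    prune_results: list[PruneResult] = []
    for gene in genes:
        rows = gene_rows.get(gene)
        if rows is None:
            continue
        try:
            if len(rows) < 3:
                prune_results.append(
                    PruneResult(gene_id=gene, retained_leaves={tuple(k.split("|", 1)) for k in rows},
                                removed_leaves=set(), is_clean=True)
                )
                continue
            tree = estimate_gene_tree(rows)
            prune_results.append(
                prune_paralogs(tree, config.collapse_threshold, gene_id=gene)
            )
        except Exception as exc:
            raise PipelineStageError("paralogy-screen", f"gene {gene}", exc)
    clean, flagged = strict_gene_filter(prune_results)
    report["genes_screened"] = len(prune_results)
    report["genes_clean"] = len(clean)
    report["genes_flagged"] = len(flagged)
    kept_genes = clean if config.strict else [r.gene_id for r in prune_results]
    retained_by_gene = {r.gene_id: r.retained_leaves for r in prune_results}
    report["genes_kept"] = len(kept_genes)

    # --- reduction to one row per taxon ------------------------------------
    reduced: dict[str, CodonAlignment] = {}
    for gene in kept_genes:
        rows = gene_rows[gene]
        try:
            retained_leaves = retained_by_gene[gene]
            per_taxon: dict[str, list[str]] = {}
            for key, row in rows.items():
                taxon, seq_id = key.split("|", 1)
                if (taxon, seq_id) not in retained_leaves:
                    continue
                per_taxon.setdefault(taxon, []).append(row)
            ref_row = ref_best[gene].seq  # ungapped, full reference frame
            out_rows: dict[str, str] = {}
            for taxon in sorted(per_taxon):
                cand = sorted(per_taxon[taxon])
                if config.mode == "consensus":
                    out_rows[taxon] = build_consensus(cand)
                else:
                    out_rows[taxon] = choose_representative(cand, ref_row)
            if out_rows:
                reduced[gene] = CodonAlignment(gene_id=gene, rows=out_rows)
        except Exception as exc:
            raise PipelineStageError("reduction", f"gene {gene}", exc)

    # --- recode, concatenate, occupancy filter -----------------------------
    alignments = list(reduced.values())
    if config.degen:
        try:
            alignments = [degen_alignment(a) for a in alignments]
        except Exception as exc:
            raise PipelineStageError("degen-recoding", "matrix", exc)
    matrix = concatenate_supermatrix(alignments, taxa)
    report["matrix_sites_before_occupancy"] = matrix.length
    matrix = occupancy_filter(matrix, config.min_taxa)
    report["matrix_sites"] = matrix.length
    mreport = matrix_report(matrix)
    report["completeness_overall"] = mreport.completeness_overall

    # --- final tree --------------------------------------------------------
    tree = None
    occupied = {t: r for t, r in matrix.rows.items() if set(r) - _MISSING}
    if len(occupied) >= 3 and matrix.length > 0:
        tree = nj_tree(occupied)
        if inputs.true_tree is not None:
            try:
                report["rf_to_true_tree"] = rf_distance(tree, inputs.true_tree)
            except InvalidInputError:
                report["rf_to_true_tree"] = None

    if outdir is not None:
        export_supermatrix(matrix, config, Path(outdir), tree=tree, report=report)
    return PipelineResult(
        supermatrix=matrix,
        tree=tree,
        report=report,
        prune_results=prune_results,
        gene_alignments=reduced,
        assembly=assembly,
        coverage=coverage,
    )


def write_phylip(matrix: SuperMatrix, path: Path) -> None:
    """Relaxed PHYLIP: names and sequences separated by whitespace."""
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.rows)} {matrix.length}\n")
        for taxon in sorted(matrix.rows):
            fh.write(f"{taxon}  {matrix.rows[taxon]}\n")


def write_fasta(matrix: SuperMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        for taxon in sorted(matrix.rows):
            fh.write(f">{taxon}\n{matrix.rows[taxon]}\n")


def write_partitions(matrix: SuperMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        for gene, start, end in matrix.partitions:
            fh.write(f"DNA, {gene} = {start}-{end}\n")


def export_supermatrix(
    matrix: SuperMatrix,
    config: PipelineConfig,
    outdir: Path,
    tree: dendropy.Tree | None = None,
    report: dict | None = None,
) -> None:
    """Write the external-ML export bundle (matrix, partitions, settings note)."""
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(matrix, outdir / "supermatrix.fasta")
    write_phylip(matrix, outdir / "supermatrix.phy")
    write_partitions(matrix, outdir / "partitions.txt")
    settings = (
        "# Intended external maximum-likelihood analysis settings\n"
        "# model = GTR+I+G\n"
        f"# bootstrap_replicates = {config.bootstrap_replicates}\n"
        f"# search_replicates_per_bootstrap = {config.search_replicates}\n"
        "# starting_trees = random stepwise addition\n"
    )
    (outdir / "ml_settings.txt").write_text(settings)
    if tree is not None:
        (outdir / "nj_tree.nwk").write_text(
            tree.as_string(schema="newick", unquoted_underscores=True)
        )
    if report is not None:
        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
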