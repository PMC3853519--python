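#!/usr/bin/env python
"""Read quality control and assembly summary for the clean dataset.

Applies the Phred filter (discard a read when quality <= 20 at > 90% of
positions), summarizes the transcript set with standard assembly metrics
(count, median length, total bases, N50), lists the multi-k assembly sweep
(k = 52..96 step 2, i.e. 23 runs per sample), and computes coverage per base
as read length x median mapped reads / median sequence length.
"""

import json
from pathlib import Path

from orthomatrix.matrixkit import coverage_per_base
from orthomatrix.readqc import ContigSet, FilterParams, KmerSweep, assembly_metrics, kmer_grid, phred_filter
from orthomatrix.simdata import emit_sequencing_artifacts, simulate_gene_families, simulate_species_tree

import importlib.util

ROOT = Path(__file__).resolve().parent.parent
spec = importlib.util.spec_from_file_location("sim01", ROOT / "analysis" / "01_simulate.py")
sim01 = importlib.util.module_from_spec(spec)
spec.loader.exec_module(sim01)


def main() -> None:
    cfg = sim01.CLEAN
    tree = simulate_species_tree(cfg.n_taxa, cfg.seed, cfg.birth_rate, cfg.tree_height)
    families = simulate_gene_families(tree, cfg)
    artifacts = emit_sequencing_artifacts(families, cfg)

    kept_total = discarded_total = 0
    for taxon in sorted(artifacts.reads):
        kept, discarded = phred_filter(artifacts.reads[taxon], FilterParams())
        kept_total += len(kept)
        discarded_total += discarded

    lengths = [len(tr.seq) for trs in artifacts.transcripts.values() for tr in trs]
    metrics = assembly_metrics(ContigSet(lengths))
    counts = list(artifacts.reads_per_transcript_id.values())
    cov = coverage_per_base(cfg.read_length, counts, lengths)

    summary = {
        "reads_in": kept_total + discarded_total,
        "reads_kept": kept_total,
        "reads_discarded": discarded_total,
        "discard_fraction": discarded_total / max(1, kept_total + discarded_total),
        "transcripts": metrics.count,
        "median_transcript_length": metrics.median_length,
        "total_bases": metrics.total_bases,
        "n50": metrics.n50,
        "kmer_sweep": kmer_grid(KmerSweep(52, 96, 2)),
        "coverage_per_base": cov.coverage,
    }
    out = ROOT / "results" / "02_read_qc.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps(summary, indent=2) + "\n")
    print(f"kept {kept_total}/{kept_total + discarded_total} reads; "
          f"N50 {metrics.n50} over {metrics.count} transcripts; "
          f"{len(summary['kmer_sweep'])} k-mer sweep runs; "
          f"coverage {cov.coverage:.1f}x")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
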