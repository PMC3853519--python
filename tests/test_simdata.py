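import filecmp

import numpy as np
import pytest
from Bio.Seq import Seq

from orthomatrix.errors import InvalidParameterError
from orthomatrix.simdata import (
    SimulationConfig,
    emit_sequencing_artifacts,
    simulate_gene_families,
    simulate_species_tree,
    write_dataset,
)


class TestSpeciesTree:
    def test_two_taxa_minimal_tree(self):
        tree = simulate_species_tree(2, seed=0)
        assert sum(1 for _ in tree.leaf_node_iter()) == 2

    def test_seed_determinism(self):
        t1 = simulate_species_tree(8, seed=7).as_string(schema="newick")
        t2 = simulate_species_tree(8, seed=7).as_string(schema="newick")
        assert t1 == t2

    def test_one_root_path_per_leaf(self):
        tree = simulate_species_tree(8, seed=7)
        paths = 0
        for leaf in tree.leaf_node_iter():
            node = leaf
            while node.parent_node is not None:
                node = node.parent_node
            assert node is tree.seed_node
            paths += 1
        assert paths == 8

    def test_height_rescaled(self):
        tree = simulate_species_tree(10, seed=3, tree_height=0.4)
        depths = [sum(e.length for e in _path(l)) for l in tree.leaf_node_iter()]
        assert max(depths) == pytest.approx(0.4)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_species_tree(1, seed=0)


def _path(leaf):
    node = leaf
    while node.parent_node is not None:
        yield node.edge
        node = node.parent_node


class TestGeneFamilies:
    def test_no_duplications_all_clean(self, small_simulation):
        _, _, families, _ = small_simulation
        assert all(f.truth.is_clean for f in families)

    def test_truth_records_realized_duplications(self):
        cfg = SimulationConfig(seed=5, n_taxa=10, n_genes=40, gene_length_codons=30,
                               dup_probability=0.2)
        tree = simulate_species_tree(cfg.n_taxa, cfg.seed)
        families = simulate_gene_families(tree, cfg)
        n_dirty = sum(1 for f in families if not f.truth.is_clean)
        n_events = sum(len(f.truth.duplication_events) for f in families)
        assert n_dirty == n_events  # one planted event per non-clean gene
        assert 0 < n_dirty < 40

    def test_one_sequence_per_taxon_per_gene_when_rates_zero(self):
        cfg = SimulationConfig(seed=9, n_taxa=10, n_genes=50, gene_length_codons=20,
                               dup_probability=0.0, isoform_rate=0.0,
                               allele_rate=0.0, fragment_rate=0.0)
        tree = simulate_species_tree(cfg.n_taxa, cfg.seed)
        families = simulate_gene_families(tree, cfg)
        artifacts = emit_sequencing_artifacts(families, cfg)
        # brute-force count over the emitted per-taxon records
        for taxon, trs in artifacts.transcripts.items():
            per_gene = {}
            for tr in trs:
                per_gene[tr.gene_id] = per_gene.get(tr.gene_id, 0) + 1
            assert set(per_gene.values()) == {1} and len(per_gene) == 50

    def test_no_internal_stop_codons(self, small_simulation):
        _, _, families, _ = small_simulation
        for fam in families:
            for seqs in fam.cds_by_taxon.values():
                for _, cds in seqs:
                    assert "*" not in str(Seq(cds).translate())

    def test_truth_labels_partition_all_sequences(self, small_simulation):
        _, _, families, _ = small_simulation
        for fam in families:
            emitted = {
                f"{taxon}|{sid}"
                for taxon, seqs in fam.cds_by_taxon.items()
                for sid, _ in seqs
            }
            assert emitted == set(fam.truth.per_sequence_labels)

    def test_synonymous_exceed_nonsynonymous_in_substitution_log(self, small_simulation):
        # with a 5x synonymous multiplier the simulator's own event log must
        # show more synonymous than nonsynonymous accepted substitutions
        _, _, families, _ = small_simulation
        syn = sum(f.truth.syn_events for f in families)
        nonsyn = sum(f.truth.nonsyn_events for f in families)
        assert syn > nonsyn > 0

    def test_duplicated_taxa_get_two_labeled_copies(self):
        cfg = SimulationConfig(seed=5, n_taxa=8, n_genes=20, gene_length_codons=30,
                               dup_probability=1.0, dup_min_taxa=3)
        tree = simulate_species_tree(cfg.n_taxa, cfg.seed)
        families = simulate_gene_families(tree, cfg)
        for fam in families:
            assert not fam.truth.is_clean
            statuses = {s for _, s in fam.truth.per_sequence_labels.values()}
            assert statuses == {"ortholog", "paralog"}
            dup_taxa = {t for t, s in fam.truth.per_sequence_labels.values() if s == "paralog"}
            assert len(dup_taxa) >= 3

    def test_zero_length_rejected(self):
        with pytest.raises(InvalidParameterError):
            SimulationConfig(seed=0, gene_length_codons=0)


class TestSequencingArtifacts:
    def test_error_free_reads_are_exact_substrings(self):
        cfg = SimulationConfig(seed=3, n_taxa=4, n_genes=5, gene_length_codons=50,
                               read_error_rate=0.0, reads_per_transcript=5)
        tree = simulate_species_tree(cfg.n_taxa, cfg.seed)
        families = simulate_gene_families(tree, cfg)
        artifacts = emit_sequencing_artifacts(families, cfg)
        by_id = {tr.id: tr.seq for trs in artifacts.transcripts.values() for tr in trs}
        for reads in artifacts.reads.values():
            for read in reads:
                assert read.bases in by_id[read.id.rsplit(":", 2)[0]]

    def test_quality_profile_mean(self):
        cfg = SimulationConfig(seed=3, n_taxa=4, n_genes=5, gene_length_codons=50,
                               quality_mean=35.0, quality_sd=4.0, reads_per_transcript=5)
        tree = simulate_species_tree(cfg.n_taxa, cfg.seed)
        families = simulate_gene_families(tree, cfg)
        artifacts = emit_sequencing_artifacts(families, cfg)
        quals = [q for reads in artifacts.reads.values() for r in reads for q in r.quals]
        assert len(quals) > 10_000
        assert abs(float(np.mean(quals)) - 35.0) < 3 * 4.0  # within 3 sd of the profile
        assert min(quals) >= 2 and max(quals) <= 41

    def test_byte_identical_outputs_under_fixed_seed(self, tmp_path):
        cfg = SimulationConfig(seed=21, n_taxa=4, n_genes=3, gene_length_codons=40,
                               reads_per_transcript=2)
        for sub in ("a", "b"):
            tree = simulate_species_tree(cfg.n_taxa, cfg.seed)
            families = simulate_gene_families(tree, cfg)
            artifacts = emit_sequencing_artifacts(families, cfg)
            write_dataset(tree, families, artifacts, tmp_path / sub)
        names = [p.name for p in (tmp_path / "a").iterdir()]
        match, mismatch, errors = filecmp.cmpfiles(tmp_path / "a", tmp_path / "b", names, shallow=False)
        assert sorted(match) == sorted(names) and not mismatch and not errors

    def test_short_transcripts_emit_fragment_reads(self):
        cfg = SimulationConfig(seed=3, n_taxa=4, n_genes=2, gene_length_codons=20,
                               read_length=100, reads_per_transcript=2)
        tree = simulate_species_tree(cfg.n_taxa, cfg.seed)
        families = simulate_gene_families(tree, cfg)
        artifacts = emit_sequencing_artifacts(families, cfg)
        assert all(len(r.bases) <= 60 for reads in artifacts.reads.values() for r in reads)
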