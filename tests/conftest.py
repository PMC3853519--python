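import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_simulation():
    """8-taxon, 10-gene clean simulated dataset shared across tests."""
    from orthomatrix import simdata

    cfg = simdata.SimulationConfig(
        seed=11, n_taxa=8, n_genes=10, gene_length_codons=100, reads_per_transcript=3
    )
    tree = simdata.simulate_species_tree(cfg.n_taxa, cfg.seed, cfg.birth_rate, cfg.tree_height)
    families = simdata.simulate_gene_families(tree, cfg)
    artifacts = simdata.emit_sequencing_artifacts(families, cfg)
    return cfg, tree, families, artifacts
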