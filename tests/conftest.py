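import pytest

from msgnoise import GeneratorConfig, generate_gene_table, load_organism


@pytest.fixture(scope="session")
def organisms():
    """Bundled constants for the four reference conditions."""
    return {name: load_organism(name) for name in ("ecoli_lb", "ecoli_m9", "yeast", "human")}


@pytest.fixture(scope="session")
def yeast_table(organisms):
    """A default yeast-like synthetic gene table with its ground truth."""
    cfg = GeneratorConfig(seed=42)
    records, truth = generate_gene_table(cfg, organisms["yeast"])
    return cfg, records, truth
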