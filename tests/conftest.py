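import pytest

from lncturnover.synthetic import ExpressionConfig, ScenarioConfig, generate_scenario


def tiny_config(seed: int = 0, **overrides) -> ScenarioConfig:
    """Small, fast scenario: one 400-kb chromosome pair worth of features."""
    defaults = dict(
        seed=seed,
        chrom_lengths={"chr1": 400_000, "chr2": 250_000},
        n_protein_coding=40,
        n_lncRNA_per_category={"I": 2, "II": 2, "III": 2, "IV": 2, "V": 2},
        read_depth_per_species={"mus": 4000, "cas": 2500, "rat": 3500},
        n_ARs=20,
        n_housekeeping=8,
        n_paralog_pairs=3,
        n_lineage_pc=4,
        n_indel_purified=10,
        expression=ExpressionConfig(),
    )
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_bundle():
    return generate_scenario(tiny_config(seed=0))


@pytest.fixture(scope="session")
def default_bundle():
    """The default study scenario: 3 species, 50 lncRNA loci across the five
    conservation categories, 300 protein-coding genes."""
    return generate_scenario(ScenarioConfig(seed=1))
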