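import pandas as pd
import pytest

from memsig.bsio import SampleManifest
from memsig.synthdata import SyntheticConfig, build_toy_genome, simulate_generations


def five_vs_five_manifest() -> SampleManifest:
    rows = [(f"C{i}", "control", 1, "WT") for i in range(5)] + [
        (f"T{i}", "treatment", 1, "MM") for i in range(5)
    ]
    return SampleManifest(
        pd.DataFrame(rows, columns=["sample_id", "group", "generation", "phenotype"])
    )


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig(seed=0)


@pytest.fixture(scope="session")
def toy_annotation(default_config):
    return build_toy_genome(default_config)


@pytest.fixture(scope="session")
def study(default_config, toy_annotation):
    """One full six-generation study at the default conditions."""
    return simulate_generations(toy_annotation, default_config)


@pytest.fixture(scope="session")
def gen1_call(study):
    """Signal-detection DMP call for the generation-1 WT vs memory contrast."""
    from memsig.dmpcall import call_dmp_pipeline

    manifest, tables = study.comparison(1, "WT", "MM")
    return manifest, call_dmp_pipeline(tables, manifest)
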