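import pytest

from intronseek.pipeline import run_pipeline
from intronseek.simulate import GeneratorConfig, generate_dataset


def small_config(seed: int, **overrides) -> GeneratorConfig:
    """A scaled-down study used for repeated-seed tests."""
    defaults = dict(
        seed=seed, n_datasets=4, n_genes=15, n_true_short=60,
        n_artifacts_per_class=6, n_long_unannotated=12,
        n_single_dataset=60, n_noise_per_replicate=80,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size synthetic study (the default generator conditions)."""
    return generate_dataset(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_result(default_dataset):
    ds = default_dataset
    return run_pipeline(ds.junctions, ds.genome, ds.annotation, ds.coverage)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_config(seed=7))
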