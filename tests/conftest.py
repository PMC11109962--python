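import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from notchdyn import GeneratorConfig, generate  # noqa: E402


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete synthetic bundle with materialized reads."""
    cfg = GeneratorConfig(
        seed=7,
        n_chroms=2,
        chrom_length=4_000_000,
        n_genes=300,
        n_sites=400,
        emit_reads=True,
    )
    return generate(cfg)


def tiny_config(seed: int, **overrides) -> GeneratorConfig:
    """Config for throwaway bundles in property loops."""
    base = dict(
        seed=seed,
        n_chroms=1,
        chrom_length=2_500_000,
        n_genes=150,
        n_sites=250,
    )
    base.update(overrides)
    return GeneratorConfig(**base)
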