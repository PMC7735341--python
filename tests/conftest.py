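import pytest

from songculture import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def default_corpus():
    """The shipped two-lineage scenario at its default noise, seed 1."""
    return generate_corpus(GeneratorConfig.default(seed=1))


@pytest.fixture(scope="session")
def clean_corpus():
    """Same scenario with transcription noise and theme drop switched off."""
    cfg = GeneratorConfig.default(seed=1)
    cfg.noise_sub = cfg.noise_del = cfg.noise_ins = 0.0
    cfg.theme_drop = 0.0
    return generate_corpus(cfg)
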