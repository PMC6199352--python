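import numpy as np
import pytest

from scarnascan.promoter import load_default_model
from scarnascan.synthetic import ArchitectureSpec, generate_locus


@pytest.fixture(scope="session")
def model():
    return load_default_model()


@pytest.fixture(scope="session")
def make_locus(model):
    """Factory for seeded synthetic loci: make_locus(template, seed, **kw)."""

    def _make(template: str, seed: int, **kwargs):
        spec = ArchitectureSpec(template=template, seed=seed, **kwargs)
        return generate_locus(spec, model, rng=np.random.default_rng(seed))

    return _make


@pytest.fixture(scope="session")
def iib_locus(make_locus):
    """One Type IIB-architecture locus with its ground truth."""
    return make_locus("IIB_fnovicida_like", 11)


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.4) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
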