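import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from photoredox.ml_e00 import ChromophoreEntry, build_targets
from photoredox.synthetic import SyntheticSpec, gen_chromophores


@pytest.fixture(scope="session")
def small_corpus():
    """A 400-molecule noiseless chromophore corpus with its planted rule."""
    spec = SyntheticSpec(chromophore_counts={"MeCN": 400}, seed=17)
    corpus, truth = gen_chromophores(spec)
    entries = build_targets([
        ChromophoreEntry(r.smiles, r.solvent, r.lambda_abs_nm, r.lambda_em_nm)
        for r in corpus.itertuples(index=False)
    ])
    return entries, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
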