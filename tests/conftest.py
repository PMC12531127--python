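import numpy as np
import pytest
from hypothesis import settings

from tpdiverge import CladeSpec, generate_clade

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


_CACHE: dict = {}


@pytest.fixture
def make_clade():
    """Factory for small synthetic clades, cached by parameters."""

    def _make(
        n_species=4,
        mito=5,
        plastid=5,
        dual=3,
        separation_delta=3.0,
        mutation_rate=0.0,
        seed=101,
    ):
        key = (n_species, mito, plastid, dual, separation_delta,
               mutation_rate, seed)
        if key not in _CACHE:
            spec = CladeSpec(
                clade_name="toy",
                n_species=n_species,
                n_families_per_organelle={
                    "mito": mito, "plastid": plastid, "dual": dual
                },
                separation_delta=separation_delta,
                mutation_rate=mutation_rate,
                seed=seed,
            )
            _CACHE[key] = generate_clade(spec)
        return _CACHE[key]

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
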