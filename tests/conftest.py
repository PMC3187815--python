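import numpy as np
import pytest

from dggetax import (
    CloneLibrarySpec,
    TaxonomySpec,
    make_clone_library,
    make_reference_db,
)


@pytest.fixture(scope="session")
def reference_db():
    """Default synthetic reference database (48 references, 24 genera)."""
    db, truth = make_reference_db(TaxonomySpec(seed=11))
    return db, truth


@pytest.fixture(scope="session")
def small_clone_library(reference_db):
    """20 clones at 1% substitution from the session reference database."""
    db, _ = reference_db
    clones, truth = make_clone_library(
        CloneLibrarySpec(n_clones=20, mutation_rate=0.01, seed=12), db
    )
    return clones, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
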