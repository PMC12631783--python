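import numpy as np
import pytest

from cathsf import SyntheticSpec, gen_embedding_dataset, gen_structure_set


@pytest.fixture(scope="session")
def structure_set(tmp_path_factory):
    """Ten synthetic predicted-model structures, two withheld."""
    out = tmp_path_factory.mktemp("pdb")
    spec = SyntheticSpec(seed=7, n_domains=10, withhold_fraction=0.2)
    return spec, gen_structure_set(spec, str(out))


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 10-class balanced embedding dataset with both channels."""
    path = tmp_path_factory.mktemp("store") / "emb.h5"
    spec = SyntheticSpec(seed=1, n_classes=10, train_support=20,
                         n_val_per_class=3, n_test_per_class=3,
                         dim_aa=8, dim_tdi=8)
    bundle, store, info = gen_embedding_dataset(spec, str(path))
    yield spec, bundle, store, info
    store.close()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
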