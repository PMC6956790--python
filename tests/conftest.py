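import numpy as np
import pytest

import mitoloc as ml


@pytest.fixture(scope="session")
def small_dataset():
    """Small synthetic benchmark: 6 proteins/class, verbatim motifs, 4 dup pairs."""
    spec = ml.SyntheticSpec(n_per_class=6, n_duplicates=4, seed=7)
    return ml.generate(spec)


@pytest.fixture(scope="session")
def small_dataset_dir(small_dataset, tmp_path_factory):
    """The same benchmark written to disk (FASTA, PSSMs, labels, hit list)."""
    outdir = tmp_path_factory.mktemp("synthdata")
    paths = ml.write_dataset(small_dataset, outdir)
    return paths


@pytest.fixture
def tiny_model():
    """A small seeded model over one-hot features."""
    hp = ml.Hyperparameters(F=4, w=3, H=5, seed=11)
    return ml.CNNModel.initialize(hp, d=20, feature_set="SEQ")


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
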