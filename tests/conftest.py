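import numpy as np
import pytest

from pathwaykit import Protein, UniverseConfig, build_registry, generate_universe


@pytest.fixture(scope="session")
def registry():
    return build_registry()


@pytest.fixture(scope="session")
def small_cfg():
    return UniverseConfig(
        n_proteins=40,
        annotation_dim=60,
        annotation_density=0.05,
        seq_len_range=(20, 40),
        n_positive=6,
        pathway_size_range=(3, 8),
        similarity_bias=2.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_universe(small_cfg):
    return generate_universe(small_cfg)


def make_protein(pid, hits, dim=10, seq="ACDEF", ss=None, acc=None):
    ann = np.zeros(dim, dtype=np.uint8)
    ann[list(hits)] = 1
    ss = ss or "H" * len(seq)
    acc = acc or "E" * len(seq)
    return Protein(id=pid, annotation=ann, sequence=seq, ss_string=ss, acc_string=acc)
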