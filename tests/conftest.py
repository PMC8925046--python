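import numpy as np
import pytest

import microrank as mr


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_dataset():
    """Hand-written 4 microbes x 3 diseases network."""
    matrix = np.array(
        [
            [1, 0, 1],
            [1, 1, 0],
            [0, 1, 0],
            [1, 0, 0],
        ]
    )
    return mr.AssociationDataset(
        ["m1", "m2", "m3", "m4"], ["d1", "d2", "d3"], matrix
    )


@pytest.fixture(scope="session")
def planted_world():
    """Small planted-block study reused by the heavier tests."""
    spec = mr.SyntheticSpec(nm=30, nd=8, seed=7)
    data, microbe_blocks, disease_blocks = mr.make_network(spec)
    seqs = mr.make_sequences(spec, microbe_blocks)
    codes = mr.make_disease_dag(spec, disease_blocks=disease_blocks)
    return spec, data, microbe_blocks, disease_blocks, seqs, codes


@pytest.fixture(scope="session")
def planted_similarities(planted_world):
    spec, data, mb, db, seqs, codes = planted_world
    block = mr.AlignedBlock(
        sorted(seqs.records), [seqs.records[n] for n in sorted(seqs.records)]
    )
    mss, mes, sm = mr.build_microbe_similarity(
        seqs, data.microbe_names, msa=block
    )
    sd = mr.disease_similarity_from_codes(codes, data.disease_names)
    return sd, sm
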