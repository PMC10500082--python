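import numpy as np
import pytest

from oligocodec import construct_code, scaled_config
from oligocodec.channel import ChannelParams, Read
from oligocodec.encoder import encode_file


@pytest.fixture(scope="session")
def toy_code():
    """Small (16, 8) code for exhaustive-ML comparisons."""
    return construct_code(16, 8, column_weight=2, seed=3)


@pytest.fixture(scope="session")
def small_cfg():
    """Tiny pool layout for fast unit round trips: 48 oligos of 26 nt."""
    return scaled_config(48, 36, 10, column_weight=2, ldpc_seed=5)


@pytest.fixture(scope="session")
def small_code(small_cfg):
    return construct_code(
        small_cfg.total_oligos,
        small_cfg.payload_oligos,
        small_cfg.column_weight,
        seed=small_cfg.ldpc_seed,
    )


@pytest.fixture(scope="session")
def small_pool(small_cfg, small_code):
    data = np.random.default_rng(77).integers(0, 256, 60, np.uint8).tobytes()
    records, meta = encode_file(data, small_cfg, code=small_code)
    return data, records, meta


def clean_read(oligo_seq: str, q: int = 38, source: int = -1) -> Read:
    return Read(oligo_seq, np.full(len(oligo_seq), q, dtype=np.int16), source)


@pytest.fixture
def make_read():
    return clean_read


@pytest.fixture(scope="session")
def default_channel():
    return ChannelParams()
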