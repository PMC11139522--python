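import numpy as np
import pytest

from qscodec.qsd_io import QsdBlock, QualityRecord


def random_block(rng: np.random.Generator, m: int, L: int,
                 alphabet: int = 94, variable: bool = False) -> QsdBlock:
    """A small uniformly-random block for roundtrip tests."""
    records = []
    for i in range(m):
        n = int(rng.integers(0, L + 1)) if variable else L
        records.append(QualityRecord(
            symbols=rng.integers(0, alphabet, n).tolist(), index=i))
    return QsdBlock(records=records)


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)
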