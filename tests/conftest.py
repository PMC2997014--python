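import numpy as np
import pytest

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def rand_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)].tobytes().decode("ascii")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
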