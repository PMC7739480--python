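import numpy as np
import pytest

from dracp import PeptideRecord, SyntheticSpec, generate_synthetic


@pytest.fixture(scope="session")
def synthetic_records() -> list[PeptideRecord]:
    """Default 150/150 synthetic set with the planted hydropathy signal."""
    return generate_synthetic(SyntheticSpec(seed=42))


@pytest.fixture(scope="session")
def small_records() -> list[PeptideRecord]:
    """A small 30/30 set for fast pipeline tests."""
    return generate_synthetic(SyntheticSpec(n_pos=30, n_neg=30, seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_peptide(rng: np.random.Generator, min_len: int = 2, max_len: int = 60) -> str:
    from dracp.io import AMINO_ACIDS

    length = int(rng.integers(min_len, max_len + 1))
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))
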