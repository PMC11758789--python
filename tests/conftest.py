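import numpy as np
import pytest

from rnatorsion.angles import ANGLE_NAMES, AngleTable, N_ANGLES
from rnatorsion.model import ModelConfig, TorsionPredictor


def full_random_table(sequence: str, seed: int) -> AngleTable:
    """Angle table with every entry defined (no chain-end rules), uniform
    on (-180, 180]; used where tests need a fully defined table."""
    rng = np.random.default_rng(seed)
    L = len(sequence)
    values = rng.uniform(-180.0, 180.0, (L, N_ANGLES))
    return AngleTable(sequence=sequence, values=values)


def sparse_random_table(sequence: str, seed: int,
                        undefined_rate: float = 0.1) -> AngleTable:
    rng = np.random.default_rng(seed)
    L = len(sequence)
    values = rng.uniform(-180.0, 180.0, (L, N_ANGLES))
    values[rng.random((L, N_ANGLES)) < undefined_rate] = np.nan
    return AngleTable(sequence=sequence, values=values)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_model():
    """Small randomly initialized regressor shared across read-only tests."""
    return TorsionPredictor(ModelConfig(
        kmer_k=3, hidden_size=32, head_hidden=48,
        encoder_depth=1, encoder_heads=2, seed=11,
    ))
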