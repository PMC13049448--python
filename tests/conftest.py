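import sys
from pathlib import Path

import numpy as np
import pytest

# make tests/oracles.py importable regardless of invocation directory
sys.path.insert(0, str(Path(__file__).parent))

from ibdscan import GeneticMap, HaplotypePanel


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def uniform_map() -> GeneticMap:
    """1 cM per 10 kb over [1, 1000001]: 0.1 cM per 1 kb site spacing."""
    return GeneticMap(bp=np.array([1, 1_000_001]), cm=np.array([0.0, 100.0]))


def make_panel(alleles: np.ndarray, bp_per_site: int = 100) -> HaplotypePanel:
    alleles = np.asarray(alleles, dtype=np.int8)
    N, M = alleles.shape
    assert M % 2 == 0
    return HaplotypePanel(
        alleles=alleles,
        positions=1 + bp_per_site * np.arange(N, dtype=np.int64),
        sample_ids=[f"s{i:06d}" for i in range(M // 2)],
    )
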