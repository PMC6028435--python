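import numpy as np
import pandas as pd
import pytest

from degnet.simulate import SimulationConfig
from degnet.types import PairedExpressionSet, SamplePair


@pytest.fixture
def small_config():
    """A scaled-down simulation for fast unit tests (same structure as defaults)."""
    return SimulationConfig(
        seed=7, n_genes=800, planted_up=30, planted_down=20,
        n_tumor=20, n_normal=8, n_clinical_samples=150,
    )


def make_paired_rpkm(values: np.ndarray, n_pairs: int, genes=None) -> PairedExpressionSet:
    """Build a PairedExpressionSet from a (genes x 2*n_pairs) array laid out
    as [1ca, 1adj, 2ca, 2adj, ...]."""
    values = np.asarray(values, dtype=float)
    cols = [s for p in range(1, n_pairs + 1) for s in (f"{p}ca", f"{p}adj")]
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    pairs = [SamplePair(str(p), f"{p}ca", f"{p}adj") for p in range(1, n_pairs + 1)]
    return PairedExpressionSet(
        values=pd.DataFrame(values, index=genes, columns=cols),
        pairs=pairs, unit="rpkm",
    )


@pytest.fixture
def paired_builder():
    return make_paired_rpkm
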