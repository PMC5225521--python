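import numpy as np
import pandas as pd
import pytest

from chromreg.annotation import GeneModel, Transcript


@pytest.fixture
def two_tx_gene() -> GeneModel:
    """Plus-strand gene with two transcripts sharing a body, distinct TSSs."""
    t1 = Transcript("gA.t0", [(10_000, 10_400), (11_000, 11_500)], cds=(10_200, 11_200))
    t2 = Transcript("gA.t1", [(10_050, 10_400), (11_000, 11_400)])
    return GeneModel("gA", "chr1", "+", [t1, t2])


@pytest.fixture
def minus_gene() -> GeneModel:
    t = Transcript("gB.t0", [(20_000, 20_300), (21_000, 21_600)], cds=(20_100, 21_300))
    return GeneModel("gB", "chr1", "-", [t])


@pytest.fixture
def simple_peaks() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * 4,
            "start": [100, 300, 1000, 5000],
            "end": [200, 400, 1200, 5400],
            "reads": [25, 19, 40, 100],
            "input_reads": [30, 100, 19, 60],
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
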