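import numpy as np
import pandas as pd
import pytest

from orsmell.io_catalog import ExpressionMatrix, GeneCatalog, TPM


@pytest.fixture
def toy_catalog() -> GeneCatalog:
    """Six chemoreceptors across families, statuses and chromosomes."""
    return GeneCatalog(
        pd.DataFrame(
            {
                "symbol": ["OR1", "OR2", "OR3", "ORP1", "TAAR1", "T2R1"],
                "family": ["OR", "OR", "OR", "OR", "TAAR", "T2R"],
                "or_class": ["ClassI", "ClassII", "ClassII", "", "", ""],
                "chromosome": ["chr11", "chr11", "chr1", "chr11", "chr6", "chr12"],
                "status": [
                    "functional", "functional", "functional",
                    "pseudogene", "functional", "functional",
                ],
            }
        )
    )


@pytest.fixture
def toy_matrix(toy_catalog) -> ExpressionMatrix:
    """Deterministic 8-gene x 4-cell TPM matrix containing the catalog genes."""
    rng = np.random.default_rng(42)
    genes = list(toy_catalog.table["symbol"]) + ["BG1", "BG2"]
    values = rng.uniform(0, 100, size=(len(genes), 4))
    values = values / values.sum(axis=0, keepdims=True) * 1e6
    return ExpressionMatrix(values, genes, [f"c{i}" for i in range(4)], TPM)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
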