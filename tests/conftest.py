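import numpy as np
import pandas as pd
import pytest

from pcqtl.io_formats import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_expression(values: np.ndarray, chrom: str = "chr1", gene_prefix: str = "g",
                    start0: int = 1000, spacing: int = 10_000) -> ExpressionMatrix:
    """Expression matrix helper: genes along one chromosome, BED anchors."""
    n_genes, n_samples = values.shape
    ids = [f"{gene_prefix}{i}" for i in range(n_genes)]
    anchors = pd.DataFrame(
        {
            "chrom": chrom,
            "start": [start0 + i * spacing for i in range(n_genes)],
            "end": [start0 + i * spacing + 1000 for i in range(n_genes)],
        },
        index=pd.Index(ids, name="phenotype_id"),
    )
    samples = [f"S{j:03d}" for j in range(n_samples)]
    return ExpressionMatrix(anchors, pd.DataFrame(values, index=anchors.index, columns=samples))


@pytest.fixture
def small_expr(rng):
    return make_expression(rng.standard_normal((5, 30)))
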