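import numpy as np
import pandas as pd
import pytest

from cosplicex.counts_io import ExonCountTable


def make_table(gene_exon_counts: dict[str, np.ndarray], sample_ids=None) -> ExonCountTable:
    """Build an ExonCountTable from {gene: exon x sample array}."""
    rows, index = [], []
    for gene, arr in gene_exon_counts.items():
        arr = np.asarray(arr, dtype=float)
        for e in range(arr.shape[0]):
            index.append((gene, f"e{e + 1}"))
            rows.append(arr[e])
    n_samples = rows[0].shape[0]
    cols = sample_ids or [f"s{i}" for i in range(n_samples)]
    df = pd.DataFrame(np.vstack(rows), index=pd.MultiIndex.from_tuples(index), columns=cols)
    return ExonCountTable(df)


@pytest.fixture
def tiny_table() -> ExonCountTable:
    return make_table(
        {
            "geneA": [[10.0, 20.0], [5.0, 2.0]],
            "geneB": [[1.0, 3.0]],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
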