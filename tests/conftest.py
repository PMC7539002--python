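import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def toy_genes():
    """Small annotation table: 4 clean genes on two chromosomes."""
    return pd.DataFrame({
        "gene_name": ["A", "B", "C", "D"],
        "chrom": ["chr1", "chr1", "chr1", "chr2"],
        "start": [5_000, 12_000, 26_000, 1_000],
        "end": [11_000, 20_000, 35_000, 3_000],
        "strand": ["+", "-", "+", "+"],
        "gene_type": ["protein_coding"] * 4,
    })


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def make_binned(values: np.ndarray, bin_size: int = 10_000):
    """Wrap a bins x samples array into a BinnedExpression for direct testing."""
    from dcescan.binning import BinGrid, BinnedExpression

    n_bins, n_samples = values.shape
    grid = BinGrid(chrom="chrT", bin_size=bin_size, anchor=0, n_bins=n_bins)
    samples = [f"s{i}" for i in range(n_samples)]
    df = pd.DataFrame(values, index=np.arange(n_bins), columns=samples)
    return BinnedExpression(grid=grid, values=df, gene_map={
        i: [f"g{i}"] for i in range(n_bins)
    }), samples
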