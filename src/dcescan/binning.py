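"""Fixed-width chromosomal binning of gene-level expression.

Each chromosome is tiled with ``bin_size``-bp bins anchored at the start
of its first gene and extending to the end of its last gene.  A bin's
expression in a sample is the mean normalized expression of the genes
assigned to it; bins without genes carry NaN and are excluded from all
downstream correlation work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BinGrid", "BinnedExpression", "build_grid", "assign_genes", "bin_expression"]


@dataclass(frozen=True)
class BinGrid:
    """Bin coordinate system for one chromosome.

    Bin ``i`` spans ``[anchor + i*bin_size, anchor + (i+1)*bin_size)``.
    """

    chrom: str
    bin_size: int
    anchor: int
    n_bins: int

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.n_bins <= 0:
            raise ValueError("grid must have at least one bin")

    def bin_start(self, i: int | np.ndarray) -> int | np.ndarray:
        return self.anchor + np.asarray(i) * self.bin_size

    def bin_end(self, i: int | np.ndarray) -> int | np.ndarray:
        return self.anchor + (np.asarray(i) + 1) * self.bin_size

    @property
    def span(self) -> tuple[int, int]:
        return self.anchor, self.anchor + self.n_bins * self.bin_size

    def to_bed(self) -> pd.DataFrame:
        idx = np.arange(self.n_bins)
        return pd.DataFrame({
            "chrom": self.chrom,
            "start": self.bin_start(idx),
            "end": self.bin_end(idx),
            "name": [f"{self.chrom}:bin{i}" for i in idx],
        })


@dataclass
class BinnedExpression:
    """Bin x sample mean-expression matrix plus the bin->gene map."""

    grid: BinGrid
    values: pd.DataFrame          # index: bin id 0..n_bins-1; columns: samples; NaN = no genes
    gene_map: dict[int, list[str]] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def build_grid(genes: pd.DataFrame, chrom: str, bin_size: int = 10_000) -> BinGrid:
    """Grid from the start of the first gene to the end of the last gene."""
    sub = genes[genes["chrom"] == chrom]
    if sub.empty:
        raise ValueError(f"no genes on chromosome {chrom!r}")
    anchor = int(sub["start"].min())
    end = int(sub["end"].max())
    n_bins = max(1, math.ceil((end - anchor) / bin_size))
    return BinGrid(chrom=chrom, bin_size=bin_size, anchor=anchor, n_bins=n_bins)


def assign_genes(
    genes: pd.DataFrame, grid: BinGrid, assignment: str = "overlap"
) -> dict[int, list[str]]:
    """Map bin index -> contributing gene names.

    ``assignment='overlap'``: a gene contributes to every bin its span
    overlaps by >= 1 bp (genes typically exceed the bin size, so this is
    the default).  ``assignment='tss'``: a gene contributes only to the
    bin of its strand-aware 5' end.
    """
    sub = genes[genes["chrom"] == grid.chrom]
    gene_map: dict[int, list[str]] = {}
    for name, start, end, strand in zip(
        sub["gene_name"], sub["start"], sub["end"], sub["strand"]
    ):
        if assignment == "overlap":
            first = (start - grid.anchor) // grid.bin_size
            last = (end - 1 - grid.anchor) // grid.bin_size
            first = max(int(first), 0)
            last = min(int(last), grid.n_bins - 1)
            bins = range(first, last + 1)
        elif assignment == "tss":
            tss = start if strand != "-" else end - 1
            b = int((tss - grid.anchor) // grid.bin_size)
            bins = [b] if 0 <= b < grid.n_bins else []
        else:
            raise ValueError(f"unknown assignment mode {assignment!r}")
        for b in bins:
            gene_map.setdefault(b, []).append(name)
    return gene_map


def bin_expression(
    norm: pd.DataFrame,
    genes: pd.DataFrame,
    grid: BinGrid,
    assignment: str = "overlap",
) -> BinnedExpression:
    """Mean per-bin expression from the normalized gene matrix.

    Bins without assigned genes get NaN rows (excluded downstream).
    """
    gene_map = assign_genes(genes, grid, assignment=assignment)
    present = set(norm.index)
    gene_map = {
        b: [g for g in gs if g in present] for b, gs in gene_map.items()
    }
    gene_map = {b: gs for b, gs in gene_map.items() if gs}

    values = np.full((grid.n_bins, norm.shape[1]), np.nan)
    for b, gs in gene_map.items():
        values[b] = norm.loc[gs].to_numpy(dtype=float).mean(axis=0)
    df = pd.DataFrame(values, index=np.arange(grid.n_bins), columns=norm.columns)
    df.index.name = "bin"
    return BinnedExpression(grid=grid, values=df, gene_map=gene_map)
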