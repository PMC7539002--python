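"""Genome-level orchestration: binning all chromosomes and calling per group."""

from __future__ import annotations

import pandas as pd

from .binning import BinnedExpression, bin_expression, build_grid
from .detection import DCESet, call_dces
from .io_prep import PrepResult

__all__ = ["bin_genome", "call_group"]


def bin_genome(
    prep: PrepResult, bin_size: int = 10_000, assignment: str = "overlap"
) -> dict[str, BinnedExpression]:
    """One BinnedExpression per chromosome present in the prepared gene table."""
    out = {}
    for chrom in pd.unique(prep.genes["chrom"]):
        grid = build_grid(prep.genes, chrom, bin_size=bin_size)
        out[chrom] = bin_expression(prep.normalized, prep.genes, grid, assignment=assignment)
    return out


def call_group(
    binned: dict[str, BinnedExpression],
    prep: PrepResult,
    group: str,
    **call_kwargs,
) -> DCESet:
    """Run the domain caller on every chromosome for one sample group."""
    samples = prep.samples_in(group)
    sets = [
        call_dces(be, samples, group=group, **call_kwargs)
        for be in binned.values()
    ]
    return DCESet.combine(sets)
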