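"""Calibration and recovery harnesses on synthetic data.

These drive the whole pipeline on generated inputs with known ground
truth: planted-boundary recovery, null calibration of the correlation
mask, the null domain-call rate, and end-to-end dynamics-scenario
accuracy.  They are the package's own way of quantifying how well the
caller works under controlled conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .binning import BinGrid, BinnedExpression
from .correlation import permutation_mask, surviving_bins
from .detection import DCESet
from .dynamics import classify_dces
from .io_prep import prepare
from .pipeline import bin_genome, call_group
from .simulate import BlockSpec, SimConfig, make_scenario, simulate_annotation, \
    simulate_counts, simulate_metadata

__all__ = [
    "run_two_group",
    "dce_bins",
    "boundary_recovery",
    "mask_null_retention",
    "null_dce_coverage",
    "scenario_label_accuracy",
]


def run_two_group(
    cfg: SimConfig,
    ref_blocks: list[BlockSpec],
    query_blocks: list[BlockSpec],
    n_perm: int = 200,
    shuffle: bool = False,
    **call_kwargs,
) -> tuple[DCESet, DCESet, dict]:
    """Simulate two groups, run prep + binning + calling on both.

    ``shuffle`` destroys all structure by permuting each sample's counts
    across genes (independent permutations), for null-rate studies.
    Returns (ref set, query set, context) where context holds the
    prepared data, binned matrices and per-group eligible bins.
    """
    genes = simulate_annotation(cfg)
    ref_counts = simulate_counts(cfg, genes, ref_blocks, "healthy")
    query_counts = simulate_counts(cfg, genes, query_blocks, "low")
    if shuffle:
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=cfg.seed, spawn_key=(99,)
        ))
        for df in (ref_counts, query_counts):
            arr = df.to_numpy()
            df.iloc[:, :] = rng.permuted(arr, axis=0)
    counts = pd.concat([ref_counts, query_counts], axis=1)
    meta = simulate_metadata(cfg, {"healthy": "healthy", "low": "low"})
    prep = prepare(genes, counts, meta)
    binned = bin_genome(prep, bin_size=cfg.bin_size)
    call_kwargs.setdefault("seed", cfg.seed)
    ref_set = call_group(binned, prep, "healthy", n_perm=n_perm, **call_kwargs)
    query_set = call_group(binned, prep, "low", n_perm=n_perm, **call_kwargs)
    ctx = {
        "prep": prep,
        "binned": binned,
        "eligible": {
            g: {c: surviving_bins(be, prep.samples_in(g)) for c, be in binned.items()}
            for g in ("healthy", "low")
        },
    }
    return ref_set, query_set, ctx


def dce_bins(dceset: DCESet, grids: dict[str, BinGrid]) -> list[tuple[str, int, int]]:
    """Called domains as inclusive original-bin ranges per chromosome."""
    out = []
    for d in dceset.dces:
        grid = grids[d.chrom]
        lo = (d.start - grid.anchor) // grid.bin_size
        hi = (d.end - grid.anchor) // grid.bin_size - 1
        out.append((d.chrom, int(lo), int(hi)))
    return out


def boundary_recovery(
    dceset: DCESet,
    blocks: list[BlockSpec],
    grids: dict[str, BinGrid],
    tol: int = 1,
) -> float:
    """Fraction of planted block boundaries matched by a called boundary
    within ``tol`` bins."""
    called = dce_bins(dceset, grids)
    starts: dict[str, list[int]] = {}
    ends: dict[str, list[int]] = {}
    for chrom, lo, hi in called:
        starts.setdefault(chrom, []).append(lo)
        ends.setdefault(chrom, []).append(hi)
    hit = total = 0
    for blk in blocks:
        for planted, pool in ((blk.start_bin, starts), (blk.end_bin, ends)):
            total += 1
            if any(abs(planted - c) <= tol for c in pool.get(blk.chrom, [])):
                hit += 1
    if total == 0:
        raise ValueError("no planted boundaries to score")
    return hit / total


def mask_null_retention(
    n_bins: int = 40,
    n_samples: int = 30,
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Retained off-diagonal fraction of the mask on i.i.d. noise bins.

    Under the global null this estimates the mask's effective level and
    should sit near ``alpha``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(7,)))
    values = rng.lognormal(mean=2.0, sigma=1.0, size=(n_bins, n_samples))
    grid = BinGrid(chrom="chrN", bin_size=10_000, anchor=0, n_bins=n_bins)
    samples = [f"s{i}" for i in range(n_samples)]
    be = BinnedExpression(
        grid=grid,
        values=pd.DataFrame(values, index=np.arange(n_bins), columns=samples),
        gene_map={i: [f"g{i}"] for i in range(n_bins)},
    )
    mc = permutation_mask(be, samples, n_perm=n_perm, alpha=alpha, seed=seed)
    off = ~np.eye(mc.n_bins, dtype=bool)
    return float((mc.masked_rho[off] != 0).mean())


def null_dce_coverage(
    cfg: SimConfig, n_perm: int = 200, **call_kwargs
) -> float:
    """Fraction of eligible bins covered by domains on fully shuffled data."""
    ref_blocks, query_blocks, _ = make_scenario("split", n_bins=cfg.n_bins)
    ref_set, query_set, ctx = run_two_group(
        cfg, ref_blocks, query_blocks, n_perm=n_perm, shuffle=True, **call_kwargs
    )
    fracs = []
    for group, dceset in (("healthy", ref_set), ("low", query_set)):
        covered = eligible = 0
        ranges = dce_bins(dceset, {c: be.grid for c, be in ctx["binned"].items()})
        for chrom, bins in ctx["eligible"][group].items():
            eligible += len(bins)
            for c, lo, hi in ranges:
                if c == chrom:
                    covered += int(((bins >= lo) & (bins <= hi)).sum())
        fracs.append(covered / eligible if eligible else 0.0)
    return float(np.mean(fracs))


def scenario_label_accuracy(
    scenario: str,
    n_reps: int = 20,
    base_seed: int = 0,
    cfg_kwargs: dict | None = None,
    n_perm: int = 200,
    **call_kwargs,
) -> float:
    """Fraction of seeded replicates reproducing the scenario's labels end-to-end.

    A replicate succeeds when, for every planted block on either side,
    the called domain with the largest overlap carries the expected
    dynamics label.
    """
    cfg_kwargs = dict(cfg_kwargs or {})
    cfg_kwargs.setdefault("n_bins", 100)
    ok = 0
    for rep in range(n_reps):
        seed = int(np.random.SeedSequence(
            entropy=base_seed, spawn_key=(11, rep)
        ).generate_state(1)[0] % (2**31))
        cfg = SimConfig(seed=seed, **cfg_kwargs)
        ref_blocks, query_blocks, expected = make_scenario(scenario, n_bins=cfg.n_bins)
        ref_set, query_set, ctx = run_two_group(
            cfg, ref_blocks, query_blocks, n_perm=n_perm, **call_kwargs
        )
        report = classify_dces(ref_set, query_set)
        grids = {c: be.grid for c, be in ctx["binned"].items()}
        if _labels_match(ref_set, ref_blocks, report.ref_labels, expected["ref"], grids) and \
           _labels_match(query_set, query_blocks, report.query_labels, expected["query"], grids):
            ok += 1
    return ok / n_reps


def _labels_match(dceset, blocks, labels, expected, grids) -> bool:
    if len(expected) != len(blocks):
        raise ValueError("expected labels must align with planted blocks")
    ranges = dce_bins(dceset, grids)
    for blk, want in zip(blocks, expected):
        best, best_ov = None, 0
        for i, (chrom, lo, hi) in enumerate(ranges):
            if chrom != blk.chrom:
                continue
            ov = min(hi, blk.end_bin) - max(lo, blk.start_bin) + 1
            if ov > best_ov:
                best, best_ov = i, ov
        if best is None or labels[best] != want:
            return False
    return True
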