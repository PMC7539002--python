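"""Synthetic annotation and grouped count matrices with planted co-expression.

The generator emulates the statistical structure the domain model
assumes: genes inside a planted block share a per-sample latent factor,
so their counts are positively correlated across samples, while genes
outside blocks vary independently.  Counts are negative-binomial
(overdispersed, bulk RNA-seq-like marginals).  Group differences are
expressed purely through block presence and geometry, never through
library-size confounds, so a failure to recover the planted layout
points at the caller, not the input.

Scenario builders script the seven domain-dynamics outcomes (split,
merge, emerge, deplete, expand, contract, intact) with known ground
truth for end-to-end testing.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "BlockSpec",
    "SCENARIOS",
    "simulate_annotation",
    "simulate_counts",
    "simulate_metadata",
    "make_scenario",
    "write_fixture",
]


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters (defaults mirror the intended study conditions)."""

    n_chrom: int = 1
    n_bins: int = 100            # chromosome length, in bins
    bin_size: int = 10_000
    genes_per_bin: int = 1
    n_samples: int = 50          # per group
    dispersion: float = 0.1      # NB: var = mu + dispersion * mu^2
    mu_log_mean: float = np.log(100.0)
    mu_log_sd: float = 1.0
    noise_sd: float = 0.3        # per-gene log-normal noise on top of the latent factor
    seed: int = 0

    def __post_init__(self):
        for name in ("n_chrom", "n_bins", "bin_size", "genes_per_bin", "n_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dispersion <= 0 or self.noise_sd < 0:
            raise ValueError("dispersion must be > 0 and noise_sd >= 0")


@dataclass(frozen=True)
class BlockSpec:
    """A planted co-expression block: an inclusive bin range on one chromosome."""

    chrom: str
    start_bin: int
    end_bin: int
    lam: float = 1.0             # latent loading (co-expression strength)

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("latent loading must be >= 0")
        if self.end_bin < self.start_bin or self.start_bin < 0:
            raise ValueError("invalid block bin range")

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin + 1


def _chrom_name(i: int) -> str:
    return f"chr{i + 1}"


def simulate_annotation(cfg: SimConfig) -> pd.DataFrame:
    """Gene table tiling each chromosome with ``genes_per_bin`` genes per bin.

    Genes are non-overlapping, strand-alternating and deterministic under
    the config seed (gene body margins are jittered for realism).
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(0,)))
    rows = []
    for c in range(cfg.n_chrom):
        chrom = _chrom_name(c)
        for b in range(cfg.n_bins):
            slot = cfg.bin_size // cfg.genes_per_bin
            for g in range(cfg.genes_per_bin):
                lo = b * cfg.bin_size + g * slot
                # fixed start margin keeps every gene inside its own bin
                # (the grid anchors at the first gene start); only the end
                # is jittered
                margin = int(rng.integers(50, max(51, slot // 10)))
                rows.append({
                    "gene_name": f"{chrom}_g{b * cfg.genes_per_bin + g}",
                    "chrom": chrom,
                    "start": lo + 40,
                    "end": lo + slot - margin,
                    "strand": "+" if (b + g) % 2 == 0 else "-",
                    "gene_type": "protein_coding",
                })
    return pd.DataFrame(rows)


def _gene_block_index(
    genes: pd.DataFrame, blocks: list[BlockSpec], bin_size: int
) -> np.ndarray:
    """Block id per gene (-1 = background); a gene belongs to the block
    containing its body midpoint."""
    idx = np.full(len(genes), -1)
    mid_bin = ((genes["start"] + genes["end"]) // 2) // bin_size
    for k, blk in enumerate(blocks):
        inside = (
            (genes["chrom"] == blk.chrom)
            & (mid_bin >= blk.start_bin)
            & (mid_bin <= blk.end_bin)
        )
        idx[inside.to_numpy()] = k
    return idx


def simulate_counts(
    cfg: SimConfig,
    genes: pd.DataFrame,
    blocks: list[BlockSpec],
    group: str,
    sample_prefix: str | None = None,
) -> pd.DataFrame:
    """Negative-binomial counts with the group's planted blocks active.

    Gene i in block k gets mean mu_i * exp(lam * g_ks + eps) for sample s,
    with latent g_ks ~ N(0,1) shared by the block's genes; background
    genes get independent noise only.  Deterministic under
    (cfg.seed, group).
    """
    group_key = zlib.crc32(group.encode()) % (2**31)  # stable across processes
    ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1, group_key))
    rng = np.random.default_rng(ss)
    n_genes, n_samples = len(genes), cfg.n_samples
    mu = np.exp(rng.normal(cfg.mu_log_mean, cfg.mu_log_sd, size=n_genes))
    block_of = _gene_block_index(genes, blocks, cfg.bin_size)
    latent = rng.normal(size=(len(blocks), n_samples))
    eps = rng.normal(0.0, cfg.noise_sd, size=(n_genes, n_samples))

    log_mean = np.log(mu)[:, None] + eps
    for k, blk in enumerate(blocks):
        members = block_of == k
        log_mean[members] += blk.lam * latent[k][None, :]
    mean = np.exp(log_mean)

    r = 1.0 / cfg.dispersion
    p = r / (r + mean)
    counts = rng.negative_binomial(r, p)
    prefix = sample_prefix or group
    cols = [f"{prefix}_s{i}" for i in range(n_samples)]
    out = pd.DataFrame(counts, index=genes["gene_name"].to_numpy(), columns=cols)
    out.index.name = "gene_name"
    return out


def simulate_metadata(cfg: SimConfig, groups: dict[str, str]) -> pd.DataFrame:
    """Metadata table for samples of several groups (``groups``: prefix -> group).

    Patients get a SLEDAI score consistent with their group; healthy
    samples get none.
    """
    sledai_for = {"low": 1, "intermediate": 5, "high": 12}
    rows = []
    for prefix, group in groups.items():
        for i in range(cfg.n_samples):
            rows.append({
                "sample_id": f"{prefix}_s{i}",
                "group": group,
                "sledai": sledai_for.get(group, np.nan),
            })
    return pd.DataFrame(rows)


def _blk(chrom: str, lo: int, hi: int, lam: float = 1.0) -> BlockSpec:
    return BlockSpec(chrom=chrom, start_bin=lo, end_bin=hi, lam=lam)


def make_scenario(
    name: str, n_bins: int = 100, lam: float = 1.0
) -> tuple[list[BlockSpec], list[BlockSpec], dict]:
    """Paired block layouts whose ideal domain calls yield the named label.

    Returns ``(ref_blocks, query_blocks, expected)`` where ``expected``
    records the ground-truth label per side.
    """
    # block coverage is kept under ~1/3 of the chromosome so that the
    # median-of-ratios normalization retains a stable background
    # reference, as it does on real whole transcriptomes
    c = _chrom_name(0)
    scenarios = {
        "intact": (
            [_blk(c, 30, 54, lam)], [_blk(c, 30, 54, lam)],
            {"ref": ["intact"], "query": ["intact"]},
        ),
        "split": (
            [_blk(c, 25, 54, lam)], [_blk(c, 25, 37, lam), _blk(c, 43, 54, lam)],
            {"ref": ["split"], "query": ["split", "split"]},
        ),
        "merge": (
            [_blk(c, 25, 37, lam), _blk(c, 43, 54, lam)], [_blk(c, 25, 54, lam)],
            {"ref": ["merged", "merged"], "query": ["merged"]},
        ),
        "deplete": (
            [_blk(c, 30, 54, lam)], [],
            {"ref": ["depleted"], "query": []},
        ),
        "emerge": (
            [], [_blk(c, 30, 54, lam)],
            {"ref": [], "query": ["emerged"]},
        ),
        "expand": (
            [_blk(c, 35, 49, lam)], [_blk(c, 28, 56, lam)],
            {"ref": ["expanded"], "query": ["expanded"]},
        ),
        "contract": (
            [_blk(c, 28, 56, lam)], [_blk(c, 35, 49, lam)],
            {"ref": ["contracted"], "query": ["contracted"]},
        ),
    }
    if name not in scenarios:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(scenarios)}")
    ref, query, expected = scenarios[name]
    for blk in ref + query:
        if blk.end_bin >= n_bins:
            raise ValueError("scenario blocks exceed chromosome length")
    return ref, query, expected


SCENARIOS = ("intact", "split", "merge", "deplete", "emerge", "expand", "contract")


def write_fixture(
    out_dir: str,
    cfg: SimConfig,
    scenario: str,
) -> dict:
    """Write GTF, counts TSV, metadata TSV and a truth JSON for a scenario."""
    os.makedirs(out_dir, exist_ok=True)
    ref_blocks, query_blocks, expected = make_scenario(scenario, n_bins=cfg.n_bins)
    genes = simulate_annotation(cfg)

    gtf_path = os.path.join(out_dir, "annotation.gtf")
    with open(gtf_path, "w") as fh:
        for rec in genes.itertuples(index=False):
            attrs = (
                f'gene_id "{rec.gene_name}"; gene_name "{rec.gene_name}"; '
                f'gene_type "{rec.gene_type}";'
            )
            fh.write(
                f"{rec.chrom}\tdcescan\tgene\t{rec.start + 1}\t{rec.end}\t.\t"
                f"{rec.strand}\t.\t{attrs}\n"
            )

    healthy = simulate_counts(cfg, genes, ref_blocks, "healthy")
    patient = simulate_counts(cfg, genes, query_blocks, "low")
    counts = pd.concat([healthy, patient], axis=1)
    counts.to_csv(os.path.join(out_dir, "counts.tsv"), sep="\t")

    meta = simulate_metadata(cfg, {"healthy": "healthy", "low": "low"})
    meta.to_csv(os.path.join(out_dir, "metadata.tsv"), sep="\t", index=False)

    truth = {
        "scenario": scenario,
        "config": asdict(cfg),
        "ref_blocks": [asdict(b) for b in ref_blocks],
        "query_blocks": [asdict(b) for b in query_blocks],
        "expected_labels": expected,
    }
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2)
    return truth
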