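"""Permutation-masked Spearman correlation matrices over chromosome bins.

For one sample group and one chromosome, every pair of surviving
(gene-containing, expressed) bins gets a Spearman rho across the group's
samples.  Significance is assessed by a Monte-Carlo scheme that shuffles
each sample's bin values independently, rebuilds the full matrix each
round, and scores how often the permuted coefficient is at least as
extreme as the observed one.  Coefficients with p > alpha are zeroed
("masked"); the masked matrix is the input to domain calling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .binning import BinnedExpression

__all__ = [
    "MaskedCorrelation",
    "surviving_bins",
    "spearman_matrix",
    "permutation_mask",
    "write_masked_tsv",
    "read_masked_tsv",
]


@dataclass
class MaskedCorrelation:
    """Permutation-thresholded Spearman matrix for one chromosome/group."""

    chrom: str
    group: str
    bin_index: np.ndarray      # original grid bin ids of surviving bins
    rho: np.ndarray            # symmetric, diag 1
    pval: np.ndarray           # permutation p-values, diag 0
    masked_rho: np.ndarray     # rho with p > alpha entries zeroed, diag 1
    n_perm: int
    alpha: float
    seed: int | None
    constant_bins: np.ndarray  # original bin ids dropped for zero variance

    @property
    def n_bins(self) -> int:
        return len(self.bin_index)


def surviving_bins(binned: BinnedExpression, group_samples: list[str]) -> np.ndarray:
    """Bins that contain genes and have nonzero expression in the group."""
    sub = binned.values[group_samples]
    arr = sub.to_numpy(dtype=float)
    ok = ~np.isnan(arr).any(axis=1) & (np.nansum(arr, axis=1) > 0)
    return np.flatnonzero(ok)


def _rank_rows(values: np.ndarray) -> np.ndarray:
    return rankdata(values, axis=1)


def _corr_from_ranks(ranks: np.ndarray) -> np.ndarray:
    """Pearson correlation of row vectors; zero-variance rows give NaN."""
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = centered / norms[:, None]
    rho = unit @ unit.T
    np.clip(rho, -1.0, 1.0, out=rho)
    return rho


def spearman_matrix(
    binned: BinnedExpression, group_samples: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spearman rho between all surviving bins of one chromosome.

    Returns ``(bin_index, rho, constant_bins)`` where ``bin_index`` are
    the original grid bin ids kept, ``rho`` their correlation matrix
    (average-rank based, symmetric, unit diagonal) and ``constant_bins``
    the ids additionally dropped for zero variance across samples.
    """
    if len(group_samples) < 3:
        raise ValueError("need at least 3 samples in the group")
    idx = surviving_bins(binned, group_samples)
    values = binned.values.loc[idx, group_samples].to_numpy(dtype=float)
    ranks = _rank_rows(values)
    variable = ranks.std(axis=1) > 0
    constant = idx[~variable]
    idx = idx[variable]
    rho = _corr_from_ranks(ranks[variable])
    np.fill_diagonal(rho, 1.0)
    return idx, rho, constant


def permutation_mask(
    binned: BinnedExpression,
    group_samples: list[str],
    group: str = "",
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = 0,
    two_sided: bool = True,
) -> MaskedCorrelation:
    """Monte-Carlo significance mask for the Spearman matrix.

    Each permutation round shuffles bin values within every sample
    independently, recomputes the whole matrix once, and counts rounds
    where the permuted coefficient is at least as extreme as the observed
    one (on absolute value when ``two_sided``).  p = count / n_perm, per
    the plain-fraction estimator; entries with p > alpha become 0.
    Bit-for-bit reproducible for a given (data, n_perm, alpha, seed):
    round ``k`` uses ``SeedSequence(seed, spawn_key=(k,))``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    idx, rho, constant = spearman_matrix(binned, group_samples)
    values = binned.values.loc[idx, group_samples].to_numpy(dtype=float)

    obs = np.abs(rho) if two_sided else rho
    count = np.zeros_like(rho)
    root = np.random.SeedSequence(entropy=seed)
    for k in range(n_perm):
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=root.entropy, spawn_key=(k,)
        ))
        shuffled = rng.permuted(values, axis=0)  # independent shuffle per sample
        perm_rho = _corr_from_ranks(_rank_rows(shuffled))
        perm_stat = np.abs(perm_rho) if two_sided else perm_rho
        count += perm_stat >= obs
    pval = count / n_perm
    np.fill_diagonal(pval, 0.0)

    masked = np.where(pval <= alpha, rho, 0.0)
    np.fill_diagonal(masked, 1.0)
    return MaskedCorrelation(
        chrom=binned.grid.chrom,
        group=group,
        bin_index=idx,
        rho=rho,
        pval=pval,
        masked_rho=masked,
        n_perm=n_perm,
        alpha=alpha,
        seed=seed,
        constant_bins=constant,
    )


def write_masked_tsv(mc: MaskedCorrelation, path: str) -> None:
    """Write the masked matrix as sparse TSV triplets (bin_i, bin_j, rho)."""
    iu = np.triu_indices(mc.n_bins)
    rows = []
    for i, j in zip(*iu):
        v = mc.masked_rho[i, j]
        if v != 0.0:
            rows.append((int(mc.bin_index[i]), int(mc.bin_index[j]), v))
    df = pd.DataFrame(rows, columns=["bin_i", "bin_j", "masked_rho"])
    with open(path, "w") as fh:
        fh.write(f"# chrom={mc.chrom} group={mc.group} n_perm={mc.n_perm} "
                 f"alpha={mc.alpha} seed={mc.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_masked_tsv(path: str) -> MaskedCorrelation:
    """Read a masked matrix written by :func:`write_masked_tsv`."""
    with open(path) as fh:
        header = fh.readline().lstrip("# ").split()
        meta = dict(kv.split("=", 1) for kv in header)
        df = pd.read_csv(fh, sep="\t")
    bins = np.unique(np.concatenate([df["bin_i"].to_numpy(), df["bin_j"].to_numpy()]))
    pos = {b: i for i, b in enumerate(bins)}
    n = len(bins)
    masked = np.zeros((n, n))
    for bi, bj, v in zip(df["bin_i"], df["bin_j"], df["masked_rho"]):
        masked[pos[bi], pos[bj]] = v
        masked[pos[bj], pos[bi]] = v
    seed = meta.get("seed")
    return MaskedCorrelation(
        chrom=meta["chrom"],
        group=meta["group"],
        bin_index=bins.astype(np.int64),
        rho=masked.copy(),
        pval=np.full((n, n), np.nan),
        masked_rho=masked,
        n_perm=int(meta["n_perm"]),
        alpha=float(meta["alpha"]),
        seed=None if seed in (None, "None") else int(seed),
        constant_bins=np.array([], dtype=np.int64),
    )
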