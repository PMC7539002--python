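"""Shared statistical primitives: rank-sum tests and seed derivation.

The boundary test and the entropy comparison both need a Mann-Whitney /
Wilcoxon rank-sum p-value on very small samples that are full of tied
zeros, so the exact path enumerates label assignments on midranks
(scipy's exact method assumes no ties).  Larger samples fall back to the
tie-corrected normal approximation.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = ["rank_sum_test", "stage_seed", "EXACT_MAX_N"]

#: Per-side sample size up to which the exact enumeration is used.
EXACT_MAX_N = 8


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """Exact rank-sum p by enumerating all C(n+m, n) label assignments.

    Ties are handled with midranks: the statistic is the rank sum of the
    ``x`` sample in the pooled midranked data, and the null distribution
    enumerates every subset of positions of size ``len(x)``.
    """
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n = len(x)
    observed = ranks[:n].sum()
    total = 0
    ge = 0
    le = 0
    eps = 1e-9
    for idx in combinations(range(len(pooled)), n):
        s = ranks[list(idx)].sum()
        total += 1
        if s >= observed - eps:
            ge += 1
        if s <= observed + eps:
            le += 1
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return min(1.0, 2.0 * min(ge / total, le / total))


def rank_sum_test(x, y, alternative: str = "greater") -> float:
    """Mann-Whitney U / rank-sum p-value with midrank tie handling.

    Exact enumeration when both sides have <= EXACT_MAX_N observations,
    otherwise scipy's tie-corrected normal approximation.  ``alternative``
    is interpreted as: 'greater' means x tends larger than y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N:
        return _exact_rank_sum_p(x, y, alternative)
    res = sps.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return float(res.pvalue)


def stage_seed(master_seed: int, stage: str, counter: int = 0) -> np.random.SeedSequence:
    """Derive a per-stage seed sequence from one master seed.

    Stages have fixed indices so any stage can be re-run independently of
    the others; ``counter`` sub-keys chunks within a stage (e.g. one
    permutation round, one replicate).
    """
    stage_index = {
        "simulate": 0,
        "correlate": 1,
        "call": 2,
        "compare": 3,
        "enrich": 4,
        "tune": 5,
    }
    if stage not in stage_index:
        raise KeyError(f"unknown stage {stage!r}")
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(stage_index[stage], counter))
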