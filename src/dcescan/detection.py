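"""The four-step domain caller: bin signal, minima, boundary tests, fusion.

A domain of co-ordinated expression (DCE) is a run of consecutive bins
whose mutual correlation is high, delimited by boundaries that pass a
rank-sum test of within- versus between-window correlation.  The caller
adapts a contact-map TAD-calling strategy to masked expression
correlation matrices:

1. slide two juxtaposed ``w``-bin windows along the chromosome and
   record the mean of the w x w cross-window correlations at each step
   (the *bin signal*, assigned to the downstream-most bin of the
   upstream window);
2. smooth the signal with a cubic smoothing spline and take local
   minima below a threshold as candidate boundaries; candidate domains
   are the maximal runs of above-threshold smoothed signal;
3. test every boundary with a one-sided Mann-Whitney comparison of
   within-domain versus cross-boundary coefficients, chopping the
   boundary one bin inward until it becomes significant (domains that
   never do are discarded);
4. fuse neighbouring domains separated by at most two low-signal bins,
   never chaining more than three original domains.

All positions are on the *surviving-bin axis* (bins dropped for missing
or zero expression are compacted away); genomic coordinates are
recovered through the grid and the surviving-bin index map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .binning import BinnedExpression
from .correlation import MaskedCorrelation, permutation_mask
from .stats import rank_sum_test

__all__ = [
    "BinSignal",
    "DCE",
    "DCESet",
    "bin_signal",
    "detect_minima",
    "evaluate_boundaries",
    "fuse_dces",
    "call_dces",
    "tune_window",
    "write_bed",
]

DEFAULT_W = 3
DEFAULT_THRESHOLD = 0.25
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_SIZE = 2
DEFAULT_MAX_MISSING_GAP = 2
FUSE_MAX_GAP = 2
FUSE_MAX_LOW_BINS = 2
FUSE_MAX_CHAIN = 3


@dataclass
class BinSignal:
    """Sliding cross-window correlation signal along one chromosome."""

    chrom: str
    group: str
    w: int
    values: np.ndarray        # raw signal, one value per surviving bin
    smoothed: np.ndarray      # spline-smoothed values at the same positions
    bin_index: np.ndarray     # original grid bin ids of surviving bins

    @property
    def admissible(self) -> tuple[int, int]:
        """Inclusive range of positions with a full window on both sides."""
        n = len(self.values)
        return self.w - 1, n - 1 - self.w


@dataclass
class DCE:
    """One called domain, on both bin and genomic coordinates."""

    chrom: str
    start_bin: int            # surviving-bin axis, inclusive
    end_bin: int
    start: int                # genomic bp, half-open
    end: int
    mean_signal: float
    left_p: float
    right_p: float
    genes: list[str] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin + 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DCESet:
    """Sorted, non-overlapping domains for one group (possibly many chromosomes)."""

    group: str
    dces: list[DCE] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.dces.sort(key=lambda d: (d.chrom, d.start))
        by_chrom: dict[str, DCE] = {}
        for d in self.dces:
            prev = by_chrom.get(d.chrom)
            if prev is not None and d.start < prev.end:
                raise ValueError(
                    f"overlapping DCEs on {d.chrom}: [{prev.start},{prev.end}) "
                    f"and [{d.start},{d.end})"
                )
            by_chrom[d.chrom] = d

    def __len__(self) -> int:
        return len(self.dces)

    def on(self, chrom: str) -> list[DCE]:
        return [d for d in self.dces if d.chrom == chrom]

    @property
    def chroms(self) -> list[str]:
        return sorted({d.chrom for d in self.dces})

    @classmethod
    def combine(cls, sets: list["DCESet"]) -> "DCESet":
        if not sets:
            raise ValueError("nothing to combine")
        group = sets[0].group
        dces = [d for s in sets for d in s.dces]
        params = dict(sets[0].params)
        return cls(group=group, dces=dces, params=params)


def _smooth(values: np.ndarray) -> np.ndarray:
    """Cubic smoothing spline (GCV-selected penalty) evaluated in place.

    Degenerate inputs (short or constant series, singular GCV systems)
    fall back to the raw values.
    """
    n = len(values)
    if n < 5 or np.ptp(values) == 0:
        return values.astype(float).copy()
    x = np.arange(n, dtype=float)
    try:
        from scipy.interpolate import make_smoothing_spline

        spline = make_smoothing_spline(x, values.astype(float), lam=None)
        return np.asarray(spline(x), dtype=float)
    except Exception:
        return values.astype(float).copy()


def bin_signal(mc: MaskedCorrelation, w: int = DEFAULT_W) -> BinSignal:
    """Cross-window mean correlation along the surviving-bin axis.

    For admissible position ``i`` the upstream window is bins
    ``[i-w+1, i]`` and the downstream window ``[i+1, i+w]``; the signal
    is the mean of the w x w cross-window block of the masked matrix
    (masked entries count as 0).  Positions within ``w-1`` of either end
    take the value of the nearest admissible position.
    """
    n = mc.n_bins
    if n < 2 * w:
        raise ValueError(
            f"chromosome {mc.chrom}: {n} surviving bins < 2w = {2 * w}"
        )
    m = mc.masked_rho
    values = np.empty(n, dtype=float)
    lo, hi = w - 1, n - 1 - w
    for i in range(lo, hi + 1):
        values[i] = m[i - w + 1 : i + 1, i + 1 : i + w + 1].mean()
    values[:lo] = values[lo]
    values[hi + 1 :] = values[hi]
    return BinSignal(
        chrom=mc.chrom,
        group=mc.group,
        w=w,
        values=values,
        smoothed=_smooth(values),
        bin_index=mc.bin_index,
    )


def _local_minima(s: np.ndarray) -> list[int]:
    """Strict slope-sign-change minima; plateau minima take the leftmost bin."""
    n = len(s)
    minima = []
    for i in range(1, n - 1):
        if not s[i - 1] > s[i]:
            continue  # plateau-leftmost: must descend into i
        j = i
        while j + 1 < n and s[j + 1] == s[i]:
            j += 1
        if j + 1 < n and s[j + 1] > s[i]:
            minima.append(i)
    return minima


def _break_at_missing_gaps(
    runs: list[tuple[int, int]], bin_index: np.ndarray, max_missing_gap: int
) -> list[tuple[int, int]]:
    """Split runs wherever consecutive surviving bins hide too many missing bins."""
    out = []
    for s, e in runs:
        start = s
        for p in range(s, e):
            if bin_index[p + 1] - bin_index[p] - 1 > max_missing_gap:
                out.append((start, p))
                start = p + 1
        out.append((start, e))
    return out


def detect_minima(
    sig: BinSignal,
    threshold: float = DEFAULT_THRESHOLD,
    max_missing_gap: int = DEFAULT_MAX_MISSING_GAP,
) -> tuple[list[int], list[tuple[int, int]]]:
    """Candidate boundaries and initial domains from the smoothed signal.

    Boundaries are local minima of the smoothed signal whose value is
    below ``threshold``.  Initial domains are the segments between
    consecutive qualifying minima (minima bins excluded) that contain at
    least one bin of above-threshold smoothed signal; segments that
    never rise above the threshold are background and dropped.  Domains
    are clipped to the admissible window range -- edge positions without
    a full window pair cannot open a domain -- and broken wherever they
    would bridge more than ``max_missing_gap`` consecutive missing bins
    in genomic space.  The deliberately generous segment ends are then
    refined inward by the boundary test.
    """
    s = sig.smoothed
    lo, hi = sig.admissible
    minima = [i for i in _local_minima(s) if s[i] < threshold and lo <= i <= hi]

    # signal(i) describes the junction between bins i and i+1, so a
    # boundary minimum at i closes the upstream segment *inclusive* of i
    starts = [lo] + [m + 1 for m in minima]
    ends = minima + [hi]
    runs: list[tuple[int, int]] = []
    for start, end in zip(starts, ends):
        if end >= start and (s[start : end + 1] > threshold).any():
            runs.append((start, end))
    runs = _break_at_missing_gaps(runs, sig.bin_index, max_missing_gap)
    return minima, runs


def _boundary_samples(
    m: np.ndarray, s: int, e: int, w: int, side: str
) -> tuple[np.ndarray, np.ndarray]:
    """Within-domain pairs and cross-boundary block for one boundary."""
    n = m.shape[0]
    if side == "left":
        inner = np.arange(s, min(s + w, e + 1))
        outer = np.arange(max(s - w, 0), s)
    else:
        inner = np.arange(max(e - w + 1, s), e + 1)
        outer = np.arange(e + 1, min(e + 1 + w, n))
    within = m[np.ix_(inner, inner)][np.triu_indices(len(inner), k=1)]
    between = m[np.ix_(inner, outer)].ravel()
    return within, between


def evaluate_boundaries(
    domains: list[tuple[int, int]],
    mc: MaskedCorrelation,
    w: int = DEFAULT_W,
    alpha: float = DEFAULT_ALPHA,
    min_size: int = DEFAULT_MIN_SIZE,
) -> list[tuple[int, int, float, float]]:
    """Validate and refine domain boundaries by rank-sum testing.

    For each boundary, "within" coefficients are the pairs among the
    (up to) ``w`` domain bins adjacent to it and "between" the w x w
    cross block spanning it.  A one-sided test (within > between) with
    p > alpha chops the boundary one bin toward the domain centre and
    retests; domains shrinking below ``min_size`` bins are dropped.
    Returns ``(start, end, left_p, right_p)`` tuples of survivors.
    """
    m = mc.masked_rho
    validated = []
    for s, e in domains:
        left_p = right_p = None
        while e - s + 1 >= min_size:
            within, between = _boundary_samples(m, s, e, w, "left")
            if len(within) == 0 or len(between) == 0:
                left_p = None
                break
            p = rank_sum_test(within, between, alternative="greater")
            if p <= alpha:
                left_p = p
                break
            s += 1
        if left_p is None or e - s + 1 < min_size:
            continue
        while e - s + 1 >= min_size:
            within, between = _boundary_samples(m, s, e, w, "right")
            if len(within) == 0 or len(between) == 0:
                right_p = None
                break
            p = rank_sum_test(within, between, alternative="greater")
            if p <= alpha:
                right_p = p
                break
            e -= 1
        if right_p is None or e - s + 1 < min_size:
            continue
        validated.append((s, e, left_p, right_p))
    return validated


def fuse_dces(
    domains: list[tuple[int, int, float, float]],
    signal: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    bin_index: np.ndarray | None = None,
    max_gap: int = FUSE_MAX_GAP,
    max_low_bins: int = FUSE_MAX_LOW_BINS,
    max_chain: int = FUSE_MAX_CHAIN,
    max_missing_gap: int = DEFAULT_MAX_MISSING_GAP,
) -> list[tuple[int, int, float, float]]:
    """Greedy left-to-right fusion of neighbouring domains.

    Two consecutive domains fuse when the gap between them holds between
    one and ``max_gap`` bins, every gap bin has raw signal below
    ``threshold`` (adjacent domains separated by a validated boundary
    alone are never rejoined),
    the cumulative number of such intervening low-signal bins within the
    fused chain stays <= ``max_low_bins``, and the chain holds at most
    ``max_chain`` original domains.  A fusion may not bridge a run of
    more than ``max_missing_gap`` consecutive missing bins in genomic
    space.  Fused domains keep the outermost boundary p-values.
    """
    if not domains:
        return []
    domains = sorted(domains)
    fused = []
    cs, ce, clp, crp = domains[0]
    chain_count, chain_low = 1, 0
    for s, e, lp, rp in domains[1:]:
        gap = s - ce - 1
        gap_bins = signal[ce + 1 : s]
        missing_ok = True
        if bin_index is not None:
            diffs = np.diff(bin_index[ce : s + 1]) - 1
            missing_ok = bool((diffs <= max_missing_gap).all())
        if (
            1 <= gap <= max_gap
            and bool((gap_bins < threshold).all())
            and chain_low + gap <= max_low_bins
            and chain_count + 1 <= max_chain
            and missing_ok
        ):
            ce, crp = e, rp
            chain_count += 1
            chain_low += gap
        else:
            fused.append((cs, ce, clp, crp))
            cs, ce, clp, crp = s, e, lp, rp
            chain_count, chain_low = 1, 0
    fused.append((cs, ce, clp, crp))
    return fused


def _genes_in_range(binned: BinnedExpression, orig_lo: int, orig_hi: int) -> list[str]:
    names: list[str] = []
    seen = set()
    for b in range(orig_lo, orig_hi + 1):
        for g in binned.gene_map.get(b, []):
            if g not in seen:
                seen.add(g)
                names.append(g)
    return names


def call_dces(
    binned: BinnedExpression,
    group_samples: list[str],
    group: str = "",
    mc: MaskedCorrelation | None = None,
    w: int = DEFAULT_W,
    threshold: float = DEFAULT_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = 1000,
    mask_alpha: float = 0.05,
    seed: int | None = 0,
    min_size: int = DEFAULT_MIN_SIZE,
    max_missing_gap: int = DEFAULT_MAX_MISSING_GAP,
    two_sided: bool = True,
) -> DCESet:
    """Full caller for one chromosome: mask -> signal -> minima -> test -> fuse.

    ``mc`` may be supplied to reuse a precomputed masked matrix (the mask
    does not depend on ``w``); otherwise it is computed here with
    ``n_perm`` permutations at ``mask_alpha``.  Chromosomes with fewer
    than ``2w`` surviving bins are skipped with a warning, yielding an
    empty set.
    """
    params = {
        "w": w, "threshold": threshold, "alpha": alpha, "n_perm": n_perm,
        "mask_alpha": mask_alpha, "seed": seed, "min_size": min_size,
        "max_missing_gap": max_missing_gap, "two_sided": two_sided,
        "fuse_max_gap": FUSE_MAX_GAP, "fuse_max_low_bins": FUSE_MAX_LOW_BINS,
        "fuse_max_chain": FUSE_MAX_CHAIN,
    }
    if mc is None:
        mc = permutation_mask(
            binned, group_samples, group=group, n_perm=n_perm,
            alpha=mask_alpha, seed=seed, two_sided=two_sided,
        )
    if mc.n_bins < 2 * w:
        warnings.warn(
            f"chromosome {mc.chrom}: only {mc.n_bins} surviving bins "
            f"(< 2w = {2 * w}); skipped"
        )
        return DCESet(group=group, dces=[], params=params)

    sig = bin_signal(mc, w=w)
    _, initial = detect_minima(sig, threshold=threshold, max_missing_gap=max_missing_gap)
    validated = evaluate_boundaries(initial, mc, w=w, alpha=alpha, min_size=min_size)
    final = fuse_dces(
        validated, sig.values, threshold=threshold, bin_index=mc.bin_index,
        max_missing_gap=max_missing_gap,
    )

    grid = binned.grid
    dces = []
    for i, (s, e, lp, rp) in enumerate(final):
        orig_lo, orig_hi = int(mc.bin_index[s]), int(mc.bin_index[e])
        dces.append(DCE(
            chrom=grid.chrom,
            start_bin=s,
            end_bin=e,
            start=int(grid.bin_start(orig_lo)),
            end=int(grid.bin_end(orig_hi)),
            mean_signal=float(sig.values[s : e + 1].mean()),
            left_p=float(lp),
            right_p=float(rp),
            genes=_genes_in_range(binned, orig_lo, orig_hi),
        ))
    return DCESet(group=group, dces=dces, params=params)


def mean_intra_dce_correlation(dceset: DCESet, mc: MaskedCorrelation) -> float:
    """Mean off-diagonal masked rho inside the set's domains (one chromosome)."""
    vals = []
    for d in dceset.on(mc.chrom):
        block = mc.masked_rho[d.start_bin : d.end_bin + 1, d.start_bin : d.end_bin + 1]
        iu = np.triu_indices(block.shape[0], k=1)
        if len(iu[0]):
            vals.append(block[iu].mean())
    if not vals:
        raise ValueError("no DCEs with at least one within pair")
    return float(np.mean(vals))


def tune_window(
    binned: BinnedExpression,
    group_samples: list[str],
    candidate_ws: list[int],
    group: str = "",
    **call_kwargs,
) -> int:
    """Pick the window size maximizing mean within-DCE correlation.

    The masked matrix is computed once (it does not depend on ``w``);
    each candidate re-runs only the calling stages.  Ties go to the
    smallest window.
    """
    if not candidate_ws:
        raise ValueError("need at least one candidate window size")
    mc = permutation_mask(
        binned, group_samples, group=group,
        n_perm=call_kwargs.get("n_perm", 1000),
        alpha=call_kwargs.get("mask_alpha", 0.05),
        seed=call_kwargs.get("seed", 0),
        two_sided=call_kwargs.get("two_sided", True),
    )
    best_w, best_score = None, -np.inf
    for w in sorted(candidate_ws):
        dceset = call_dces(binned, group_samples, group=group, mc=mc, w=w, **call_kwargs)
        try:
            score = mean_intra_dce_correlation(dceset, mc)
        except ValueError:
            continue
        if score > best_score:
            best_w, best_score = w, score
    if best_w is None:
        raise ValueError("no DCEs called for any candidate window size")
    return best_w


def write_bed(dceset: DCESet, path: str) -> None:
    """BED6+ export: name = DCE id, score = 1000 * mean_signal clamped to [0,1000]."""
    with open(path, "w") as fh:
        for i, d in enumerate(dceset.dces):
            score = int(np.clip(round(1000 * d.mean_signal), 0, 1000))
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\t{dceset.group or 'dce'}_{i}\t"
                f"{score}\t.\t{d.left_p:.6g}\t{d.right_p:.6g}\n"
            )


def read_bed(path: str, group: str = "") -> DCESet:
    """Read a DCE BED file written by :func:`write_bed` (or any BED3+)."""
    dces = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            score = float(f[4]) / 1000 if len(f) > 4 else 0.0
            dces.append(DCE(
                chrom=f[0], start_bin=-1, end_bin=-1,
                start=int(f[1]), end=int(f[2]),
                mean_signal=score,
                left_p=float(f[6]) if len(f) > 6 else float("nan"),
                right_p=float(f[7]) if len(f) > 7 else float("nan"),
            ))
    return DCESet(group=group, dces=dces)
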