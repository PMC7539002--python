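"""Permutation enrichment of domains in gene sets and interval tracks,
enhancer-promoter link disruption, and cell-type proportion entropy.

The null model for enrichment re-places the domain intervals uniformly
at random within their own chromosomes, restricted to the *eligible
territory* -- the expressed, gene-containing bins that domain calling
operated on -- preserving interval sizes and forbidding overlaps.
Empirical p-values use the (k+1)/(n+1) estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import entropy as _scipy_entropy
from statsmodels.stats.multitest import multipletests

from .binning import BinGrid, BinnedExpression
from .detection import DCESet
from .stats import rank_sum_test

__all__ = [
    "Territory",
    "EnrichmentResult",
    "geneset_enrichment",
    "track_enrichment",
    "ep_disruption",
    "shannon_entropy",
    "entropy_group_test",
]


@dataclass
class Territory:
    """Eligible placement space: per-chromosome surviving bins of a grid."""

    grids: dict[str, BinGrid]
    bins: dict[str, np.ndarray]  # chrom -> original grid bin ids, sorted

    @classmethod
    def from_binned(
        cls, binned: dict[str, BinnedExpression], group_samples: list[str]
    ) -> "Territory":
        from .correlation import surviving_bins

        grids, bins = {}, {}
        for chrom, be in binned.items():
            grids[chrom] = be.grid
            bins[chrom] = surviving_bins(be, group_samples)
        return cls(grids=grids, bins=bins)

    def n_eligible(self, chrom: str) -> int:
        return len(self.bins[chrom])

    def interval_to_positions(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Eligible-axis positions of bins fully inside a genomic interval."""
        grid = self.grids[chrom]
        b = self.bins[chrom]
        return np.flatnonzero((grid.bin_start(b) >= start) & (grid.bin_end(b) <= end))

    def overlap_positions(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Eligible-axis positions of bins overlapping a genomic interval by >= 1 bp."""
        grid = self.grids[chrom]
        b = self.bins[chrom]
        return np.flatnonzero((grid.bin_start(b) < end) & (grid.bin_end(b) > start))


def _dce_spans(dces: DCESet | list, territory: Territory) -> dict[str, list[tuple[int, int]]]:
    """Domains as (start, length) spans on each chromosome's eligible axis."""
    spans: dict[str, list[tuple[int, int]]] = {}
    items = dces.dces if isinstance(dces, DCESet) else dces
    for d in items:
        if d.chrom not in territory.bins:
            continue
        pos = territory.interval_to_positions(d.chrom, d.start, d.end)
        if len(pos):
            spans.setdefault(d.chrom, []).append((int(pos[0]), int(len(pos))))
    return spans


def _random_placement(
    rng: np.random.Generator, n_eligible: int, lengths: list[int]
) -> list[tuple[int, int]]:
    """Uniform non-overlapping placement of intervals on an axis of bins.

    Stars-and-bars: sample the gap composition uniformly and permute the
    interval order, so every non-overlapping arrangement is equally
    likely.  Returns (start, length) spans.
    """
    k = len(lengths)
    free = n_eligible - sum(lengths)
    if free < 0:
        raise ValueError("intervals do not fit in the eligible territory")
    order = rng.permutation(k)
    cut = np.sort(rng.choice(free + k, size=k, replace=False))
    gaps = np.diff(np.concatenate([[-1], cut])) - 1
    spans = []
    pos = 0
    for slot, g in zip(order, gaps):
        pos += int(g)
        spans.append((pos, lengths[slot]))
        pos += lengths[slot]
    return spans


@dataclass
class EnrichmentResult:
    """Observed statistic versus its randomized-placement null."""

    observed: float
    null_mean: float
    null_sd: float
    z: float
    p_enrich: float
    p_deplete: float
    p_two_sided: float
    n_perm: int
    extra: dict = field(default_factory=dict)


def _summarize_null(observed: float, null: np.ndarray) -> EnrichmentResult:
    n = len(null)
    mean = float(null.mean())
    sd = float(null.std(ddof=0))
    z = (observed - mean) / sd if sd > 0 else (0.0 if observed == mean else np.inf * np.sign(observed - mean))
    p_en = (int((null >= observed).sum()) + 1) / (n + 1)
    p_de = (int((null <= observed).sum()) + 1) / (n + 1)
    return EnrichmentResult(
        observed=float(observed), null_mean=mean, null_sd=sd, z=float(z),
        p_enrich=p_en, p_deplete=p_de, p_two_sided=min(1.0, 2 * min(p_en, p_de)),
        n_perm=n,
    )


def geneset_enrichment(
    dces: DCESet | list,
    gene_set: list[str],
    genes: pd.DataFrame,
    territory: Territory,
    n_perm: int = 1000,
    seed: int | None = 0,
    gene_anchor: str = "span",
) -> EnrichmentResult:
    """Are the set's genes inside the domains more often than chance?

    The observed statistic is the number of set genes whose anchor (span
    by default, 5' bin with ``gene_anchor='tss'``) touches a domain bin;
    the null re-places the domain intervals ``n_perm`` times within the
    eligible territory of their chromosomes.
    """
    sub = genes[genes["gene_name"].isin(set(gene_set))]
    gene_pos: list[tuple[str, np.ndarray]] = []
    for name, chrom, start, end, strand in zip(
        sub["gene_name"], sub["chrom"], sub["start"], sub["end"], sub["strand"]
    ):
        if chrom not in territory.bins:
            continue
        if gene_anchor == "tss":
            tss = start if strand != "-" else end - 1
            pos = territory.overlap_positions(chrom, tss, tss + 1)
        else:
            pos = territory.overlap_positions(chrom, start, end)
        if len(pos):
            gene_pos.append((chrom, pos))
    if not gene_pos:
        raise ValueError("no gene of the set lies on any covered chromosome")

    spans = _dce_spans(dces, territory)

    def count(span_map: dict[str, list[tuple[int, int]]]) -> int:
        covered = {
            chrom: np.sort(np.concatenate(
                [np.arange(s, s + l) for s, l in sp]
            )) if sp else np.array([], dtype=int)
            for chrom, sp in span_map.items()
        }
        c = 0
        for chrom, pos in gene_pos:
            cov = covered.get(chrom)
            if cov is not None and len(cov) and np.isin(pos, cov).any():
                c += 1
        return c

    observed = count(spans)
    root = np.random.SeedSequence(entropy=seed)
    null = np.empty(n_perm)
    lengths = {chrom: [l for _, l in sp] for chrom, sp in spans.items()}
    for k in range(n_perm):
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=root.entropy, spawn_key=(k,)
        ))
        placed = {
            chrom: _random_placement(rng, territory.n_eligible(chrom), ls)
            for chrom, ls in lengths.items()
        }
        null[k] = count(placed)
    return _summarize_null(observed, null)


def track_enrichment(
    dces: DCESet | list,
    track: pd.DataFrame,
    territory: Territory,
    n_perm: int = 1000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Per-label bp-overlap enrichment against an interval track (BED4-style).

    ``track`` needs columns chrom, start, end, label.  Observed and null
    statistics are base-pair overlaps between domain bins and the label's
    intervals; labels absent from the covered chromosomes are reported
    untestable (NaN p-values) rather than zero.  Benjamini-Hochberg
    correction is applied across testable labels.
    """
    labels = sorted(track["label"].unique())
    # bp overlap of each eligible bin with each label's intervals
    per_pos: dict[str, dict[str, np.ndarray]] = {}
    for chrom, bins in territory.bins.items():
        grid = territory.grids[chrom]
        starts, ends = grid.bin_start(bins), grid.bin_end(bins)
        per_pos[chrom] = {}
        tsub = track[track["chrom"] == chrom]
        for lab in labels:
            lsub = tsub[tsub["label"] == lab]
            ov = np.zeros(len(bins))
            for s, e in zip(lsub["start"], lsub["end"]):
                ov += np.clip(np.minimum(ends, e) - np.maximum(starts, s), 0, None)
            per_pos[chrom][lab] = ov

    spans = _dce_spans(dces, territory)
    lengths = {chrom: [l for _, l in sp] for chrom, sp in spans.items()}

    def overlaps(span_map: dict[str, list[tuple[int, int]]]) -> dict[str, float]:
        tot = {lab: 0.0 for lab in labels}
        for chrom, sp in span_map.items():
            for s, l in sp:
                for lab in labels:
                    tot[lab] += per_pos[chrom][lab][s : s + l].sum()
        return tot

    observed = overlaps(spans)
    root = np.random.SeedSequence(entropy=seed)
    null = {lab: np.empty(n_perm) for lab in labels}
    for k in range(n_perm):
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=root.entropy, spawn_key=(k,)
        ))
        placed = {
            chrom: _random_placement(rng, territory.n_eligible(chrom), ls)
            for chrom, ls in lengths.items()
        }
        o = overlaps(placed)
        for lab in labels:
            null[lab][k] = o[lab]

    rows = []
    for lab in labels:
        testable = any(per_pos[c][lab].sum() > 0 for c in per_pos)
        if not testable:
            rows.append({
                "label": lab, "observed_bp": observed[lab], "null_mean": np.nan,
                "null_sd": np.nan, "z": np.nan, "p_two_sided": np.nan,
                "testable": False,
            })
            continue
        res = _summarize_null(observed[lab], null[lab])
        rows.append({
            "label": lab, "observed_bp": res.observed, "null_mean": res.null_mean,
            "null_sd": res.null_sd, "z": res.z, "p_two_sided": res.p_two_sided,
            "testable": True,
        })
    out = pd.DataFrame(rows)
    mask = out["testable"].to_numpy()
    out["p_adjusted"] = np.nan
    if mask.any():
        out.loc[mask, "p_adjusted"] = multipletests(
            out.loc[mask, "p_two_sided"], method="fdr_bh"
        )[1]
    return out


def _nested_in(chrom: str, lo: int, hi: int, dceset: DCESet) -> bool:
    return any(
        d.chrom == chrom and d.start <= lo and d.end >= hi for d in dceset.dces
    )


def ep_disruption(
    links: pd.DataFrame, ref: DCESet, query: DCESet
) -> tuple[pd.DataFrame, dict]:
    """Enhancer-promoter links nested in a reference domain but not in the query.

    ``links`` needs columns gene_name, chrom, promoter_pos, enh_start,
    enh_end (cell_type optional).  A link is *nested* in a set when the
    promoter position and the whole enhancer interval fall inside one
    domain.  Links never nested in the reference are not evaluable and
    excluded from the disruption denominator; malformed links are skipped
    with a warning count.
    """
    rows = []
    skipped = 0
    for rec in links.itertuples(index=False):
        try:
            prom = int(rec.promoter_pos)
            es, ee = int(rec.enh_start), int(rec.enh_end)
            if es >= ee or prom < 0:
                raise ValueError
        except (ValueError, TypeError):
            skipped += 1
            continue
        lo = min(prom, es)
        hi = max(prom + 1, ee)
        in_ref = _nested_in(rec.chrom, lo, hi, ref)
        if not in_ref:
            status = "not_evaluable"
        elif _nested_in(rec.chrom, lo, hi, query):
            status = "preserved"
        else:
            status = "disrupted"
        rows.append({
            "gene_name": rec.gene_name, "chrom": rec.chrom,
            "promoter_pos": prom, "enh_start": es, "enh_end": ee,
            "status": status,
        })
    if skipped:
        warnings.warn(f"{skipped} malformed enhancer-promoter links skipped")
    df = pd.DataFrame(rows, columns=[
        "gene_name", "chrom", "promoter_pos", "enh_start", "enh_end", "status",
    ])
    evaluable = df[df["status"] != "not_evaluable"]
    n_disrupted = int((evaluable["status"] == "disrupted").sum())
    summary = {
        "n_links": len(df),
        "n_skipped": skipped,
        "n_evaluable": len(evaluable),
        "n_disrupted": n_disrupted,
        "fraction_disrupted": n_disrupted / len(evaluable) if len(evaluable) else float("nan"),
        "disrupted_genes": sorted(evaluable.loc[evaluable["status"] == "disrupted", "gene_name"].unique()),
    }
    return df, summary


def shannon_entropy(p) -> float:
    """Shannon entropy H = -sum p_i log2 p_i, in bits, of a proportion vector."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("negative proportion")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"proportions sum to {p.sum()}, not 1")
    return float(_scipy_entropy(p, base=2))


def entropy_group_test(healthy, patient) -> float:
    """Two-sided rank-sum p-value comparing two entropy distributions."""
    healthy = np.asarray(healthy, dtype=float)
    patient = np.asarray(patient, dtype=float)
    if len(healthy) < 3 or len(patient) < 3:
        raise ValueError("need at least 3 values per group")
    return rank_sum_test(healthy, patient, alternative="two-sided")
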