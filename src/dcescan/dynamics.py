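"""Comparison of two domain segmentations: dynamics classes, similarity, disruptors.

Given a reference segmentation (e.g. healthy) and a query segmentation
(e.g. one disease-activity group), every domain receives exactly one of
seven labels describing how it changed:

    intact, depleted, emerged, split, merged, expanded, contracted

Labels are assigned from the bipartite overlap graph with a fixed
precedence: no partner (depleted / emerged), one-to-many events
(split / merged), then one-to-one pairs resolved by Jaccard similarity
and relative length.  Two segmentation-level similarity metrics are
provided: per-pair Jaccard indices and the BP distance, a partition
metric that weights disagreement by relative segment size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import DCE, DCESet

__all__ = [
    "LABELS",
    "DynamicsReport",
    "jaccard",
    "bp_distance",
    "genome_bp_distance",
    "classify_dces",
    "find_disruptors",
    "disruptor_report",
    "coverage_stats",
]

LABELS = ("intact", "depleted", "emerged", "split", "merged", "expanded", "contracted")


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Intersection-over-union of two half-open intervals, in bp."""
    if a[1] <= a[0] or b[1] <= b[0]:
        raise ValueError("zero-length interval")
    inter = _overlap(a, b)
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union


def _partition(intervals: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    """Complete a sorted interval set into a partition of [0, length)."""
    segs = []
    pos = 0
    for s, e in sorted(intervals):
        if s < 0 or e > length:
            raise ValueError("interval outside [0, chromosome length)")
        if s > pos:
            segs.append((pos, s))
        segs.append((s, e))
        pos = e
    if pos < length:
        segs.append((pos, length))
    return segs


def bp_distance(
    seg_a: list[tuple[int, int]] | DCESet,
    seg_b: list[tuple[int, int]] | DCESet,
    chrom_length: int,
    chrom: str | None = None,
) -> float:
    """BP distance between two segmentations of one chromosome.

    Both sets are completed into partitions of ``[0, chrom_length)`` by
    treating uncovered regions as background segments.  The distance is

        d(A, B) = 1 - (1/N) * sum_{a, b} |a n b|^2 / max(|a|, |b|)

    over all overlapping segment pairs; it is symmetric, lies in [0, 1]
    and is 0 exactly for identical partitions.
    """
    if isinstance(seg_a, DCESet):
        if chrom is None:
            raise ValueError("chrom required when passing DCESets")
        seg_a = [(d.start, d.end) for d in seg_a.on(chrom)]
    if isinstance(seg_b, DCESet):
        seg_b = [(d.start, d.end) for d in seg_b.on(chrom)]
    if chrom_length <= 0:
        raise ValueError("inconsistent chromosome length")
    pa = _partition(seg_a, chrom_length)
    pb = _partition(seg_b, chrom_length)
    total = 0.0
    for a in pa:
        for b in pb:
            if b[1] <= a[0]:
                continue
            if b[0] >= a[1]:
                break
            o = _overlap(a, b)
            if o:
                total += o * o / max(a[1] - a[0], b[1] - b[0])
    return 1.0 - total / chrom_length


def genome_bp_distance(
    ref: DCESet, query: DCESet, chrom_lengths: dict[str, int]
) -> tuple[dict[str, float], float]:
    """Per-chromosome BP distances plus their length-weighted mean."""
    per_chrom = {}
    wsum = tsum = 0.0
    for chrom, length in chrom_lengths.items():
        d = bp_distance(ref, query, length, chrom=chrom)
        per_chrom[chrom] = d
        wsum += d * length
        tsum += length
    return per_chrom, wsum / tsum if tsum else float("nan")


@dataclass
class DynamicsReport:
    """Seven-way classification of every domain in a two-group comparison."""

    ref_labels: dict[int, str]
    query_labels: dict[int, str]
    pairs: list[tuple[int, int, int, float]]   # (ref idx, query idx, overlap bp, jaccard)
    events: list[dict] = field(default_factory=list)
    intact_jaccard: float = 0.8

    def counts(self, side: str = "ref") -> dict[str, int]:
        labels = self.ref_labels if side == "ref" else self.query_labels
        out = {lab: 0 for lab in LABELS}
        for lab in labels.values():
            out[lab] += 1
        return out

    def ratios(self, side: str = "ref") -> dict[str, float]:
        c = self.counts(side)
        total = sum(c.values())
        return {k: v / total for k, v in c.items()} if total else c

    def to_frame(self) -> pd.DataFrame:
        partner: dict[tuple[str, int], list[int]] = {}
        jac: dict[tuple[str, int], list[float]] = {}
        for ri, qi, _, j in self.pairs:
            partner.setdefault(("ref", ri), []).append(qi)
            partner.setdefault(("query", qi), []).append(ri)
            jac.setdefault(("ref", ri), []).append(j)
            jac.setdefault(("query", qi), []).append(j)
        rows = []
        for side, labels in (("ref", self.ref_labels), ("query", self.query_labels)):
            for i, lab in labels.items():
                rows.append({
                    "side": side,
                    "dce_index": i,
                    "label": lab,
                    "partners": ",".join(map(str, partner.get((side, i), []))),
                    "best_jaccard": max(jac.get((side, i), [0.0]), default=0.0),
                })
        return pd.DataFrame(rows)


def _assert_internally_disjoint(dceset: DCESet) -> None:
    by_chrom: dict[str, int] = {}
    for d in sorted(dceset.dces, key=lambda d: (d.chrom, d.start)):
        if d.chrom in by_chrom and d.start < by_chrom[d.chrom]:
            raise ValueError(f"overlapping DCEs within one set on {d.chrom}")
        by_chrom[d.chrom] = d.end


def classify_dces(
    ref: DCESet,
    query: DCESet,
    intact_jaccard: float = 0.8,
    min_overlap_frac: float = 0.0,
    tolerance_bp: int = 10_000,
) -> DynamicsReport:
    """Label every reference and query domain with its dynamics class.

    Precedence: a domain with no overlapping partner is depleted (ref
    side) or emerged (query side); a domain overlapping >= 2 partners
    triggers a split or merged event (split when the partners' union
    stays within the single domain +- ``tolerance_bp``, which guards a
    fragmentation against partners that reach far outside it); remaining
    one-to-one pairs are intact when Jaccard >= ``intact_jaccard``, else
    expanded / contracted by the query's relative length (equal lengths
    count as intact).  ``min_overlap_frac`` discards contacts smaller
    than that fraction of the shorter interval (>= 1 bp always required).
    """
    _assert_internally_disjoint(ref)
    _assert_internally_disjoint(query)
    rdces, qdces = ref.dces, query.dces

    pairs: list[tuple[int, int, int, float]] = []
    r_partners: dict[int, list[int]] = {i: [] for i in range(len(rdces))}
    q_partners: dict[int, list[int]] = {i: [] for i in range(len(qdces))}
    for ri, r in enumerate(rdces):
        for qi, q in enumerate(qdces):
            if q.chrom != r.chrom:
                continue
            o = _overlap((r.start, r.end), (q.start, q.end))
            if o < 1 or o < min_overlap_frac * min(r.length, q.length):
                continue
            pairs.append((ri, qi, o, jaccard((r.start, r.end), (q.start, q.end))))
            r_partners[ri].append(qi)
            q_partners[qi].append(ri)

    ref_labels: dict[int, str] = {}
    query_labels: dict[int, str] = {}
    events: list[dict] = []

    for ri in range(len(rdces)):
        if not r_partners[ri]:
            ref_labels[ri] = "depleted"
    for qi in range(len(qdces)):
        if not q_partners[qi]:
            query_labels[qi] = "emerged"

    def one_to_many(side: str, xi: int, partners: list[int]) -> None:
        x = rdces[xi] if side == "ref" else qdces[xi]
        others = [qdces[p] for p in partners] if side == "ref" else [rdces[p] for p in partners]
        union_lo = min(o.start for o in others)
        union_hi = max(o.end for o in others)
        nested = union_lo >= x.start - tolerance_bp and union_hi <= x.end + tolerance_bp
        # a fragmentation nests inside the single domain: split seen from the
        # reference, merged seen from the query; swap-symmetric by design
        if side == "ref":
            label = "split" if nested else "merged"
            ev = {"type": label, "ref": [xi], "query": partners}
        else:
            label = "merged" if nested else "split"
            ev = {"type": label, "ref": partners, "query": [xi]}
        changed = False
        for i in ev["ref"]:
            if i not in ref_labels:
                ref_labels[i] = label
                changed = True
        for i in ev["query"]:
            if i not in query_labels:
                query_labels[i] = label
                changed = True
        if changed:
            events.append(ev)

    for ri, ps in r_partners.items():
        if len(ps) >= 2 and ri not in ref_labels:
            one_to_many("ref", ri, ps)
    for qi, ps in q_partners.items():
        if len(ps) >= 2 and qi not in query_labels:
            one_to_many("query", qi, ps)

    for ri, qi, o, j in pairs:
        if ri in ref_labels or qi in query_labels:
            continue
        if len(r_partners[ri]) == 1 and len(q_partners[qi]) == 1:
            if j >= intact_jaccard or qdces[qi].length == rdces[ri].length:
                label = "intact"
            elif qdces[qi].length > rdces[ri].length:
                label = "expanded"
            else:
                label = "contracted"
            ref_labels[ri] = label
            query_labels[qi] = label

    # partners consumed by an event on the other side; fall back to the
    # pairwise rule against their best partner
    for ri, qi, o, j in sorted(pairs, key=lambda t: -t[2]):
        if ri not in ref_labels:
            ref_labels[ri] = query_labels.get(qi, "intact")
        if qi not in query_labels:
            query_labels[qi] = ref_labels[ri]

    assert set(ref_labels) == set(range(len(rdces)))
    assert set(query_labels) == set(range(len(qdces)))
    assert set(ref_labels.values()) | set(query_labels.values()) <= set(LABELS)
    return DynamicsReport(
        ref_labels=ref_labels,
        query_labels=query_labels,
        pairs=pairs,
        events=events,
        intact_jaccard=intact_jaccard,
    )


def find_disruptors(
    ref_dce: DCE, query_partners: list[DCE], genes: pd.DataFrame,
    all_query: list[DCE] | None = None,
) -> list[str]:
    """Genes stranded in the gap(s) of a split event.

    A disruptor (i) overlaps the reference domain, (ii) overlaps no query
    domain, and (iii) intersects the area between the query partners (the
    split locus).  ``all_query`` defaults to the partners themselves.
    """
    if len(query_partners) < 2:
        raise ValueError("disruptors are defined only for split events (>= 2 partners)")
    if all_query is None:
        all_query = query_partners
    partners = sorted(query_partners, key=lambda d: d.start)
    gaps = []
    for left, right in zip(partners, partners[1:]):
        lo = max(left.end, ref_dce.start)
        hi = min(right.start, ref_dce.end)
        if lo < hi:
            gaps.append((lo, hi))

    sub = genes[genes["chrom"] == ref_dce.chrom]
    out = []
    for name, s, e in zip(sub["gene_name"], sub["start"], sub["end"]):
        if _overlap((s, e), (ref_dce.start, ref_dce.end)) < 1:
            continue
        if any(
            q.chrom == ref_dce.chrom and _overlap((s, e), (q.start, q.end)) >= 1
            for q in all_query
        ):
            continue
        if any(_overlap((s, e), g) >= 1 for g in gaps):
            out.append(name)
    return out


def disruptor_report(
    report: DynamicsReport, ref: DCESet, query: DCESet, genes: pd.DataFrame
) -> pd.DataFrame:
    """Disruptor genes for every split event in a dynamics report."""
    rows = []
    for ev in report.events:
        if ev["type"] != "split" or len(ev["ref"]) != 1:
            continue
        ri = ev["ref"][0]
        partners = [query.dces[qi] for qi in ev["query"]]
        names = find_disruptors(ref.dces[ri], partners, genes, all_query=query.dces)
        for g in names:
            rows.append({
                "ref_index": ri,
                "chrom": ref.dces[ri].chrom,
                "query_indices": ",".join(map(str, ev["query"])),
                "gene_name": g,
            })
    return pd.DataFrame(rows, columns=["ref_index", "chrom", "query_indices", "gene_name"])


def coverage_stats(
    dceset: DCESet,
    eligible_bins: dict[str, np.ndarray],
    grids: dict[str, "object"],
) -> dict:
    """Fraction of eligible (expressed) bins organized into domains.

    ``eligible_bins`` maps chromosome -> original grid bin ids of
    surviving bins; ``grids`` maps chromosome -> BinGrid.
    """
    per_chrom = {}
    covered_total = eligible_total = 0
    sizes = [d.length for d in dceset.dces]
    for chrom, bins in eligible_bins.items():
        grid = grids[chrom]
        starts = grid.bin_start(bins)
        ends = grid.bin_end(bins)
        inside = np.zeros(len(bins), dtype=bool)
        for d in dceset.on(chrom):
            inside |= (starts >= d.start) & (ends <= d.end)
        per_chrom[chrom] = float(inside.mean()) if len(bins) else float("nan")
        covered_total += int(inside.sum())
        eligible_total += len(bins)
    return {
        "per_chrom_fraction": per_chrom,
        "genome_fraction": covered_total / eligible_total if eligible_total else float("nan"),
        "n_dces": len(dceset.dces),
        "sizes_bp": sizes,
    }
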