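"""Input loading, gene filtering, normalization and cohort stratification.

The preparation stage turns three plain-text inputs -- a GTF gene
annotation, a gene x sample raw-count matrix, and a sample metadata
table -- into the filtered, normalized expression matrix that the
binning stage consumes.  The fixed composition order is:

    biotype filter -> duplicate filter -> nonzero filter -> RLE -> length
    normalization

Gene coordinates are converted to 0-based half-open on read and stay
that way throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_EXCLUDED_TYPES",
    "GENE_COLUMNS",
    "PrepResult",
    "read_gtf",
    "read_counts",
    "read_metadata",
    "filter_genes",
    "drop_zero_genes",
    "rle_normalize",
    "length_normalize",
    "stratify_samples",
    "prepare",
    "write_prep",
    "read_prep",
]

#: Biotypes excluded from the analysis (normalized spelling; see
#: :func:`_normalize_biotype`).
DEFAULT_EXCLUDED_TYPES = frozenset({
    "pseudogene",
    "processed_transcript",
    "polymorphic_pseudogene",
    "antisense",
    "sense_intronic",
    "sense_overlapping",
    "ig_v_pseudogene",
    "ig_c_pseudogene",
    "tr_v_pseudogene",
    "tr_j_pseudogene",
    "ig_j_pseudogene",
    "non_coding",
    "mt_trna",
    "mt_rrna",
})

GENE_COLUMNS = ["gene_name", "chrom", "start", "end", "strand", "gene_type"]


def _normalize_biotype(t: str) -> str:
    """Canonical biotype spelling: lowercase, spaces/hyphens -> underscores."""
    return str(t).strip().lower().replace(" ", "_").replace("-", "_")


def _validate_gene_table(genes: pd.DataFrame) -> None:
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    if len(genes) and not (genes["start"] < genes["end"]).all():
        bad = genes.loc[genes["start"] >= genes["end"], "gene_name"].tolist()
        raise ValueError(f"genes with start >= end (after 0-based conversion): {bad[:5]}")


def read_gtf(path: str) -> pd.DataFrame:
    """Read gene-level features from a GTF into a gene table.

    Uses :func:`pyranges.read_gtf`, which converts 1-based inclusive GTF
    coordinates to the 0-based half-open convention used internally.
    Only ``gene`` features are kept.  A missing ``gene_type`` attribute is
    recorded as the sentinel biotype ``"__missing__"`` which the default
    filter treats as excluded (conservative).
    """
    import pyranges as pr

    df = pr.read_gtf(path).df
    if "Feature" in df.columns:
        df = df[df["Feature"] == "gene"]
    if df.empty:
        raise ValueError(f"no gene features found in {path}")
    if "gene_name" not in df.columns:
        raise ValueError(f"GTF {path} lacks gene_name attributes")
    gene_type = df["gene_type"] if "gene_type" in df.columns else pd.Series(
        "__missing__", index=df.index
    )
    out = pd.DataFrame({
        "gene_name": df["gene_name"].astype(str),
        "chrom": df["Chromosome"].astype(str),
        "start": df["Start"].astype(np.int64),
        "end": df["End"].astype(np.int64),
        "strand": df["Strand"].astype(str) if "Strand" in df.columns else ".",
        "gene_type": gene_type.fillna("__missing__").astype(str),
    }).reset_index(drop=True)
    _validate_gene_table(out)
    return out


def read_counts(path: str) -> pd.DataFrame:
    """Read a raw count TSV (first column gene_name, header sample ids)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    counts.index.name = "gene_name"
    if counts.shape[1] == 0:
        raise ValueError(f"count matrix {path} has no sample columns")
    if (counts.values < 0).any():
        raise ValueError("count matrix contains negative entries")
    return counts


def read_metadata(path: str) -> pd.DataFrame:
    """Read sample metadata TSV with columns sample_id and group and/or sledai."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise ValueError("metadata must have a sample_id column")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dup[:5]}")
    if "group" not in meta.columns and "sledai" not in meta.columns:
        raise ValueError("metadata must have a group or sledai column")
    return meta


def filter_genes(
    genes: pd.DataFrame,
    excluded_types: frozenset | set = DEFAULT_EXCLUDED_TYPES,
) -> pd.DataFrame:
    """Drop excluded biotypes and ambiguous gene names.

    Genes whose (normalized) biotype is in ``excluded_types`` are removed,
    as are gene names annotated on more than one chromosome.  Duplicated
    names on a single chromosome are collapsed to their span union so that
    gene_name is unique afterwards.  Relative order is preserved and the
    operation is idempotent.
    """
    if genes.empty:
        raise ValueError("no genes survive filtering")
    _validate_gene_table(genes)
    excluded = {_normalize_biotype(t) for t in excluded_types} | {"__missing__"}
    kept = genes[~genes["gene_type"].map(_normalize_biotype).isin(excluded)]

    # names present on >1 chromosome are ambiguous and dropped entirely
    nchrom = kept.groupby("gene_name")["chrom"].nunique()
    ambiguous = set(nchrom.index[nchrom > 1])
    kept = kept[~kept["gene_name"].isin(ambiguous)]

    if kept["gene_name"].duplicated().any():
        # same-chromosome duplicates: collapse to the union span
        agg = kept.groupby("gene_name", sort=False).agg(
            chrom=("chrom", "first"),
            start=("start", "min"),
            end=("end", "max"),
            strand=("strand", "first"),
            gene_type=("gene_type", "first"),
        ).reset_index()
        order = kept.drop_duplicates("gene_name")["gene_name"]
        kept = agg.set_index("gene_name").loc[order].reset_index()

    if kept.empty:
        raise ValueError("no genes survive filtering")
    return kept.reset_index(drop=True)


def drop_zero_genes(counts: pd.DataFrame) -> pd.DataFrame:
    """Remove genes whose counts are zero in every sample."""
    return counts.loc[(counts != 0).any(axis=1)]


def rle_normalize(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Relative log expression (median-of-ratios) library-size correction.

    The per-sample size factor is the median, over genes with a positive
    geometric mean across samples, of count / geometric mean; normalized
    values are counts divided column-wise by the size factor.

    Returns ``(normalized, size_factors)``.
    """
    values = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(values)
    all_positive = np.isfinite(logs).all(axis=1)
    if not all_positive.any():
        raise ValueError("RLE reference undefined: no gene positive in all samples")
    log_gm = logs[all_positive].mean(axis=1)
    ratios = logs[all_positive] - log_gm[:, None]
    size_factors = np.exp(np.median(ratios, axis=0))
    sf = pd.Series(size_factors, index=counts.columns, name="size_factor")
    normalized = counts / sf
    return normalized, sf


def length_normalize(
    norm: pd.DataFrame, genes: pd.DataFrame, scale: float = 1000.0,
    length_mode: str = "span",
) -> pd.DataFrame:
    """Divide expression by gene length, in units of ``scale`` bp (default kb).

    ``length_mode='span'`` uses the annotated gene-body span end - start.
    (An exon-union mode would need exon features, which the gene-level
    table does not carry; span is the mode used throughout.)
    """
    if length_mode != "span":
        raise NotImplementedError(
            "length_mode 'exon_union' requires exon features; only 'span' is available"
        )
    if scale <= 0:
        raise ValueError("scale must be positive")
    lengths = (genes["end"] - genes["start"]).to_numpy(dtype=float)
    length_map = pd.Series(lengths, index=genes["gene_name"])
    missing = norm.index.difference(length_map.index)
    if len(missing):
        raise ValueError(f"genes without annotated length: {sorted(missing)[:10]}")
    lens = length_map.reindex(norm.index)
    return norm.mul(scale / lens, axis=0)


def stratify_samples(meta: pd.DataFrame) -> pd.Series:
    """Assign each sample a disease-activity group from its SLEDAI score.

    Healthy samples pass through unchanged; patients are binned by SLEDAI:
    low <= 2, intermediate 3-8, high > 8.  Returns a Series indexed by
    sample_id with values in {healthy, low, intermediate, high}.
    """
    if "sledai" in meta.columns:
        sledai = pd.to_numeric(meta["sledai"], errors="coerce")
        if (sledai.dropna() < 0).any():
            raise ValueError("negative SLEDAI score")
    else:
        sledai = pd.Series(np.nan, index=meta.index)

    given = meta["group"].astype(str) if "group" in meta.columns else pd.Series(
        "", index=meta.index
    )
    groups = []
    for g, s in zip(given, sledai):
        if g == "healthy":
            groups.append("healthy")
            continue
        if math.isnan(s):
            if g in {"low", "intermediate", "high"}:
                groups.append(g)
                continue
            raise ValueError("non-healthy sample without SLEDAI score or group")
        if s <= 2:
            groups.append("low")
        elif s <= 8:
            groups.append("intermediate")
        else:
            groups.append("high")
    out = pd.Series(groups, index=meta["sample_id"].to_numpy(), name="group")
    out.index.name = "sample_id"
    return out


@dataclass
class PrepResult:
    """Output bundle of the preparation stage."""

    genes: pd.DataFrame
    normalized: pd.DataFrame
    size_factors: pd.Series
    groups: pd.Series
    provenance: dict = field(default_factory=dict)

    def samples_in(self, group: str) -> list[str]:
        ids = [s for s in self.normalized.columns if self.groups.get(s) == group]
        if not ids:
            raise ValueError(f"no samples in group {group!r}")
        return ids


def write_prep(prep: PrepResult, out_dir: str) -> None:
    """Write a prepared dataset as a directory of TSV + JSON (self-describing)."""
    import json
    import os

    os.makedirs(out_dir, exist_ok=True)
    prep.genes.to_csv(os.path.join(out_dir, "genes.tsv"), sep="\t", index=False)
    prep.normalized.to_csv(os.path.join(out_dir, "normalized.tsv"), sep="\t")
    prep.size_factors.to_csv(os.path.join(out_dir, "size_factors.tsv"), sep="\t")
    prep.groups.to_csv(os.path.join(out_dir, "groups.tsv"), sep="\t")
    with open(os.path.join(out_dir, "prep.json"), "w") as fh:
        json.dump(prep.provenance, fh, indent=2)


def read_prep(in_dir: str) -> PrepResult:
    """Read a prepared dataset written by :func:`write_prep`."""
    import json
    import os

    genes = pd.read_csv(os.path.join(in_dir, "genes.tsv"), sep="\t")
    normalized = pd.read_csv(os.path.join(in_dir, "normalized.tsv"), sep="\t", index_col=0)
    sf = pd.read_csv(os.path.join(in_dir, "size_factors.tsv"), sep="\t", index_col=0).iloc[:, 0]
    groups = pd.read_csv(
        os.path.join(in_dir, "groups.tsv"), sep="\t", index_col=0, dtype=str
    ).iloc[:, 0]
    with open(os.path.join(in_dir, "prep.json")) as fh:
        prov = json.load(fh)
    return PrepResult(genes, normalized, sf, groups, prov)


def prepare(
    genes: pd.DataFrame,
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    excluded_types: frozenset | set = DEFAULT_EXCLUDED_TYPES,
    scale: float = 1000.0,
    length_mode: str = "span",
) -> PrepResult:
    """Full preparation pipeline in the fixed composition order."""
    n_raw = len(genes)
    genes_f = filter_genes(genes, excluded_types)
    counts = counts.loc[counts.index.intersection(genes_f["gene_name"])]
    counts = drop_zero_genes(counts)
    if counts.empty:
        raise ValueError("no genes with nonzero counts after filtering")
    normalized, sf = rle_normalize(counts)
    normalized = length_normalize(normalized, genes_f, scale=scale, length_mode=length_mode)
    groups = stratify_samples(meta)
    missing_meta = [s for s in counts.columns if s not in groups.index]
    if missing_meta:
        raise ValueError(f"samples without metadata: {missing_meta[:5]}")
    genes_f = genes_f[genes_f["gene_name"].isin(normalized.index)].reset_index(drop=True)
    prov = {
        "n_genes_annotation": n_raw,
        "n_genes_after_filters": len(genes_f),
        "n_genes_nonzero": normalized.shape[0],
        "n_samples": normalized.shape[1],
        "scale": scale,
        "length_mode": length_mode,
        "order": "type-filter -> duplicate-filter -> nonzero-filter -> RLE -> length",
    }
    return PrepResult(genes_f, normalized, sf, groups, prov)
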