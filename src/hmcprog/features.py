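"""Map fragment intervals onto genomic feature catalogs.

Feature catalogs (gene bodies, promoters, H3K4me1/H3K27ac enhancer peaks) are
BED-like tables in 0-based half-open coordinates. Fragments are assigned to
features by midpoint containment: a fragment increments a feature's count iff
its midpoint falls inside the feature interval. With pairwise-disjoint
features this assigns each fragment to at most one feature; overlapping
features (e.g. a gene body and an enhancer peak covering the same locus) may
both be incremented. An any-overlap rule is available behind ``rule="overlap"``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_CLASSES",
    "CatalogError",
    "load_catalog",
    "count_fragments",
    "metagene_profile",
    "filter_fragments",
    "MAX_FRAGMENT_LENGTH",
]

FEATURE_CLASSES = ("gene_body", "promoter", "H3K4me1", "H3K27ac")
#: concordant-pair filter used upstream of counting
MAX_FRAGMENT_LENGTH = 500

CATALOG_COLUMNS = ["chrom", "start", "end", "feature_id", "feature_class", "strand", "gene_symbol"]


class CatalogError(ValueError):
    """Malformed feature catalog."""


def load_catalog(path: str | Path) -> pd.DataFrame:
    """Load a feature catalog from a BED-like file.

    Expected tab-separated columns: chrom, start, end, feature_id,
    feature_class, strand, and optionally gene_symbol. Coordinates are 0-based
    half-open. Overlapping features are permitted (a fragment may hit several
    classes); duplicate ids within a class are not.

    Raises :class:`CatalogError` naming the offending line.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise CatalogError(f"line {lineno}: expected >= 6 columns, got {len(parts)}")
            chrom, start, end, fid, fclass, strand = parts[:6]
            symbol = parts[6] if len(parts) > 6 else ""
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise CatalogError(f"line {lineno}: non-integer coordinates") from exc
            if start_i >= end_i:
                raise CatalogError(f"line {lineno}: start >= end ({start_i} >= {end_i})")
            if fclass not in FEATURE_CLASSES:
                raise CatalogError(f"line {lineno}: unknown feature class {fclass!r}")
            if strand not in ("+", "-", "."):
                raise CatalogError(f"line {lineno}: invalid strand {strand!r}")
            rows.append((chrom, start_i, end_i, fid, fclass, strand, symbol))
    catalog = pd.DataFrame(rows, columns=CATALOG_COLUMNS)
    dup = catalog.duplicated(subset=["feature_id", "feature_class"])
    if dup.any():
        first = catalog.loc[dup, "feature_id"].iloc[0]
        raise CatalogError(f"duplicate feature_id within class: {first!r}")
    return catalog


def filter_fragments(frags: pd.DataFrame, max_length: int = MAX_FRAGMENT_LENGTH) -> pd.DataFrame:
    """Drop fragments longer than ``max_length`` bp (concordant-pair filter)."""
    keep = (frags["end"] - frags["start"]) <= max_length
    return frags.loc[keep].reset_index(drop=True)


def _build_trees(catalog: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in catalog.groupby("chrom", sort=False):
        tree = IntervalTree()
        for row_idx, start, end in zip(sub.index, sub["start"], sub["end"]):
            tree.addi(start, end, row_idx)
        trees[chrom] = tree
    return trees


def count_fragments(
    frags: pd.DataFrame,
    catalog: pd.DataFrame,
    rule: str = "midpoint",
    sample_col: str = "sample_id",
    apply_length_filter: bool = True,
) -> pd.DataFrame:
    """Summarize fragments into a feature x sample count matrix.

    ``rule="midpoint"`` (default): entry (g, s) counts sample-s fragments whose
    midpoint lies inside feature g. ``rule="overlap"``: any positive overlap
    counts. Fragments on chromosomes absent from the catalog contribute zero
    and are logged.
    """
    if rule not in ("midpoint", "overlap"):
        raise ValueError(f"unknown counting rule {rule!r}")
    if apply_length_filter:
        frags = filter_fragments(frags)
    catalog = catalog.reset_index(drop=True)

    feature_ids = catalog["feature_id"].to_numpy()
    samples = sorted(frags[sample_col].unique()) if len(frags) else []
    counts = np.zeros((len(catalog), len(samples)), dtype=np.int64)
    trees = _build_trees(catalog)
    sample_pos = {s: j for j, s in enumerate(samples)}

    missing_chroms = set()
    for chrom, sub in frags.groupby("chrom", sort=False):
        tree = trees.get(chrom)
        if tree is None:
            missing_chroms.add(chrom)
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cols = sub[sample_col].map(sample_pos).to_numpy()
        if rule == "midpoint":
            mids = (starts + ends) // 2
            for mid, col in zip(mids, cols):
                for hit in tree.at(mid):
                    counts[hit.data, col] += 1
        else:
            for start, end, col in zip(starts, ends, cols):
                for hit in tree.overlap(start, end):
                    counts[hit.data, col] += 1
    if missing_chroms:
        logger.warning(
            "fragments on %d chromosome(s) absent from catalog counted as zero: %s",
            len(missing_chroms),
            ", ".join(sorted(missing_chroms)),
        )
    out = pd.DataFrame(counts, index=feature_ids, columns=samples)
    out.index.name = "feature_id"
    return out


def metagene_profile(
    frags: pd.DataFrame,
    gene_bodies: pd.DataFrame,
    n_body_bins: int = 100,
    flank_bp: int = 2000,
    n_flank_bins: int = 20,
) -> pd.DataFrame:
    """Average fragment-midpoint density over gene bodies scaled TSS -> TES.

    Each gene body is rescaled to ``n_body_bins`` bins; ``flank_bp`` of
    upstream/downstream sequence is split into ``n_flank_bins`` fixed-width
    bins. Minus-strand genes are reversed so bin 0 is always the upstream
    flank edge and the last bin the downstream edge. Per-gene densities
    (midpoints per bp) are averaged across genes.

    Returns a DataFrame with columns bin, segment (upstream/body/downstream)
    and coverage.
    """
    genes = gene_bodies[gene_bodies["feature_class"] == "gene_body"] if (
        "feature_class" in gene_bodies
    ) else gene_bodies
    if genes.empty:
        raise ValueError("no gene bodies supplied")
    short = (genes["end"] - genes["start"]) < n_body_bins
    if short.any():
        raise ValueError("gene bodies must be at least n_body_bins bases long")

    n_bins = 2 * n_flank_bins + n_body_bins
    total = np.zeros(n_bins)
    mids_by_chrom = {
        chrom: np.sort(((sub["start"] + sub["end"]) // 2).to_numpy())
        for chrom, sub in frags.groupby("chrom", sort=False)
    }
    flank_width = flank_bp / n_flank_bins

    for _, gene in genes.iterrows():
        mids = mids_by_chrom.get(gene["chrom"])
        dens = np.zeros(n_bins)
        if mids is not None and len(mids):
            start, end = int(gene["start"]), int(gene["end"])
            body_width = (end - start) / n_body_bins
            edges = np.concatenate(
                [
                    start - flank_bp + np.arange(n_flank_bins) * flank_width,
                    start + np.arange(n_body_bins) * body_width,
                    end + np.arange(n_flank_bins + 1) * flank_width,
                ]
            )
            hist, _ = np.histogram(mids, bins=edges)
            widths = np.diff(edges)
            dens = hist / widths
        if gene.get("strand", "+") == "-":
            dens = dens[::-1]
        total += dens

    mean_dens = total / len(genes)
    segment = (
        ["upstream"] * n_flank_bins + ["body"] * n_body_bins + ["downstream"] * n_flank_bins
    )
    return pd.DataFrame({"bin": np.arange(n_bins), "segment": segment, "coverage": mean_dens})
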