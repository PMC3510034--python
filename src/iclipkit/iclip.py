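"""Crosslink-event processing: deduplication, segment assignment,
cluster calling, occupancy and target ranking.

The processing chain mirrors standard iCLIP practice: reads sharing a
start position and barcode pair collapse to one cDNA; the crosslink
nucleotide sits one nt 5' of the read start; per-gene crosslink sites
are tested against a within-gene uniform tag-scatter null to call
significant clusters at a chosen FDR; cluster windows (31 nt around the
count-weighted centre of mass) are scored as occupancy
``(window_sum / library_total) / FPKM``; and genes are ranked by the
wildtype occupancy of their strongest cluster minus the best cluster
occupancy observed in the null-genotype (background) libraries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .simulate import GenomeAnnotation

logger = logging.getLogger(__name__)

#: assignment hierarchy, highest priority first
SEGMENT_PRIORITY = ("ncRNA", "3UTR", "5UTR", "ORF", "intron")

EXP_BARCODE_LEN = 4
RAND_BARCODE_LEN = 5


# ---------------------------------------------------------------------------
# deduplication

def deduplicate(reads: pd.DataFrame, per_replicate: bool = False) -> pd.DataFrame:
    """Collapse PCR duplicates and return crosslink events.

    Reads sharing (chrom, position, strand, experimental barcode, random
    barcode) are one cDNA.  The crosslink nucleotide is one nt 5' of the
    read start: position - 1 on '+', position + 1 on '-'.  Replicates
    are pooled per genotype unless ``per_replicate`` is set.

    Returns a frame with columns chrom, position (crosslink nt), strand,
    genotype [, replicate], count (unique cDNAs at that nucleotide).
    """
    if reads.empty:
        cols = ["chrom", "position", "strand", "genotype", "count"]
        return pd.DataFrame(columns=cols)
    bad = (reads["exp_barcode"].str.len() != EXP_BARCODE_LEN) | (
        reads["rand_barcode"].str.len() != RAND_BARCODE_LEN
    )
    if bad.any():
        raise ValueError(f"{int(bad.sum())} reads carry malformed barcodes")

    key = ["chrom", "position", "strand", "genotype", "exp_barcode", "rand_barcode"]
    if per_replicate:
        key.append("replicate")
    cdnas = reads.drop_duplicates(subset=key).copy()
    cdnas["position"] = np.where(
        cdnas["strand"] == "+", cdnas["position"] - 1, cdnas["position"] + 1
    )
    group = ["chrom", "position", "strand", "genotype"]
    if per_replicate:
        group.append("replicate")
    events = cdnas.groupby(group, as_index=False).size().rename(columns={"size": "count"})
    events = events[events["position"] >= 0].reset_index(drop=True)
    return events


# ---------------------------------------------------------------------------
# segment assignment

class SegmentIndex:
    """Interval lookup over annotation segments for hierarchy calls."""

    def __init__(self, ann: GenomeAnnotation):
        self.tree = IntervalTree()
        for row in ann.segments.itertuples():
            if row.end > row.start:
                self.tree[row.start : row.end] = (row.strand, row.seg_type, row.gene_id)

    def label(self, position: int, strand: str) -> str:
        hits = self.tree[position]
        same = [iv.data[1] for iv in hits if iv.data[0] == strand]
        if same:
            return min(same, key=SEGMENT_PRIORITY.index)
        if hits:
            return "antisense"
        return "intergenic"


def assign_segments(events: pd.DataFrame, ann: GenomeAnnotation) -> pd.Series:
    """Hierarchy label (ncRNA > 3UTR > 5UTR > ORF > intron > antisense >
    intergenic) for every event; a total function."""
    index = SegmentIndex(ann)
    labels = [
        index.label(int(p), s) for p, s in zip(events["position"], events["strand"])
    ]
    return pd.Series(labels, index=events.index, name="segment")


def _union_length(ivals: list[tuple[int, int]]) -> int:
    total, prev_end = 0, -1
    for s, e in sorted(ivals):
        s = max(s, prev_end)
        if e > s:
            total += e - s
            prev_end = e
    return total


def segment_enrichment(
    calls: pd.Series, ann: GenomeAnnotation, events: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-label enrichment: fraction of events / fraction of genome.

    Event counts can be weighted by cDNA count when ``events`` (with a
    ``count`` column aligned to ``calls``) is given.  Labels without
    genomic coverage (antisense; anything absent) get NaN enrichment.
    """
    if calls.empty:
        raise ValueError("no segment calls supplied")
    weights = (
        events["count"].astype(float)
        if events is not None and "count" in events
        else pd.Series(1.0, index=calls.index)
    )
    totals = weights.groupby(calls).sum()
    total = float(weights.sum())

    cov = {}
    for label in SEGMENT_PRIORITY:
        ivals = [
            (int(r.start), int(r.end))
            for r in ann.segments.itertuples()
            if r.seg_type == label
        ]
        cov[label] = _union_length(ivals)
    all_ivals = [(int(r.start), int(r.end)) for r in ann.segments.itertuples()]
    cov["intergenic"] = ann.chrom_len - _union_length(all_ivals)
    cov["antisense"] = 0  # no dedicated genomic territory

    rows = []
    for label in list(SEGMENT_PRIORITY) + ["antisense", "intergenic"]:
        n = float(totals.get(label, 0.0))
        frac_ev = n / total
        frac_gen = cov[label] / ann.chrom_len
        ratio = frac_ev / frac_gen if frac_gen > 0 else float("nan")
        rows.append((label, n, frac_ev, frac_gen, ratio))
    return pd.DataFrame(
        rows, columns=["segment", "n_events", "frac_events", "frac_genome", "enrichment"]
    ).set_index("segment")


def assign_genes(events: pd.DataFrame, ann: GenomeAnnotation) -> pd.Series:
    """Gene id containing each event (same strand), else NA."""
    out = pd.Series(pd.NA, index=events.index, dtype="object")
    for strand in ("+", "-"):
        sub = ann.genes[ann.genes["strand"] == strand].sort_values("start")
        if sub.empty:
            continue
        starts, ends = sub["start"].to_numpy(), sub["end"].to_numpy()
        mask = events["strand"] == strand
        pos = events.loc[mask, "position"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        hit = mask.index[mask][ok]
        out.loc[hit] = sub.index.to_numpy()[idx[ok]]
    return out.rename("gene_id")


# ---------------------------------------------------------------------------
# cluster calling

@dataclass
class Cluster:
    """A significant crosslink cluster and its 31-nt occupancy window."""

    gene_id: str
    chrom: str
    strand: str
    positions: np.ndarray  # member crosslink sites
    counts: np.ndarray     # member cDNA counts
    com: int               # count-weighted centre of mass, rounded half up
    window_start: int
    window_end: int        # com - 15 .. com + 16 (half open, 31 nt)
    window_sum: int        # summed cDNA counts of all gene events in window
    fdr: float             # achieved site-level FDR of the count threshold


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def call_clusters(
    positions: np.ndarray,
    counts: np.ndarray,
    span: tuple[int, int],
    fdr_level: float = 0.05,
    n_perm: int = 100,
    rng: np.random.Generator | int | None = 0,
    merge_dist: int = 15,
    gene_id: str = "",
    chrom: str = "",
    strand: str = "+",
) -> list[Cluster]:
    """Call significant clusters among one gene's crosslink sites.

    The null scatters the gene's total cDNA count uniformly over the
    gene span ``n_perm`` times.  The count threshold is the smallest
    height h for which
    ``mean permuted #sites >= h / observed #sites >= h <= fdr_level``.
    Significant sites within ``merge_dist`` nt merge into one cluster;
    each cluster gets a 31-nt window centred on its count-weighted
    centre of mass (rounded half up), summing all gene events inside.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    positions = np.asarray(positions, dtype=np.int64)
    counts = np.asarray(counts, dtype=np.int64)
    if positions.size == 0:
        return []
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    start, end = span
    L = max(int(end - start), 1)
    T = int(counts.sum())

    perm = rng.integers(0, L, size=n_perm * T, dtype=np.int64)
    keys = np.repeat(np.arange(n_perm, dtype=np.int64), T) * L + perm
    _, perm_heights = np.unique(keys, return_counts=True)

    threshold, achieved = None, float("nan")
    for h in np.unique(counts):
        obs_ge = int((counts >= h).sum())
        perm_ge = float((perm_heights >= h).sum()) / n_perm
        fdr = perm_ge / obs_ge
        if fdr <= fdr_level:
            threshold, achieved = int(h), fdr
            break
    if threshold is None:
        return []

    sig = counts >= threshold
    order = np.argsort(positions[sig])
    spos, scnt = positions[sig][order], counts[sig][order]

    clusters: list[Cluster] = []
    block = [0]
    for i in range(1, len(spos)):
        if spos[i] - spos[i - 1] <= merge_dist:
            block.append(i)
        else:
            clusters.append(_build_cluster(
                spos[block], scnt[block], positions, counts, achieved,
                gene_id, chrom, strand))
            block = [i]
    clusters.append(_build_cluster(
        spos[block], scnt[block], positions, counts, achieved,
        gene_id, chrom, strand))
    return clusters


def _build_cluster(mpos, mcnt, all_pos, all_cnt, fdr, gene_id, chrom, strand) -> Cluster:
    com = _round_half_up(float(np.sum(mpos * mcnt)) / float(np.sum(mcnt)))
    ws, we = com - 15, com + 16
    in_win = (all_pos >= ws) & (all_pos < we)
    return Cluster(
        gene_id=gene_id, chrom=chrom, strand=strand,
        positions=mpos.copy(), counts=mcnt.copy(),
        com=com, window_start=ws, window_end=we,
        window_sum=int(all_cnt[in_win].sum()), fdr=fdr,
    )


# ---------------------------------------------------------------------------
# occupancy and ranking

def occupancy(window_sum: float, library_total: float, fpkm: float) -> float:
    """(window_sum / library_total) / FPKM."""
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    if fpkm <= 0:
        raise ValueError("fpkm must be positive")
    return (window_sum / library_total) / fpkm


def genotype_occupancy(
    events: pd.DataFrame,
    ann: GenomeAnnotation,
    fpkm: pd.Series,
    fdr_level: float = 0.05,
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Call clusters gene by gene and score their window occupancy.

    ``events`` is a deduplicated event table for one library (replicates
    already pooled).  The library total is the summed cDNA count over
    all events, including those outside genes.  Genes with non-positive
    FPKM are excluded and logged.
    """
    library_total = float(events["count"].sum())
    if library_total <= 0:
        raise ValueError("empty event table")
    ev = events.copy()
    ev["gene_id"] = assign_genes(ev, ann)
    ev = ev.dropna(subset=["gene_id"])
    rng = np.random.default_rng([7, seed])

    rows = []
    for gid, sub in ev.groupby("gene_id", sort=True):
        f = float(fpkm.get(gid, np.nan))
        if not np.isfinite(f) or f <= 0:
            logger.warning("gene %s excluded: non-positive FPKM", gid)
            continue
        g = ann.genes.loc[gid]
        clusters = call_clusters(
            sub["position"].to_numpy(), sub["count"].to_numpy(),
            (int(g["start"]), int(g["end"])),
            fdr_level=fdr_level, n_perm=n_perm, rng=rng,
            gene_id=str(gid), chrom=ann.chrom, strand=str(g["strand"]),
        )
        for c in clusters:
            rows.append((
                c.gene_id, c.chrom, c.strand, c.window_start, c.window_end,
                c.com, c.window_sum, c.fdr,
                occupancy(c.window_sum, library_total, f),
            ))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "strand", "window_start", "window_end",
                 "com", "window_sum", "fdr", "occupancy"],
    )


def expressed_genes(fpkm: pd.Series, reads_per_fpkm: float, min_reads: float = 10.0) -> pd.Index:
    """Genes passing the normalized-read expression filter (default >= 10)."""
    return fpkm.index[fpkm * reads_per_fpkm >= min_reads]


def rank_genes(
    wt: pd.DataFrame, null: pd.DataFrame, expressed: pd.Index | list
) -> pd.DataFrame:
    """Rank expressed genes by wildtype-minus-null cluster occupancy.

    Per gene, ``wt_occ`` is the occupancy of the wildtype cluster with
    the highest cDNA count (leftmost on ties; 0 when the gene has no
    wildtype cluster) and ``null_occ`` the highest cluster occupancy in
    the null library (0 when absent).  Genes sort by
    ``score = wt_occ - null_occ`` descending, ties by ``wt_occ`` then
    gene id.
    """
    expressed = pd.Index(expressed)
    if expressed.empty:
        raise ValueError("expressed gene set is empty")

    def best_wt(df: pd.DataFrame) -> pd.Series:
        if df.empty:
            return pd.Series(dtype=float)
        top = df.sort_values(
            ["gene_id", "window_sum", "window_start"],
            ascending=[True, False, True],
        ).drop_duplicates("gene_id")
        return top.set_index("gene_id")["occupancy"]

    wt_occ = best_wt(wt).reindex(expressed).fillna(0.0)
    null_occ = (
        null.groupby("gene_id")["occupancy"].max().reindex(expressed).fillna(0.0)
        if not null.empty
        else pd.Series(0.0, index=expressed)
    )
    out = pd.DataFrame(
        {"gene_id": expressed, "wt_occ": wt_occ.values, "null_occ": null_occ.values}
    )
    out["score"] = out["wt_occ"] - out["null_occ"]
    out = out.sort_values(
        ["score", "wt_occ", "gene_id"], ascending=[False, False, True]
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
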