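"""Synthetic genome, iCLIP library, count-matrix and term-set generators.

Everything downstream of read alignment is exercised on data produced
here: a single-chromosome genome of tiled genes (5'UTR / ORF / intron /
3'UTR, optionally overlapped by an antisense ncRNA decoy), lognormal
per-gene expression, crosslink tags that concentrate at motif sites
planted in target 3'UTRs of the wildtype library only, PCR duplicates
tagged by random barcodes, negative-binomial 2x2 count matrices with a
planted genotype-by-treatment interaction, and term sets concentrated in
the planted targets.

All generators are deterministic functions of ``SimConfig.seed``; each
draws from its own seed stream so that, for example, regenerating reads
does not perturb the annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig

GENOTYPES = ("wildtype", "null")
SEGMENT_TYPES = ("5UTR", "ORF", "intron", "3UTR", "ncRNA")

_BASES = np.array(list("ACGT"))

# seed-stream ids, one per generator
_S_ANNOTATION, _S_SEQUENCE, _S_FPKM, _S_READS, _S_COUNTS, _S_TERMS = range(1, 7)


@dataclass
class GenomeAnnotation:
    """Segment model of the simulated chromosome.

    ``segments`` has one row per (gene, segment); ``genes`` is indexed by
    gene id with the gene's genomic span, strand and target status.
    ``plant_sites`` maps each target gene to the genomic start positions
    of its planted motif occurrences (ground truth for read placement and
    for tests).
    """

    chrom: str
    chrom_len: int
    segments: pd.DataFrame
    genes: pd.DataFrame
    plant_sites: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def targets(self) -> list[str]:
        return list(self.genes.index[self.genes["is_target"]])


def _rng(stream: int, cfg: SimConfig, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([stream, extra, cfg.seed])


def _seg_len(rng: np.random.Generator, mean: int) -> int:
    lo = max(10, int(0.75 * mean))
    hi = max(lo + 1, int(1.25 * mean) + 1)
    return int(rng.integers(lo, hi))


def generate_annotation(cfg: SimConfig) -> GenomeAnnotation:
    """Tile ``n_genes`` genes along one chromosome with intergenic gaps.

    Genes alternate strand; each carries exactly one 5'UTR, ORF, intron
    and 3'UTR segment (transcript-ordered, genome coordinates 0-based
    half-open).  A fraction of genes receives an opposite-strand ncRNA
    decoy over the intron so that the assignment hierarchy is exercised.
    Target genes get ``sites_per_target`` motif plant sites spaced along
    the 3'UTR.
    """
    rng = _rng(_S_ANNOTATION, cfg)
    n = cfg.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]
    target_idx = np.sort(rng.choice(n, size=cfg.n_targets, replace=False))
    is_target = np.zeros(n, dtype=bool)
    is_target[target_idx] = True

    seg_rows: list[tuple] = []
    gene_rows: list[tuple] = []
    plant_sites: dict[str, np.ndarray] = {}
    cursor = 0
    motif_len = len(cfg.motif)
    for i, gid in enumerate(gene_ids):
        cursor += _seg_len(rng, cfg.intergenic_len)
        strand = "+" if i % 2 == 0 else "-"
        lens = {
            "5UTR": _seg_len(rng, cfg.utr5_len),
            "ORF": _seg_len(rng, cfg.orf_len),
            "intron": _seg_len(rng, cfg.intron_len),
            "3UTR": _seg_len(rng, cfg.utr3_len),
        }
        order = ["5UTR", "ORF", "intron", "3UTR"]
        genome_order = order if strand == "+" else order[::-1]
        start = cursor
        ivals = {}
        for seg in genome_order:
            ivals[seg] = (cursor, cursor + lens[seg])
            cursor += lens[seg]
        end = cursor
        for seg in order:
            s, e = ivals[seg]
            seg_rows.append((gid, strand, seg, s, e))
        gene_rows.append((gid, strand, start, end, bool(is_target[i])))
        if rng.random() < cfg.decoy_fraction:
            s, e = ivals["intron"]
            seg_rows.append((f"{gid}_nc", "-" if strand == "+" else "+", "ncRNA", s, e))
        if is_target[i]:
            u3s, u3e = ivals["3UTR"]
            u3len = u3e - u3s
            k = cfg.sites_per_target
            span = max(1, u3len - motif_len)
            base = (np.arange(k) + 0.5) / k * span
            jitter = rng.integers(-span // (4 * k) or 0, span // (4 * k) + 1, size=k)
            offs = np.clip(base.astype(int) + jitter, 0, span - 1)
            plant_sites[gid] = np.sort(u3s + offs)

    segments = pd.DataFrame(
        seg_rows, columns=["gene_id", "strand", "seg_type", "start", "end"]
    )
    segments.insert(1, "chrom", "chr1")
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "strand", "start", "end", "is_target"]
    ).set_index("gene_id")
    chrom_len = cursor + _seg_len(rng, cfg.intergenic_len)
    return GenomeAnnotation("chr1", chrom_len, segments, genes, plant_sites)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def generate_sequences(ann: GenomeAnnotation, cfg: SimConfig) -> dict[str, str]:
    """Random chromosome sequence with the motif written at plant sites.

    On minus-strand genes the reverse complement is written so that the
    transcript carries the motif in its own orientation.
    """
    rng = _rng(_S_SEQUENCE, cfg)
    arr = _BASES[rng.integers(0, 4, size=ann.chrom_len)]
    for gid, sites in ann.plant_sites.items():
        strand = ann.genes.at[gid, "strand"]
        planted = cfg.motif if strand == "+" else _revcomp(cfg.motif)
        for pos in sites:
            arr[pos : pos + len(planted)] = list(planted)
    return {ann.chrom: "".join(arr)}


def generate_fpkm(ann: GenomeAnnotation, cfg: SimConfig) -> pd.Series:
    """Lognormal per-gene expression (FPKM)."""
    rng = _rng(_S_FPKM, cfg)
    vals = np.exp(rng.normal(cfg.fpkm_log_mean, cfg.fpkm_log_sd, size=len(ann.genes)))
    return pd.Series(vals, index=ann.genes.index, name="fpkm")


def _barcode(code: int, length: int) -> str:
    out = []
    for _ in range(length):
        out.append("ACGT"[code % 4])
        code //= 4
    return "".join(out)


def experimental_barcode(genotype: str, replicate: int) -> str:
    """Fixed 4-nt library barcode for a (genotype, replicate) pair."""
    g = GENOTYPES.index(genotype)
    return _barcode(1 + g * 16 + replicate, 4)


def generate_iclip_reads(
    ann: GenomeAnnotation,
    fpkm: pd.Series,
    cfg: SimConfig,
    genotype: str,
) -> pd.DataFrame:
    """Simulate one genotype's iCLIP tag library.

    Background tags fall uniformly within each gene (rate scaled by the
    gene's expression relative to the median) and over intergenic space;
    in the wildtype library, target genes additionally receive tags at
    their planted motif sites at ``wt_target_rate`` per 3'UTR nt.  Each
    tag records the 5' position of the read, whose crosslink nucleotide
    is one nt upstream (strand-aware).  PCR duplicates are injected with
    probability ``pcr_dup_rate`` as identical (position, barcode) copies.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}")
    rng = _rng(_S_READS, cfg, extra=GENOTYPES.index(genotype))
    genes = ann.genes
    median_fpkm = float(np.exp(cfg.fpkm_log_mean))
    scale = (fpkm.reindex(genes.index) / median_fpkm).to_numpy()
    glen = (genes["end"] - genes["start"]).to_numpy()

    # genic background
    n_bg = rng.poisson(cfg.background_rate * glen * scale)
    g_idx = np.repeat(np.arange(len(genes)), n_bg)
    starts = genes["start"].to_numpy()[g_idx]
    lens = glen[g_idx]
    xl_pos = starts + (rng.random(len(g_idx)) * lens).astype(np.int64)
    xl_strand = genes["strand"].to_numpy()[g_idx]

    # planted signal (wildtype only)
    if genotype == "wildtype" and cfg.wt_target_rate > 0 and ann.plant_sites:
        tgids = [g for g in genes.index if g in ann.plant_sites]
        tpos, tstrand = [], []
        u3 = ann.segments.query("seg_type == '3UTR'").set_index("gene_id")
        for gid in tgids:
            u3len = int(u3.at[gid, "end"] - u3.at[gid, "start"])
            lam = cfg.wt_target_rate * u3len * fpkm[gid] / median_fpkm
            k = rng.poisson(lam)
            if k == 0:
                continue
            sites = ann.plant_sites[gid]
            pos = sites[rng.integers(0, len(sites), k)] + rng.integers(
                0, len(cfg.motif), k
            )
            tpos.append(pos)
            tstrand.append(np.repeat(genes.at[gid, "strand"], k))
        if tpos:
            xl_pos = np.concatenate([xl_pos, *tpos])
            xl_strand = np.concatenate([xl_strand, *tstrand])

    # intergenic background
    gaps = []
    prev = 0
    for s, e in zip(genes["start"], genes["end"]):
        if s > prev:
            gaps.append((prev, s))
        prev = max(prev, e)
    if ann.chrom_len > prev:
        gaps.append((prev, ann.chrom_len))
    gap_lens = np.array([e - s for s, e in gaps])
    n_int = rng.poisson(cfg.background_rate * gap_lens.sum())
    if n_int:
        flat = (rng.random(n_int) * gap_lens.sum()).astype(np.int64)
        edges = np.cumsum(gap_lens)
        which = np.searchsorted(edges, flat, side="right")
        offs = flat - np.concatenate([[0], edges[:-1]])[which]
        ipos = np.array([gaps[w][0] for w in which]) + offs
        istrand = np.where(rng.random(n_int) < 0.5, "+", "-")
        xl_pos = np.concatenate([xl_pos, ipos])
        xl_strand = np.concatenate([xl_strand, istrand])

    # read 5' position is one nt downstream of the crosslink nucleotide
    pos5 = np.where(xl_strand == "+", xl_pos + 1, xl_pos - 1)
    keep = (pos5 >= 0) & (pos5 < ann.chrom_len)
    pos5, xl_strand = pos5[keep], xl_strand[keep]
    n = len(pos5)
    replicate = rng.integers(1, cfg.n_replicates_iclip + 1, n)
    # Distinct random barcodes for distinct cDNAs within a (position,
    # strand, replicate) stack: each sampled read is its own crosslink
    # molecule, so only the injected PCR duplicates share a (position,
    # barcode) pair.  Stacks deeper than 4^5 would wrap (not reached at
    # simulated rates).
    if n:
        strand_code = (xl_strand == "-").astype(np.int64)
        key = (pos5.astype(np.int64) * 2 + strand_code) * (
            cfg.n_replicates_iclip + 1
        ) + replicate
        order = np.argsort(key, kind="stable")
        sk = key[order]
        new_group = np.concatenate([[True], sk[1:] != sk[:-1]])
        group_id = np.cumsum(new_group) - 1
        pos_in_group = np.arange(n) - np.maximum.accumulate(
            np.where(new_group, np.arange(n), 0)
        )
        starts = rng.integers(0, 1024, size=group_id[-1] + 1)
        steps = rng.integers(0, 512, size=group_id[-1] + 1) * 2 + 1
        codes_sorted = (starts[group_id] + pos_in_group * steps[group_id]) % 1024
        codes = np.empty(n, dtype=np.int64)
        codes[order] = codes_sorted
        rand_bc = [_barcode(int(c), 5) for c in codes]
    else:
        rand_bc = []
    exp_bc = [experimental_barcode(genotype, int(r)) for r in replicate]

    reads = pd.DataFrame(
        {
            "chrom": ann.chrom,
            "position": pos5,
            "strand": xl_strand,
            "exp_barcode": exp_bc,
            "rand_barcode": rand_bc,
            "genotype": genotype,
            "replicate": replicate,
        }
    )
    dup = reads[rng.random(n) < cfg.pcr_dup_rate]
    out = pd.concat([reads, dup], ignore_index=True)
    out.attrs["n_sampled"] = n
    out.attrs["n_duplicates"] = len(dup)
    return out


def planted_interaction_genes(ann: GenomeAnnotation, cfg: SimConfig) -> list[str]:
    """The target subset that carries the interaction effect."""
    return ann.targets[: cfg.n_interaction_genes]


def generate_counts_experiment(
    ann: GenomeAnnotation,
    fpkm: pd.Series,
    cfg: SimConfig,
    treatments: tuple[str, str] = ("A", "B"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial counts for a 2 (genotype) x 2 (treatment) design.

    Gene baselines follow expression; planted genes are shifted by
    ``interaction_effect`` log2 units only in the null x treatment-B
    cell.  Returns ``(counts, design)`` with one column per sample.
    """
    if len(treatments) != 2 or cfg.n_replicates_counts < 1:
        raise ValueError("design must be 2x2 with at least one replicate per cell")
    rng = _rng(_S_COUNTS, cfg)
    genes = ann.genes.index
    base = fpkm.reindex(genes).to_numpy() * cfg.count_depth
    planted = pd.Index(planted_interaction_genes(ann, cfg))
    planted_mask = genes.isin(planted)

    cols, design_rows, mats = [], [], []
    for genotype in GENOTYPES:
        for trt in treatments:
            shift = (
                2.0**cfg.interaction_effect
                if (genotype == "null" and trt == treatments[1])
                else 1.0
            )
            mean = np.where(planted_mask, base * shift, base)
            for rep in range(1, cfg.n_replicates_counts + 1):
                if cfg.dispersion > 0:
                    lam = rng.gamma(1.0 / cfg.dispersion, mean * cfg.dispersion)
                else:
                    lam = mean
                mats.append(rng.poisson(lam))
                sid = f"{genotype}_{trt}_{rep}"
                cols.append(sid)
                design_rows.append((sid, genotype, trt, rep))

    counts = pd.DataFrame(np.column_stack(mats), index=genes, columns=cols)
    design = pd.DataFrame(
        design_rows, columns=["sample", "genotype", "treatment", "replicate"]
    ).set_index("sample")
    return counts, design


def generate_term_sets(ann: GenomeAnnotation, cfg: SimConfig) -> dict[str, list[str]]:
    """Term -> gene-set map with a fraction of terms drawn from targets.

    ``enriched_term_fraction`` of terms sample their members from the
    planted target set (topped up from non-targets only if the target
    pool is too small); the remainder sample uniformly from all genes.
    """
    rng = _rng(_S_TERMS, cfg)
    genes = np.asarray(ann.genes.index)
    targets = np.asarray(ann.targets)
    non_targets = genes[~ann.genes["is_target"].to_numpy()]
    n_enriched = int(round(cfg.enriched_term_fraction * cfg.n_terms))
    terms: dict[str, list[str]] = {}
    for i in range(cfg.n_terms):
        name = f"T{i:03d}"
        if i < n_enriched and len(targets) > 0:
            k = min(cfg.term_size, len(targets))
            members = list(rng.choice(targets, size=k, replace=False))
            if k < cfg.term_size:
                members += list(
                    rng.choice(non_targets, size=cfg.term_size - k, replace=False)
                )
        else:
            members = list(rng.choice(genes, size=cfg.term_size, replace=False))
        terms[name] = sorted(members)
    return terms
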