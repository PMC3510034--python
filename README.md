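# iclipkit

Analysis pipeline for mapping the mRNA targets of a neuronal RNA-binding
protein from iCLIP (individual-nucleotide-resolution UV crosslinking and
immunoprecipitation) data, estimating how deep into the genome-wide
target ranking functional binding extends, and testing how loss of the
protein redistributes its target mRNAs across polysome fractions and the
neuronal cell-body/neuropil axis.

It is written for the setting where a wildtype library is contrasted
with a knockout-genotype library of the same protein (the knockout
serving as the background control), as in CELF4 studies of mouse brain,
and ships a synthetic-data module that generates every input with known
ground truth so the whole chain is testable end to end.

## What it computes

**Crosslink events.** Reads sharing (position, strand, 4-nt experimental
barcode, 5-nt random barcode) collapse to one cDNA; the crosslink
nucleotide is one nt 5′ of the read start. Events are classified against
the segment hierarchy ncRNA > 3′UTR > 5′UTR > ORF > intron > antisense >
intergenic, and per-segment enrichment is the fraction of events over
the fraction of genome in that segment class.

**Clusters and occupancy.** Within each gene, crosslink-site cDNA counts
are tested against a null that scatters the gene's total tag count
uniformly over the gene, n_perm times. The count threshold is the
smallest height *h* with

    FDR(h) = E_perm[#sites ≥ h] / #observed sites ≥ h  ≤  α .

Significant sites within 15 nt merge; each cluster gets a 31-nt window
centred on its count-weighted centre of mass, and

    occupancy = (window_sum / library_total) / FPKM .

**Target ranking.** Per expressed gene (≥ 10 normalized reads),
score = occupancy of the strongest wildtype cluster minus the highest
cluster occupancy in the knockout library; genes are ranked by score.

**Walk-down threshold.** The ranking is split serially into fixed-size
groups (e.g. 357 genes); each group is scored for term
over-representation (one-sided hypergeometric, BH-corrected), the
number of significant terms and −log10 min p are accumulated down the
ranking, permuted rankings give control curves, and a two-segment
piecewise-linear fit locates the inflection where functional signal
dissipates — the estimated binding threshold.

**Motif z-scores.** For every pentamer,
z = (obs − mean_shuffled) / sd_shuffled over windows of ±10 or ±30 nt
around cluster sites, with per-window mononucleotide shuffles as
controls; Δz between genotypes ranks binding-specific sequence
preference.

**Differential models.** Counts are upper-quartile normalized, each
gene's values are rank normal-quantile transformed
(Φ⁻¹((r − ½)/n)), and a per-gene two-way ANOVA yields F statistics for
treatment, genotype, and their interaction, with a permutation-adjusted
interaction p. Follow-ups: rank association between interaction
strength and the binding ranking, Δ log p term-enrichment contrasts
between the high/low interaction halves of the top targets, 2×2
genotype-by-direction Fisher tables of treatment ratios, and qPCR
2^ΔΔCt fold changes.

## Worked example

`examples/02_target_ranking.py` simulates 500 genes with 50 planted
targets, runs the iCLIP chain, and prints:

```
wildtype: 8353 unique cDNAs at 5088 crosslink sites
null: 4150 unique cDNAs at 4143 crosslink sites

wildtype segment enrichment (events fraction / genome fraction):
segment
3UTR          3.16
5UTR          0.50
ORF           0.52
intron        0.54
intergenic    0.39

top of the occupancy-difference ranking:
 rank gene_id   wt_occ  null_occ    score  planted
    1  G00044 0.000252       0.0 0.000252     True
    2  G00050 0.000244       0.0 0.000244     True
    ...

planted-target recovery AUC: 1.000
```

Every top-ranked gene is a planted target, and the AUC says the
occupancy-difference score separates targets from background almost
perfectly. `examples/04_walkdown_threshold.py` continues to the
walk-down: cumulative significant-term counts rise steeply over the
first two 25-gene groups and flatten once the planted block is
exhausted; the detected inflection (rank 50) matches the planted target
count. The remaining examples cover simulation output files, pentamer
Δz (the planted UGU-core motif dominates: ATGTT, TGTTA, …), and the
interaction models (planted genes' median interaction F of 4.6 vs 0.6
for background, with a null-genotype-specific direction table).

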