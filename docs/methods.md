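# Methods

## The inference problem

An RNA-binding protein is crosslinked to its RNA contacts in vivo;
truncated cDNAs mark single crosslink nucleotides. Two libraries are
compared: wildtype tissue, and tissue from animals null for the protein,
which measures everything the immunoprecipitation captures that is not
the protein of interest (antibody cross-reactivity, background RNA).
The pipeline turns tags into a genome-wide target ranking, estimates how
deep the ranking remains functionally meaningful, and asks whether
target transcripts redistribute across polysome fractions or the
cell-body/neuropil axis when the protein is absent.

## Crosslink events and deduplication

Each read carries a 4-nt experimental (library) barcode and a 5-nt
random barcode. Reads identical in (chromosome, start, strand,
experimental barcode, random barcode) are PCR copies of one cDNA; the
per-position event count is the number of distinct cDNAs. The crosslink
nucleotide is taken one nt 5′ of the read start, strand-aware.
Replicates are pooled per genotype by default (`per_replicate=True`
keeps them apart): replicate-level occupancy was left unspecified by the
upstream protocol descriptions, and pooling matches how the library
total is defined below.

## Cluster calling

Site significance is assessed per gene against a uniform tag-scatter
null: the gene's total cDNA count T is scattered uniformly over the gene
span n_perm times (default 100) and per-position pile-up heights
recorded. For each candidate height h,
FDR(h) = (mean permuted number of positions with height ≥ h) /
(observed number of sites with count ≥ h); the count threshold is the
smallest h with FDR(h) ≤ α (default 0.05), and the achieved FDR is
stored on the cluster. This reconstructs the standard CLIP cluster-FDR
approach; scattering individual tags (rather than moving whole sites)
is what makes tall stacks informative, since the multiset of site
heights is itself the statistic being calibrated. Significant sites
within 15 nt merge into one cluster. The centre of mass is the
count-weighted mean position rounded half up — rounding direction is
arbitrary but must be fixed for reproducible windows — and the window is
[com − 15, com + 16), 31 nt. Degenerate inputs: an empty event set
returns no clusters; a gene where no height reaches the FDR level
returns no clusters rather than a lenient threshold.

With all counts equal to 1 on uniform data the observed and permuted
height distributions coincide, so FDR(1) ≈ 1 and nothing is called;
false clusters arise only from chance pile-ups that survive the
calibration, which keeps the per-gene false-cluster rate at or below α
(measured 0–2% on background-only simulations).

## Occupancy and ranking

occupancy = (window_sum / library_total) / FPKM, where window_sum sums
all of the gene's event counts inside the window, library_total is the
summed cDNA count of the whole library (including extragenic events),
and FPKM is an externally supplied per-gene expression value (any
positive scale works; the score is used comparatively). Genes with
non-positive FPKM are excluded and logged. The ranking score per
expressed gene (≥ 10 normalized reads, threshold exposed) is the
occupancy of the wildtype cluster with the highest cDNA count (leftmost
on ties) minus the highest cluster occupancy in the pooled null
library, with absent clusters contributing 0. Ties in score break by
wildtype occupancy, then gene id, making ranks a deterministic
permutation.

## Pentamer z-scores

Windows of ±10 nt (or ±30, exposed) around crosslink sites inside
significant cluster windows — cluster sites are the default evaluation
set because background sites dilute the signal; a flag uses all sites —
are compared against n_random per-window mononucleotide shuffles:
z = (obs − mean)/sd with the population sd over control sets. The
mononucleotide shuffle is the simplest composition-preserving null; a
non-overlapping-pair dinucleotide shuffle is available. sd = 0 yields
z = 0 when obs equals the mean and a ±inf sentinel otherwise. Occurrence
counting is overlapping, summed over windows, so the pentamer totals sum
to Σ(window length − 4). The genotype contrast Δz = z_wt − z_null ranks
binding-specific preference without a motif-discovery step.

## Walk-down threshold

The ranking is split serially into ⌊N/g⌋ groups of g genes (g = 357 for
a 14,288-gene list, 204 for a 3,222-gene filtered list; the remainder
joins the last group — with those sizes this yields 40 and 15 groups
respectively). Each group is scored for term over-representation with a
one-sided hypergeometric test per term and Benjamini–Hochberg
correction across terms, against the full ranking as universe; the
"cluster count" is the number of terms with adjusted p < α and min p
the smallest raw p. Cumulative curves of both are compared with
pointwise means over uniformly shuffled rankings (default 100
permutations, exposed — the source material reports both 50 and 100).
The threshold is located by fitting two least-squares segments over
every candidate breakpoint and keeping the breakpoint that minimizes
total squared error subject to a strict slope decrease; a strictly
linear or constant curve returns no threshold. A keep-list filter
restricts the ranking (order preserved, ranks renumbered) before the
same machinery is applied, and an indicator variant walks any per-gene
differential-expression statistic down the ranking in place of
enrichment.

## Interaction models

Counts are normalized per sample by the 75th percentile of nonzero
values (linear-interpolation quantile) and rescaled by the mean upper
quartile. Within each two-level experiment, each gene's 12 values (2
genotypes × 2 treatments × 3 replicates) are transformed to normal
scores Φ⁻¹((r − ½)/n) with ties averaged; all-tied genes map to zeros.
A balanced two-way fixed-effects ANOVA gives F statistics for treatment
("experiment"), genotype and interaction. The interaction p is
permutation-adjusted: sample labels are shuffled identically across
genes and the permuted interaction F values of all genes pooled into
one null (a parametric F(1, n−4) p is also reported). Unreplicated or
unbalanced cells are rejected.

Known limitation: with only 12 samples, the per-gene rank transform
spreads the unshifted samples over the full normal-score range whatever
their true noise, which caps the interaction F attainable by a
single-cell shift (median ≈ 4 against a 5% critical value of 5.3 even
for a noise-free shift). Per-gene power for a 4-fold single-cell effect
at 3 replicates per cell is therefore ≈ 0.4 regardless of the count
noise level or of whether the permutation null is pooled or per-gene.
The transform's value here is robustness and exchangeability for the
permutation test, not per-gene power; detecting target-wide shifts is
the job of the rank-association step, which aggregates across genes and
is very powerful in the simulations. Type-I error of the permutation p
is nominal (measured 0.044–0.055 at α = 0.05 over 1,000 null genes).

Rank association reports a rank-regression F of the interaction-F rank
on binary target status (top 2,000 by default vs rest) together with a
Spearman correlation — a reconstruction of a summary model whose exact
original form is unspecified — and splits the top targets at the median
interaction F into equal high/low sets (odd counts give the extra gene
to low). Δ log p = log10 p(term | high) − log10 p(term | low) from the
same hypergeometric machinery. Direction tables classify each gene's
treatment-B/treatment-A mean-expression ratio per genotype as >1 or <1
(exact ties excluded and logged), with a two-sided Fisher exact p via
the conditional point-probability rule and the sample odds ratio
(infinite on a zero cross-cell). qPCR fold change is 2^ΔΔCt with
ΔCt = mean Ct(target) − mean Ct(reference) per genotype and
ΔΔCt = ΔCt_control − ΔCt_experimental, so fold > 1 means up in the
experimental genotype; missing replicates average the rest with a
warning.

## Synthetic data

One chromosome carries tiled genes (5′UTR/ORF/intron/3′UTR, alternating
strand, segment lengths uniform within ±25% of their means, intergenic
gaps), a fraction with an opposite-strand ncRNA decoy over the intron to
exercise the assignment hierarchy. Expression is lognormal
(μ = 2.5, σ = 0.8 on the log scale, i.e. median FPKM ≈ 12 — a typical
bulk-tissue profile). Target genes carry 5 motif plant sites spaced
along the 3′UTR (UGU-core, default TGTT). Wildtype libraries place
Poisson tag counts at plant sites at 0.1 crosslinks per 3′UTR nt at
median expression (scaled by each gene's FPKM); both genotypes receive
uniform genic background at 0.002/nt (FPKM-scaled) and intergenic
background. Distinct sampled cDNAs at one position receive distinct
random barcodes, and PCR duplicates are injected as identical copies
with probability 0.15 — at the high end of observed iCLIP duplication
so deduplication is genuinely exercised. Counts are negative binomial
(Gamma–Poisson, dispersion 0.1 — typical for biological replicates)
around FPKM-proportional baselines, with the planted interaction
applied as a 2^effect multiplier in the null × treatment-B cell only.
Term sets draw a configurable fraction of terms from the planted
targets, the rest uniformly.

The study-scale configuration uses 14,288 genes with 2,000 planted
targets (and 120 terms of 40 genes, half target-concentrated, sized so
357-gene rank groups resolve enrichment); default unit-test scale is
500 genes with 50 targets. Every generator draws from its own seed
stream of the single configured seed, so identical configurations give
byte-identical outputs and regenerating one input never perturbs
another.

What the simulation does not emulate: real read sequences and quality,
alignment artefacts, splice isoforms, crosslinking sequence bias beyond
the planted motif, correlated library composition effects, and
gene-length/GC confounds. Passing tests therefore demonstrate that the
algorithms recover the structure they assume, not that the assumptions
hold in any particular real library.

## Numerical and design choices

Coordinates are 0-based half-open throughout (BED convention).
Deterministic tie-breaks everywhere a choice exists (leftmost cluster,
mergesort ranking, gene-id lexicographic). The inflection fit requires
a strict slope decrease of at least 1e-8·(|slope1| + 1) to avoid
declaring thresholds on flat curves. Hypergeometric p values come from
scipy's survival function; BH correction from statsmodels; Fisher's
exact test from scipy (cross-checked in the test suite against exact
rational-arithmetic enumeration). The permutation null for cluster
calling uses one generator per library pass so per-gene results are
independent of which other genes carry events.

Problem sizes in the shipped checks (50 calibration genes, 1,000-gene
ANOVA simulations, one study-scale ranking run) were chosen to give
stable Monte-Carlo estimates at interactive runtimes; all are ordinary
function arguments and scale up freely.
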