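"""Simulate a small iCLIP study and write its files.

Builds a 60-gene genome with 12 planted binding targets, an expression
profile, wildtype and null crosslink-tag libraries, a 2x2 count
experiment and term sets, and writes everything as plain-text files.
"""

from pathlib import Path

import iclipkit as ik
from iclipkit import io

cfg = ik.SimConfig(n_genes=60, n_targets=12, n_interaction_genes=6, seed=7)
ann = ik.generate_annotation(cfg)
fpkm = ik.generate_fpkm(ann, cfg)
seqs = ik.generate_sequences(ann, cfg)
counts, design = ik.generate_counts_experiment(ann, fpkm, cfg)
terms = ik.generate_term_sets(ann, cfg)

outdir = Path("scratch/example_sim")
outdir.mkdir(parents=True, exist_ok=True)
io.write_annotation(ann, outdir / "annotation.tsv")
io.write_fasta(seqs, outdir / "genome.fa")
io.write_table(fpkm.to_frame(), outdir / "fpkm.tsv", index=True)
io.write_table(counts, outdir / "counts.tsv", index=True)
io.write_table(design, outdir / "design.tsv", index=True)
io.write_gmt(terms, outdir / "terms.gmt")

for genotype in ik.GENOTYPES:
    reads = ik.generate_iclip_reads(ann, fpkm, cfg, genotype)
    io.write_reads_bed(reads, outdir / f"reads_{genotype}.bed")
    print(f"{genotype}: {len(reads)} tags "
          f"({reads.attrs['n_duplicates']} PCR duplicates) "
          f"-> reads_{genotype}.bed")

print(f"genome: {ann.chrom_len} nt, {len(ann.genes)} genes, "
      f"{len(ann.targets)} planted targets")
print(f"wrote simulation to {outdir}/")
# The two BED files differ in structure: wildtype tags pile up at the
# motif sites planted in target 3'UTRs, the null library is background.
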