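"""Rank genes as binding targets from wildtype vs null iCLIP libraries.

Deduplicates tags into crosslink events, calls significant clusters per
gene against a permutation null, scores 31-nt window occupancy
normalized by library size and expression, and ranks genes by the
wildtype-minus-null occupancy difference.
"""

from scipy.stats import mannwhitneyu

import iclipkit as ik

cfg = ik.SimConfig(seed=11)  # 500 genes, 50 planted targets
ann = ik.generate_annotation(cfg)
fpkm = ik.generate_fpkm(ann, cfg)

events = {g: ik.deduplicate(ik.generate_iclip_reads(ann, fpkm, cfg, g))
          for g in ik.GENOTYPES}
for g, ev in events.items():
    print(f"{g}: {ev['count'].sum()} unique cDNAs at {len(ev)} crosslink sites")

enr = ik.segment_enrichment(
    ik.assign_segments(events["wildtype"], ann), ann, events["wildtype"]
)
print("\nwildtype segment enrichment (events fraction / genome fraction):")
print(enr["enrichment"].round(2).to_string())

wt_occ = ik.genotype_occupancy(events["wildtype"], ann, fpkm, seed=1)
null_occ = ik.genotype_occupancy(events["null"], ann, fpkm, seed=2)
ranking = ik.rank_genes(
    wt_occ, null_occ, ik.expressed_genes(fpkm, cfg.reads_per_fpkm)
)

targets = set(ann.targets)
top = ranking.head(10).copy()
top["planted"] = top["gene_id"].isin(targets)
print("\ntop of the occupancy-difference ranking:")
print(top[["rank", "gene_id", "wt_occ", "null_occ", "score", "planted"]]
      .to_string(index=False))

lab = ranking["gene_id"].isin(targets).to_numpy()
u = mannwhitneyu(ranking.loc[lab, "score"], ranking.loc[~lab, "score"]).statistic
print(f"\nplanted-target recovery AUC: {u / (lab.sum() * (~lab).sum()):.3f}")
# AUC near 1 means the occupancy-difference score cleanly separates the
# planted binding targets from background genes.
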