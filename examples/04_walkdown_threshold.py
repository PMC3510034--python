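"""Estimate the functional binding threshold by walking down a ranking.

Serial rank groups are scored for term over-representation; cumulative
curves flatten once groups run out of true targets, and a two-segment
fit locates that inflection.  Permuted rankings give the control curve.
"""

import iclipkit as ik

cfg = ik.SimConfig(seed=11)
ann = ik.generate_annotation(cfg)
fpkm = ik.generate_fpkm(ann, cfg)
wt = ik.deduplicate(ik.generate_iclip_reads(ann, fpkm, cfg, "wildtype"))
null = ik.deduplicate(ik.generate_iclip_reads(ann, fpkm, cfg, "null"))
ranking = ik.rank_genes(
    ik.genotype_occupancy(wt, ann, fpkm, seed=1),
    ik.genotype_occupancy(null, ann, fpkm, seed=2),
    ik.expressed_genes(fpkm, cfg.reads_per_fpkm),
)
terms = ik.generate_term_sets(ann, cfg)

group_size = 25
genes = list(ranking["gene_id"])
curve = ik.walk_down(genes, group_size, terms)
perm = ik.permute_walkdown(genes, n_perm=20, seed=3, group_size=group_size,
                           terms=terms)

print("group  cum_clusters  permuted_mean")
for i, (c, p) in enumerate(zip(curve.cum_clusters, perm["mean_cum_clusters"]), 1):
    print(f"{i:5d}  {c:12.0f}  {p:13.1f}")

threshold = ik.detect_inflection(curve)
print(f"\ndetected threshold: rank {threshold} "
      f"(planted targets: {cfg.n_targets})")
# The experimental curve rises steeply while groups are rich in planted
# targets and flattens after them; the permuted control rises slowly and
# linearly.  The inflection estimates how deep the ranking stays
# functionally coherent.
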