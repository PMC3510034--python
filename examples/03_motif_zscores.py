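"""Pentamer z-scores around crosslink sites, contrasted by genotype.

Windows around cluster sites are compared with mononucleotide-shuffled
controls; the wildtype-minus-null delta-z ranking recovers the planted
UGU-core motif (TGT in DNA alphabet).
"""

import iclipkit as ik

cfg = ik.SimConfig(seed=11)
ann = ik.generate_annotation(cfg)
fpkm = ik.generate_fpkm(ann, cfg)
seqs = ik.generate_sequences(ann, cfg)

z = {}
for genotype, seed in (("wildtype", 1), ("null", 2)):
    events = ik.deduplicate(ik.generate_iclip_reads(ann, fpkm, cfg, genotype))
    clusters = ik.genotype_occupancy(events, ann, fpkm, seed=seed)
    sites = ik.significant_site_events(events, clusters)
    if sites.empty:
        sites = events  # background library: fall back to all sites
    windows = ik.extract_flanks(sites, seqs, half_width=10)
    z[genotype] = ik.pentamer_zscores(windows, n_random=50, seed=3)
    print(f"{genotype}: {len(windows)} windows, top pentamer "
          f"{z[genotype].iloc[0]['pentamer']} (z={z[genotype].iloc[0]['z']:.1f})")

dz = ik.genotype_contrast(z["wildtype"], z["null"])
print("\ntop 5 wildtype-vs-null delta-z pentamers:")
print(dz.head(5).to_string(index=False))
# Pentamers carrying the TGT core dominate: binding-specific sequence
# preference, not composition, drives the wildtype signal.
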