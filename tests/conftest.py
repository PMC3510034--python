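import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

import iclipkit as ik

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cfg() -> ik.SimConfig:
    return ik.SimConfig(n_genes=40, n_targets=8, n_interaction_genes=5, seed=1)


@pytest.fixture(scope="session")
def small_world(small_cfg):
    """Annotation + expression + both read libraries at toy scale."""
    ann = ik.generate_annotation(small_cfg)
    fpkm = ik.generate_fpkm(ann, small_cfg)
    wt = ik.generate_iclip_reads(ann, fpkm, small_cfg, "wildtype")
    null = ik.generate_iclip_reads(ann, fpkm, small_cfg, "null")
    return {"cfg": small_cfg, "ann": ann, "fpkm": fpkm, "wt": wt, "null": null}


@pytest.fixture(scope="session")
def default_pipeline():
    """Default-scale run (500 genes, 50 planted targets) through ranking."""
    cfg = ik.SimConfig(seed=11)
    ann = ik.generate_annotation(cfg)
    fpkm = ik.generate_fpkm(ann, cfg)
    wt_ev = ik.deduplicate(ik.generate_iclip_reads(ann, fpkm, cfg, "wildtype"))
    null_ev = ik.deduplicate(ik.generate_iclip_reads(ann, fpkm, cfg, "null"))
    wt_occ = ik.genotype_occupancy(wt_ev, ann, fpkm, seed=1)
    null_occ = ik.genotype_occupancy(null_ev, ann, fpkm, seed=2)
    expressed = ik.expressed_genes(fpkm, cfg.reads_per_fpkm)
    ranking = ik.rank_genes(wt_occ, null_occ, expressed)
    return {
        "cfg": cfg, "ann": ann, "fpkm": fpkm,
        "wt_events": wt_ev, "null_events": null_ev,
        "wt_occ": wt_occ, "null_occ": null_occ,
        "expressed": expressed, "ranking": ranking,
    }
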