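"""Shared fixtures: one fully planted synthetic scene reused across tests."""

from collections import namedtuple

import pytest

from circnet import synthdata as s
from circnet.splice import SpliceSiteModel

Scene = namedtuple("Scene", "config genome plantings truth reads")

SCENE_SEED = 7


@pytest.fixture(scope="session")
def splice_model():
    return SpliceSiteModel.load()


@pytest.fixture(scope="session")
def scene():
    """Default study conditions: 2 x 100 kb chromosomes, 50 callable planted
    circRNAs (depth >= 10) + 20 decoys each violating exactly one rule,
    planted DE and ceRNA triplets, 150 bp split reads."""
    cfg = s.SynthConfig()
    genome = s.generate_genome(cfg, SCENE_SEED)
    plantings, truth = s.plant_circrnas(genome, cfg.n_true_circs,
                                        cfg.n_decoys, SCENE_SEED, cfg)
    s.plant_regulatory_truth(genome, truth, cfg, SCENE_SEED)
    reads = s.simulate_split_alignments(genome, plantings,
                                        read_len=cfg.read_len,
                                        seed=SCENE_SEED,
                                        n_background=cfg.n_background_reads,
                                        truth=truth)
    return Scene(cfg, genome, plantings, truth, reads)


@pytest.fixture(scope="session")
def small_scene():
    """A compact scene with sub-overhang junction reads for counting tests."""
    cfg = s.SynthConfig(n_mrna=14, n_lncrna=4, n_mirna=6, n_true_circs=6,
                        n_decoys=0, n_sub_overhang_per_circ=2,
                        n_background_reads=20, include_long_chrom=False,
                        n_de={"mRNA": (3, 2), "lncRNA": (1, 1),
                              "miRNA": (2, 2), "circRNA": (2, 1)},
                        n_triplets={"circRNA": (1, 0), "lncRNA": (1, 0)},
                        n_decoy_triplets=0, n_circ_free_mrna=4)
    genome = s.generate_genome(cfg, 13)
    plantings, truth = s.plant_circrnas(genome, cfg.n_true_circs,
                                        cfg.n_decoys, 13, cfg)
    s.plant_regulatory_truth(genome, truth, cfg, 13)
    reads = s.simulate_split_alignments(genome, plantings,
                                        read_len=cfg.read_len, seed=13,
                                        n_background=cfg.n_background_reads,
                                        truth=truth)
    return Scene(cfg, genome, plantings, truth, reads)
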