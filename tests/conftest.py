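"""Shared fixtures: a toy digestion and a session-scoped synthetic study."""

from dataclasses import replace

import numpy as np
import pytest

from cnc4c import (
    GenomeIndex,
    SyntheticConfig,
    build_nonexonic_blocks,
    digest_genome,
    generate_annotation,
    generate_genome,
    make_baits,
)
from cnc4c.synthetic import LibraryModel

TOY_SEQ = "AAGATCTTGATCAA"  # cuts at 2 and 8 -> fragments [0,2) [2,8) [8,14)


@pytest.fixture(scope="session")
def toy_index():
    genome = GenomeIndex(["c1"], {"c1": len(TOY_SEQ)}, {"c1": TOY_SEQ})
    return digest_genome(genome)


@pytest.fixture(scope="session")
def grid_index():
    """Regular digestion: GATC every 10 bp on one 200 bp chromosome."""
    seq = ("GATC" + "AATTAA") * 20
    genome = GenomeIndex(["g1"], {"g1": len(seq)}, {"g1": seq})
    return digest_genome(genome)


# The simulation study conditions: a scaled-down genome with human-like
# chromosome proportions (bait chromosome ~1.5% of the genome), 4-cutter
# site spacing, length-proportional conservation-block density, and library
# depth such that threshold-passing fragments are a small share (~2-6%) of
# the fragment universe, as in a genome-scale experiment.
STUDY_CONFIG = SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def study_world():
    """Genome, fragment index, blocks and one bait, built once."""
    cfg = STUDY_CONFIG
    genome = generate_genome(cfg)
    index = digest_genome(genome)
    conserved, exons, truth = generate_annotation(cfg, genome)
    blocks = build_nonexonic_blocks(conserved, exons)
    bait = make_baits(replace(cfg, n_baits=1), index)[0]
    return {
        "cfg": cfg,
        "genome": genome,
        "index": index,
        "conserved": conserved,
        "exons": exons,
        "blocks": blocks,
        "bait": bait,
    }


@pytest.fixture(scope="session")
def study_model(study_world):
    return LibraryModel(study_world["index"], study_world["blocks"], study_world["cfg"])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
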