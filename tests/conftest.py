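"""Shared fixtures: hand-built toy catalogs and a small synthetic bundle."""

from __future__ import annotations

import numpy as np
import pytest

from ltrtx.genome_model import Feature, FeatureCatalog
from ltrtx.intervals import GenomicInterval


def make_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def plant(genome: str, pos: int, insert: str) -> str:
    """Overwrite genome[pos:pos+len(insert)] with *insert*."""
    return genome[:pos] + insert + genome[pos + len(insert) :]


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def toy_catalog(rng):
    """5 kb chromosome: LTR-int-LTR element, two solitary LTRs, one gene.

    The element's two LTRs are identical 60-mers; solo1 is a copy of the
    element LTR (multi-mapping family member), solo2 is unrelated sequence.
    """
    genome = make_sequence(rng, 5000)
    ltr = make_sequence(rng, 60)
    internal = make_sequence(rng, 200)
    solo2 = make_sequence(rng, 60)

    genome = plant(genome, 500, ltr + internal + ltr)  # element at [500, 820)
    genome = plant(genome, 1500, ltr)  # solo1 at [1500, 1560)
    genome = plant(genome, 2500, solo2)  # solo2 at [2500, 2560)

    features = [
        Feature("ltr5", "ltr", GenomicInterval("chr1", 500, 560)),
        Feature("int1", "retro_internal", GenomicInterval("chr1", 560, 760)),
        Feature("ltr3", "ltr", GenomicInterval("chr1", 760, 820)),
        Feature("solo1", "ltr", GenomicInterval("chr1", 1500, 1560)),
        Feature("solo2", "ltr", GenomicInterval("chr1", 2500, 2560)),
        Feature("geneA", "gene", GenomicInterval("chr1", 3500, 4200, "+")),
    ]
    return FeatureCatalog(chromosomes={"chr1": genome}, features=features)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small simulated genome + truth shared by the heavier tests."""
    from ltrtx.synthetic_data import SimConfig, generate_genome

    cfg = SimConfig(
        seed=1234,
        chrom_length=120_000,
        n_full_elements=5,
        n_solitary=15,
        n_genes=10,
    )
    catalog, truth = generate_genome(cfg)
    return cfg, catalog, truth
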