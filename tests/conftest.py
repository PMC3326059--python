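import numpy as np
import pandas as pd
import pytest

from clinetile import synthetic_data as sd


@pytest.fixture(scope="session")
def small_world():
    """A small single-chromosome fixture shared by mapping/labelling tests."""
    spec = sd.GenomeSpec(n_chromosomes=1, chrom_length=30_000, n_genes=8,
                         gene_length_range=(1200, 2400))
    genome, annotation = sd.generate_annotation(spec, seed=11)
    probes = sd.generate_probes(genome, probe_length=25, step=40)
    return genome, annotation, probes


@pytest.fixture(scope="session")
def simulated_experiment(small_world):
    """Intensities with planted DE genes on the small fixture."""
    genome, annotation, probes = small_world
    design = sd.make_design(replicates=5)
    effects = sd.EffectSpec(de_gene_fraction=0.25, seed=23)
    intensities, truth = sd.simulate_intensities(probes, design, effects, annotation)
    return design, effects, intensities, truth
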