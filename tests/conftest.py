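import numpy as np
import pytest

from inosinome.calling import CallAnnotations, FilterConfig, call_sites
from inosinome.io_formats import KnownVariantIndex
from inosinome.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=7,
                     chrom_lengths={"chr1": 220_000, "chr2": 120_000},
                     n_genes=10, n_edit_sites=80, n_hom_snps=6,
                     n_het_snps=6, n_hyper_clusters=5)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_sample(small_dataset):
    return small_dataset.sample("s1")


@pytest.fixture(scope="session")
def small_annotations(small_dataset):
    known = KnownVariantIndex()
    for s in small_dataset.truth.snps:
        known.add(s.chrom, s.pos0, s.ref, s.alt)
    return CallAnnotations(
        repeat_index=small_dataset.sim_genome.repeat_index(),
        known_variants=known,
        retro_index=small_dataset.sim_genome.retro_index(),
        transcripts=small_dataset.sim_genome.models)


@pytest.fixture(scope="session")
def small_callset(small_dataset, small_sample, small_annotations):
    return call_sites(small_sample.rna_records, small_dataset.dna,
                      small_dataset.genome, small_annotations,
                      FilterConfig(), emit_rejected=True, sample_id="s1")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
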