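import numpy as np
import pytest

from mabid.genome import MotifIndex
from mabid.scheme import AbbcEntry, BarcodeScheme
from mabid.simulate import (
    SimConfig,
    simulate_accessibility,
    simulate_domains,
    simulate_genome,
)


@pytest.fixture(scope="session")
def scheme() -> BarcodeScheme:
    return BarcodeScheme(
        sbc_whitelist=("TTCCAGGA", "GGAACTTC"),
        abbc_whitelist=(
            AbbcEntry("CATGCGTA", "H3K27me3", "TTAA"),
            AbbcEntry("GTACTAGC", "H3K4me1", "GATC"),
            AbbcEntry("TGCAAGTC", "control", "both"),
        ),
        sample_names={"TTCCAGGA": "sample1", "GGAACTTC": "sample2"},
    )


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def sim_bundle(sim_config, scheme):
    """Genome + motif index + domains + accessibility, shared across tests."""
    genome = simulate_genome(sim_config)
    rng = np.random.default_rng(sim_config.seed + 1)
    motif_index = MotifIndex.from_genome(genome)
    epitopes = [e.epitope for e in scheme.abbc_whitelist if e.epitope != "control"]
    domains = simulate_domains(sim_config, epitopes, rng)
    accessibility = simulate_accessibility(sim_config, rng)
    return {
        "genome": genome,
        "motif_index": motif_index,
        "domains": domains,
        "accessibility": accessibility,
    }


def make_read(scheme: BarcodeScheme, umi="ACGGAT", sbc=None, abbc=None, genomic="ACGT" * 10):
    """Assemble a perfectly structured read from scheme parts."""
    sbc = sbc or scheme.sbc_whitelist[0]
    abbc = abbc or scheme.abbc_whitelist[0].barcode
    return (
        umi[: scheme.umi1_len]
        + sbc[: scheme.sbc1_len]
        + umi[scheme.umi1_len :]
        + sbc[scheme.sbc1_len :]
        + scheme.constant
        + abbc
        + genomic
    )
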