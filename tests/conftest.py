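import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from noamp import (  # noqa: E402
    AlleleModel,
    MarkerHaplotype,
    SimConfig,
    ctg18_locus,
    fmr1_locus,
    simulate_sample,
)


@pytest.fixture(scope="session")
def ctg18():
    return ctg18_locus()


@pytest.fixture(scope="session")
def fmr1():
    return fmr1_locus()


@pytest.fixture(scope="session")
def haplotypes():
    return (
        MarkerHaplotype(sec_tract_len=13, ctt_index=6, snp_allele="A"),
        MarkerHaplotype(sec_tract_len=14, ctt_index=6, snp_allele="T"),
    )


@pytest.fixture(scope="session")
def sim_noisefree(ctg18, haplotypes):
    """Error-free biallelic 23/91 sample with 10% decoys."""
    config = SimConfig(
        locus=ctg18,
        alleles=(
            AlleleModel(center_len=23, spread=0, haplotype=haplotypes[0]),
            AlleleModel(center_len=91, spread=0, haplotype=haplotypes[1]),
        ),
        n_reads=120,
        error_sub_rate=0.0,
        error_ins_rate=0.0,
        error_del_rate=0.0,
        offtarget_fraction=0.1,
        seed=11,
    )
    return config, simulate_sample(config)


@pytest.fixture(scope="session")
def sim_noisy(ctg18, haplotypes):
    """Study-condition sample: 23 (stable) / 91 (spread 4), CCS-like errors."""
    config = SimConfig(
        locus=ctg18,
        alleles=(
            AlleleModel(center_len=23, spread=0, haplotype=haplotypes[0]),
            AlleleModel(center_len=91, spread=4, haplotype=haplotypes[1]),
        ),
        n_reads=300,
        seed=7,
    )
    return config, simulate_sample(config)
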