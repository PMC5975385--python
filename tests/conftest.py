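import pytest

from cnvcohort.models import CNVCall, GenomeBuild
from cnvcohort.synthetic import SimConfig, simulate_cohort


def make_call(
    chrom="1",
    start=1000,
    end=2000,
    cnv_type="DUP",
    caller="read_depth",
    sample="S1",
):
    return CNVCall(sample, chrom, start, end, cnv_type, caller)


@pytest.fixture(scope="session")
def toy_build():
    return GenomeBuild("toy", {"1": 10_000_000, "2": 10_000_000, "3": 10_000_000})


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated five-breed cohort, fixed seed, used across tests."""
    return simulate_cohort(SimConfig(seed=7))


@pytest.fixture(scope="session")
def tiny_sim_config():
    """Four equal breeds, no low-coverage samples, no false positives:
    120 true loci of which 96 (80%) are individual-private."""
    return SimConfig(
        seed=11,
        breeds={"A": 6, "B": 6, "C": 6, "D": 6},
        n_low_coverage=0,
        n_shared_global=8,
        n_shared_per_breed=4,
        n_private_per_sample=4,
        fp_rate_rd=0.0,
    )
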