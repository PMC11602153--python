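import pytest

from duskit.core import ModificationProfile, ReferenceBundle
from duskit.simulate import build_fixture_references
from duskit import aas


@pytest.fixture(scope="session")
def bundle20() -> ReferenceBundle:
    return build_fixture_references(20, seed=7)


@pytest.fixture(scope="session")
def bundle5() -> ReferenceBundle:
    return build_fixture_references(5, seed=7)


@pytest.fixture(scope="session")
def baseline20(bundle20) -> ModificationProfile:
    return bundle20.baseline_profile()


def zero_profile(bundle: ReferenceBundle) -> ModificationProfile:
    return ModificationProfile(
        occupancy={(a.trna_id, a.seq_index): 0.0 for a in bundle.annotations},
        enzymes={(a.trna_id, a.seq_index): a.enzyme for a in bundle.annotations},
    )


@pytest.fixture(scope="session")
def null_profile20(bundle20) -> ModificationProfile:
    return zero_profile(bundle20)


def score_library(reads, bundle, min_cov=aas.DEFAULT_MIN_COV):
    """FASTQ-free convenience: map, tally and score simulated reads."""
    aligned, report = aas.map_reads([(r.read_id, r.sequence) for r in reads], bundle)
    return aas.stop_ratio(aas.tally(aligned, bundle), min_cov=min_cov), report
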