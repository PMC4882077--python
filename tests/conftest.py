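import pytest
from hypothesis import settings

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")

from itsloci import fixtures
from itsloci.genotypes import LocusCall, SSIRecord

# Published phenotype-class counts of the 94 single-spore isolates,
# split by karyotype (homokaryons n=69, heterokaryons n=25).
HOMOKARYON_COUNTS = {
    "[A]": 19, "[B]": 20, "[C]": 0, "[A+C]": 19, "[A+B]": 0, "[B+C]": 11, "[A+B+C]": 0,
}
HETEROKARYON_COUNTS = {
    "[A]": 2, "[B]": 3, "[C]": 0, "[A+C]": 2, "[A+B]": 1, "[B+C]": 6, "[A+B+C]": 11,
}


@pytest.fixture(scope="session")
def haplotypes():
    return fixtures.builtin_haplotypes()

@pytest.fixture(scope="session")
def markers():
    return fixtures.load_markers()

@pytest.fixture(scope="session")
def its_marker(markers):
    return markers["ITS"]


def make_heterokaryons(phenotype_counts):
    """SSIRecords classified heterokaryon carrying the given ITS phenotypes."""
    records = []
    k = 0
    for label, n in phenotype_counts.items():
        for _ in range(n):
            k += 1
            records.append(SSIRecord(
                f"het-{k:03d}",
                {"PRS016": LocusCall("PRS016", frozenset({"1", "2"}))},
                label,
                karyotype="heterokaryon",
            ))
    return records
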