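import pytest
from hypothesis import HealthCheck, settings

from olgkit.seqcore import enumerate_embedded_orfs
from olgkit.synthdata import FixtureSpec, make_overlap_genome

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture():
    """Default toy genome with the canonical overlap geometry."""
    return make_overlap_genome(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def planted_orfs(fixture):
    return enumerate_embedded_orfs(fixture.record, fixture.mother)


@pytest.fixture(scope="session")
def embedded_orf(planted_orfs, fixture):
    [orf] = [
        o
        for o in planted_orfs
        if (o.start, o.end) == tuple(fixture.ledger["orf"])
    ]
    return orf
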