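import pytest
from hypothesis import HealthCheck, settings

from ablineage import simulate

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def germline_set():
    return simulate.make_fixture_germline_set(seed=0)


@pytest.fixture(scope="session")
def germ_by_name(germline_set):
    return {a.name: a for a in germline_set}


@pytest.fixture(scope="session")
def germline_fasta(tmp_path_factory, germline_set):
    from ablineage.imgt import write_germline_set

    path = tmp_path_factory.mktemp("germ") / "germline.fasta"
    write_germline_set(germline_set, path)
    return path
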