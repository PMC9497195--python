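import pytest
from hypothesis import settings

from ddaflux import PhysiologyParams, build_quotas

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return PhysiologyParams()


@pytest.fixture(scope="session")
def quotas():
    return build_quotas()
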