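import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def group_map_abc():
    return {"a": "G_type", "b": "C_type", "c": "outgroup"}
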