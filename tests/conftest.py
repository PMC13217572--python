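import pytest
from hypothesis import settings

import autocatnet as an

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def typeV():
    return an.synth.make_typeV()


@pytest.fixture
def typeV_graph(typeV):
    return an.build_konig(typeV)


@pytest.fixture
def typeV_table(tmp_path, typeV):
    path = tmp_path / "typeV.tsv"
    an.write_table(typeV, path)
    return path
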