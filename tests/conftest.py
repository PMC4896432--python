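import pytest

from offl import build_example


@pytest.fixture
def sir():
    return build_example("sir")


@pytest.fixture
def lotka_volterra():
    return build_example("lotka_volterra")


@pytest.fixture
def growth():
    return build_example("growth")


@pytest.fixture
def si():
    return build_example("si")
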