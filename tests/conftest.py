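import pytest

from terescore import Formulation, FormulationComponent, default_affinity_table


def make_formulation(label, *components, annotation=None):
    return Formulation(
        label,
        tuple(FormulationComponent(name, mg) for name, mg in components),
        annotation,
    )


@pytest.fixture(scope="session")
def table():
    return default_affinity_table()


@pytest.fixture
def assay1():
    return make_formulation("assay-1", ("daidzein", 25), ("genistein", 75))


@pytest.fixture
def assay2():
    return make_formulation("assay-2", ("daidzein", 75), ("genistein", 25))
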