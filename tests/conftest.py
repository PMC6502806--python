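import pytest

from amplipanel import SimulationPlan
from amplipanel.synthetic_data import gen_families, gen_reference, gen_wild_vcf


@pytest.fixture(scope="session")
def plan():
    return SimulationPlan(seed=7)


@pytest.fixture(scope="session")
def reference_bundle(plan):
    return gen_reference(plan)


@pytest.fixture(scope="session")
def wild_fixture(plan):
    records, manifest = gen_wild_vcf(plan)
    return records, manifest


@pytest.fixture(scope="session")
def family_fixture(plan):
    matrix, phenotypes, manifest = gen_families(plan)
    return matrix, phenotypes, manifest
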