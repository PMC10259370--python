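import pytest
from hypothesis import HealthCheck, settings

from qcfill.energy_backends import SurrogateBackend
from qcfill.molecule_io import embed_3d, parse_smiles
from qcfill.orchestrator import (
    WILLIAMSON_MAPPED_SMILES,
    williamson_route,
    williamson_rule_table,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def structure_cache():
    """Session cache of embedded structures keyed by SMILES (embedding is the
    slow part of most tests)."""
    cache = {}

    def get(smiles, seed=11):
        if smiles not in cache:
            cache[smiles] = embed_3d(parse_smiles(smiles), seed=seed)
        return cache[smiles]

    return get


@pytest.fixture(scope="session")
def alkane(structure_cache):
    """Linear alkane with n carbons — a molecule with exactly n heavy atoms."""

    def get(n):
        return structure_cache("C" * n)

    return get


@pytest.fixture()
def iodoethane(structure_cache):
    return structure_cache("CCI")


@pytest.fixture()
def phenol(structure_cache):
    return structure_cache("Oc1ccccc1")


@pytest.fixture()
def williamson_mapping_smiles():
    return WILLIAMSON_MAPPED_SMILES


@pytest.fixture()
def williamson_backend():
    return SurrogateBackend(rule_table=williamson_rule_table())


@pytest.fixture()
def williamson_step():
    return williamson_route().steps[0]
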