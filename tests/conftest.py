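import pytest

from rxncure import (NoiseConfig, UNIQUE_LG_FAMILIES, ValenceTable,
                     curate_reaction, extract_generic_template,
                     extract_template_library, generate_fixture_dataset,
                     inject_noise, merge_isomorphic_templates, parse_reaction)

GRIGNARD_SMILES = (
    "Br[c:1]1[cH:2][cH:3][cH:4][cH:5][cH:6]1.[O:8]=[CH:7][CH3:9]"
    ">>[OH:8][CH:7]([CH3:9])[c:1]1[cH:2][cH:3][cH:4][cH:5][cH:6]1"
)

#: printed detailed retro template of the Grignard example and its generic form
GRIGNARD_DETAILED = (
    "[OH;D1;+0:4]-[CH;D3;+0:5](-[c:6])-[c;H0;D3;+0:1](:[c:2]):[c:3]"
    ">>Br-[c;H0;D3;+0:1](:[c:2]):[c:3].[O;H0;D1;+0:4]=[CH;D2;+0:5]-[c:6]"
)
GRIGNARD_GENERIC = "[#6:1]-[#6:2]-[#8:3]>>Br-[#6:1].[#6:2]=[#8:3]"


@pytest.fixture(scope="session")
def vt():
    return ValenceTable()


@pytest.fixture(scope="session")
def grignard_rxn():
    return parse_reaction(GRIGNARD_SMILES, "grignard-1")


@pytest.fixture(scope="session")
def grignard_library(grignard_rxn):
    t = extract_generic_template(grignard_rxn)
    return merge_isomorphic_templates([t] * 7)


@pytest.fixture(scope="session")
def unique_lg_dataset():
    """Small clean dataset over the unique-leaving-group families."""
    return generate_fixture_dataset(UNIQUE_LG_FAMILIES, 40, seed=101)


@pytest.fixture(scope="session")
def unique_lg_library(unique_lg_dataset):
    lib, errors = extract_template_library(unique_lg_dataset, min_frequency=5)
    assert not errors
    return lib


@pytest.fixture(scope="session")
def benchmark_run(vt):
    """One full noise-inject/extract/curate cycle shared across tests."""
    data = generate_fixture_dataset(UNIQUE_LG_FAMILIES, 40, seed=7)
    corrupted, labels = inject_noise(data, NoiseConfig(noise_ratio=0.2, seed=8))
    lib, _ = extract_template_library(corrupted, min_frequency=5)
    outcomes = [curate_reaction(r, lib, vt) for r in corrupted]
    return data, corrupted, labels, lib, outcomes
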