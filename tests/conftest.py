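import numpy as np
import pytest

from halosite import synthetic as syn
from halosite.structio import Atom, StructureModel


def make_atom(
    serial=1,
    name="O",
    element=None,
    residue_name="ALA",
    residue_seq=1,
    chain_id="A",
    position=(0.0, 0.0, 0.0),
    is_hetero=False,
    occupancy=1.0,
    alt_loc="",
):
    if element is None:
        element = name[0]
    return Atom(
        serial=serial,
        name=name,
        element=element,
        alt_loc=alt_loc,
        occupancy=occupancy,
        b_iso=15.0,
        residue_name=residue_name,
        residue_seq=residue_seq,
        icode="",
        chain_id=chain_id,
        is_hetero=is_hetero,
        position=tuple(float(x) for x in position),
    )


@pytest.fixture(scope="session")
def helix10():
    return syn.gen_helix(10, "A" * 10)


@pytest.fixture(scope="session")
def mixed_helix():
    return syn.gen_helix(10, "ADSEKGTMAF")


@pytest.fixture(scope="session")
def planted_k_site(helix10):
    return syn.plant_site(helix10, "K_carbonyl_cluster", cn=7, seed=3)


@pytest.fixture(scope="session")
def composite_crystal():
    return syn.build_composite_crystal(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
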