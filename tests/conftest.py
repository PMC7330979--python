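import numpy as np
import pytest

from triadmut.fixtures import (FixtureSpec, PlantedInteraction, make_fixture,
                               strip_pair_to_alanine)


@pytest.fixture
def helix10():
    return make_fixture(FixtureSpec(n_residues=10, seed=0), structure_id="helix10")


@pytest.fixture
def planted_disulfide():
    spec = FixtureSpec(n_residues=12,
                       planted_interactions=(PlantedInteraction(3, 7, "disulfide"),),
                       seed=11)
    return make_fixture(spec, structure_id="ssfix")


@pytest.fixture
def planted_hb():
    spec = FixtureSpec(n_residues=16,
                       planted_interactions=(PlantedInteraction(4, 8, "hydrogen_bond"),),
                       seed=5)
    return make_fixture(spec, structure_id="hbfix")


@pytest.fixture
def recovery_pair(planted_hb):
    """(template, target) where the target is the template stripped to
    alanine at the planted pair (same frame: no rigid motion)."""
    target = strip_pair_to_alanine(planted_hb, 4, 8)
    target.id = "hbtarget"
    return planted_hb, target


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
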