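import numpy as np
import pytest

from geophylocausal.core import GeoPhyloTree, NodeRecord
from geophylocausal.simulate import (
    FounderJump,
    SimulationConfig,
    TraitModelConfig,
    simulate_dataset,
)


def make_tree(edges, ages, locations=None, traits=None):
    """Build a GeoPhyloTree from {child: parent} edges and {id: age}."""
    locations = locations or {}
    traits = traits or {}
    parents = dict(edges)
    records = {}
    for nid, age in ages.items():
        parent = parents.get(nid)
        blen = (ages[parent] - age) if parent is not None else 0.0
        lat, lon = locations.get(nid, (0.0, 0.0))
        records[nid] = NodeRecord(
            id=nid, parent=parent, branch_length=blen, age=age,
            lat=lat, lon=lon, traits=dict(traits.get(nid, {})),
        )
    return GeoPhyloTree(records)


@pytest.fixture
def two_leaf_tree():
    return make_tree({"A": "R", "B": "R"}, {"R": 1.0, "A": 0.0, "B": 0.0})


@pytest.fixture
def four_taxon_tree():
    # ((A:1,B:1)C:2,D:3)R;
    return make_tree(
        {"C": "R", "D": "R", "A": "C", "B": "C"},
        {"R": 3.0, "C": 1.0, "D": 0.0, "A": 0.0, "B": 0.0},
    )


@pytest.fixture
def worksheet_tree():
    """3-leaf tree with known ages, locations and node traits used for the
    hand-computed node-pair worksheet."""
    tree = make_tree(
        {"A": "R", "B": "R", "C": "A", "D": "A"},
        {"R": 3.0, "A": 1.0, "B": 0.0, "C": 0.0, "D": 0.0},
        locations={
            "R": (0.0, 0.0), "A": (0.0, 0.5), "B": (0.0, 4.0),
            "C": (0.0, 0.4), "D": (0.0, 0.7),
        },
    )
    tree.set_trait("trait", {"R": 2.0, "A": 3.0, "B": 1.0, "C": 4.0, "D": 2.0})
    tree.set_trait("humidity", {"R": 1.0, "A": 2.0, "B": 0.0, "C": 2.5, "D": 1.5})
    return tree


def founder_null_config(n_tips=200, seed=0):
    return SimulationConfig(
        n_tips=n_tips, seed=seed, founder_jump=FounderJump(),
        trait=TraitModelConfig(kind="null"),
    )


@pytest.fixture
def founder_dataset():
    return simulate_dataset(founder_null_config(n_tips=100, seed=11))


def humidity_of(tree):
    return {nid: tree.nodes[nid].traits["humidity"] for nid in tree.node_ids}


def trait_of(tree):
    return {nid: tree.nodes[nid].traits["trait"] for nid in tree.node_ids}


def random_tree(rng, n_tips=6, crown_age=4.0):
    cfg = SimulationConfig(n_tips=n_tips, crown_age=crown_age,
                           seed=int(rng.integers(2**31 - 1)))
    return simulate_dataset(cfg)
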