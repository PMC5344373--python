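from __future__ import annotations

import numpy as np
import pytest

from syntroflux import config
from syntroflux.core import Metabolite, Reaction, build_model
from syntroflux.dfba import SimulationConfig, simulate_batch


@pytest.fixture
def chain_model():
    """Minimal uptake -> growth chain: 1x2 internal matrix [[+1, -1]]."""
    mets = [
        Metabolite("A_ext", compartment="external"),
        Metabolite("A", compartment="internal"),
    ]
    rxns = [
        Reaction("uptake", {"A_ext": -1, "A": 1}, 0, 10, is_exchange=True),
        Reaction("growth", {"A": -1}, 0, 1000),
    ]
    return build_model(mets, rxns, "growth")


@pytest.fixture
def diamond_symmetric():
    """Two equivalent parallel routes A -> B; total flux T = 10."""
    mets = [
        Metabolite("A_ext", compartment="external"),
        Metabolite("A"),
        Metabolite("B"),
    ]
    rxns = [
        Reaction("up", {"A_ext": -1, "A": 1}, 0, 10, is_exchange=True),
        Reaction("p1", {"A": -1, "B": 1}, 0, 1000),
        Reaction("p2", {"A": -1, "B": 1}, 0, 1000),
        Reaction("growth", {"B": -1}, 0, 1000),
    ]
    return build_model(mets, rxns, "growth")


@pytest.fixture
def diamond_asymmetric():
    """Parallel routes of unequal length: p1 direct, p2 via two steps."""
    mets = [
        Metabolite("A_ext", compartment="external"),
        Metabolite("A"),
        Metabolite("B"),
        Metabolite("C"),
    ]
    rxns = [
        Reaction("up", {"A_ext": -1, "A": 1}, 0, 10, is_exchange=True),
        Reaction("p1", {"A": -1, "B": 1}, 0, 1000),
        Reaction("p2a", {"A": -1, "C": 1}, 0, 1000),
        Reaction("p2b", {"C": -1, "B": 1}, 0, 1000),
        Reaction("growth", {"B": -1}, 0, 1000),
    ]
    return build_model(mets, rxns, "growth")


class _BatchCache:
    """Session cache of the expensive full-batch co-culture simulations."""

    def __init__(self):
        self._store = {}

    def get(self, name: str, optimal: bool = False):
        key = (name, optimal)
        if key not in self._store:
            cond = config.condition(name)
            com = config.build_community(cond, optimal=optimal)
            tc = simulate_batch(
                com, cond.initial_state, SimulationConfig(t_end=30.0, dt=0.01)
            )
            tc.condition = name
            self._store[key] = (cond, com, tc)
        return self._store[key]


@pytest.fixture(scope="session")
def batches():
    return _BatchCache()


@pytest.fixture(scope="session")
def mono_clostridium_nh4():
    """Fermenter monoculture in the ammonium condition (fast fixture used
    by fitting and synthetic-data tests)."""
    cond = config.condition("NH4")
    com = config.build_community(cond, species=("clostridium",))
    cfg = SimulationConfig(t_end=12.0, dt=0.05)
    tc = simulate_batch(com, cond.initial_state, cfg)
    tc.condition = "NH4"
    return cond, com, tc, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)
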