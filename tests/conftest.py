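"""Shared fixtures: tiny hand-built networks and random-instance helpers."""

from __future__ import annotations

import numpy as np
import pytest

from bmlp.network import GprRule, MetabolicNetwork, Reaction


def random_network(rng: np.random.Generator, max_mets: int = 30, max_rxns: int = 40) -> MetabolicNetwork:
    """A random directed reaction network (no gene rules) for engine tests."""
    n_m = int(rng.integers(2, max_mets + 1))
    n_r = int(rng.integers(1, max_rxns + 1))
    metabolites = [f"m{i}" for i in range(n_m)]
    reactions = []
    for j in range(n_r):
        k_in = int(rng.integers(0, min(3, n_m) + 1))
        k_out = int(rng.integers(1, min(3, n_m) + 1))
        reactants = frozenset(int(x) for x in rng.choice(n_m, size=k_in, replace=False))
        products = frozenset(int(x) for x in rng.choice(n_m, size=k_out, replace=False))
        reactions.append(Reaction(f"r{j}", reactants, products, GprRule.spontaneous()))
    return MetabolicNetwork(metabolites, [], reactions)


def random_medium(rng: np.random.Generator, network: MetabolicNetwork) -> set[str]:
    n = network.n_metabolites
    k = int(rng.integers(0, n + 1))
    picks = rng.choice(n, size=k, replace=False)
    return {network.metabolites[int(i)] for i in picks}


@pytest.fixture
def chain_network() -> MetabolicNetwork:
    """a -> b -> c, single-gene rules."""
    return MetabolicNetwork(
        ["a", "b", "c"],
        ["g1", "g2"],
        [
            Reaction("R1", frozenset({0}), frozenset({1}), GprRule.leaf("g1")),
            Reaction("R2", frozenset({1}), frozenset({2}), GprRule.leaf("g2")),
        ],
    )


@pytest.fixture
def diamond_network() -> MetabolicNetwork:
    """{a}->{b}, {a}->{c}, {b,c}->{d}; all spontaneous."""
    return MetabolicNetwork(
        ["a", "b", "c", "d"],
        [],
        [
            Reaction("R1", frozenset({0}), frozenset({1}), GprRule.spontaneous()),
            Reaction("R2", frozenset({0}), frozenset({2}), GprRule.spontaneous()),
            Reaction("R3", frozenset({1, 2}), frozenset({3}), GprRule.spontaneous()),
        ],
    )


@pytest.fixture
def pathway_fixture() -> dict:
    """5-metabolite essential-pathway fixture for prediction tests.

    Medium {a}; chain a -> b -> e (essential) where the b -> e step (Rx) has
    a masked rule, plus an isoenzyme reaction a -> c with rule OR(g1, g2).
    Gene g3 is the true catalyst of Rx.
    """
    network = MetabolicNetwork(
        ["a", "b", "c", "d", "e"],
        ["g1", "g2", "g3", "g4"],
        [
            Reaction("Ra", frozenset({0}), frozenset({1}), GprRule.leaf("g4")),
            Reaction("Riso", frozenset({0}), frozenset({2}), GprRule.or_(GprRule.leaf("g1"), GprRule.leaf("g2"))),
            Reaction("Rc", frozenset({2}), frozenset({3}), GprRule.spontaneous()),
            Reaction("Rx", frozenset({1}), frozenset({4}), GprRule.unknown()),
        ],
    )
    return {
        "network": network,
        "base_medium": {"a"},
        "essential": ["e"],
        "true_facts": [("g3", "Rx")],
    }
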