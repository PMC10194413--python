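from __future__ import annotations

import numpy as np
import pytest

from causalmaps.map_model import CausalMap


def random_map(rng: np.random.Generator, n_max: int = 8, p: float = 0.3,
               p_negative: float = 0.35, map_id: str = "rand") -> CausalMap:
    """Random signed digraph on up to ``n_max`` nodes (no self-loops)."""
    n = int(rng.integers(2, n_max + 1))
    labels = [f"n{i}" for i in range(n)]
    m = CausalMap(map_id=map_id)
    for lbl in labels:
        m.add_concept(lbl)
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                sign = -1 if rng.random() < p_negative else 1
                m.add_edge(labels[i], labels[j], sign)
    return m


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20261001)


@pytest.fixture
def chain_map() -> CausalMap:
    m = CausalMap(map_id="chain")
    m.add_edge("A", "B", 1)
    m.add_edge("B", "C", -1)
    return m
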