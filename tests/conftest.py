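import numpy as np
import pandas as pd
import pytest

from crepipe.diffexp import DESignature
from crepipe.io import CausalGraph, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_matrix():
    """Two conditions x three replicates, four probes, log2 scale."""
    data = pd.DataFrame(
        {
            "a1": [8.0, 6.0, 10.0, 5.0],
            "a2": [8.2, 6.1, 10.1, 5.2],
            "a3": [7.8, 5.9, 9.9, 4.8],
            "b1": [9.0, 6.0, 8.0, 5.1],
            "b2": [9.2, 6.2, 8.1, 5.0],
            "b3": [8.8, 5.8, 7.9, 4.9],
        },
        index=["p1", "p2", "p3", "p4"],
    )
    cond = {s: ("A" if s.startswith("a") else "B") for s in data.columns}
    return ExpressionMatrix(data, cond)


@pytest.fixture
def toy_graph():
    g = CausalGraph()
    g.add_edge("R", "g1", +1)
    g.add_edge("R", "g2", +1)
    g.add_edge("R", "g3", -1)
    g.add_edge("S", "g2", -1)
    g.add_edge("S", "g4", +1)
    return g


def make_signature(directions: dict[str, int], condition="kd") -> DESignature:
    fold = {g: d * 2.0 for g, d in directions.items()}
    return DESignature(condition, dict(directions), fold,
                       {g: g for g in directions})


@pytest.fixture
def signature_factory():
    return make_signature
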