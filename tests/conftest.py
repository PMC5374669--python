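import numpy as np
import pytest

from fgsig import ScoreSpec, build_factor_graph


@pytest.fixture
def two_var_graph():
    """Two binary variables: unary factor on x1, pairwise on (x1, x2)."""
    return build_factor_graph(
        [("x1", 2), ("x2", 2)],
        [("a", ("x1",), np.array([0.5, 0.5])),
         ("b", ("x1", "x2"), np.array([[0.9, 0.1], [0.2, 0.8]]))],
    )


@pytest.fixture
def bernoulli():
    """Bernoulli(0.3) with the event-indicator score S = Y."""
    g = build_factor_graph([("y", 2)], [("f", ("y",), np.array([0.7, 0.3]))])
    return g, ScoreSpec(g, [np.array([0.0, 1.0])])


def small_fixtures(n=12, max_vars=8, max_configs=200_000):
    """Deterministic stream of small random tree fixtures for oracle checks."""
    from fgsig import random_tree_fixture

    out = []
    seed = 0
    while len(out) < n:
        n_vars = 3 + seed % (max_vars - 2)
        g, s = random_tree_fixture(n_vars, max_states=4, seed=seed)
        if g.n_configurations <= max_configs:
            out.append((seed, g, s))
        seed += 1
    return out
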