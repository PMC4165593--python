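import numpy as np
import pandas as pd
import pytest

import traitnet as tn


@pytest.fixture(scope="session")
def default_spec():
    return tn.default_paracou_like_spec()


@pytest.fixture(scope="session")
def default_data(default_spec):
    """A large sample from the default ten-node SEM."""
    return tn.simulate_sem(default_spec, n=2000, seed=101)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def trivariate_chain():
    """Data from the chain A -> B -> C with moderate coefficients."""
    dag = tn.Dag.from_edges(["A", "B", "C"], [("A", "B"), ("B", "C")])
    spec = tn.SemSpec(
        dag=dag,
        intercepts={v: 0.0 for v in dag.nodes},
        coefficients={("A", "B"): 0.7, ("B", "C"): 0.7},
        sigmas={v: 1.0 for v in dag.nodes},
        n=1000,
        seed=42,
    )
    return spec, tn.simulate_sem(spec)


def random_correlation(rng, p):
    """Random positive-definite correlation matrix."""
    A = rng.normal(size=(p, 2 * p))
    S = A @ A.T / (2 * p)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def tiny_census():
    """Hand-built census: 3 trees over 3 years, one flagged death."""
    rows = [
        # tree a: alive throughout
        ("a", "SP", 2000, 20.0, "alive", False),
        ("a", "SP", 2001, 20.5, "alive", False),
        ("a", "SP", 2002, 21.0, "alive", False),
        # tree b: dies (not excluded)
        ("b", "SP", 2000, 15.0, "alive", False),
        ("b", "SP", 2001, 15.0, "dead", False),
        # tree c: recruited in 2001
        ("c", "SP", 2001, 10.1, "recruited", False),
        ("c", "SP", 2002, 10.4, "alive", False),
    ]
    return pd.DataFrame(
        rows,
        columns=["tree_id", "species_id", "year", "dbh", "status", "excluded"],
    )
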