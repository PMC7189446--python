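"""Shared fixtures: small layouts and simulated matrices."""

import numpy as np
import pytest

import territoria as t


@pytest.fixture(scope="session")
def toy_layout():
    """3 subgenomes x 2 chromosomes x 1 Mb at 100 kb (10 bins per chromosome)."""
    return t.make_layout(3, 2, 1_000_000, 100_000)


@pytest.fixture(scope="session")
def null_params():
    """No planted structure: pure decay + territory hierarchy."""
    return t.SimParams(
        seed=11, n_domains=0, loop_rate=0, inter_loop_rate=0,
        domain_depletion=1.0, rabl_strength=1.0,
    )


@pytest.fixture(scope="session")
def structured_sim():
    """Default study conditions on a 6 x 4.2-Mb genome at 25 kb, seed 7."""
    layout = t.make_layout(3, 2, 4_200_000, 25_000)
    params = t.SimParams(seed=7)
    matrix, truth = t.simulate_contacts(layout, params)
    genes = t.simulate_genes_and_expression(layout, truth, params)
    return layout, params, matrix, truth, genes


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
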