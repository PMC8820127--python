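"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pytest

from opsinsel.site_models import get_model
from opsinsel.synthetic_data import simulate_codon_alignment, simulate_tree


@pytest.fixture(scope="session")
def uniform_pi():
    return np.full(61, 1.0 / 61)


@pytest.fixture(scope="session")
def m0_dataset(uniform_pi):
    """8 taxa x 200 codons simulated under M0 (omega 0.2, kappa 2)."""
    tree = simulate_tree(8, seed=101)
    aln, truth = simulate_codon_alignment(
        tree, get_model("M0"), {"omega": 0.2}, 200, kappa=2.0, pi=uniform_pi, seed=102
    )
    return aln, tree, truth


@pytest.fixture(scope="session")
def m8_dataset(uniform_pi):
    """8 taxa x 200 codons simulated under M8 with a 10% positive class."""
    tree = simulate_tree(8, seed=201)
    theta = {"p0": 0.9, "p": 0.5, "q": 1.5, "omega_s": 3.0}
    aln, truth = simulate_codon_alignment(
        tree, get_model("M8"), theta, 200, kappa=2.0, pi=uniform_pi, seed=202
    )
    return aln, tree, truth
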