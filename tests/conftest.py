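import numpy as np
import pytest

import phaselattice as pl


@pytest.fixture(scope="session")
def limit_cycle() -> pl.LimitCycle:
    """Converged Wang-Buzsaki limit cycle with adjoint (shared, ~10 s)."""
    return pl.compute_adjoint(pl.find_limit_cycle())


@pytest.fixture(scope="session")
def interaction(limit_cycle) -> pl.InteractionFunction:
    return pl.interaction_function(limit_cycle)


@pytest.fixture(scope="session")
def h_prime(interaction):
    return interaction.derivative()


@pytest.fixture(scope="session")
def h_odd_prime(interaction):
    return interaction.odd_part().derivative()


@pytest.fixture(scope="session")
def phase_tol(limit_cycle) -> float:
    """Pattern-matching tolerance: two milliseconds of phase."""
    return 2.0 * np.pi * 2.0 / limit_cycle.T
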