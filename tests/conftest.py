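import numpy as np
import pytest

from mcat4pl import BankSpec, ItemBank, ItemParameters, generate_bank


@pytest.fixture
def item_2pl():
    """Unit-slope 2PL item centered at zero."""
    return ItemParameters("i2pl", np.array([1.0]), 0.0)


@pytest.fixture
def bank_1d():
    """Five 1-D 2PL items spread over the difficulty range."""
    items = [
        ItemParameters(f"b{k}", np.array([a]), d)
        for k, (a, d) in enumerate(
            [(1.0, 0.0), (2.0, 0.0), (1.5, -1.0), (1.5, 1.0), (0.8, 2.0)]
        )
    ]
    return ItemBank(items=items, n_dimensions=1, starting_items={"4": "b2", "5": "b0", "6": "b3"})


@pytest.fixture
def bank_2d():
    """Two orthogonal unit-slope 2PL items plus two loaded 4PL items."""
    items = [
        ItemParameters("x1", np.array([1.0, 0.0]), 0.0),
        ItemParameters("x2", np.array([0.0, 1.0]), 0.0),
        ItemParameters("x3", np.array([1.5, 0.0]), -0.5, 0.2, 0.95),
        ItemParameters("x4", np.array([0.0, 1.2]), 0.8, 0.1, 0.9),
    ]
    return ItemBank(items=items, n_dimensions=2)


@pytest.fixture(scope="session")
def small_bank():
    """Compact generated bank (seeded) for session-level tests."""
    spec = BankSpec(
        scale_sizes=(8, 6, 5, 6, 8, 7),
        n_nuisance=1,
        n_excellent=6,
    )
    return generate_bank(spec, seed=11)


def respond_from_vector(bank, responses):
    index = {iid: k for k, iid in enumerate(bank.item_ids)}
    return lambda iid: int(responses[index[iid]])
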