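import numpy as np
import pytest

from catrend import GenotypeTable, make_table


@pytest.fixture(scope="session")
def enos_table() -> GenotypeTable:
    """eNOS -786T>C counts: 421 breast-cancer cases, 423 controls."""
    return make_table(167, 200, 54, 203, 185, 35)


def random_table(rng: np.random.Generator, r_x: int, r_y: int) -> GenotypeTable:
    """Random 2x3 table with fixed arm sizes and random genotype frequencies."""
    p = rng.dirichlet([1.0, 1.0, 1.0])
    q = rng.dirichlet([1.0, 1.0, 1.0])
    x = rng.multinomial(r_x, p)
    y = rng.multinomial(r_y, q)
    return make_table(*x.tolist(), *y.tolist())
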