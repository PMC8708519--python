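import numpy as np
import pytest

import mycomap as mm

CODES = np.array(["N", "H", "A", "V"])


def random_grid(rng, p_colonized=0.3, p_arb=0.15, p_ves=0.05) -> np.ndarray:
    """Random 10x10 grid of cell codes with independent cells."""
    p = p_colonized
    probs = [1 - p, p * (1 - p_arb - p_ves), p * p_arb, p * p_ves]
    return rng.choice(CODES, size=(10, 10), p=probs)


def brute_force_metrics(cells) -> dict:
    """Plain-loop enumerator of the grid-derived parameters (test oracle)."""
    cells = [list(row) for row in np.asarray(cells)]
    occupied_rows = 0
    for r in range(10):
        if any(cells[r][c] != "N" for c in range(10)):
            occupied_rows += 1
    occupied_cols = 0
    for c in range(10):
        if any(cells[r][c] != "N" for r in range(10)):
            occupied_cols += 1
    k = sum(cells[r][c] != "N" for r in range(10) for c in range(10))
    a = sum(cells[r][c] == "A" for r in range(10) for c in range(10))
    v = sum(cells[r][c] == "V" for r in range(10) for c in range(10))
    freq = 100.0 * (occupied_rows + occupied_cols) / 20.0
    inten = 100.0 * k / 100.0
    return {
        "frequency": freq,
        "intensity": inten,
        "arbuscules": 100.0 * a / 100.0,
        "vesicles": 100.0 * v / 100.0,
        "degree": freq * inten / 100.0,
        "non_mycorrhizal": 100.0 - inten,
    }


@pytest.fixture(scope="session")
def design_data():
    """One full simulated design (390 maps, 5850 field observations)."""
    return mm.generate_design(seed=7)


@pytest.fixture(scope="session")
def design_table(design_data):
    return design_data[1]


@pytest.fixture(scope="session")
def design_maps(design_data):
    return design_data[0]
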