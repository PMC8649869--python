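import numpy as np
import pandas as pd
import pytest

from dropscreen.matrix import CountMatrix
from dropscreen.synthetic import generate_library, plant_screen_truth


@pytest.fixture(scope="session")
def small_library():
    return generate_library(n_genes=20, shrnas_per_gene=4, barcode_length=12, seed=3)


@pytest.fixture(scope="session")
def planted_screen():
    """100-gene screen with 10 drivers and 5 acute-essential genes."""
    from dropscreen.synthetic import ScreenDesign, simulate_screen

    library = generate_library(n_genes=100, shrnas_per_gene=8, barcode_length=18, seed=11)
    truth = plant_screen_truth(library, n_drivers=10, n_acute=5, seed=12)
    design = ScreenDesign()
    counts = simulate_screen(library, truth, design, seed=13)
    return library, truth, design, counts


@pytest.fixture()
def random_counts():
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.integers(1, 500, size=(50, 6)),
        index=pd.Index([f"f{i}" for i in range(50)], name="feature_id"),
        columns=[f"s{j}" for j in range(6)],
    )
    return CountMatrix(values=values)
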