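import numpy as np
import pytest

from arqsar import DescriptorTable, SyntheticSpec, generate, load_published_data


@pytest.fixture(scope="session")
def fixture():
    """Packaged published reference data, values as printed."""
    return load_published_data()


@pytest.fixture(scope="session")
def fixture_corrected():
    """Reference data with training compound 7's predicted value corrected."""
    return load_published_data(correct_compound7=True)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_table(rng):
    """20 compounds x 5 independent Gaussian descriptors."""
    return DescriptorTable(
        tuple(f"c{i}" for i in range(20)),
        ("A", "B", "C", "D", "E"),
        rng.standard_normal((20, 5)),
    )


@pytest.fixture(scope="session")
def planted():
    """Default-scale synthetic dataset (29 train / 7 ext / 110 screen) with a
    planted 4-descriptor signal and known ground truth."""
    spec = SyntheticSpec(seed=7, n_correlated_pairs=5, n_outlier_screen=26)
    table, activities, truth = generate(spec)
    return spec, table, activities, truth


def make_xy(n, p, seed, beta=None, noise=0.1):
    """Small regression instance with a known linear signal."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    if beta is None:
        beta = rng.uniform(0.5, 1.5, size=p) * rng.choice([-1, 1], size=p)
    y = 1.0 + X @ beta + noise * rng.standard_normal(n)
    table = DescriptorTable(
        tuple(f"c{i}" for i in range(n)),
        tuple(f"x{j}" for j in range(p)),
        X,
    )
    return table, y
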