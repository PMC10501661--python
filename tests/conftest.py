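import numpy as np
import pytest

from rsim import CountMatrix, SimulationConfig, generate


@pytest.fixture
def toy_counts() -> CountMatrix:
    """3 taxa x 2 samples with known column sums 4 and 7."""
    return CountMatrix(
        np.array([[1, 2], [0, 5], [3, 0]]),
        ("tA", "tB", "tC"),
        ("s1", "s2"),
    )


@pytest.fixture
def proportional_counts() -> tuple[CountMatrix, np.ndarray]:
    """Noiseless proportional model N_ij = c_i * A_j with distinct c_i."""
    rng = np.random.default_rng(7)
    d, n = 50, 20
    base = rng.integers(1, 30, size=d)
    c = np.arange(1, n + 1)
    counts = np.outer(base, c)
    cm = CountMatrix(
        counts,
        tuple(f"t{j}" for j in range(d)),
        tuple(f"s{i}" for i in range(n)),
    )
    return cm, c.astype(float)


@pytest.fixture
def small_random_counts() -> CountMatrix:
    """6 taxa x 10 samples of small random integers, no constant rows."""
    rng = np.random.default_rng(11)
    counts = rng.integers(0, 40, size=(6, 10))
    counts[:, 0] += np.arange(6)  # guards against an all-constant row
    return CountMatrix(
        counts,
        tuple(f"t{j}" for j in range(6)),
        tuple(f"s{i}" for i in range(10)),
    )


@pytest.fixture(scope="session")
def strong_signal_sim():
    """One strong-signal replicate of the default study design."""
    return generate(SimulationConfig(seed=123))
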