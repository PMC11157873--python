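import numpy as np
import pytest

from radcombat import FeatureTable, SimulationConfig, simulate_features


@pytest.fixture(scope="session")
def study_table():
    """The study-structure simulation with strong batch effects."""
    cfg = SimulationConfig(
        n_per_batch=[53, 42, 40],
        n_features=100,
        additive_effect_scale=1.5,
        multiplicative_effect_range=(0.5, 2.0),
        noise_sd=1.0,
        seed=0,
    )
    return simulate_features(cfg)


@pytest.fixture(scope="session")
def small_fixture_table():
    """Fixed 3-batch, 20-feature table for oracle-equivalence checks."""
    cfg = SimulationConfig(
        n_per_batch=[12, 10, 8],
        n_features=20,
        additive_effect_scale=1.0,
        multiplicative_effect_range=(0.7, 1.4),
        seed=42,
    )
    table, _ = simulate_features(cfg)
    return table


def make_informative_table(
    n_per_class=60, n_features=100, n_informative=25, effect=1.5, seed=0
):
    """Two balanced classes; the first n_informative features carry the
    class effect, the rest are independent noise."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    y = np.r_[np.zeros(n_per_class, dtype=int), np.ones(n_per_class, dtype=int)]
    X = rng.normal(0, 1, (n, n_features))
    X[:, :n_informative] += y[:, None] * effect
    return FeatureTable(
        X,
        [f"f{g:03d}" for g in range(n_features)],
        np.where(np.arange(n) % 2 == 0, "batchA", "batchB"),
        y,
    )
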