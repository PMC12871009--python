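import numpy as np

from missarf.dataset import Dataset, Feature, Schema


def continuous_schema(p, prefix="x"):
    return Schema([Feature(f"{prefix}{j+1}", "continuous") for j in range(p)])


def make_two_cluster_data(n_per=100, sd=0.1, seed=0) -> Dataset:
    """Two Gaussian clusters around (-1, 1) and (1, -1)."""
    rng = np.random.default_rng(seed)
    a = rng.normal([-1.0, 1.0], sd, size=(n_per, 2))
    b = rng.normal([1.0, -1.0], sd, size=(n_per, 2))
    return Dataset(np.vstack([a, b]), continuous_schema(2))
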