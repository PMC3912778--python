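import numpy as np
import pandas as pd
import pytest

from ehgkit.features import FEATURE_NAMES


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_feature_table(
    n_per_class: int,
    rng: np.random.Generator,
    informative: tuple[str, ...] = ("E3", "RA"),
    separation: float = 6.0,
    n_groups: int = 10,
) -> pd.DataFrame:
    """Synthetic labeled table: Gaussian features, `informative` ones shifted
    by `separation` SDs for the artifacted class, the rest pure noise."""
    rows = []
    for label, shift in (("nonartifacted", 0.0), ("artifacted", separation)):
        for i in range(n_per_class):
            row = {f: rng.normal() for f in FEATURE_NAMES}
            for f in informative:
                row[f] += shift
            row["label"] = label
            row["group_id"] = i % n_groups
            rows.append(row)
    return pd.DataFrame(rows)


def make_rings_table(n_per_class: int, rng: np.random.Generator) -> pd.DataFrame:
    """Concentric-ring two-feature problem: linearly inseparable."""
    rows = []
    for label, radius in (("nonartifacted", 1.0), ("artifacted", 3.0)):
        theta = rng.uniform(0, 2 * np.pi, n_per_class)
        r = radius + rng.normal(0, 0.2, n_per_class)
        for x, y in zip(r * np.cos(theta), r * np.sin(theta)):
            row = {f: 0.0 for f in FEATURE_NAMES}
            row["E3"], row["RA"] = x, y
            row["label"] = label
            rows.append(row)
    return pd.DataFrame(rows)
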