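import numpy as np
import pytest

from wildgut import AbundanceTable, PhyloTree, SampleMeta


def make_samples(groups):
    """SampleMeta list from a group-label list, ids g_0, g_1, ..."""
    return [
        SampleMeta(f"s{i}_{g}", g, 1_000_000) for i, g in enumerate(groups)
    ]


def random_table(rng, n_sgbs, groups, zero_frac=0.2):
    values = rng.lognormal(3.0, 1.0, size=(n_sgbs, len(groups)))
    values[rng.random(values.shape) < zero_frac] = 0.0
    return AbundanceTable(
        [f"SGB_{i + 1:04d}" for i in range(n_sgbs)], make_samples(groups), values
    )


def random_tree(rng, labels):
    """Random binary tree over the given leaf labels (uniform joins)."""
    parts = [f"{lbl}:{rng.uniform(0.05, 1.0):.6f}" for lbl in labels]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        parts.append(f"({a},{b}):{rng.uniform(0.05, 1.0):.6f}")
    newick = f"({parts[0]});" if len(labels) == 1 else parts[0][: parts[0].rfind(":")] + ";"
    return PhyloTree.from_newick(newick)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_group_table(rng):
    return random_table(rng, 12, ["g1"] * 4 + ["g2"] * 4 + ["g3"] * 4)
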