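import numpy as np
import pandas as pd
import pytest
import skbio

from phylosym import FeatureTable, SampleMetadata


@pytest.fixture
def tiny_table():
    """2 taxa x 2 samples with easy hand arithmetic."""
    return FeatureTable(pd.DataFrame(
        [[3, 0], [1, 2]], index=["ta", "tb"], columns=["s1", "s2"]
    ))


@pytest.fixture
def small_table():
    """6 taxa x 6 samples, two species with three replicates each."""
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 50, size=(6, 6))
    counts[0] += 30  # one clearly dominant, ubiquitous taxon
    return FeatureTable(pd.DataFrame(
        counts,
        index=[f"t{i}" for i in range(6)],
        columns=[f"s{j}" for j in range(6)],
    ))


@pytest.fixture
def small_metadata(small_table):
    rows = []
    for j, sid in enumerate(small_table.sample_ids):
        rows.append({
            "sample_id": sid,
            "species": "spA" if j < 3 else "spB",
            "divergence_class": "early" if j < 3 else "late",
            "ploidy": "diploid",
            "life_cycle": "annual",
            "compartment": "root",
            "genome_type": "AA",
            "grain_weight": 0.02 + 0.001 * j,
        })
    return SampleMetadata(pd.DataFrame(rows))


@pytest.fixture
def balanced_tree():
    """4-leaf balanced tree, unit branches including the root edge."""
    return skbio.TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1):1;"])


@pytest.fixture
def triplet_tree():
    return skbio.TreeNode.read(["((A:1,B:1):1,C:2):0;"])
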