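import numpy as np
import pandas as pd
import pytest

import farmbiome as fb


@pytest.fixture(scope="session")
def wall_dataset():
    """Default wall-like synthetic dataset (57 genera, 3+3 farms x 2 pools)."""
    return fb.generate_dataset(fb.SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def scaled_wall(wall_dataset):
    """Preprocessed (filter -> replace -> ALR -> autoscale) wall dataset."""
    counts, meta, truth = wall_dataset
    filtered = fb.filter_sparse_genera(counts, meta)
    replaced = fb.replace_zeros(filtered)
    alr = fb.alr_transform(replaced, fb.select_alr_reference(replaced))
    scaled, _ = fb.autoscale(alr)
    labels = meta.set_index("sample_id")["status"].loc[scaled.index].to_numpy()
    return scaled, labels, truth


@pytest.fixture
def toy_counts():
    """6 HHS + 6 LHS samples, hand-sized zero patterns per genus.

    g_clean: no zeros anywhere.
    g_half_lhs: 3 zeros among the 6 LHS samples (50%).
    g_third: exactly 2 zeros in HHS (33.3%), none in LHS.
    g_sixth: exactly 1 zero in each status (16.7%).
    """
    counts = pd.DataFrame(
        {
            "g_clean": [5, 6, 7, 8, 9, 10, 5, 6, 7, 8, 9, 10],
            "g_half_lhs": [4, 4, 4, 4, 4, 4, 0, 0, 0, 9, 9, 9],
            "g_third": [0, 0, 3, 3, 3, 3, 2, 2, 2, 2, 2, 2],
            "g_sixth": [0, 5, 5, 5, 5, 5, 0, 5, 5, 5, 5, 5],
        },
        index=pd.Index([f"s{i}" for i in range(12)], name="sample_id"),
    )
    meta = pd.DataFrame(
        {
            "sample_id": counts.index,
            "status": ["HHS"] * 6 + ["LHS"] * 6,
            "sample_type": ["wall"] * 12,
            "farm_id": [f"f{i // 2}" for i in range(12)],
        }
    )
    return counts, meta
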