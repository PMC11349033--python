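import warnings

import numpy as np
import pytest
from sklearn.exceptions import ConvergenceWarning

from netla import build_block_map, build_edge_index
from netla.synthetic import EffectSpec, FamilyLayout, generate_dataset, generate_partition

# liblinear occasionally stops at max_iter on small noisy fits; the warning is
# informative in interactive use but noise in the suite
warnings.filterwarnings("ignore", category=ConvergenceWarning)


@pytest.fixture(scope="session")
def small_partition():
    """30 parcels in 6 equal networks (E=435, B=21)."""
    return generate_partition(30, [5] * 6)


@pytest.fixture(scope="session")
def small_block_map(small_partition):
    return build_block_map(small_partition, build_edge_index(30))


@pytest.fixture(scope="session")
def null_dataset_pair(small_partition):
    """Two-day dataset with no age effect anywhere."""
    layout = FamilyLayout(n_families=60, members=(1, 3))
    return generate_dataset(small_partition, layout, EffectSpec(), seed=7)


@pytest.fixture(scope="session")
def planted_dataset_pair(small_partition):
    """Two-day dataset with one strongly enriched block (block 0)."""
    from netla.synthetic import beta_for_target_r

    effects = EffectSpec(block_betas={0: beta_for_target_r(0.4, EffectSpec())})
    layout = FamilyLayout(n_families=80, members=(2, 2))
    return generate_dataset(small_partition, layout, effects, seed=11)
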