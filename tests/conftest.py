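import numpy as np
import pandas as pd
import pytest

from mavemap.simulate import (SimulationConfig, simulate_screen,
                              simulate_true_effects, synthetic_orf)
from mavemap.variants import enumerate_variant_space


@pytest.fixture(scope="session")
def orf():
    return synthetic_orf(n_codons=154, seed=7)


@pytest.fixture(scope="session")
def space(orf):
    return enumerate_variant_space(orf)


@pytest.fixture(scope="session")
def sim_cfg():
    """Default scaled-down study conditions, seed pinned."""
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def effects(space, sim_cfg):
    return simulate_true_effects(space, sim_cfg)


@pytest.fixture(scope="session")
def growth_counts(effects, sim_cfg):
    return simulate_screen(effects, sim_cfg, assay="growth")


@pytest.fixture(scope="session")
def effect_map(growth_counts, effects):
    from mavemap.scoring import score_pipeline
    return score_pipeline(growth_counts, variant_info=effects)


def make_toy_bundle(rows):
    """Tidy counts table from (tile, condition, replicate, variant, count, depth)."""
    return pd.DataFrame(
        rows, columns=["tile", "condition", "replicate", "variant",
                       "count", "depth"])


@pytest.fixture()
def toy_scores():
    """A small labeled score set for curve oracles."""
    rng = np.random.default_rng(5)
    pos = rng.normal(0.25, 0.15, 6)
    neg = rng.normal(0.85, 0.15, 6)
    return pd.DataFrame({
        "score": np.concatenate([pos, neg]),
        "label": ["positive"] * 6 + ["negative"] * 6,
    })
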