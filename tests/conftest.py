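"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sdleeg import GeneratorConfig, PipelineConfig, gen_background
from sdleeg.pipeline import build_feature_table
from sdleeg.synthetic import gen_epileptiform


@pytest.fixture(scope="session")
def gen_cfg() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def pipe_cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def background_epoch(gen_cfg):
    return gen_background(gen_cfg, seed=42)


@pytest.fixture(scope="session")
def sinusoid_period40():
    return np.sin(2 * np.pi * np.arange(1024) / 40)


@pytest.fixture(scope="session")
def feature_table_small(pipe_cfg) -> pd.DataFrame:
    """Features of 60 normal + 60 epileptiform seeded epochs.

    Computed once per session; used by every empirical
    class-separation check.
    """
    rng = np.random.default_rng(2024)
    subtypes = ["spike", "sharp", "spike_slow", "sharp_slow",
                "polyspike", "polyspike_slow"]
    epochs = []
    for k in range(60):
        seed = int(rng.integers(0, 2 ** 31))
        epochs.append(gen_background(pipe_cfg.generator, seed,
                                     epoch_id=f"n{k}"))
    for k in range(60):
        seed = int(rng.integers(0, 2 ** 31))
        epochs.append(gen_epileptiform(subtypes[k % len(subtypes)],
                                       pipe_cfg.generator, seed,
                                       epoch_id=f"e{k}"))
    return build_feature_table(epochs, pipe_cfg)
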