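import numpy as np
import pandas as pd
import pytest

from bcl2panel import synth


@pytest.fixture(scope="session")
def demo_run():
    """One small synthetic corpus shared across read-only tests."""
    cfg = synth.demo_config(seed=11)
    probe_matrix, ann, probe_map, gt = synth.generate_dataset(cfg)
    return cfg, probe_matrix, ann, probe_map, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def tiny_config(seed=0, entities=None, **overrides):
    """Small-footprint config for Monte-Carlo loops: 35 genes, 60 probes."""
    if entities is None:
        entities = {e: 20 for e in ("CLL", "MCL", "FL", "DLBCL", "MM")}
    overrides.setdefault("n_probes", 60)
    overrides.setdefault("n_genes", 35)
    overrides.setdefault("probes_per_gene", (1, 2))
    overrides.setdefault("transformed_fraction", {})
    cfg = synth.SynthConfig(seed=seed, entities=entities, **overrides)
    cfg.validate()
    return cfg
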